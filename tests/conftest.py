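import numpy as np
import pandas as pd
import pytest

from dartmap import (
    GenotypeMatrix,
    SimulationConfig,
    simulate_dh_population,
    simulate_truth_map,
)


@pytest.fixture(scope="session")
def truth_small():
    """Three dense chromosomes, 20 markers each."""
    return simulate_truth_map(n_chromosomes=3, markers_per_chr=20, chr_length=60.0, seed=42)


@pytest.fixture(scope="session")
def clean_population(truth_small):
    """A noiseless DH population large enough for accurate r estimates."""
    cfg = SimulationConfig(n_lines=300, missing_rate=0.0, error_rate=0.0, seed=7)
    return simulate_dh_population(truth_small, cfg)


@pytest.fixture()
def tiny_matrix():
    """Hand-built genotype matrix with known segregation patterns."""
    calls = np.array(
        [
            [1, 1, 1, 1, 0, 0, 0, 0],
            [1, 1, 1, 1, 0, 0, 0, 0],
            [0, 0, 0, 0, 1, 1, 1, 1],
            [1, 0, 1, 0, 1, 0, 1, 0],
        ],
        dtype=np.int8,
    )
    quality = pd.DataFrame(
        {
            "q_value": [95.0, 90.0, 85.0, 80.0],
            "call_rate": [100.0, 100.0, 100.0, 100.0],
            "reproducibility": [100.0, 100.0, 100.0, 100.0],
        },
        index=pd.Index(["mA", "mB", "mC", "mD"], name="marker_id"),
    )
    return GenotypeMatrix(
        ["mA", "mB", "mC", "mD"], [f"L{i}" for i in range(8)], calls, quality
    )
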