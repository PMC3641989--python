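"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV with a header row and deterministic column order;
cM positions are written at 2 decimals.  Missing genotype calls are
"NA".  Hit tables follow the 12-column tabular alignment layout.
Schema violations raise with the offending line where applicable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .consensus import ConsensusMap
from .linkage import ComponentMap
from .qc import MISSING, GenotypeMatrix, QUALITY_COLUMNS
from .synthetic_data import BLAST_COLUMNS, TruthChromosome, TruthMap


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, with its default."""

    q_min: float = 77.0
    call_min: float = 97.0
    repro_min: float = 100.0
    alpha: float = 0.01
    min_overlap: int = 20
    r_threshold: float = 0.2
    min_informative: int = 20
    min_shared: int = 3
    min_corr: float = 0.5
    gap_threshold: float = 10.0
    cluster_min_loci: int = 5
    cluster_window: float = 0.01
    identity_threshold: float = 80.0
    e_max: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "q_min": (0, 100), "call_min": (0, 100), "repro_min": (0, 100),
            "alpha": (0, 1), "r_threshold": (0, 0.5), "min_corr": (0, 1),
            "identity_threshold": (0, 100),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes(matrix: GenotypeMatrix, geno_path, quality_path=None) -> None:
    cells = np.where(matrix.calls == MISSING, "NA", matrix.calls.astype(str))
    df = pd.DataFrame(cells, index=pd.Index(matrix.marker_ids, name="marker_id"),
                      columns=matrix.line_ids)
    df.to_csv(geno_path, sep="\t")
    if quality_path is not None:
        q = matrix.quality.copy()
        q.index.name = "marker_id"
        q.to_csv(quality_path, sep="\t", float_format="%.4f")


def read_genotypes(geno_path, quality_path=None) -> GenotypeMatrix:
    df = pd.read_csv(geno_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate marker id {dup} in {geno_path}")
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            v = values[i, j]
            if v == "NA":
                calls[i, j] = MISSING
            elif v in ("0", "1"):
                calls[i, j] = int(v)
            else:
                raise ValueError(
                    f"invalid genotype cell {v!r} at line {i + 2} of {geno_path}"
                )
    quality = pd.DataFrame(columns=list(QUALITY_COLUMNS))
    if quality_path is not None:
        quality = read_quality(quality_path)
    return GenotypeMatrix(df.index.tolist(), df.columns.tolist(), calls, quality)


def read_quality(path) -> pd.DataFrame:
    q = pd.read_csv(path, sep="\t", index_col="marker_id")
    missing = [c for c in QUALITY_COLUMNS if c not in q.columns]
    if missing:
        raise ValueError(f"quality table missing columns {missing}")
    return q


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def write_component_map(cmap: ComponentMap, path) -> None:
    df = cmap.to_frame()
    df["pos_cM"] = df["pos_cM"].map(lambda p: f"{p:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_component_map(path) -> ComponentMap:
    df = pd.read_csv(path, sep="\t")
    required = ["population_id", "chromosome", "marker_id", "pos_cM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"map table missing columns {missing}")
    return ComponentMap.from_frame(df)


def write_consensus(consensus: ConsensusMap, path) -> None:
    df = consensus.to_frame()
    df["pos_cM"] = df["pos_cM"].map(lambda p: f"{p:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_consensus(path) -> ConsensusMap:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    chromosomes = {}
    provenance = {}
    for chrom, sub in df.groupby("chromosome", sort=True):
        chromosomes[str(chrom)] = sub[["marker_id", "pos_cM", "source"]].reset_index(drop=True)
        for m, pops in zip(sub["marker_id"], sub.get("populations", "")):
            provenance[m] = [p for p in str(pops).split(";") if p]
    return ConsensusMap(chromosomes, provenance)


def write_truth_map(truth: TruthMap, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_truth_map(path) -> TruthMap:
    df = pd.read_csv(path, sep="\t")
    chroms = []
    from .linkage import kosambi_inv

    for chrom, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values("pos_cM", kind="stable")
        pos = sub["pos_cM"].to_numpy(dtype=float)
        pos = pos - pos[0]
        chroms.append(
            TruthChromosome(str(chrom), sub["marker_id"].tolist(), pos,
                            kosambi_inv(np.diff(pos)))
        )
    return TruthMap(chroms)


# ---------------------------------------------------------------------------
# Sequences and hits
# ---------------------------------------------------------------------------

def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_hits(hits: pd.DataFrame, path) -> None:
    hits[BLAST_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST_COLUMNS):
        raise ValueError(
            f"expected {len(BLAST_COLUMNS)}-column tabular hits, got {df.shape[1]} columns"
        )
    df.columns = BLAST_COLUMNS
    return df


# ---------------------------------------------------------------------------
# Run logs
# ---------------------------------------------------------------------------

def write_run_log(path, stage: str, config: PipelineConfig, counts: dict) -> None:
    """Machine-readable record of one pipeline stage."""
    import dartmap

    payload = {
        "stage": stage,
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": dartmap.__version__,
        "counts": counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
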