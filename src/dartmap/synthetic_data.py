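"""Synthetic DH populations, clone sequences and scaffold hit tables.

The generator emulates the data regime of biparental doubled-haploid
mapping panels genotyped with a dominant presence/absence array:
population sizes of roughly 71-172 lines, 19 linkage groups (A1-A10,
C1-C9), partial marker sharing between populations, missing calls,
genotyping error and segregation distortion.

Meiosis is modelled as a first-order Markov chain along each
chromosome: the allele at the first marker is Bernoulli(0.5) (or the
distorted allele frequency at named loci) and each subsequent allele
switches parent with probability equal to the interval recombination
fraction.  There is no crossover interference across intervals, which
makes pairwise recombination fractions recoverable exactly in
expectation.  Truth distances are defined in Kosambi cM and converted
to interval fractions by the inverse Kosambi function, so that
estimate -> Kosambi round trips recover the truth positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage import kosambi_inv
from .qc import MISSING, GenotypeMatrix

#: chromosome labels of the amphidiploid A/C genome complement
AC_CHROMOSOMES = [f"A{i}" for i in range(1, 11)] + [f"C{i}" for i in range(1, 10)]

#: DH population sizes of the six study panels (AT, BS, LM, MW, SAS, TN)
POPULATION_SIZES = {"AT": 71, "BS": 134, "LM": 131, "MW": 100, "SAS": 172, "TN": 153}

NUCLEOTIDES = np.array(list("ACGT"))

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class TruthChromosome:
    name: str
    marker_ids: list[str]
    pos_cM: np.ndarray       # strictly non-decreasing, first at 0
    interval_r: np.ndarray   # len = n_markers - 1, each in [0, 0.5)

    def __post_init__(self) -> None:
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        self.interval_r = np.asarray(self.interval_r, dtype=float)
        if len(self.marker_ids) != len(self.pos_cM):
            raise ValueError("marker/position length mismatch")
        if len(self.interval_r) != max(len(self.marker_ids) - 1, 0):
            raise ValueError("interval_r must have n_markers - 1 entries")
        if len(self.pos_cM):
            if self.pos_cM[0] != 0.0 or np.any(np.diff(self.pos_cM) < 0):
                raise ValueError("positions must start at 0 and be non-decreasing")
        if np.any((self.interval_r < 0) | (self.interval_r >= 0.5)):
            raise ValueError("interval recombination fractions must be in [0, 0.5)")


@dataclass
class TruthMap:
    chromosomes: list[TruthChromosome]

    def __post_init__(self) -> None:
        ids = [m for c in self.chromosomes for m in c.marker_ids]
        if len(ids) != len(set(ids)):
            raise ValueError("marker ids must be globally unique")

    @property
    def n_markers(self) -> int:
        return sum(len(c.marker_ids) for c in self.chromosomes)

    @property
    def marker_ids(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.marker_ids]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"marker_id": m, "chromosome": c.name, "pos_cM": p}
            for c in self.chromosomes
            for m, p in zip(c.marker_ids, c.pos_cM)
        ]
        return pd.DataFrame(rows, columns=["marker_id", "chromosome", "pos_cM"])


@dataclass
class SimulationConfig:
    """Study conditions for one simulated DH population."""

    n_lines: int
    missing_rate: float = 0.02
    error_rate: float = 0.01
    distortion: dict[str, float] = field(default_factory=dict)
    shared_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        for name in ("missing_rate", "error_rate", "shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        for m, f in self.distortion.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"distortion frequency {f} for {m} not in [0, 1]")


def simulate_truth_map(
    n_chromosomes: int = 19,
    markers_per_chr: int = 40,
    chr_length: float = 100.0,
    seed: int = 0,
    chromosome_names: list[str] | None = None,
) -> TruthMap:
    """Draw a ground-truth map: marker positions uniform on each
    chromosome (sorted, shifted so the first sits at 0) and interval
    recombination fractions from the inverse Kosambi of adjacent gaps."""
    if n_chromosomes <= 0 or markers_per_chr < 2:
        raise ValueError("need n_chromosomes >= 1 and markers_per_chr >= 2")
    if chr_length <= 0:
        raise ValueError("chr_length must be positive")
    if chromosome_names is None:
        chromosome_names = (
            AC_CHROMOSOMES if n_chromosomes == len(AC_CHROMOSOMES)
            else [f"chr{i + 1}" for i in range(n_chromosomes)]
        )
    rng = np.random.default_rng(seed)
    chroms = []
    counter = 0
    for name in chromosome_names[:n_chromosomes]:
        pos = np.sort(rng.uniform(0.0, chr_length, markers_per_chr))
        pos -= pos[0]
        ids = [f"M{counter + i:05d}" for i in range(markers_per_chr)]
        counter += markers_per_chr
        chroms.append(TruthChromosome(name, ids, pos, kosambi_inv(np.diff(pos))))
    return TruthMap(chroms)


def simulate_dh_population(truth: TruthMap, config: SimulationConfig) -> GenotypeMatrix:
    """Simulate one DH population from a truth map.

    Per line and chromosome the parental origin follows the Markov
    chain described in the module docstring; distorted loci are
    re-anchored to their shifted allele frequency and propagate
    downstream through the same chain.  Genotyping errors then flip
    calls at ``error_rate`` and calls are masked missing at
    ``missing_rate``.  Markers are included with probability
    ``shared_fraction`` (monomorphic-in-this-cross emulation).  Quality
    metadata is emitted with call_rate computed from the realised
    missingness.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    blocks, kept_ids = [], []
    for chrom in truth.chromosomes:
        m = len(chrom.marker_ids)
        alleles = np.empty((n, m), dtype=np.int8)
        first = chrom.marker_ids[0]
        p0 = config.distortion.get(first, 0.5)
        alleles[:, 0] = rng.random(n) < p0
        for j in range(1, m):
            marker = chrom.marker_ids[j]
            if marker in config.distortion:
                alleles[:, j] = rng.random(n) < config.distortion[marker]
            else:
                switch = rng.random(n) < chrom.interval_r[j - 1]
                alleles[:, j] = alleles[:, j - 1] ^ switch
        keep = rng.random(m) < config.shared_fraction
        blocks.append(alleles[:, keep])
        kept_ids.extend(np.array(chrom.marker_ids)[keep])
    calls = np.concatenate(blocks, axis=1).T.astype(np.int8)  # markers x lines
    if config.error_rate > 0:
        flip = rng.random(calls.shape) < config.error_rate
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if config.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < config.missing_rate,
                         np.int8(MISSING), calls)
    call_rate = 100.0 * (calls != MISSING).mean(axis=1)
    quality = pd.DataFrame(
        {
            "q_value": rng.uniform(80.0, 100.0, len(kept_ids)),
            "call_rate": call_rate,
            "reproducibility": 100.0,
        },
        index=pd.Index(kept_ids, name="marker_id"),
    )
    line_ids = [f"DH{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(list(kept_ids), line_ids, calls, quality)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return NUCLEOTIDES[rng.integers(0, 4, length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, divergence: float) -> np.ndarray:
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < divergence)[0]
    # substitute to a strictly different base: two independently mutated
    # copies then agree at a site with prob (1-d)^2 + d^2/3
    shift = rng.integers(1, 4, len(hit))
    codes = {b: i for i, b in enumerate(NUCLEOTIDES)}
    cur = np.array([codes[b] for b in out[hit]], dtype=int)
    out[hit] = NUCLEOTIDES[(cur + shift) % 4]
    return out


def simulate_clone_sequences(
    truth: TruthMap,
    length_bp: int = 500,
    redundancy_groups: list[set[str]] | None = None,
    divergence: float = 0.02,
    seed: int = 0,
    no_hit_fraction: float = 0.0,
    multi_hit_fraction: float = 0.0,
    bp_per_cm: float = 600_000.0,
) -> tuple[list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Marker clone sequences, scaffold sequences and an alignment hit table.

    Markers within one redundancy group are mutated from a common
    template at ``divergence``; all other markers get independent
    random sequences.  One scaffold is emitted per chromosome (a short
    random sequence named ``scf_<chrom>``; placement coordinates scale
    genetic position by ``bp_per_cm`` and need not index into it).  The
    hit table uses the 12-column tabular alignment layout with 1-based
    inclusive coordinates; a seeded fraction of markers is withheld
    from the table entirely and another fraction receives a secondary,
    lower-scoring hit on a different scaffold.
    """
    if truth.n_markers == 0:
        raise ValueError("empty truth map")
    if length_bp < 50:
        raise ValueError("length_bp must be >= 50")
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    redundancy_groups = redundancy_groups or []
    grouped = {m: gi for gi, grp in enumerate(redundancy_groups) for m in grp}
    templates = [_random_seq(rng, length_bp) for _ in redundancy_groups]

    clones = []
    for marker in truth.marker_ids:
        if marker in grouped:
            seq = _mutate(rng, templates[grouped[marker]], divergence)
        else:
            seq = _random_seq(rng, length_bp)
        clones.append(SeqRecord(Seq("".join(seq)), id=marker, description=""))

    scaffolds = [
        SeqRecord(Seq("".join(_random_seq(rng, 200))), id=f"scf_{c.name}", description="")
        for c in truth.chromosomes
    ]
    scaffold_names = [s.id for s in scaffolds]

    no_hit = set(
        np.array(truth.marker_ids)[rng.random(truth.n_markers) < no_hit_fraction]
    )
    rows = []
    for c in truth.chromosomes:
        for marker, pos in zip(c.marker_ids, c.pos_cM):
            if marker in no_hit:
                continue
            start = int(round(pos * bp_per_cm)) + 1
            minus = rng.random() < 0.5
            s1, s2 = start, start + length_bp - 1
            if minus:
                s1, s2 = s2, s1
            pident = round(100.0 * (1.0 - divergence), 2)
            rows.append([marker, f"scf_{c.name}", pident, length_bp, 0, 0,
                         1, length_bp, s1, s2, 1e-50, 2.0 * length_bp])
            if rng.random() < multi_hit_fraction:
                other = scaffold_names[int(rng.integers(0, len(scaffold_names)))]
                off = int(rng.integers(1, 10_000_000))
                rows.append([marker, other, round(pident * 0.9, 2), length_bp, 10, 2,
                             1, length_bp, off, off + length_bp - 1, 1e-10, length_bp])
    hits = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    return clones, scaffolds, hits


def subsample_component_map(
    truth: TruthMap,
    population_id: str,
    fraction: float = 0.6,
    jitter_cm: float = 0.0,
    seed: int = 0,
):
    """A component map drawn from the truth: each marker is included
    with probability ``fraction`` and positions optionally perturbed by
    uniform jitter (clipped to keep order-of-magnitude realism, then
    re-anchored at 0).  Used to exercise consensus integration without
    running the full genotype pipeline."""
    from .linkage import ComponentMap, LinkageGroup

    rng = np.random.default_rng(seed)
    groups = []
    for c in truth.chromosomes:
        keep = rng.random(len(c.marker_ids)) < fraction
        if keep.sum() < 2:
            continue
        ids = list(np.array(c.marker_ids)[keep])
        pos = c.pos_cM[keep].astype(float)
        if jitter_cm > 0:
            pos = pos + rng.uniform(-jitter_cm, jitter_cm, len(pos))
        order = np.argsort(pos, kind="stable")
        ids = [ids[i] for i in order]
        pos = pos[order]
        groups.append(LinkageGroup(c.name, ids, pos - pos[0]))
    return ComponentMap(population_id, groups)
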