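"""Marker quality control for dominant binary DH genotype data.

Doubled-haploid (DH) lines are fully homozygous, so a dominant
presence/absence marker segregates 1:1 in the absence of distortion.
This module filters markers on array-quality metadata (Q value, call
rate, scoring reproducibility), tests segregation ratios by chi-square,
and collapses co-segregating (redundant) markers into bins represented
by their highest-quality member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1  # sentinel for a missing call in the int8 call matrix

QUALITY_COLUMNS = ("q_value", "call_rate", "reproducibility")


@dataclass
class MarkerQuality:
    """Per-marker assay quality: all fields are percentages in [0, 100]."""

    marker_id: str
    q_value: float
    call_rate: float
    reproducibility: float

    def __post_init__(self) -> None:
        for name in QUALITY_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} for {self.marker_id} not in [0, 100]")


@dataclass
class GenotypeMatrix:
    """Markers x lines binary call matrix with quality metadata.

    ``calls`` is int8 with values 1 (fragment present), 0 (absent) and
    -1 (missing).  ``quality`` is a DataFrame indexed by marker_id with
    columns q_value, call_rate and reproducibility; it may cover only a
    subset of markers, but quality-dependent operations require full
    coverage and raise otherwise.
    """

    marker_ids: list[str]
    line_ids: list[str]
    calls: np.ndarray
    quality: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(QUALITY_COLUMNS)))

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.marker_ids), len(self.line_ids)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.line_ids)} lines"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call {self.calls[i, j]} at marker {self.marker_ids[i]}, "
                f"line {self.line_ids[j]}"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, marker_ids: list[str]) -> "GenotypeMatrix":
        """Row-subset preserving the given marker order."""
        index = {m: i for i, m in enumerate(self.marker_ids)}
        rows = [index[m] for m in marker_ids]
        quality = self.quality.loc[self.quality.index.intersection(marker_ids)]
        return GenotypeMatrix(list(marker_ids), list(self.line_ids), self.calls[rows], quality)

    def marker_quality(self, marker_id: str) -> MarkerQuality:
        if marker_id not in self.quality.index:
            raise KeyError(f"no quality record for marker {marker_id}")
        row = self.quality.loc[marker_id]
        return MarkerQuality(marker_id, row["q_value"], row["call_rate"], row["reproducibility"])


@dataclass
class SegregationResult:
    """Chi-square segregation test outcome for one marker.

    The one-locus model expects a 1:1 presence/absence ratio; markers
    failing it are rescued if consistent with a two-locus 3:1 or 1:3
    ratio.  ``verdict`` is "keep" when any of the three models fits at
    the given alpha, else "distorted".
    """

    marker_id: str
    n_one: int
    n_zero: int
    chi2_11: float
    chi2_31: float
    chi2_13: float
    p_11: float
    p_31: float
    p_13: float
    verdict: str
    zero_count: bool = False


def filter_marker_quality(
    matrix: GenotypeMatrix,
    q_min: float = 77.0,
    call_min: float = 97.0,
    repro_min: float = 100.0,
) -> GenotypeMatrix:
    """Retain markers with q_value > q_min, call_rate > call_min and
    reproducibility >= repro_min (strict inequality on the first two,
    matching the quality rules for DArT clone selection)."""
    missing = [m for m in matrix.marker_ids if m not in matrix.quality.index]
    if missing:
        raise ValueError(f"missing quality record for marker {missing[0]}")
    q = matrix.quality
    keep = [
        m
        for m in matrix.marker_ids
        if q.at[m, "q_value"] > q_min
        and q.at[m, "call_rate"] > call_min
        and q.at[m, "reproducibility"] >= repro_min
    ]
    return matrix.subset(keep)


def _chisq(n_one: int, n_zero: int, ratio_one: float) -> tuple[float, float]:
    n = n_one + n_zero
    expected = [n * ratio_one, n * (1.0 - ratio_one)]
    res = stats.chisquare([n_one, n_zero], expected)
    return float(res.statistic), float(res.pvalue)


def segregation_test(matrix: GenotypeMatrix, alpha: float = 0.01) -> list[SegregationResult]:
    """Chi-square tests of each marker against 1:1, then 3:1 and 1:3.

    All three statistics are reported; the marker is kept if any model
    has p >= alpha.  Markers with no scored lines are flagged distorted
    with ``zero_count`` set.
    """
    results = []
    for i, marker in enumerate(matrix.marker_ids):
        calls = matrix.calls[i]
        n_one = int(np.sum(calls == 1))
        n_zero = int(np.sum(calls == 0))
        if n_one + n_zero == 0:
            results.append(
                SegregationResult(marker, 0, 0, np.nan, np.nan, np.nan,
                                  np.nan, np.nan, np.nan, "distorted", zero_count=True)
            )
            continue
        chi2_11, p_11 = _chisq(n_one, n_zero, 0.5)
        chi2_31, p_31 = _chisq(n_one, n_zero, 0.75)
        chi2_13, p_13 = _chisq(n_one, n_zero, 0.25)
        keep = (p_11 >= alpha) or (p_31 >= alpha) or (p_13 >= alpha)
        results.append(
            SegregationResult(marker, n_one, n_zero, chi2_11, chi2_31, chi2_13,
                              p_11, p_31, p_13, "keep" if keep else "distorted")
        )
    return results


def drop_distorted(matrix: GenotypeMatrix, alpha: float = 0.01) -> GenotypeMatrix:
    """Remove markers whose segregation is distorted under all three ratio models."""
    keep = [r.marker_id for r in segregation_test(matrix, alpha) if r.verdict == "keep"]
    return matrix.subset(keep)


def _compatible_pairs(calls: np.ndarray, min_overlap: int):
    """Yield (i, j) pairs identical on every co-observed line with at
    least min_overlap co-observed lines.  Chunked over rows to bound
    memory on large marker sets."""
    observed = calls != MISSING
    m = calls.shape[0]
    for i in range(m - 1):
        both = observed[i] & observed[i + 1 :]
        overlap = both.sum(axis=1)
        disagree = ((calls[i] != calls[i + 1 :]) & both).any(axis=1)
        for off in np.nonzero(~disagree & (overlap >= min_overlap))[0]:
            yield i, i + 1 + int(off)


def bin_redundant(
    matrix: GenotypeMatrix, min_overlap: int = 20
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Merge co-segregating markers into bins and keep one representative.

    Two markers are compatible when their call vectors agree on every
    line where both are scored and they share at least ``min_overlap``
    informative lines (missing cells are treated as compatible-with-
    anything).  Bins are connected components of the compatibility
    graph; the representative is the member with the highest q_value
    (ties broken by lexicographic marker id).  Returns the reduced
    matrix (original marker order) and a map representative -> all bin
    members (including singletons), which partitions the input set.
    """
    g = nx.Graph()
    g.add_nodes_from(range(matrix.n_markers))
    g.add_edges_from(_compatible_pairs(matrix.calls, min_overlap))

    def q_of(idx: int) -> float:
        m = matrix.marker_ids[idx]
        if m in matrix.quality.index:
            return float(matrix.quality.at[m, "q_value"])
        return -np.inf

    bins: dict[str, list[str]] = {}
    rep_rows = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = min(members, key=lambda i: (-q_of(i), matrix.marker_ids[i]))
        bins[matrix.marker_ids[rep]] = sorted(matrix.marker_ids[i] for i in members)
        rep_rows.append(rep)
    rep_rows.sort()
    reduced = matrix.subset([matrix.marker_ids[i] for i in rep_rows])
    return reduced, bins


def qc_report(matrix: GenotypeMatrix, alpha: float = 0.01, min_overlap: int = 20) -> pd.DataFrame:
    """Combined per-marker QC table: counts, chi-square statistics,
    p-values, verdict and bin assignment."""
    seg = segregation_test(matrix, alpha)
    _, bins = bin_redundant(matrix, min_overlap)
    bin_of = {m: rep for rep, members in bins.items() for m in members}
    rows = []
    for r in seg:
        rows.append(
            {
                "marker_id": r.marker_id,
                "n_one": r.n_one,
                "n_zero": r.n_zero,
                "chi2_11": r.chi2_11,
                "chi2_31": r.chi2_31,
                "chi2_13": r.chi2_13,
                "p_11": r.p_11,
                "p_31": r.p_31,
                "p_13": r.p_13,
                "verdict": r.verdict,
                "bin_id": bin_of.get(r.marker_id, r.marker_id),
            }
        )
    return pd.DataFrame(rows)
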