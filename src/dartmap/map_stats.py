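"""Summary statistics over component and consensus maps.

All operations work on a tidy map frame with columns ``chromosome``,
``marker_id`` and ``pos_cM`` (one row per mapped locus).  Marker
classes (e.g. DArT vs non-DArT) are supplied as a mapping marker_id ->
class label.

Conventions: map length is the per-chromosome span (max position)
summed over chromosomes; the mean inter-marker interval is
length / n_markers — the denominator is the marker count, not n-1,
which is the arithmetic that reproduces published per-chromosome
density columns (e.g. 92 markers over 82.0 cM -> 0.89 cM/marker).
Redundancy counts k-1 markers in every set of k co-positioned markers,
tallied per class against all markers of that class on the map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

POSITION_DECIMALS = 2  # cM values are reported at 2 decimals

_ALLELE_SUFFIX = re.compile(r"-[a-z]$")


@dataclass
class MapSummary:
    map_id: str
    n_markers: int
    length: float
    mean_interval: float
    n_gaps_gt: int
    redundancy: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    # class -> (n_redundant, n_total, percent)


def _redundancy(sub: pd.DataFrame, classes: dict[str, str] | None):
    counts: dict[str, list[int]] = {}
    cls = (lambda m: classes.get(m, "all")) if classes else (lambda m: "all")
    for m in sub["marker_id"]:
        counts.setdefault(cls(m), [0, 0])[1] += 1
    pos = sub["pos_cM"].round(POSITION_DECIMALS + 4)
    for (_, _), co in sub.groupby([sub["chromosome"], pos]):
        if len(co) < 2:
            continue
        by_class: dict[str, int] = {}
        for m in co["marker_id"]:
            by_class[cls(m)] = by_class.get(cls(m), 0) + 1
        for c, k in by_class.items():
            if k >= 2:
                counts.setdefault(c, [0, 0])[0] += k - 1
    return {
        c: (r, t, 100.0 * r / t if t else np.nan) for c, (r, t) in counts.items()
    }


def summarize_map(
    map_frame: pd.DataFrame,
    gap_threshold: float = 10.0,
    classes: dict[str, str] | None = None,
    map_id: str = "map",
) -> tuple[MapSummary, pd.DataFrame]:
    """Overall and per-chromosome map summaries.

    The per-chromosome frame carries chromosome, genome (leading A/C
    letter when applicable), n_markers, length, mean_interval and gap
    count; per-genome and overall rows are the sums of their
    chromosome constituents, with mean_interval recomputed from the
    summed length and count.
    """
    if map_frame.empty:
        import warnings

        warnings.warn("empty map: zeroed summary")
        return MapSummary(map_id, 0, 0.0, np.nan, 0), pd.DataFrame(
            columns=["chromosome", "genome", "n_markers", "length", "mean_interval", "n_gaps_gt"]
        )
    rows = []
    for chrom, sub in map_frame.groupby("chromosome", sort=True):
        pos = np.sort(sub["pos_cM"].to_numpy(dtype=float))
        gaps = int(np.sum(np.diff(pos) > gap_threshold)) if len(pos) > 1 else 0
        length = float(pos.max() - pos.min()) if len(pos) else 0.0
        genome = chrom[0] if re.fullmatch(r"[AC]\d+", str(chrom)) else "other"
        rows.append(
            {"chromosome": chrom, "genome": genome, "n_markers": len(sub),
             "length": length, "mean_interval": length / len(sub), "n_gaps_gt": gaps}
        )
    per_chr = pd.DataFrame(rows)
    total_len = float(per_chr["length"].sum())
    n = int(per_chr["n_markers"].sum())
    overall = MapSummary(
        map_id, n, total_len, total_len / n, int(per_chr["n_gaps_gt"].sum()),
        _redundancy(map_frame, classes),
    )
    return overall, per_chr


def mean_interval(n_markers: int, length: float) -> float:
    """Mean inter-marker distance from a (marker count, map length) pair."""
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return length / n_markers


def detect_clusters(map_frame: pd.DataFrame, min_loci: int = 5,
                    window: float = 0.01) -> list[dict]:
    """Maximal runs of at least ``min_loci`` markers whose positions
    all lie within ``window`` cM of one another."""
    clusters = []
    for chrom, sub in map_frame.groupby("chromosome", sort=True):
        sub = sub.sort_values("pos_cM", kind="stable")
        pos = sub["pos_cM"].to_numpy(dtype=float)
        ids = sub["marker_id"].tolist()
        i = 0
        n = len(pos)
        last_end = -1
        while i < n:
            j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= window + 1e-12:
                j += 1
            if j - i + 1 >= min_loci and j > last_end:
                clusters.append(
                    {"chromosome": chrom, "pos_cM": float(pos[i]),
                     "n_loci": j - i + 1, "marker_ids": ids[i : j + 1]}
                )
                last_end = j
            i += 1
    return clusters


def base_marker_id(marker_id: str) -> str:
    """Strip a single-letter allele suffix ("Xpw123-a" -> "Xpw123")."""
    return _ALLELE_SUFFIX.sub("", marker_id)


def detect_duplicated_loci(map_frame: pd.DataFrame,
                           classes: dict[str, str] | None = None) -> pd.DataFrame:
    """Markers placed at more than one locus.

    Loci of one marker share a base id and differ by allele suffix;
    repeated identical ids also count.  Returns one row per duplicated
    marker with its locus count, chromosomes, and class if supplied.
    """
    df = map_frame.copy()
    df["base_id"] = df["marker_id"].map(base_marker_id)
    rows = []
    for base, sub in df.groupby("base_id", sort=True):
        if len(sub) < 2:
            continue
        rows.append(
            {
                "marker_id": base,
                "n_loci": len(sub),
                "chromosomes": ";".join(sorted(sub["chromosome"].astype(str))),
                "class": classes.get(base, "") if classes else "",
            }
        )
    return pd.DataFrame(rows, columns=["marker_id", "n_loci", "chromosomes", "class"])


def shared_marker_stats(map_a: pd.DataFrame, map_b: pd.DataFrame,
                        min_shared: int = 4) -> pd.DataFrame:
    """Per-chromosome shared-marker counts and Spearman rank
    correlation of the orders; rho is NA below ``min_shared`` shared
    markers, where a rank correlation carries no real evidence."""
    merged = map_a.merge(map_b, on=["chromosome", "marker_id"], suffixes=("_a", "_b"))
    rows = []
    for chrom, sub in merged.groupby("chromosome", sort=True):
        n = len(sub)
        if n >= min_shared:
            rho = float(stats.spearmanr(sub["pos_cM_a"], sub["pos_cM_b"]).statistic)
        else:
            rho = np.nan
        rows.append({"chromosome": chrom, "n_shared": n, "spearman_rho": rho})
    return pd.DataFrame(rows, columns=["chromosome", "n_shared", "spearman_rho"])


def cross_population_correlation(summaries: list[MapSummary]) -> float:
    """Pearson correlation between marker counts and map lengths across
    maps; NaN when fewer than two maps or either quantity is constant."""
    n = np.array([s.n_markers for s in summaries], dtype=float)
    length = np.array([s.length for s in summaries], dtype=float)
    if len(n) < 2 or np.std(n) == 0 or np.std(length) == 0:
        return float("nan")
    return float(np.corrcoef(n, length)[0, 1])
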