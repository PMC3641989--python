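"""Consensus map integration across component linkage maps.

The consensus map is initialised from a seed (reference) map with one
linkage group per chromosome.  For each chromosome, the candidate
groups from the component maps are repeatedly scored by their
*commonality* with the current consensus — |Pearson correlation of
shared-marker positions| x ln(number of shared markers), defined only
for groups sharing at least three markers — and the highest-scoring
group whose correlation exceeds 0.5 in magnitude is merged: its shared
markers define a piecewise-linear transform from component to
consensus coordinates, through which all of its markers are mapped
(extrapolating on the nearest segment's slope beyond the terminal
shared markers).  Consensus positions of markers already present never
move.  The process repeats until no remaining group qualifies; each
chromosome is finally translated so its smallest position is 0.

Conventions left open by the pseudo-code are fixed as follows: the log
is natural (the base only rescales scores monotonically, so selection
order is unaffected); correlation is Pearson on positions; the gate is
applied to |corr|, with negatively oriented groups reversed before
interpolation, because map orientation is arbitrary; coincident shared
anchors are averaged.  These choices are surfaced in the run report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import ComponentMap, LinkageGroup


@dataclass
class CommonalityScore:
    group_key: str
    n_common: int
    corr: float
    score: float          # |corr| * ln(n_common)
    flip: bool            # corr < 0: reverse the group before joining


@dataclass
class ConsensusMap:
    """Per-chromosome ordered markers with provenance.

    ``chromosomes`` maps a label to a DataFrame with columns marker_id,
    pos_cM and source ("seed" or "interpolated"); ``provenance`` maps a
    marker id to the contributing population ids.
    """

    chromosomes: dict[str, pd.DataFrame]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return sum(len(df) for df in self.chromosomes.values())

    def marker_ids(self) -> list[str]:
        return [m for df in self.chromosomes.values() for m in df["marker_id"]]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom in sorted(self.chromosomes):
            df = self.chromosomes[chrom].copy()
            df.insert(0, "chromosome", chrom)
            df["populations"] = [
                ";".join(self.provenance.get(m, [])) for m in df["marker_id"]
            ]
            parts.append(df)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
            columns=["chromosome", "marker_id", "pos_cM", "source", "populations"]
        )


def score_group(group: LinkageGroup, consensus_chr: pd.DataFrame,
                group_key: str = "") -> tuple[CommonalityScore | None, str]:
    """Commonality of a component group with the current consensus
    chromosome.  Returns (score, "") or (None, reason) when the group
    cannot be scored (fewer than three shared markers, or degenerate
    zero-variance positions)."""
    cons_pos = dict(zip(consensus_chr["marker_id"], consensus_chr["pos_cM"]))
    shared = [(p, cons_pos[m]) for m, p in zip(group.marker_ids, group.positions)
              if m in cons_pos]
    if len(shared) < 3:
        return None, f"n_common < 3 (got {len(shared)})"
    x, y = np.array(shared).T
    if np.std(x) == 0 or np.std(y) == 0:
        return None, "degenerate shared-marker positions (zero variance)"
    corr = float(np.corrcoef(x, y)[0, 1])
    score = abs(corr) * float(np.log(len(shared)))
    return CommonalityScore(group_key, len(shared), corr, score, corr < 0), ""


def _piecewise_transform(comp: np.ndarray, cons: np.ndarray):
    """Monotone-anchored piecewise-linear map component -> consensus.

    ``comp`` must be sorted; coincident component coordinates are
    collapsed by averaging their consensus values.  Outside the anchor
    range the nearest segment's slope extrapolates; a single surviving
    anchor degenerates to a unit-slope translation.
    """
    df = pd.DataFrame({"x": comp, "y": cons}).groupby("x", as_index=False).mean()
    x, y = df["x"].to_numpy(), df["y"].to_numpy()
    if len(x) == 1:
        return lambda q: y[0] + (np.asarray(q, dtype=float) - x[0])

    def transform(q):
        q = np.asarray(q, dtype=float)
        out = np.interp(q, x, y)
        lo = q < x[0]
        hi = q > x[-1]
        s_lo = (y[1] - y[0]) / (x[1] - x[0])
        s_hi = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out = np.where(lo, y[0] + s_lo * (q - x[0]), out)
        out = np.where(hi, y[-1] + s_hi * (q - x[-1]), out)
        return out

    return transform


def integrate_group(consensus_chr: pd.DataFrame, group: LinkageGroup,
                    score: CommonalityScore) -> pd.DataFrame:
    """Join one component group to a consensus chromosome by linear
    interpolation through the shared markers.  Existing consensus
    positions are untouched; new markers are appended and the frame
    re-sorted by position (stable, so ties keep insertion order)."""
    if abs(score.corr) <= 0.5:
        raise ValueError("integration requires |corr| > 0.5")
    g = group.reversed() if score.flip else group
    cons_pos = dict(zip(consensus_chr["marker_id"], consensus_chr["pos_cM"]))
    shared = [(p, cons_pos[m]) for m, p in zip(g.marker_ids, g.positions) if m in cons_pos]
    comp, cons = np.array(sorted(shared)).T
    transform = _piecewise_transform(comp, cons)
    new = [(m, p) for m, p in zip(g.marker_ids, g.positions) if m not in cons_pos]
    if not new:
        return consensus_chr
    ids, pos = zip(*new)
    added = pd.DataFrame(
        {"marker_id": ids, "pos_cM": transform(np.array(pos)), "source": "interpolated"}
    )
    out = pd.concat([consensus_chr, added], ignore_index=True)
    return out.sort_values("pos_cM", kind="stable", ignore_index=True)


def build_consensus(
    seed: ComponentMap,
    components: list[ComponentMap],
    min_shared: int = 3,
    min_corr: float = 0.5,
) -> tuple[ConsensusMap, pd.DataFrame]:
    """Greedy per-chromosome integration of component maps into the seed.

    Ties on commonality score are broken by larger n_common, then by
    component input order, making the result deterministic.  Returns
    the consensus and a report of groups never integrated, with the
    blocking reason from the final scoring round.
    """
    chrom_labels = [g.chromosome for g in seed.groups]
    if len(set(chrom_labels)) != len(chrom_labels):
        raise ValueError("seed map must have one group per chromosome")
    chromosomes: dict[str, pd.DataFrame] = {}
    provenance: dict[str, list[str]] = {}
    for g in seed.groups:
        chromosomes[g.chromosome] = pd.DataFrame(
            {"marker_id": g.marker_ids, "pos_cM": g.positions.astype(float),
             "source": "seed"}
        )
        for m in g.marker_ids:
            provenance[m] = [seed.population_id]

    report_rows = []
    for chrom in chromosomes:
        pool = [
            (ci, cmap.population_id, g)
            for ci, cmap in enumerate(components)
            for g in cmap.groups
            if g.chromosome == chrom
        ]
        while pool:
            scored = []
            reasons = {}
            for slot, (ci, pop, g) in enumerate(pool):
                sc, reason = score_group(g, chromosomes[chrom], group_key=f"{pop}:{chrom}")
                if sc is None or sc.n_common < min_shared:
                    reasons[slot] = reason or f"n_common < {min_shared}"
                elif abs(sc.corr) <= min_corr:
                    reasons[slot] = f"|corr| = {abs(sc.corr):.3f} <= {min_corr}"
                else:
                    scored.append((slot, sc))
            if not scored:
                for slot, (ci, pop, g) in enumerate(pool):
                    report_rows.append(
                        {"population_id": pop, "chromosome": chrom,
                         "n_markers": len(g.marker_ids), "reason": reasons[slot]}
                    )
                break
            slot, best = max(scored, key=lambda t: (t[1].score, t[1].n_common, -t[0]))
            ci, pop, g = pool.pop(slot)
            chromosomes[chrom] = integrate_group(chromosomes[chrom], g, best)
            for m in g.marker_ids:
                provenance.setdefault(m, [])
                if pop not in provenance[m]:
                    provenance[m].append(pop)

    # groups on chromosomes absent from the seed can never be integrated
    seed_chroms = set(chromosomes)
    for cmap in components:
        for g in cmap.groups:
            if g.chromosome not in seed_chroms:
                report_rows.append(
                    {"population_id": cmap.population_id, "chromosome": g.chromosome,
                     "n_markers": len(g.marker_ids),
                     "reason": "chromosome not in seed map"}
                )

    for chrom, df in chromosomes.items():
        df["pos_cM"] = df["pos_cM"] - df["pos_cM"].min()
        chromosomes[chrom] = df.sort_values("pos_cM", kind="stable", ignore_index=True)

    report = pd.DataFrame(
        report_rows, columns=["population_id", "chromosome", "n_markers", "reason"]
    )
    return ConsensusMap(chromosomes, provenance), report
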