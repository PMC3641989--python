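"""Anchoring genetically mapped markers to genome scaffolds.

Consumes precomputed alignment hit tables in the 12-column tabular
layout (qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore; 1-based inclusive coordinates, minus-
strand hits encoded by sstart > send).  The E-value filter keeps *all*
passing hits per marker rather than collapsing to the best one, so
genome-wide homologies (duplicated loci) remain visible; colinearity
against the genetic map then uses a single best-bit-score placement
per marker, excluding markers whose best placements tie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusMap
from .synthetic_data import BLAST_COLUMNS


@dataclass
class TraitInterval:
    trait: str
    chromosome: str
    flank_a: str
    flank_b: str
    contained: list[str]


def filter_hits(hits: pd.DataFrame, e_max: float = 1e-5) -> pd.DataFrame:
    """Keep every hit with evalue <= e_max; order and multiplicity
    preserved (idempotent)."""
    missing = [c for c in BLAST_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    return hits[hits["evalue"] <= e_max].reset_index(drop=True)


def placement_report(marker_ids: list[str], hits: pd.DataFrame,
                     e_max: float = 1e-5) -> dict:
    """Scaffold placements for each marker.

    Returns ``{"placed": {marker: [(scaffold, midpoint_bp, strand), ...]},
    "unplaced": [...]}`` where midpoint is the centre of the subject
    interval and strand "-" when sstart > send.  ``placed`` and
    ``unplaced`` partition the input marker set.
    """
    passing = filter_hits(hits, e_max)
    placed: dict[str, list[tuple[str, float, str]]] = {}
    for row in passing.itertuples(index=False):
        lo, hi = sorted((row.sstart, row.send))
        strand = "-" if row.sstart > row.send else "+"
        placed.setdefault(row.qseqid, []).append((row.sseqid, (lo + hi) / 2.0, strand))
    result_placed = {m: placed[m] for m in marker_ids if m in placed}
    unplaced = [m for m in marker_ids if m not in placed]
    return {"placed": result_placed, "unplaced": unplaced}


def best_placements(hits: pd.DataFrame, e_max: float = 1e-5
                    ) -> tuple[pd.DataFrame, list[str]]:
    """One best-bit-score placement per marker.

    Markers with several equal-best placements are excluded and
    returned separately as candidate duplicated loci.
    """
    passing = filter_hits(hits, e_max)
    rows, ambiguous = [], []
    for marker, sub in passing.groupby("qseqid", sort=True):
        top = sub[sub["bitscore"] == sub["bitscore"].max()]
        if len(top) > 1:
            ambiguous.append(marker)
            continue
        row = top.iloc[0]
        lo, hi = sorted((row["sstart"], row["send"]))
        rows.append({"marker_id": marker, "scaffold": row["sseqid"],
                     "midpoint_bp": (lo + hi) / 2.0,
                     "strand": "-" if row["sstart"] > row["send"] else "+"})
    return pd.DataFrame(rows, columns=["marker_id", "scaffold", "midpoint_bp", "strand"]), ambiguous


def colinearity(consensus_chr: pd.DataFrame, placements: pd.DataFrame) -> dict:
    """Genetic/physical colinearity of one chromosome.

    Spearman rho between genetic position and physical midpoint over
    markers with a unique best placement; reports the longest strictly
    decreasing run of physical ranks as the main inversion candidate.
    """
    merged = consensus_chr.merge(placements, on="marker_id")
    n = len(merged)
    if n < 2:
        return {"rho": np.nan, "n": n, "inversion": []}
    merged = merged.sort_values("pos_cM", kind="stable")
    rho = float(stats.spearmanr(merged["pos_cM"], merged["midpoint_bp"]).statistic)
    ranks = stats.rankdata(merged["midpoint_bp"])
    best_run, run_start = [], 0
    for i in range(1, n + 1):
        if i == n or ranks[i] >= ranks[i - 1]:
            if i - run_start > len(best_run):
                best_run = merged["marker_id"].iloc[run_start:i].tolist()
            run_start = i
    inversion = best_run if len(best_run) > 1 else []
    return {"rho": rho, "n": n, "inversion": inversion}


def locate_trait_interval(consensus: ConsensusMap, trait: str,
                          flank_a: str, flank_b: str) -> TraitInterval:
    """All consensus markers inside the closed interval spanned by two
    flanking markers (order-insensitive); the flanks must sit on the
    same chromosome."""
    where = {}
    for chrom, df in consensus.chromosomes.items():
        pos = dict(zip(df["marker_id"], df["pos_cM"]))
        for flank in (flank_a, flank_b):
            if flank in pos:
                where[flank] = (chrom, pos[flank])
    for flank in (flank_a, flank_b):
        if flank not in where:
            raise KeyError(f"flanking marker {flank} not on the consensus map")
    (chr_a, pos_a), (chr_b, pos_b) = where[flank_a], where[flank_b]
    if chr_a != chr_b:
        raise ValueError(f"flanks on different chromosomes ({chr_a} vs {chr_b})")
    lo, hi = sorted((pos_a, pos_b))
    df = consensus.chromosomes[chr_a]
    inside = df[(df["pos_cM"] >= lo) & (df["pos_cM"] <= hi)]
    return TraitInterval(trait, chr_a, flank_a, flank_b, inside["marker_id"].tolist())
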