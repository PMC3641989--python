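"""Sequence-level redundancy of co-segregating marker clones.

Markers that map to the same position may assay the same clone or two
tightly linked but distinct loci.  The decision rule is pairwise:
clones are globally aligned and a bin of co-segregating markers is a
redundancy candidate only if every pair reaches the identity threshold
(default 80%) — below that, fragments should not hybridise to the same
target under stringent conditions.

Alignment is Needleman-Wunsch with match +1, mismatch -1 and a linear
gap penalty of -2.  Identity is matches over aligned columns.  Among
co-optimal alignments the one maximising matches, then minimising
aligned columns, defines the identity — a deterministic convention
implemented by a lexicographic (score, matches, diagonal-steps)
dynamic programme; the plain optimal score agrees with standard
aligners.  Both orientations are compared (forward and
reverse-complement of one sequence) and the larger identity is kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

GAP = -2
MATCH = 1
MISMATCH = -1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ALPHABET = set("ACGTN")


@dataclass
class IdentityResult:
    id_a: str
    id_b: str
    percent_identity: float
    verdict: str  # "redundant_candidate" | "distinct"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _align_stats(a: str, b: str) -> tuple[int, int, int]:
    """(score, matches, diag_steps) of the lexicographically best
    global alignment.  Keys are packed into one integer per cell:
    combined = (score * K1 + matches) * K2 + diags, with K1, K2 sized
    so the minor keys never borrow from the major ones.  The column
    recurrence's horizontal dependency is removed with the standard
    prefix-scan trick (each left-gap step subtracts a constant)."""
    n, m = len(a), len(b)
    K1 = min(n, m) + 2
    K2 = min(n, m) + 2
    c_gap = -GAP * K1 * K2  # combined-key cost of one gap step (positive)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], MATCH, MISMATCH).astype(np.int64)
    is_match = (av[:, None] == bv[None, :]).astype(np.int64)
    # diagonal move adds (sub, is_match, 1) -> combined increment:
    diag_inc = (sub * K1 + is_match) * K2 + 1
    up_inc = -c_gap
    j_idx = np.arange(m + 1, dtype=np.int64)
    prev = -c_gap * j_idx  # row 0: all left-gaps
    for i in range(1, n + 1):
        mid = np.empty(m + 1, dtype=np.int64)
        mid[0] = -c_gap * i
        best_du = np.maximum(prev[:-1] + diag_inc[i - 1], prev[1:] + up_inc)
        mid[1:] = best_du
        # left-gap closure: H[j] = max over k<=j of M[k] - c_gap*(j-k)
        running = np.maximum.accumulate(mid + c_gap * j_idx)
        cur = running - c_gap * j_idx
        prev = cur
    combined = int(prev[m])
    combined, diags = divmod(combined, K2)
    score, matches = divmod(combined, K1)
    return int(score), int(matches), int(diags)


def global_identity(seq_a: str, seq_b: str, id_a: str = "a", id_b: str = "b",
                    threshold: float = 80.0, both_strands: bool = True) -> IdentityResult:
    """Percent identity of the global alignment of two clone sequences.

    identity = matches / aligned columns x 100, where aligned columns
    = len(a) + len(b) - diagonal steps.  With ``both_strands`` the
    reverse complement of ``seq_b`` is also tried and the larger
    identity kept.
    """
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise ValueError(f"{name} is empty")
        bad = set(s.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"{name} contains non-ACGTN symbols: {sorted(bad)}")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    candidates = [seq_b]
    if both_strands:
        candidates.append(reverse_complement(seq_b))
    best = 0.0
    for cand in candidates:
        _, matches, diags = _align_stats(seq_a, cand)
        columns = len(seq_a) + len(cand) - diags
        best = max(best, 100.0 * matches / columns)
    verdict = "redundant_candidate" if best >= threshold else "distinct"
    return IdentityResult(id_a, id_b, best, verdict)


def alignment_score(seq_a: str, seq_b: str) -> int:
    """Optimal global alignment score alone (for cross-checks)."""
    return _align_stats(seq_a.upper(), seq_b.upper())[0]


def classify_cosegregating(
    bins: dict[str, list[str]],
    sequences: dict[str, str],
    threshold: float = 80.0,
) -> dict[str, dict]:
    """Verdict per bin of co-segregating markers.

    A bin is a ``redundant_candidate`` when every pairwise identity
    meets the threshold; otherwise it is flagged ``distinct`` with the
    offending pairs listed.  Singleton bins are reported as
    ``singleton``.  Markers without a sequence raise.
    """
    out = {}
    for bin_id, members in bins.items():
        missing = [m for m in members if m not in sequences]
        if missing:
            raise KeyError(f"no sequence for marker {missing[0]} in bin {bin_id}")
        if len(members) < 2:
            out[bin_id] = {"verdict": "singleton", "pairs": [], "offending": []}
            continue
        pairs, offending = [], []
        for a, b in itertools.combinations(sorted(members), 2):
            res = global_identity(sequences[a], sequences[b], a, b, threshold)
            pairs.append(res)
            if res.percent_identity < threshold:
                offending.append((a, b, res.percent_identity))
        verdict = "redundant_candidate" if not offending else "distinct"
        out[bin_id] = {"verdict": verdict, "pairs": pairs, "offending": offending}
    return out
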