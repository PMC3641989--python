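"""Component linkage map construction for one DH population.

The map is built in three steps.  First, markers are grouped: a graph
is formed over all markers with edges weighted by the pairwise
recombination fraction, edges above a threshold (around 0.2) are
removed, and the connected components become linkage groups.  Second,
the markers within each group are ordered by solving the travelling-
salesman *path* problem on the recombination fractions — exactly, by
Held-Karp dynamic programming, for small groups, and by nearest-
neighbour construction plus 2-opt refinement for larger ones.  Third,
adjacent-marker recombination fractions are converted to additive
centiMorgan distances with the Kosambi mapping function and accumulated
into positions anchored at 0 for the first marker of each group.

Recombination fractions in a DH population are estimated directly as
the fraction of pairwise-complete lines with discordant calls.  Because
the presence/absence coding of a dominant marker is arbitrary, a raw
fraction above 0.5 indicates opposite phase and is complemented
(r = min(raw, 1 - raw)), with the flip recorded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .qc import MISSING, GenotypeMatrix

R_CAP = 0.4999  # largest recombination fraction given a finite Kosambi distance

EXACT_ORDER_LIMIT = 12  # groups up to this size are ordered by exact DP


# ---------------------------------------------------------------------------
# Kosambi mapping function
# ---------------------------------------------------------------------------

def kosambi_cm(r):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in cM.

    Accepts scalars or arrays with r in [0, 0.5); r >= 0.5 raises since
    the distance diverges.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inv(d):
    """Inverse Kosambi: cM distance back to a recombination fraction."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    e = np.exp(d / 25.0)
    r = (e - 1.0) / (2.0 * (e + 1.0))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Pairwise recombination fractions
# ---------------------------------------------------------------------------

@dataclass
class RecombinationEstimate:
    marker_a: str
    marker_b: str
    r: float
    n_informative: int
    flipped: bool


def estimate_r(calls_a: np.ndarray, calls_b: np.ndarray,
               marker_a: str = "a", marker_b: str = "b") -> RecombinationEstimate:
    """Recombination fraction between two call vectors.

    raw = discordant / pairwise-complete; phase is resolved by taking
    r = min(raw, 1 - raw) and recording whether the complement was used.
    """
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    if calls_a.shape != calls_b.shape:
        raise ValueError("call vectors differ in length")
    both = (calls_a != MISSING) & (calls_b != MISSING)
    n = int(both.sum())
    if n == 0:
        return RecombinationEstimate(marker_a, marker_b, np.nan, 0, False)
    raw = float(np.sum((calls_a != calls_b) & both)) / n
    flipped = raw > 0.5
    return RecombinationEstimate(marker_a, marker_b, min(raw, 1.0 - raw), n, flipped)


def pairwise_r(matrix: GenotypeMatrix, min_informative: int = 20
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs recombination fractions as dense matrices.

    Returns (r, n_informative, flipped); r is NaN where fewer than
    ``min_informative`` lines are scored at both markers.  Computed via
    three matrix products on the 0/1 calls and the observation mask.
    """
    obs = (matrix.calls != MISSING).astype(np.float64)
    ones = np.where(matrix.calls == 1, 1.0, 0.0)
    n_inf = obs @ obs.T
    n11 = ones @ ones.T
    a1 = ones @ obs.T          # a==1 among co-observed
    discordant = a1 + a1.T - 2.0 * n11
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = discordant / n_inf
    raw[n_inf < min_informative] = np.nan
    flipped = raw > 0.5
    r = np.where(flipped, 1.0 - raw, raw)
    np.fill_diagonal(r, 0.0)
    return r, n_inf.astype(int), flipped


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_markers(r: np.ndarray, marker_ids: list[str], r_threshold: float = 0.2
                  ) -> tuple[list[list[str]], list[str]]:
    """Linkage groups as connected components of the thresholded graph.

    Edges with r <= r_threshold (and a defined estimate) are kept.
    Returns (groups of size >= 2, singletons); both preserve the input
    marker order within each group.
    """
    m = len(marker_ids)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    keep = np.triu(~np.isnan(r) & (r <= r_threshold), k=1)
    g.add_edges_from(zip(*np.nonzero(keep)))
    groups, singletons = [], []
    for comp in nx.connected_components(g):
        ids = [marker_ids[i] for i in sorted(comp)]
        (groups if len(ids) > 1 else singletons).append(ids if len(ids) > 1 else ids[0])
    groups.sort(key=lambda ids: (-len(ids), ids[0]))
    singletons.sort()
    return groups, singletons


# ---------------------------------------------------------------------------
# Ordering (travelling-salesman path)
# ---------------------------------------------------------------------------

@dataclass
class OrderingResult:
    order: list[str]
    objective: float
    method: str  # "exact" | "heuristic"


def _path_cost(d: np.ndarray, order: np.ndarray) -> float:
    return float(d[order[:-1], order[1:]].sum())


def _exact_path(d: np.ndarray) -> np.ndarray:
    """Held-Karp dynamic programme over subsets for the minimum-weight
    Hamiltonian path with free endpoints.  Ties broken by choosing the
    smallest predecessor index, then canonicalised against reversal."""
    n = d.shape[0]
    full = (1 << n) - 1
    cost = np.full((1 << n, n), np.inf)
    parent = np.full((1 << n, n), -1, dtype=np.int32)
    for j in range(n):
        cost[1 << j, j] = 0.0
    for s in range(1, 1 << n):
        for j in range(n):
            c = cost[s, j]
            if not np.isfinite(c) or not (s >> j) & 1:
                continue
            for k in range(n):
                if (s >> k) & 1:
                    continue
                nc = c + d[j, k]  # relax: extend the path ending at j by k
                ns = s | (1 << k)
                if nc < cost[ns, k] - 1e-15:
                    cost[ns, k] = nc
                    parent[ns, k] = j
    end = int(np.argmin(cost[full]))
    order = [end]
    s = full
    while parent[s, order[-1]] >= 0:
        p = int(parent[s, order[-1]])
        s ^= 1 << order[-1]
        order.append(p)
    return np.array(order[::-1], dtype=int)


def _nearest_neighbour(d: np.ndarray, start: int) -> np.ndarray:
    n = d.shape[0]
    visited = np.zeros(n, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(n - 1):
        row = d[order[-1]].copy()
        row[visited] = np.inf
        nxt = int(np.argmin(row))
        order.append(nxt)
        visited[nxt] = True
    return np.array(order, dtype=int)


def _two_opt(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """2-opt on the path via a virtual depot node (zero distance to
    all), so prefix/suffix reversals are ordinary tour moves.  Repeats
    first-improvement passes until no move helps."""
    n = d.shape[0]
    dd = np.zeros((n + 1, n + 1))
    dd[:n, :n] = d
    tour = np.concatenate(([n], order))  # cycle starting at the depot
    improved = True
    while improved:
        improved = False
        for i in range(1, n):
            for j in range(i + 1, n + 1):
                a, b = tour[i - 1], tour[i]
                c, e = tour[j], tour[(j + 1) % (n + 1)]
                delta = dd[a, c] + dd[b, e] - dd[a, b] - dd[c, e]
                if delta < -1e-12:
                    tour[i : j + 1] = tour[i : j + 1][::-1]
                    improved = True
    cut = int(np.argmax(tour == n))
    cycle = np.concatenate((tour[cut + 1 :], tour[:cut]))
    return cycle


def order_markers(group: list[str], r: np.ndarray, marker_ids: list[str]
                  ) -> OrderingResult:
    """Order one linkage group by minimising the sum of adjacent
    recombination fractions over Hamiltonian paths.

    Pairs without a defined estimate are imputed at r = 0.5.  Exact DP
    is used up to EXACT_ORDER_LIMIT markers, nearest-neighbour + 2-opt
    beyond; the returned order is canonicalised to the lexicographically
    smaller of itself and its reversal.
    """
    if not group:
        raise ValueError("empty group")
    idx = {m: i for i, m in enumerate(marker_ids)}
    rows = np.array([idx[m] for m in group])
    d = r[np.ix_(rows, rows)].copy()
    d[np.isnan(d)] = 0.5
    np.fill_diagonal(d, 0.0)
    n = len(group)
    if n == 1:
        return OrderingResult(list(group), 0.0, "exact")
    if n <= EXACT_ORDER_LIMIT:
        order = _exact_path(d)
        method = "exact"
    else:
        best = None
        for start in range(n):
            cand = _two_opt(d, _nearest_neighbour(d, start))
            c = _path_cost(d, cand)
            if best is None or c < best[0] - 1e-12:
                best = (c, cand)
        order = best[1]
        method = "heuristic"
    names = [group[i] for i in order]
    if names[::-1] < names:
        names = names[::-1]
        order = order[::-1]
    return OrderingResult(names, _path_cost(d, order), method)


def brute_force_order(group: list[str], r: np.ndarray, marker_ids: list[str]) -> float:
    """Exhaustive minimum path objective (independent check for small groups)."""
    idx = {m: i for i, m in enumerate(marker_ids)}
    rows = np.array([idx[m] for m in group])
    d = r[np.ix_(rows, rows)].copy()
    d[np.isnan(d)] = 0.5
    np.fill_diagonal(d, 0.0)
    perms = np.array(list(itertools.permutations(range(len(group)))))
    costs = d[perms[:, :-1], perms[:, 1:]].sum(axis=1)
    return float(costs.min())


# ---------------------------------------------------------------------------
# Component maps
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    chromosome: str
    marker_ids: list[str]
    positions: np.ndarray  # cM, first marker at 0, non-decreasing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.marker_ids) != len(self.positions):
            raise ValueError("marker/position length mismatch")
        if len(self.positions) and self.positions[0] != 0.0:
            raise ValueError("first marker of a group must sit at 0 cM")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be non-decreasing")

    @property
    def length(self) -> float:
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def reversed(self) -> "LinkageGroup":
        pos = self.positions[-1] - self.positions[::-1]
        return LinkageGroup(self.chromosome, self.marker_ids[::-1], pos)


@dataclass
class ComponentMap:
    population_id: str
    groups: list[LinkageGroup]
    singletons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            for m in g.marker_ids:
                if m in seen:
                    raise ValueError(f"marker {m} appears in more than one group")
                seen.add(m)

    @property
    def n_markers(self) -> int:
        return sum(len(g.marker_ids) for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population_id": self.population_id, "chromosome": g.chromosome,
             "marker_id": m, "pos_cM": p}
            for g in self.groups
            for m, p in zip(g.marker_ids, g.positions)
        ]
        return pd.DataFrame(rows, columns=["population_id", "chromosome", "marker_id", "pos_cM"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ComponentMap":
        pops = df["population_id"].unique()
        if len(pops) != 1:
            raise ValueError("expected a single population per map frame")
        groups = []
        for chrom, sub in df.groupby("chromosome", sort=True):
            sub = sub.sort_values("pos_cM", kind="stable")
            pos = sub["pos_cM"].to_numpy(dtype=float)
            groups.append(LinkageGroup(str(chrom), sub["marker_id"].tolist(), pos - pos[0]))
        return cls(str(pops[0]), groups)


def build_component_map(
    matrix: GenotypeMatrix,
    population_id: str = "pop",
    r_threshold: float = 0.2,
    min_informative: int = 20,
    r_cap: float = R_CAP,
) -> ComponentMap:
    """Group, order and position all markers of one population.

    Adjacent-pair recombination fractions along the ordered path are
    capped at ``r_cap`` and converted to cM by the Kosambi function;
    positions accumulate from 0.  Groups are labelled "unassigned-k"
    until anchored to chromosomes.  Markers linked to nothing are kept
    aside as singletons rather than forced into the map.
    """
    r, _, _ = pairwise_r(matrix, min_informative)
    groups, singletons = group_markers(r, matrix.marker_ids, r_threshold)
    out = []
    for k, ids in enumerate(groups, start=1):
        ordering = order_markers(ids, r, matrix.marker_ids)
        idx = {m: i for i, m in enumerate(matrix.marker_ids)}
        rows = [idx[m] for m in ordering.order]
        adj = r[rows[:-1], rows[1:]]
        adj = np.where(np.isnan(adj), r_cap, np.minimum(adj, r_cap))
        pos = np.concatenate(([0.0], np.cumsum(kosambi_cm(adj))))
        out.append(LinkageGroup(f"unassigned-{k}", ordering.order, pos))
    return ComponentMap(population_id, out, singletons)


def assign_chromosomes(cmap: ComponentMap, anchors: pd.DataFrame) -> ComponentMap:
    """Label groups by majority vote of anchor markers and orient them.

    ``anchors`` has columns marker_id, chromosome and (optionally)
    pos_cM on the anchor map.  A group with no anchored majority keeps
    an "unassigned-k" label.  When anchor positions are available and
    they correlate negatively with the group's positions, the group is
    reversed so shared markers run in the anchor direction.
    """
    if anchors.empty:
        raise ValueError("anchor table is empty")
    anchors = anchors.set_index("marker_id") if "marker_id" in anchors.columns else anchors
    groups = []
    unassigned = 0
    for g in cmap.groups:
        hits = [m for m in g.marker_ids if m in anchors.index]
        votes = pd.Series([anchors.at[m, "chromosome"] for m in hits]).value_counts()
        if len(votes) and (len(votes) == 1 or votes.iloc[0] > votes.iloc[1]):
            label = str(votes.index[0])
        else:
            unassigned += 1
            label = f"unassigned-{unassigned}"
        g = LinkageGroup(label, g.marker_ids, g.positions)
        if "pos_cM" in anchors.columns and len(hits) >= 2:
            onchrom = [m for m in hits if anchors.at[m, "chromosome"] == label]
            if len(onchrom) >= 2:
                gp = [g.positions[g.marker_ids.index(m)] for m in onchrom]
                ap = [float(anchors.at[m, "pos_cM"]) for m in onchrom]
                if np.std(gp) > 0 and np.std(ap) > 0:
                    rho = stats.spearmanr(gp, ap).statistic
                    if rho < 0:
                        g = g.reversed()
        groups.append(g)
    return ComponentMap(cmap.population_id, groups, cmap.singletons)
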