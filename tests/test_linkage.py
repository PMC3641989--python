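"""Recombination estimation, grouping, ordering and Kosambi mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dartmap import (
    SimulationConfig,
    assign_chromosomes,
    build_component_map,
    estimate_r,
    group_markers,
    kosambi_cm,
    kosambi_inv,
    order_markers,
    pairwise_r,
    simulate_dh_population,
)
from dartmap.linkage import ComponentMap, LinkageGroup, brute_force_order
from dartmap.qc import GenotypeMatrix


class TestEstimateR:
    def test_identical_vectors(self):
        v = np.array([1, 0, 1, 1, 0], dtype=np.int8)
        res = estimate_r(v, v)
        assert res.r == 0.0 and not res.flipped

    def test_complementary_vectors_phase_flip(self):
        v = np.array([1, 0, 1, 1, 0], dtype=np.int8)
        res = estimate_r(v, 1 - v)
        assert res.r == 0.0 and res.flipped

    def test_hand_count(self):
        a = np.zeros(10, dtype=np.int8)
        b = np.zeros(10, dtype=np.int8)
        b[:2] = 1
        res = estimate_r(a, b)
        assert res.r == pytest.approx(0.2)
        assert res.n_informative == 10

    def test_missing_reduces_informative_count(self):
        a = np.array([1, 0, 1, -1], dtype=np.int8)
        b = np.array([1, -1, 0, 1], dtype=np.int8)
        res = estimate_r(a, b)
        assert res.n_informative == 2
        assert res.r == pytest.approx(0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            estimate_r(np.zeros(3, dtype=np.int8), np.zeros(4, dtype=np.int8))

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 2, (6, 40)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = -1
        mat = GenotypeMatrix([f"m{i}" for i in range(6)], [f"L{j}" for j in range(40)], calls)
        r, n_inf, flipped = pairwise_r(mat, min_informative=5)
        for i in range(6):
            for j in range(i + 1, 6):
                ref = estimate_r(calls[i], calls[j])
                assert r[i, j] == pytest.approx(ref.r)
                assert n_inf[i, j] == ref.n_informative
                assert bool(flipped[i, j]) == ref.flipped


class TestKosambi:
    def test_known_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.2) == pytest.approx(25 * np.log(1.4 / 0.6))
        assert kosambi_cm(0.2) == pytest.approx(21.18, abs=0.005)

    @given(st.floats(min_value=0.0, max_value=0.4999))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, r):
        assert abs(kosambi_inv(kosambi_cm(r)) - r) < 1e-12

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)
        with pytest.raises(ValueError):
            kosambi_cm(-0.01)
        with pytest.raises(ValueError):
            kosambi_inv(-1.0)


class TestGrouping:
    def test_threshold_splits_far_marker(self):
        r = np.array(
            [
                [0.0, 0.05, 0.05, 0.45],
                [0.05, 0.0, 0.05, 0.45],
                [0.05, 0.05, 0.0, 0.45],
                [0.45, 0.45, 0.45, 0.0],
            ]
        )
        groups, singletons = group_markers(r, ["a", "b", "c", "d"], r_threshold=0.2)
        assert groups == [["a", "b", "c"]]
        assert singletons == ["d"]

    def test_empty_edge_set_all_singletons(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 0.0)
        groups, singletons = group_markers(r, ["a", "b", "c"], r_threshold=0.2)
        assert groups == []
        assert singletons == ["a", "b", "c"]

    def test_chromosomes_recovered_from_simulation(self, truth_small, clean_population):
        r, _, _ = pairwise_r(clean_population, min_informative=20)
        groups, singletons = group_markers(r, clean_population.marker_ids, 0.2)
        truth_groups = {
            frozenset(c.marker_ids) for c in truth_small.chromosomes
        }
        # each recovered group is a subset of exactly one true chromosome
        for g in groups:
            assert any(set(g) <= t for t in truth_groups)


class TestOrdering:
    @pytest.mark.parametrize("seed", range(5))
    def test_exact_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        d = rng.uniform(0, 0.5, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"m{i}" for i in range(n)]
        res = order_markers(ids, d, ids)
        assert res.method == "exact"
        assert res.objective == pytest.approx(brute_force_order(ids, d, ids), abs=1e-12)

    def test_line_geometry_recovered(self):
        pos = np.arange(10) * 4.0
        r = kosambi_inv(np.abs(pos[:, None] - pos[None, :]))
        np.fill_diagonal(r, 0.0)
        ids = [f"m{i}" for i in range(10)]
        res = order_markers(ids, r, ids)
        assert res.order in (ids, ids[::-1])

    def test_heuristic_line_geometry_recovered(self):
        pos = np.arange(30) * 4.0  # above the exact-DP size limit
        r = kosambi_inv(np.abs(pos[:, None] - pos[None, :]))
        np.fill_diagonal(r, 0.0)
        ids = [f"m{i:02d}" for i in range(30)]
        res = order_markers(ids, r, ids)
        assert res.method == "heuristic"
        assert res.order in (ids, ids[::-1])

    def test_shuffled_input_same_objective(self):
        rng = np.random.default_rng(9)
        n = 9
        d = rng.uniform(0, 0.5, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"m{i}" for i in range(n)]
        res = order_markers(ids, d, ids)
        shuffled = list(ids)
        rng.shuffle(shuffled)
        res2 = order_markers(shuffled, d, ids)
        assert res.objective == pytest.approx(res2.objective)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            order_markers([], np.zeros((0, 0)), [])


class TestComponentMap:
    def test_two_marker_map_length(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1, :20] = 1  # 20/100 discordant -> r = 0.2
        mat = GenotypeMatrix(["a", "b"], [f"L{i}" for i in range(100)], calls)
        cmap = build_component_map(mat, "p")
        assert len(cmap.groups) == 1
        assert cmap.groups[0].length == pytest.approx(21.18, abs=0.005)

    def test_position_recovery(self):
        """A noiseless 500-line population on one 20-marker chromosome
        spaced 5 cM recovers the true Kosambi positions to within 2 cM
        RMSE (sampling error in adjacent-pair r only)."""
        from dartmap.synthetic_data import TruthChromosome, TruthMap

        pos = np.arange(20) * 5.0
        chrom = TruthChromosome(
            "c", [f"m{i:02d}" for i in range(20)], pos, kosambi_inv(np.diff(pos))
        )
        truth = TruthMap([chrom])
        cfg = SimulationConfig(n_lines=500, missing_rate=0.0, error_rate=0.0, seed=71)
        mat = simulate_dh_population(truth, cfg)
        cmap = build_component_map(mat, "p", r_threshold=0.3)
        cmap = assign_chromosomes(cmap, truth.to_frame())
        (g,) = cmap.groups
        tf = truth.to_frame().set_index("marker_id")
        tp = np.array([tf.at[m, "pos_cM"] for m in g.marker_ids])
        # map coordinates are defined up to translation (the 0-anchor end
        # is arbitrary), so align on the mean before comparing
        resid = (g.positions - tp) - np.mean(g.positions - tp)
        rmse = np.sqrt(np.mean(resid**2))
        assert rmse < 2.0

    def test_interior_marker_never_shortens_map(self):
        pos = np.array([0.0, 10.0, 20.0, 30.0])
        r = kosambi_inv(np.abs(pos[:, None] - pos[None, :]))
        np.fill_diagonal(r, 0.0)
        ids = ["a", "b", "c", "d"]
        full = order_markers(ids, r, ids)
        sub = order_markers(["a", "c", "d"], r, ids)

        def length(order):
            idx = {m: i for i, m in enumerate(ids)}
            rows = [idx[m] for m in order]
            return kosambi_cm(r[rows[:-1], rows[1:]]).sum()

        assert length(full.order) >= length(sub.order) - 1e-9


class TestChromosomeAssignment:
    def _map(self):
        g = LinkageGroup("unassigned-1", ["x", "y", "z"], np.array([0.0, 5.0, 10.0]))
        return ComponentMap("p", [g])

    def test_majority_vote(self):
        anchors = pd.DataFrame(
            {"marker_id": ["x", "y", "z"], "chromosome": ["A3", "A3", "A3"],
             "pos_cM": [0.0, 5.0, 10.0]}
        )
        out = assign_chromosomes(self._map(), anchors)
        assert out.groups[0].chromosome == "A3"

    def test_tie_left_unassigned(self):
        anchors = pd.DataFrame(
            {"marker_id": ["x", "y"], "chromosome": ["A3", "C4"], "pos_cM": [0.0, 5.0]}
        )
        out = assign_chromosomes(self._map(), anchors)
        assert out.groups[0].chromosome.startswith("unassigned")

    def test_descending_anchor_order_reverses_group(self):
        anchors = pd.DataFrame(
            {"marker_id": ["x", "y", "z"], "chromosome": ["A3", "A3", "A3"],
             "pos_cM": [10.0, 5.0, 0.0]}
        )
        out = assign_chromosomes(self._map(), anchors)
        assert out.groups[0].marker_ids == ["z", "y", "x"]
        np.testing.assert_allclose(out.groups[0].positions, [0.0, 5.0, 10.0])
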