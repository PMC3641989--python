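"""Consensus integration: commonality scoring, interpolation, greedy merge."""

import numpy as np
import pandas as pd
import pytest

from dartmap import build_consensus, integrate_group, score_group
from dartmap.consensus import CommonalityScore
from dartmap.linkage import ComponentMap, LinkageGroup


def chromosome_frame(ids, pos):
    return pd.DataFrame({"marker_id": ids, "pos_cM": pos, "source": "seed"})


class TestScoring:
    def test_perfectly_proportional_positions(self):
        cons = chromosome_frame(["a", "b", "c"], [0.0, 10.0, 20.0])
        grp = LinkageGroup("A1", ["a", "b", "c"], np.array([0.0, 5.0, 10.0]))
        score, reason = score_group(grp, cons)
        assert reason == ""
        assert score.corr == pytest.approx(1.0)
        assert score.score == pytest.approx(np.log(3))

    def test_score_formula(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.uniform(0, 100, 10))
        noisy = np.sort(pos + rng.normal(0, 8, 10))
        cons = chromosome_frame([f"m{i}" for i in range(10)], pos)
        grp = LinkageGroup("A1", [f"m{i}" for i in range(10)], noisy - noisy[0])
        score, _ = score_group(grp, cons)
        expected_corr = np.corrcoef(noisy - noisy[0], pos)[0, 1]
        assert score.corr == pytest.approx(expected_corr)
        assert score.score == pytest.approx(abs(expected_corr) * np.log(10))

    def test_reversed_group_flip_flag(self):
        cons = chromosome_frame(list("abcde"), [0.0, 5.0, 10.0, 15.0, 20.0])
        grp = LinkageGroup("A1", list("edcba"), np.arange(5) * 4.0)
        score, _ = score_group(grp, cons)
        assert score.corr == pytest.approx(-1.0)
        assert score.flip
        assert score.score == pytest.approx(np.log(5))

    def test_too_few_shared_excluded(self):
        cons = chromosome_frame(["a", "b"], [0.0, 10.0])
        grp = LinkageGroup("A1", ["a", "b", "x"], np.array([0.0, 5.0, 10.0]))
        score, reason = score_group(grp, cons)
        assert score is None
        assert "n_common" in reason

    def test_degenerate_variance_excluded(self):
        cons = chromosome_frame(["a", "b", "c"], [0.0, 10.0, 20.0])
        grp = LinkageGroup("A1", ["a", "b", "c"], np.array([0.0, 0.0, 0.0]))
        score, reason = score_group(grp, cons)
        assert score is None
        assert "variance" in reason


class TestInterpolation:
    def test_linear_interpolation_and_extrapolation(self):
        # shared anchors map component (0, 10) -> consensus (20, 40);
        # interior marker at 5 -> 30, beyond-terminal marker at 15 -> 50
        cons = chromosome_frame(["a", "b"], [20.0, 40.0])
        grp = LinkageGroup("A1", ["a", "new", "b", "far"],
                           np.array([0.0, 5.0, 10.0, 15.0]))
        sc = CommonalityScore("g", 2, 1.0, np.log(2), False)
        out = integrate_group(cons, grp, sc)
        pos = dict(zip(out["marker_id"], out["pos_cM"]))
        assert pos["new"] == pytest.approx(30.0)
        assert pos["far"] == pytest.approx(50.0)
        assert pos["a"] == 20.0 and pos["b"] == 40.0  # seed positions untouched

    def test_identity_transform(self):
        cons = chromosome_frame(["a", "b", "c"], [0.0, 10.0, 20.0])
        grp = LinkageGroup("A1", ["a", "n1", "b", "c"], np.array([0.0, 4.0, 10.0, 20.0]))
        sc, _ = score_group(grp, cons)
        out = integrate_group(cons, grp, sc)
        pos = dict(zip(out["marker_id"], out["pos_cM"]))
        assert pos["n1"] == pytest.approx(4.0)

    def test_gate_enforced(self):
        cons = chromosome_frame(["a", "b"], [0.0, 10.0])
        grp = LinkageGroup("A1", ["a", "b"], np.array([0.0, 5.0]))
        sc = CommonalityScore("g", 2, 0.4, 0.4 * np.log(2), False)
        with pytest.raises(ValueError):
            integrate_group(cons, grp, sc)


class TestBuildConsensus:
    def seed_map(self):
        return ComponentMap(
            "TN",
            [LinkageGroup("A1", ["s1", "s2", "s3", "s4"],
                          np.array([0.0, 10.0, 20.0, 30.0]))],
        )

    def test_no_components_returns_seed(self):
        cons, report = build_consensus(self.seed_map(), [])
        assert cons.n_markers == 4
        assert report.empty
        np.testing.assert_allclose(
            cons.chromosomes["A1"]["pos_cM"], [0.0, 10.0, 20.0, 30.0]
        )

    def test_two_shared_markers_reported_unintegrated(self):
        comp = ComponentMap(
            "P1", [LinkageGroup("A1", ["s1", "s2", "x1"], np.array([0.0, 5.0, 8.0]))]
        )
        cons, report = build_consensus(self.seed_map(), [comp])
        assert cons.n_markers == 4
        assert len(report) == 1
        assert "n_common < 3" in report.iloc[0]["reason"]

    def test_conservation_and_determinism(self):
        rng = np.random.default_rng(8)
        seed = self.seed_map()
        comps = []
        for k in range(3):
            ids = ["s1", "s2", "s3"] + [f"p{k}_{i}" for i in range(5)]
            pos = np.sort(rng.uniform(0, 30, len(ids)))
            comps.append(ComponentMap(f"P{k}", [LinkageGroup("A1", ids, pos - pos[0])]))
        cons1, rep1 = build_consensus(seed, comps)
        cons2, rep2 = build_consensus(seed, comps)
        # determinism
        assert cons1.to_frame().equals(cons2.to_frame())
        # conservation: every input marker in consensus or report
        inputs = {m for c in comps for g in c.groups for m in g.marker_ids}
        inputs |= {m for g in seed.groups for m in g.marker_ids}
        integrated = set(cons1.marker_ids())
        unintegrated = {
            m
            for row in rep1.itertuples()
            for c in comps
            if c.population_id == row.population_id
            for g in c.groups
            if g.chromosome == row.chromosome
            for m in g.marker_ids
        }
        assert inputs <= integrated | unintegrated

    def test_seed_spacing_preserved(self):
        rng = np.random.default_rng(21)
        seed = self.seed_map()
        ids = ["s1", "s2", "s4"] + [f"n{i}" for i in range(4)]
        pos = np.sort(rng.uniform(0, 28, len(ids)))
        comp = ComponentMap("P1", [LinkageGroup("A1", ids, pos - pos[0])])
        cons, _ = build_consensus(seed, [comp])
        df = cons.chromosomes["A1"]
        pos_map = dict(zip(df["marker_id"], df["pos_cM"]))
        assert pos_map["s2"] - pos_map["s1"] == pytest.approx(10.0)
        assert pos_map["s4"] - pos_map["s3"] == pytest.approx(10.0)
        # shared markers keep their consensus order
        assert pos_map["s1"] < pos_map["s2"] < pos_map["s3"] < pos_map["s4"]

    def test_chromosome_min_translated_to_zero(self):
        seed = self.seed_map()
        # component extends below the seed's first marker
        comp = ComponentMap(
            "P1",
            [LinkageGroup("A1", ["low", "s1", "s2", "s3"],
                          np.array([0.0, 5.0, 15.0, 25.0]))],
        )
        cons, _ = build_consensus(seed, [comp])
        df = cons.chromosomes["A1"]
        assert df["pos_cM"].min() == 0.0
        assert df.iloc[0]["marker_id"] == "low"

    def test_seed_must_have_unique_chromosomes(self):
        g1 = LinkageGroup("A1", ["a"], np.array([0.0]))
        g2 = LinkageGroup("A1", ["b"], np.array([0.0]))
        with pytest.raises(ValueError):
            build_consensus(ComponentMap("TN", [g1, g2]), [])

    def test_provenance_tracks_populations(self):
        comp = ComponentMap(
            "P1",
            [LinkageGroup("A1", ["s1", "s2", "s3", "new"],
                          np.array([0.0, 10.0, 20.0, 25.0]))],
        )
        cons, _ = build_consensus(self.seed_map(), [comp])
        assert cons.provenance["s1"] == ["TN", "P1"]
        assert cons.provenance["new"] == ["P1"]
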