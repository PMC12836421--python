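import numpy as np
import pandas as pd
import pytest

from delhit import descriptors as D
from delhit.project_rank import (
    assign_clusters,
    comparison_indicator,
    conditional_sums,
    ipca_axes,
    similarity_rank,
)


def arm_blocks(rng, n=500):
    base = rng.gamma(2, 1, n)
    cols = ["SR", "SC", "SnR", "SnC", "sigmaR", "sigmaC"]
    idx = [f"{i}-0-0" for i in range(n)]
    total = pd.DataFrame({c: base * rng.uniform(0.8, 1.2, n) for c in cols}, index=idx)
    phospho = pd.DataFrame({c: base * rng.uniform(0.8, 1.2, n) for c in cols}, index=idx)
    return total, phospho


class TestIPCA:
    def test_rank_one_block_recovered(self):
        t = np.linspace(0, 1, 40)[:, None] * np.array([[1, 2, 3, 4, 5, 6.0]])
        idx = [f"{i}-0-0" for i in range(40)]
        cols = ["SR", "SC", "SnR", "SnC", "sigmaR", "sigmaC"]
        block = pd.DataFrame(t, columns=cols, index=idx)
        xy = ipca_axes(block, block)
        # scores must be affine in the line parameter (variance fully captured)
        x = xy["x"].to_numpy()
        param = np.linspace(0, 1, 40)
        corr = np.corrcoef(x, param)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)

    def test_duplication_invariance(self, rng):
        total, phospho = arm_blocks(rng, 100)
        xy1 = ipca_axes(total, phospho)
        dup_t = pd.concat([total, total.set_index(total.index + "d")])
        dup_p = pd.concat([phospho, phospho.set_index(phospho.index + "d")])
        xy2 = ipca_axes(dup_t, dup_p)
        np.testing.assert_allclose(xy2["x"].to_numpy()[:100], xy2["x"].to_numpy()[100:], atol=1e-9)

    def test_incremental_matches_single_batch(self, rng):
        total, phospho = arm_blocks(rng, 500)
        xy_full = ipca_axes(total, phospho, batch_size=500)
        xy_mini = ipca_axes(total, phospho, batch_size=125)
        for col in ("x", "y"):
            a, b = xy_full[col].to_numpy(), xy_mini[col].to_numpy()
            if np.corrcoef(a, b)[0, 1] < 0:
                b = -b
            assert np.corrcoef(a, b)[0, 1] > 1 - 1e-8
            np.testing.assert_allclose(a, b, atol=5e-3)

    def test_orientation_follows_sr(self, rng):
        total, phospho = arm_blocks(rng)
        xy = ipca_axes(total, phospho)
        assert np.corrcoef(xy["x"], total["SR"])[0, 1] >= 0
        assert np.corrcoef(xy["y"], phospho["SR"])[0, 1] >= 0

    def test_zero_variance_rejected(self):
        cols = ["SR", "SC", "SnR", "SnC", "sigmaR", "sigmaC"]
        block = pd.DataFrame(np.ones((10, 6)), columns=cols)
        with pytest.raises(ValueError, match="no signal"):
            ipca_axes(block, block)


class TestAssignClusters:
    def test_symmetric_split(self):
        xy = pd.DataFrame({"x": [-1.0, 1.0], "y": [0.0, 0.0]}, index=["a", "b"])
        sides = assign_clusters(xy)
        assert list(sides) == ["negative", "positive"]

    def test_exact_zero_is_negative(self):
        xy = pd.DataFrame({"x": [0.0], "y": [5.0]}, index=["a"])
        assert assign_clusters(xy).iloc[0] == "negative"


def richness_pair(phospho_rows, total_rows, index=None):
    idx = index or [f"{i}-0-0" for i in range(len(phospho_rows))]
    p = pd.DataFrame(phospho_rows, index=idx)
    t = pd.DataFrame(total_rows, index=idx)
    t.columns = p.columns
    return p, t


class TestComparisonIndicator:
    def test_three_of_five_majority(self):
        p, t = richness_pair([[5, 5, 5, 1, 1]], [[1, 1, 1, 5, 5]])
        ind = comparison_indicator(p, t)
        assert ind["indicator"].iloc[0] == 1
        assert ind["dominant_side"].iloc[0] == "phospho"

    def test_all_equal_tie(self):
        p, t = richness_pair([[2, 2, 2]], [[2, 2, 2]])
        ind = comparison_indicator(p, t)
        assert ind["indicator"].iloc[0] == 0
        assert ind["dominant_side"].iloc[0] == "tie"

    def test_single_replicate(self):
        p, t = richness_pair([[3.0]], [[1.0]])
        ind = comparison_indicator(p, t)
        assert ind["indicator"].iloc[0] == 1
        assert ind["dominant_side"].iloc[0] == "phospho"
        assert ind["dominant_mask"].iloc[0].tolist() == [True]

    def test_antisymmetry(self, rng):
        p, t = richness_pair(rng.gamma(2, 3, (50, 5)).tolist(), rng.gamma(2, 3, (50, 5)).tolist())
        fwd = comparison_indicator(p, t)
        rev = comparison_indicator(t, p)
        assert (fwd["indicator"].to_numpy() == -rev["indicator"].to_numpy()).all()
        flip = {"phospho": "total", "total": "phospho", "tie": "tie"}
        assert all(flip[a] == b for a, b in zip(fwd["dominant_side"], rev["dominant_side"]))

    def test_no_replicates_rejected(self):
        p = pd.DataFrame(index=["a"])
        with pytest.raises(ValueError, match="no paired replicates"):
            comparison_indicator(p, p)


class TestConditionalSums:
    def test_worked_example(self, worked_matrix):
        man = worked_matrix.manifest
        pairs = man.paired_replicates("pY1355")
        rich = D.richness_table(worked_matrix)
        p = rich[[a.key for a, _ in pairs]]
        t = rich[[b.key for _, b in pairs]]
        ind = comparison_indicator(p, t)
        assert ind["dominant_side"].iloc[0] == "phospho"
        assert ind["dominant_mask"].iloc[0].sum() == 3
        cond = conditional_sums(p, t, ind)
        assert cond["SR_cond_phospho"].iloc[0] == pytest.approx(1628.53, abs=1e-9)
        assert cond["SR_cond_total"].iloc[0] == pytest.approx(8.85, abs=1e-9)

    def test_hand_enumeration(self):
        p, t = richness_pair([[10, 10, 10, 0, 0]], [[1, 1, 1, 5, 5]])
        ind = comparison_indicator(p, t)
        cond = conditional_sums(p, t, ind)
        assert cond["SR_cond_phospho"].iloc[0] == 30
        assert cond["SR_cond_total"].iloc[0] == 3

    def test_unanimous_preference_equals_full_sum(self):
        p, t = richness_pair([[4, 5, 6]], [[1, 2, 3]])
        ind = comparison_indicator(p, t)
        cond = conditional_sums(p, t, ind)
        assert cond["SR_cond_phospho"].iloc[0] == 15
        assert not cond["tie_flag"].iloc[0]

    def test_conditional_never_exceeds_full(self, rng):
        p, t = richness_pair(rng.gamma(2, 3, (100, 5)).tolist(), rng.gamma(2, 3, (100, 5)).tolist())
        ind = comparison_indicator(p, t)
        cond = conditional_sums(p, t, ind)
        assert (cond["SR_cond_phospho"].to_numpy() <= p.sum(axis=1).to_numpy() + 1e-9).all()
        assert (cond["SR_cond_total"].to_numpy() <= t.sum(axis=1).to_numpy() + 1e-9).all()


class TestSimilarityRank:
    def make_inputs(self, coords, I=None):
        idx = [f"{i}-0-0" for i in range(len(coords))]
        xy = pd.DataFrame(coords, columns=["x", "y"], index=idx)
        sides = pd.Series("positive", index=idx)
        ind = pd.DataFrame({
            "indicator": I if I is not None else [5] * len(coords),
            "dominant_side": ["phospho"] * len(coords),
            "dominant_mask": [np.ones(5, bool)] * len(coords),
        }, index=idx)
        cond = pd.DataFrame({
            "SR_cond_phospho": [100.0] * len(coords),
            "SR_cond_total": [10.0] * len(coords),
            "tie_flag": [False] * len(coords),
        }, index=idx)
        return xy, sides, ind, cond

    def test_vertex_candidate_ranks_first(self):
        xy, sides, ind, cond = self.make_inputs([(1.0, 1.0), (0.2, 0.3), (0.5, 0.4)])
        out = similarity_rank(xy, sides, ind, cond)
        assert out.index[0] == "0-0-0"
        assert out["score"].iloc[0] == pytest.approx(1.0)
        assert out["rank"].iloc[0] == 1

    def test_hand_euclidean_order(self):
        xy, sides, ind, cond = self.make_inputs([(1.0, 1.0), (0.0, 0.0), (0.5, 0.9)])
        out = similarity_rank(xy, sides, ind, cond).sort_index()
        ranks = dict(zip(out.index, out["rank"]))
        assert ranks["0-0-0"] == 1 and ranks["2-0-0"] == 2 and ranks["1-0-0"] == 3

    def test_rank_is_permutation_sorted_by_score(self, rng):
        n = 50
        coords = rng.uniform(-1, 1, (n, 2)).tolist()
        xy, sides, ind, cond = self.make_inputs(coords, I=rng.integers(1, 6, n))
        out = similarity_rank(xy, sides, ind, cond)
        assert sorted(out["rank"]) == list(range(1, len(out) + 1))
        assert (out.sort_values("rank")["score"].diff().dropna() <= 1e-12).all()

    def test_pool_requires_phospho_dominance(self):
        xy, sides, ind, cond = self.make_inputs([(1.0, 1.0), (0.9, 0.9)])
        ind.loc["1-0-0", "dominant_side"] = "total"
        out = similarity_rank(xy, sides, ind, cond)
        assert list(out.index) == ["0-0-0"]

    def test_empty_pool_warns(self):
        xy, sides, ind, cond = self.make_inputs([(1.0, 1.0)])
        sides[:] = "negative"
        with pytest.warns(UserWarning, match="empty candidate pool"):
            out = similarity_rank(xy, sides, ind, cond)
        assert len(out) == 0
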