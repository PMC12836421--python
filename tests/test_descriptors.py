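import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from delhit import descriptors as D
from delhit.io_manifest import CountMatrix, ManifestEntry, SelectionManifest


def make_matrix(counts: dict, pre: dict, n_phospho=3, n_total=2):
    """Counts: {code: [per-file counts]}, first n_phospho files phospho."""
    files = []
    nfiles = len(next(iter(counts.values())))
    for i in range(nfiles):
        arm = "phospho" if i < n_phospho else "total"
        rep = i + 1 if i < n_phospho else i - n_phospho + 1
        files.append(ManifestEntry(path=f"f{i}.erh", arm=arm, arm_label=arm,
                                   replicate=rep, value_kind="count"))
    # relax pairing for synthetic unit fixtures: pad totals to match
    man = SelectionManifest.__new__(SelectionManifest)
    man.files = files
    man.pre_selection = "pre.erh"
    idx = pd.Index(list(counts), name="compound")
    cdf = pd.DataFrame([counts[c] for c in idx], index=idx,
                       columns=[e.key for e in files], dtype=float)
    pre_s = pd.Series({c: float(pre.get(c, 0)) for c in idx}, name="pre")
    return CountMatrix(counts=cdf, richness=None, pre_counts=pre_s, manifest=man)


class TestRichness:
    def test_direct_ratio(self):
        # 0.01% post vs 0.001% pre -> richness 10
        post = pd.DataFrame({"f": [1.0, 9999.0]}, index=["a", "b"])
        pre = pd.Series([1.0, 99999.0], index=["a", "b"])
        r = D.compute_richness(post, pre)
        assert r.loc["a", "f"] == pytest.approx(10.0)

    def test_identity_when_frequencies_match(self):
        post = pd.DataFrame({"f": [10.0, 30.0]}, index=["a", "b"])
        pre = pd.Series([1.0, 3.0], index=["a", "b"])
        r = D.compute_richness(post, pre)
        assert np.allclose(r["f"], 1.0)

    def test_zero_pre_count_flagged_nan(self):
        post = pd.DataFrame({"f": [5.0, 5.0]}, index=["a", "b"])
        pre = pd.Series([0.0, 10.0], index=["a", "b"])
        r = D.compute_richness(post, pre)
        assert np.isnan(r.loc["a", "f"])

    def test_empty_file_rejected(self):
        post = pd.DataFrame({"f": [0.0, 0.0]}, index=["a", "b"])
        pre = pd.Series([1.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError, match="zero total"):
            D.compute_richness(post, pre)

    def test_exact_fraction_oracle(self, rng):
        n = 100
        post = pd.DataFrame({"f1": rng.integers(0, 50, n), "f2": rng.integers(0, 50, n)},
                            index=[f"{i}-0-0" for i in range(n)]).astype(float)
        post.iloc[0] = [1, 1]  # keep totals nonzero
        pre = pd.Series(rng.integers(1, 40, n), index=post.index).astype(float)
        r = D.compute_richness(post, pre)
        t1, t2 = int(post["f1"].sum()), int(post["f2"].sum())
        tp = int(pre.sum())
        for i in rng.choice(n, 20, replace=False):
            for col, tot in (("f1", t1), ("f2", t2)):
                expect = Fraction(int(post[col].iloc[i]), tot) / Fraction(int(pre.iloc[i]), tp)
                assert r[col].iloc[i] == pytest.approx(float(expect), rel=1e-12)


class TestDescriptors:
    def test_hand_arithmetic(self):
        # richness profile [2, 4, 6] engineered via counts and pre-frequencies
        mat = make_matrix({"a": [2, 4, 6], "b": [8, 6, 4]}, {"a": 10, "b": 10},
                          n_phospho=3, n_total=0)
        scope = D.DescriptorScope("all", ["1-phospho", "2-phospho", "3-phospho"])
        tab = D.compute_descriptors(mat, scope)
        # counts: SR uses richness; verify count-side aggregates directly
        assert tab.loc["a", "SC"] == 12
        assert tab.loc["a", "SnC"] == 3
        assert tab.loc["a", "sigmaC"] == pytest.approx(2.0)
        assert tab.loc["a", "kappaC"] == pytest.approx(4.0 / 2.0)

    def test_phi_bal_zero_iff_kappas_equal(self):
        # constant per-file totals make richness proportional to counts for
        # each compound, forcing kappaR == kappaC and hence phi_bal == 0
        mat = make_matrix({"a": [2, 4, 6], "b": [6, 4, 2]}, {"a": 10, "b": 10},
                          n_phospho=3, n_total=0)
        scope = D.DescriptorScope("all", ["1-phospho", "2-phospho", "3-phospho"])
        tab = D.compute_descriptors(mat, scope)
        assert tab.loc["a", "phi_bal"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["a", "kappaR"] == pytest.approx(tab.loc["a", "kappaC"], rel=1e-12)

    def test_single_replicate_spike(self):
        mat = make_matrix({"a": [5, 0, 0, 0, 0], "b": [1, 1, 1, 1, 2]},
                          {"a": 5, "b": 5}, n_phospho=5, n_total=0)
        scope = D.DescriptorScope("all", [f"{i}-phospho" for i in range(1, 6)])
        tab = D.compute_descriptors(mat, scope)
        assert tab.loc["a", "SnR"] == 1
        assert tab.loc["b", "SnR"] == 5

    def test_naive_oracle_agreement(self, small_campaign):
        matrix, manifest, _ = small_campaign
        scope = D.pooled_scope(manifest)
        tab = D.compute_descriptors(matrix, scope)
        rich = D.richness_table(matrix)[scope.members]
        cnt = matrix.counts[scope.members]
        rng = np.random.default_rng(1)
        picks = rng.choice(len(tab), 50, replace=False)
        for i in picks:
            code = tab.index[i]
            R = rich.loc[code].to_numpy()
            C = cnt.loc[code].to_numpy()
            n = len(R)
            mean = sum(R) / n
            var = sum((x - mean) ** 2 for x in R) / (n - 1)
            sigmaR = math.sqrt(var)
            assert tab.loc[code, "SR"] == pytest.approx(sum(R), rel=1e-12)
            assert tab.loc[code, "SnR"] == sum(1 for x in R if x > 0)
            assert tab.loc[code, "sigmaR"] == pytest.approx(sigmaR, rel=1e-12, abs=1e-15)
            if tab.loc[code, "valid_tier3"]:
                ratios = [r / c for r, c in zip(R, C) if c > 0]
                assert tab.loc[code, "phi_eff"] == pytest.approx(
                    sum(ratios) / len(ratios), rel=1e-12)
                meanC = sum(C) / n
                sigmaC = math.sqrt(sum((x - meanC) ** 2 for x in C) / (n - 1))
                kR = mean / sigmaR
                kC = meanC / sigmaC
                assert tab.loc[code, "kappaR"] == pytest.approx(kR, rel=1e-12)
                assert tab.loc[code, "phi_bal"] == pytest.approx(
                    abs(math.log2(kR / kC)), rel=1e-9, abs=1e-12)

    def test_depth_invariance(self, small_campaign):
        """Multiplying one file's counts by a constant leaves richness unchanged."""
        matrix, manifest, _ = small_campaign
        scope = D.pooled_scope(manifest)
        r1 = D.richness_table(matrix)
        key = manifest.files[0].key
        scaled = matrix.counts.copy()
        scaled[key] = scaled[key] * 7.0
        totals = matrix.file_totals.copy()
        totals[key] = totals[key] * 7.0
        mat2 = CountMatrix(counts=scaled, richness=None, pre_counts=matrix.pre_counts,
                           manifest=manifest, file_totals=totals, pre_total=matrix.pre_total)
        r2 = D.richness_table(mat2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_kappa_scale_invariance(self):
        mat1 = make_matrix({"a": [2, 4, 6], "b": [6, 4, 2]}, {"a": 10, "b": 10},
                           n_phospho=3, n_total=0)
        mat2 = make_matrix({"a": [6, 12, 18], "b": [18, 12, 6]}, {"a": 10, "b": 10},
                           n_phospho=3, n_total=0)
        scope = D.DescriptorScope("all", ["1-phospho", "2-phospho", "3-phospho"])
        t1, t2 = D.compute_descriptors(mat1, scope), D.compute_descriptors(mat2, scope)
        # counts tripled: kappa (mean over sigma) invariant, sums scale
        assert t1.loc["a", "kappaC"] == pytest.approx(t2.loc["a", "kappaC"], rel=1e-12)
        assert t1.loc["a", "kappaR"] == pytest.approx(t2.loc["a", "kappaR"], rel=1e-12)
        assert t2.loc["a", "SC"] == pytest.approx(3 * t1.loc["a", "SC"])
        assert t2.loc["a", "SR"] == pytest.approx(t1.loc["a", "SR"], rel=1e-12)

    def test_scope_requires_two_members(self):
        with pytest.raises(ValueError, match=">= 2"):
            D.DescriptorScope("solo", ["1-phospho"])


class TestValidityFilter:
    def test_zero_sigma_removed(self):
        mat = make_matrix({"const": [3, 3, 3], "var": [1, 2, 3]},
                          {"const": 5, "var": 5}, n_phospho=3, n_total=0)
        scope = D.DescriptorScope("all", ["1-phospho", "2-phospho", "3-phospho"])
        tab = D.compute_descriptors(mat, scope)
        valid, removed = D.apply_validity_filter(tab)
        assert "var" in valid.index
        assert [c for c, _ in removed] == ["const"]

    def test_predicate_oracle(self, small_campaign):
        matrix, manifest, _ = small_campaign
        scope = D.pooled_scope(manifest)
        tab = D.compute_descriptors(matrix, scope)
        valid, removed = D.apply_validity_filter(tab)
        removed_set = {c for c, _ in removed}
        rich = D.richness_table(matrix)[scope.members]
        cnt = matrix.counts[scope.members]
        for code in tab.index[:2000]:
            R, C = rich.loc[code], cnt.loc[code]
            ok = (R.sum() > 0 and C.sum() > 0 and R.std(ddof=1) > 0 and C.std(ddof=1) > 0
                  and not R.isna().any())
            assert (str(code) in removed_set) == (not ok)
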