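"""Cohort statistics: Welch/paired/Tukey contrasts, correlation, PCA."""

import numpy as np
import pytest
from scipy import stats as sps

from sepsispanel.io import SampleRecord
from sepsispanel.stats import (
    ContrastError,
    paired_contrast,
    pca_panels,
    permutation_fwer,
    score_sofa_correlation,
    tukey_contrasts,
    two_group_contrast,
)

from conftest import make_scores


def records_for(groups, timepoints=None, subjects=None, sofa=None):
    n = len(groups)
    return [
        SampleRecord(
            sample_id=f"S{i+1}",
            subject_id=subjects[i] if subjects else None,
            group=groups[i],
            timepoint=timepoints[i] if timepoints else None,
            sofa=sofa[i] if sofa else None,
        )
        for i in range(n)
    ]


class TestTwoGroup:
    def test_identical_groups_null(self):
        sc = make_scores(NDrG=[1, 2, 3, 1, 2, 3])
        recs = records_for(["a"] * 3 + ["b"] * 3)
        c = two_group_contrast(sc, recs, "a", "b", "NDrG")
        assert c.mean_diff == 0 and c.p_value == pytest.approx(1.0)

    def test_shift_detected(self):
        jitter = np.array([0, 1e-6, -1e-6, 2e-6])
        sc = make_scores(NDrG=np.concatenate([jitter, 5 + jitter]))
        recs = records_for(["a"] * 4 + ["b"] * 4)
        c = two_group_contrast(sc, recs, "a", "b", "NDrG")
        assert c.mean_diff == pytest.approx(5.0, abs=1e-5)
        assert c.p_value < 1e-6

    def test_welch_statistic_and_df(self):
        # hand evaluation of the Welch formulas: means 2 and 4, variances 1 and 4,
        # se^2 = 1/3 + 4/3, t = 2/sqrt(5/3) = 1.5492 (oriented B−A),
        # df = (5/3)^2 / ((1/3)^2/2 + (4/3)^2/2) = 2.9412
        sc = make_scores(NDrG=[1, 2, 3, 2, 4, 6])
        recs = records_for(["a"] * 3 + ["b"] * 3)
        c = two_group_contrast(sc, recs, "a", "b", "NDrG")
        assert c.mean_diff == pytest.approx(2.0)
        assert c.statistic == pytest.approx(1.5491933, abs=1e-6)
        assert c.df == pytest.approx(2.9411765, abs=1e-6)

    def test_swap_negates_diff_keeps_p(self):
        rng = np.random.default_rng(1)
        sc = make_scores(NDrG=rng.normal(size=10))
        recs = records_for(["a"] * 5 + ["b"] * 5)
        ab = two_group_contrast(sc, recs, "a", "b", "NDrG")
        ba = two_group_contrast(sc, recs, "b", "a", "NDrG")
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_small_or_degenerate_groups_rejected(self):
        sc = make_scores(NDrG=[1, 2, 3])
        with pytest.raises(ContrastError):
            two_group_contrast(sc, records_for(["a", "b", "b"]), "a", "b", "NDrG")
        sc2 = make_scores(NDrG=[2, 2, 2, 2])
        with pytest.raises(ContrastError, match="variance"):
            two_group_contrast(sc2, records_for(["a", "a", "b", "b"]), "a", "b", "NDrG")


class TestPaired:
    def test_deltas_123(self):
        # deltas [1,2,3]: t = 2/(1/sqrt(3)) = 3.4641, df 2; two-sided p from the
        # closed-form t CDF at df=2, CDF(t) = 1/2 + t/(2 sqrt(t^2+2)) -> 0.0742
        sc = make_scores(NDrG=[5.0, 5.0, 5.0, 6.0, 7.0, 8.0],
                         sample_ids=["a1", "a2", "a3", "b1", "b2", "b3"])
        recs = [
            SampleRecord(f"{tp_label}{i}", subject_id=f"P{i}", timepoint=tp)
            for tp, tp_label in (("T1", "a"), ("T2", "b"))
            for i in (1, 2, 3)
        ]
        c = paired_contrast(sc, recs, "T1", "T2", "NDrG")
        assert c.mean_diff == pytest.approx(2.0)
        assert c.statistic == pytest.approx(3.4641016, abs=1e-6)
        assert c.df == 2
        assert c.p_value == pytest.approx(0.0742, abs=2e-4)

    def test_incomplete_pairs_dropped(self):
        sc = make_scores(NDrG=[1.0, 2.0, 3.0, 9.0, 4.5],
                         sample_ids=["a1", "a2", "b1", "b2", "a3"])
        recs = [
            SampleRecord("a1", subject_id="P1", timepoint="T1"),
            SampleRecord("a2", subject_id="P2", timepoint="T1"),
            SampleRecord("b1", subject_id="P1", timepoint="T2"),
            SampleRecord("b2", subject_id="P2", timepoint="T2"),
            SampleRecord("a3", subject_id="P3", timepoint="T1"),  # no T2
        ]
        c = paired_contrast(sc, recs, "T1", "T2", "NDrG")
        assert c.n_a == 2  # complete pairs only

    def test_zero_delta_variance_degenerate(self):
        sc = make_scores(NDrG=[1.0, 2.0, 2.0, 3.0], sample_ids=["a1", "a2", "b1", "b2"])
        recs = [
            SampleRecord("a1", subject_id="P1", timepoint="T1"),
            SampleRecord("a2", subject_id="P2", timepoint="T1"),
            SampleRecord("b1", subject_id="P1", timepoint="T2"),
            SampleRecord("b2", subject_id="P2", timepoint="T2"),
        ]
        with pytest.raises(ContrastError, match="degenerate"):
            paired_contrast(sc, recs, "T1", "T2", "NDrG")


class TestTukey:
    def test_identical_groups_p_one(self):
        sc = make_scores(NDrG=[1, 2, 3] * 3)
        recs = records_for(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        for c in tukey_contrasts(sc, recs, ["a", "b", "c"], "NDrG"):
            assert c.p_value == pytest.approx(1.0)

    def test_two_groups_reduce_to_pooled_t(self):
        # with k = 2 the studentized range q equals sqrt(2)|t|, so the Tukey
        # p equals the pooled-variance two-sample t p
        rng = np.random.default_rng(5)
        vals = rng.normal(size=12)
        sc = make_scores(NDrG=vals)
        recs = records_for(["a"] * 6 + ["b"] * 6)
        (c,) = tukey_contrasts(sc, recs, ["a", "b"], "NDrG")
        t = sps.ttest_ind(vals[6:], vals[:6], equal_var=True)
        assert c.p_value == pytest.approx(t.pvalue, abs=1e-9)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, size=(4, 6))
        base[3] += 10  # one group shifted by 10 SD
        sc = make_scores(NDrG=base.ravel())
        recs = records_for(sum([[g] * 6 for g in "abcd"], []))
        comps = tukey_contrasts(sc, recs, list("abcd"), "NDrG")
        for c in comps:
            involved = "d" in (c.group_a, c.group_b)
            assert (c.p_value < 1e-3) == involved

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(7)
        sc = make_scores(NDrG=rng.normal(0, 1, 18) + np.repeat([0, 0.8, 1.6], 6))
        recs = records_for(sum([[g] * 6 for g in "abc"], []))
        for c in tukey_contrasts(sc, recs, list("abc"), "NDrG"):
            a = [sc.values["NDrG"][r.sample_id] for r in recs if r.group == c.group_a]
            b = [sc.values["NDrG"][r.sample_id] for r in recs if r.group == c.group_b]
            raw = sps.ttest_ind(b, a, equal_var=True).pvalue
            assert c.p_value >= raw - 1e-12

    def test_against_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 20) + np.repeat([0.0, 0.5, 1.5, 0.2], 5)
        groups = np.repeat(list("abcd"), 5)
        sc = make_scores(NDrG=vals)
        recs = records_for(list(groups))
        ours = {(c.group_a, c.group_b): c.p_value
                for c in tukey_contrasts(sc, recs, list("abcd"), "NDrG")}
        sm = pairwise_tukeyhsd(vals, groups)
        import itertools

        pairs = list(itertools.combinations(sm.groupsunique, 2))
        for (g1, g2), p in zip(pairs, sm.pvalues):
            assert ours[(g1, g2)] == pytest.approx(p, abs=1e-6)

    def test_against_permutation_oracle(self):
        rng = np.random.default_rng(9)
        arrays = [rng.normal(0, 1, 8), rng.normal(0.3, 1, 8), rng.normal(2.5, 1, 8)]
        sc = make_scores(NDrG=np.concatenate(arrays))
        recs = records_for(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        comps = tukey_contrasts(sc, recs, ["a", "b", "c"], "NDrG")
        perm = permutation_fwer(arrays, n_perm=4000, seed=11)
        for c, p_perm in zip(comps, perm):
            # both routes agree on clear separations and clear nulls; the
            # permutation max-statistic is somewhat less powerful, so the
            # agreement is checked with a band, not at a single cutoff
            if c.p_value < 0.005:
                assert p_perm < 0.05
            if c.p_value > 0.3:
                assert p_perm > 0.05


class TestCorrelation:
    def test_perfect_linearity(self):
        sc = make_scores(NDrG=[1, 2, 3])
        recs = records_for(["g"] * 3, sofa=[2, 4, 6])
        assert score_sofa_correlation(sc, recs, "NDrG").r == pytest.approx(1.0)

    def test_hand_computed_r(self):
        sc = make_scores(NDrG=[1, 2, 3])
        recs = records_for(["g"] * 3, sofa=[6, 4, 5])
        assert score_sofa_correlation(sc, recs, "NDrG").r == pytest.approx(-0.5)

    def test_missing_sofa_excluded(self):
        sc = make_scores(NDrG=[1, 2, 3, 4])
        recs = records_for(["g"] * 4, sofa=[2, 4, 6, None])
        res = score_sofa_correlation(sc, recs, "NDrG")
        assert res.n == 3 and res.r == pytest.approx(1.0)

    def test_too_few_cases_rejected(self):
        sc = make_scores(NDrG=[1, 2])
        recs = records_for(["g"] * 2, sofa=[2, 4])
        with pytest.raises(ContrastError):
            score_sofa_correlation(sc, recs, "NDrG")


class TestPCA:
    @staticmethod
    def scores_from(X):
        cols = dict(zip(["NDrG", "ISGa", "GBPs", "HLAd", "LYMd"], X.T))
        return make_scores(**cols)

    def test_isotropic_variance_fractions(self):
        rng = np.random.default_rng(10)
        res = pca_panels(self.scores_from(rng.normal(size=(4000, 5))), k=5)
        np.testing.assert_allclose(res.variance_fractions, 0.2, atol=0.03)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)

    def test_two_factor_structure_matches_loading_pattern(self):
        # factor 1 drives NDrG/−HLAd/−LYMd, factor 2 drives ISGa/GBPs
        rng = np.random.default_rng(11)
        n = 600
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        eps = 0.3 * rng.normal(size=(5, n))
        X = np.vstack([2 * f1 + eps[0], 1.5 * f2 + eps[1], 1.5 * f2 + eps[2],
                       -2 * f1 + eps[3], -2 * f1 + eps[4]]).T
        res = pca_panels(self.scores_from(X), k=2)
        L = res.loadings.abs()
        assert L.loc[["NDrG", "HLAd", "LYMd"], "PC1"].min() > L.loc[["ISGa", "GBPs"], "PC1"].max()
        assert L.loc[["ISGa", "GBPs"], "PC2"].min() > L.loc[["NDrG", "HLAd", "LYMd"], "PC2"].max()

    def test_loadings_unit_norm_and_sign_convention(self):
        rng = np.random.default_rng(12)
        res = pca_panels(self.scores_from(rng.normal(size=(50, 5))), k=3)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose((L**2).sum(axis=0), 1.0, atol=1e-12)
        for j in range(L.shape[1]):
            assert L[np.abs(L[:, j]).argmax(), j] > 0

    def test_dominant_factor_eigenvalue_oracle(self):
        # single latent factor with loadings a: top eigenvalue of the constructed
        # correlation matrix gives PC1's variance fraction = lambda1 / 5
        rng = np.random.default_rng(13)
        n = 20000
        a = np.array([1.0, 0.8, 0.6, -0.9, -0.7])
        f = rng.normal(size=n)
        X = a[None, :] * f[:, None] + 0.5 * rng.normal(size=(n, 5))
        res = pca_panels(self.scores_from(X), k=5)
        corr = np.corrcoef(X, rowvar=False)
        lam1 = np.linalg.eigvalsh(corr)[-1]
        assert res.variance_fractions[0] == pytest.approx(lam1 / 5, abs=1e-3)

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(30, 5))
        X[:, 2] = 3.0
        with pytest.raises(ContrastError, match="constant"):
            pca_panels(self.scores_from(X), k=2)


def test_null_rejection_rate_calibrated():
    """Identical groups: Welch and paired tests reject at <= 7% at alpha=0.05."""
    rng = np.random.default_rng(20)
    n, reps = 10, 1000
    rej_welch = rej_paired = 0
    for _ in range(reps):
        a, b = rng.normal(size=n), rng.normal(size=n)
        sc = make_scores(NDrG=np.concatenate([a, b]),
                         sample_ids=[f"x{i}" for i in range(2 * n)])
        recs = [SampleRecord(f"x{i}", group="a" if i < n else "b") for i in range(2 * n)]
        if two_group_contrast(sc, recs, "a", "b", "NDrG").p_value < 0.05:
            rej_welch += 1
        sc2 = make_scores(NDrG=np.concatenate([a, a + rng.normal(size=n)]),
                          sample_ids=[f"t1_{i}" for i in range(n)] + [f"t2_{i}" for i in range(n)])
        recs2 = [SampleRecord(f"t1_{i}", subject_id=f"P{i}", timepoint="T1") for i in range(n)] + \
                [SampleRecord(f"t2_{i}", subject_id=f"P{i}", timepoint="T2") for i in range(n)]
        if paired_contrast(sc2, recs2, "T1", "T2", "NDrG").p_value < 0.05:
            rej_paired += 1
    assert rej_welch / reps <= 0.07
    assert rej_paired / reps <= 0.07
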