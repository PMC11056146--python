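"""Repeated-measures battery: GG epsilon, ANOVA, Tukey, paired t, Holm."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from wmhtraj.stats import (
    class_means,
    gg_epsilon,
    holm_adjust,
    paired_tests,
    rm_anova_gg,
    tukey_pairwise,
)


class TestGgEpsilon:
    def test_k2_always_one(self, rng):
        x = rng.standard_normal((12, 2)) * [3.0, 0.5]
        assert gg_epsilon(x) == 1.0

    def test_compound_symmetry_gives_one(self, rng):
        """Exactly compound-symmetric covariance satisfies sphericity."""
        n, k = 500, 4
        subj = rng.standard_normal((n, 1))
        x = subj + rng.standard_normal((n, k))
        # impose the sample structure exactly by symmetrizing the covariance
        s = np.cov(x, rowvar=False)
        avg_var = np.trace(s) / k
        avg_cov = (s.sum() - np.trace(s)) / (k * (k - 1))
        s_cs = np.full((k, k), avg_cov)
        np.fill_diagonal(s_cs, avg_var)
        l_cs = np.linalg.cholesky(s_cs)
        l_s = np.linalg.cholesky(s)
        y = (x - x.mean(0)) @ np.linalg.inv(l_s).T @ l_cs.T
        assert gg_epsilon(y) == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_contrast_hits_lower_bound(self, rng):
        """A single dominant contrast drives epsilon to 1/(k-1)."""
        n, k = 40, 4
        c = np.array([1.0, -1.0, 0.0, 0.0])
        x = rng.standard_normal((n, 1)) * c + 1e-9 * rng.standard_normal((n, k))
        assert gg_epsilon(x) == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_bounds_always(self, rng):
        for _ in range(50):
            x = rng.standard_normal((6, 4)) @ rng.standard_normal((4, 4))
            assert 1.0 / 3.0 <= gg_epsilon(x) <= 1.0


class TestRmAnova:
    def test_identical_conditions(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 4))
        res = rm_anova_gg(x)
        assert res.f == 0.0 and res.p == 1.0

    def test_hand_computed_sums_of_squares(self):
        """F equals a from-scratch ANOVA table on a fixed 5x3 matrix."""
        x = np.array(
            [
                [3.0, 4.0, 6.0],
                [2.0, 4.0, 5.0],
                [5.0, 6.0, 9.0],
                [4.0, 4.0, 7.0],
                [1.0, 3.0, 4.0],
            ]
        )
        n, k = x.shape
        grand = x.sum() / x.size
        ss_cond = ss_subj = ss_tot = 0.0
        for j in range(k):
            ss_cond += n * (x[:, j].sum() / n - grand) ** 2
        for i in range(n):
            ss_subj += k * (x[i].sum() / k - grand) ** 2
        for i in range(n):
            for j in range(k):
                ss_tot += (x[i, j] - grand) ** 2
        ss_err = ss_tot - ss_cond - ss_subj
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        res = rm_anova_gg(x)
        assert res.f == pytest.approx(f_oracle, abs=1e-10)
        assert res.df1_uncorrected == 2 and res.df2_uncorrected == 8

    def test_against_pingouin(self, rng):
        """Independent cross-check of F, epsilon and the corrected p value."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.standard_normal((15, 4)) + rng.standard_normal((15, 1)) * 2
        x[:, 0] += 0.8
        df = pd.DataFrame(
            {
                "y": x.ravel(),
                "subject": np.repeat(np.arange(15), 4),
                "cond": np.tile(np.arange(4), 15),
            }
        )
        aov = pg.rm_anova(
            data=df, dv="y", within="cond", subject="subject", correction=True, detailed=True
        )
        res = rm_anova_gg(x)
        assert res.f == pytest.approx(float(aov["F"][0]), rel=1e-9)
        assert res.epsilon == pytest.approx(float(aov["eps"][0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_GG_corr"][0]), rel=1e-6)

    def test_missing_values_rejected(self):
        x = np.ones((4, 4))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_gg(x)


class TestTukey:
    def test_identical_means_all_null(self, rng):
        base = rng.standard_normal((10, 1))
        x = base + rng.standard_normal((10, 4)) * 1e-12
        rows = tukey_pairwise(np.repeat(base, 4, axis=1))
        for r in rows:
            assert r.estimate == 0.0 and r.p_adj == 1.0

    def test_k2_reduces_to_paired_t(self, rng):
        """Studentized-range p with k=2 equals the paired t p (q = t sqrt(2))."""
        x = rng.standard_normal((12, 2)) + [0.0, 0.6]
        rows = tukey_pairwise(x)
        t = sps.ttest_rel(x[:, 0], x[:, 1])
        assert rows[0].p_adj == pytest.approx(t.pvalue, rel=1e-6)

    def test_estimate_additivity_over_chained_pairs(self, rng):
        """(A-B) + (B-C) = (A-C), the structural identity of the contrast table."""
        x = rng.standard_normal((9, 4)) + [0.5, 0.1, -0.2, 0.0]
        rows = {r.pair: r.estimate for r in tukey_pairwise(x, labels=list("ABCD"))}
        assert rows[("A", "B")] + rows[("B", "C")] == pytest.approx(rows[("A", "C")], abs=1e-12)
        assert rows[("B", "C")] + rows[("C", "D")] == pytest.approx(rows[("B", "D")], abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        x = rng.standard_normal((8, 4))
        for r in tukey_pairwise(x):
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_adjusted_p_not_below_paired_t(self, rng):
        """For k > 2 the Tukey adjustment can only increase the p value of a
        contrast relative to its unadjusted per-pair paired t test."""
        for _ in range(20):
            x = rng.standard_normal((10, 4)) + rng.standard_normal((1, 4))
            rows = tukey_pairwise(x, labels=list("ABCD"), per_pair_error=True)
            cols = {"A": 0, "B": 1, "C": 2, "D": 3}
            for r in rows:
                i, j = cols[r.pair[0]], cols[r.pair[1]]
                p_t = sps.ttest_rel(x[:, i], x[:, j]).pvalue
                assert r.p_adj >= p_t - 1e-12


class TestPairedTests:
    def test_no_change(self, rng):
        x = rng.standard_normal((10, 4))
        rows = paired_tests(x, x.copy())
        for r in rows:
            assert r.estimate == 0.0 and r.p_raw == 1.0

    def test_constant_shift(self, rng):
        x = rng.standard_normal((10, 4))
        rows = paired_tests(x, x + 1.0)
        for r in rows:
            assert r.estimate == pytest.approx(1.0)
            assert r.p_raw < 1e-50
            assert r.ci_high - r.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy(self, rng):
        bl = rng.standard_normal((14, 4))
        fu = bl + 0.3 + rng.standard_normal((14, 4)) * 0.5
        rows = paired_tests(bl, fu)
        for j, r in enumerate(rows):
            ref = sps.ttest_rel(fu[:, j], bl[:, j])
            assert r.p_raw == pytest.approx(ref.pvalue, rel=1e-10)
            lo, hi = ref.confidence_interval()
            assert r.ci_low == pytest.approx(lo, rel=1e-9)
            assert r.ci_high == pytest.approx(hi, rel=1e-9)

    def test_power_matches_noncentral_t(self, rng):
        """Empirical power at shift = 0.5 SD, n = 100 matches the closed form."""
        n, delta, reps = 100, 0.5, 1000
        crit = sps.t.ppf(0.975, n - 1)
        nc = delta * np.sqrt(n)
        power_theory = sps.nct.sf(crit, n - 1, nc) + sps.nct.cdf(-crit, n - 1, nc)
        d = rng.standard_normal((reps, n)) + delta
        t_stats = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(n))
        power_emp = np.mean(np.abs(t_stats) > crit)
        assert power_emp == pytest.approx(power_theory, abs=3.5 * np.sqrt(0.25 / reps))


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == 0.04

    def test_worked_example(self):
        """Step-down arithmetic: ranks multiply by (m - rank + 1) with a
        running maximum."""
        adj = holm_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06, 0.02])

    @given(st.integers(0, 2**32 - 1))
    def test_monotone_bounded_and_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 15))
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        _, ref, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(adj, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestClassMeans:
    def test_constant_map(self):
        vol = np.full((4, 4, 4), 3.5)
        masks = {"a": np.zeros((4, 4, 4), bool), "b": np.ones((4, 4, 4), bool)}
        masks["a"][0, 0, 0] = True
        out = class_means(vol, masks)
        assert out == {"a": 3.5, "b": 3.5}

    def test_class_coded_map_recovers_codes(self):
        vol = np.zeros((4, 4, 4))
        m1 = np.zeros((4, 4, 4), bool)
        m2 = np.zeros((4, 4, 4), bool)
        m1[:2], m2[2:] = True, True
        vol[m1], vol[m2] = 1.0, 2.0
        out = class_means(vol, {"one": m1, "two": m2})
        assert out == {"one": 1.0, "two": 2.0}

    def test_empty_mask_yields_nan(self):
        out = class_means(np.ones((2, 2, 2)), {"e": np.zeros((2, 2, 2), bool)})
        assert np.isnan(out["e"])

    def test_nonconverged_voxels_excluded(self):
        vol = np.array([[[1.0, 100.0]]])
        mask = np.ones((1, 1, 2), bool)
        conv = np.array([[[True, False]]])
        assert class_means(vol, {"m": mask}, conv)["m"] == 1.0
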