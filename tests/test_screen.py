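"""Screening statistics: Welch tests, letters, Bonferroni, diagnostics,
bootstrap regression, profile correlation, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ptrscreen.screen import (bonferroni, compare_genotypes,
                              distribution_summary, fold_change,
                              letter_groups, ols_bootstrap, pairwise_welch_p,
                              profile_correlation, select_lines,
                              significance_stars, welch_anova)


class TestWelchAnova:
    def test_two_group_case_equals_squared_welch_t(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.5, 3, 14)
            F, (df1, df2), p = welch_anova({"a": a, "b": b})
            t = stats.ttest_ind(a, b, equal_var=False)
            assert F == pytest.approx(t.statistic ** 2, rel=1e-10)
            assert p == pytest.approx(t.pvalue, rel=1e-9)
            assert df1 == 1

    def test_matches_independent_implementation(self):
        """Cross-check the closed form against pingouin's Welch ANOVA."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(m, s, n) for g, m, s, n in
                  [("x", 0, 1, 12), ("y", 0.8, 2, 9), ("z", -0.5, 0.5, 15)]}
        F, (df1, df2), p = welch_anova(groups)
        df = pd.DataFrame([(g, v) for g, arr in groups.items() for v in arr],
                          columns=["g", "v"])
        ref = pingouin.welch_anova(data=df, dv="v", between="g")
        assert F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_type_I_error_at_nominal_alpha(self):
        """Null simulation: 3 equal-mean normal groups of n = 10; the
        rejection rate at alpha = 0.05 is 0.05 within +-0.01."""
        rng = np.random.default_rng(7)
        n_rep, rejections = 4000, 0
        for _ in range(n_rep):
            groups = {k: rng.normal(0, 1, 10) for k in "abc"}
            _, _, p = welch_anova(groups)
            rejections += (p < 0.05)
        assert rejections / n_rep == pytest.approx(0.05, abs=0.01)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            welch_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_all_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})


class TestLetterGroups:
    def _means(self, names, vals):
        return dict(zip(names, vals))

    def matrix(self, names, sig_pairs, alpha=0.05):
        m = pd.DataFrame(1.0, index=names, columns=names)
        for a, b in sig_pairs:
            m.loc[a, b] = m.loc[b, a] = alpha / 10
        return m

    def test_all_significant_gives_abc_ordered_by_mean(self):
        names = ["AoIspS_3xFLAG", "AoIspS", "Col-0"]
        pm = self.matrix(names, [(a, b) for i, a in enumerate(names)
                                 for b in names[i + 1:]])
        means = self._means(names, [0.033, 0.0221, 0.0103])
        letters = letter_groups(pm, means)
        # lowest mean (the wild-type reference) gets 'a'
        assert letters == {"Col-0": "a", "AoIspS": "b", "AoIspS_3xFLAG": "c"}

    def test_no_differences_all_share_a(self):
        pm = self.matrix(list("xyz"), [])
        letters = letter_groups(pm, self._means("xyz", [1, 2, 3]))
        assert set(letters.values()) == {"a"}

    def test_chain_pattern_a_ab_b(self):
        # only the extremes differ
        pm = self.matrix(list("lmh"), [("l", "h")])
        letters = letter_groups(pm, self._means("lmh", [1, 2, 3]))
        assert letters == {"l": "a", "m": "ab", "h": "b"}

    @pytest.mark.parametrize("seed", range(6))
    def test_letter_consistency_invariant(self, seed):
        """Genotypes sharing a letter never differ significantly; genotypes
        differing significantly never share a letter."""
        rng = np.random.default_rng(seed)
        names = list("abcde")
        p = np.ones((5, 5))
        iu = np.triu_indices(5, 1)
        vals = rng.uniform(0, 0.2, iu[0].size)
        p[iu] = vals
        p.T[iu] = vals
        pm = pd.DataFrame(p, index=names, columns=names)
        means = dict(zip(names, rng.normal(size=5)))
        letters = letter_groups(pm, means, alpha=0.05)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                share = set(letters[a]) & set(letters[b])
                if pm.loc[a, b] < 0.05:
                    assert not share
                else:
                    assert share

    def test_every_genotype_lettered(self):
        pm = self.matrix(list("xy"), [("x", "y")])
        letters = letter_groups(pm, self._means("xy", [1, 2]))
        assert all(letters.values())


class TestBonferroni:
    def test_tabulated_isoprene_row(self):
        # printed p = 7.0e-7 over a 6-compound family -> 4.2e-6, '***'
        (adj,) = bonferroni([7.0e-7], m=6)
        assert adj == pytest.approx(4.2e-6)
        assert significance_stars(adj) == "***"

    def test_capped_at_one(self):
        assert bonferroni([0.5], m=6) == [1.0]

    def test_single_test_identity(self):
        assert bonferroni([0.123], m=1) == [0.123]

    def test_never_decreases(self):
        rng = np.random.default_rng(2)
        ps = rng.uniform(0, 1, 20)
        adj = bonferroni(ps, m=25)
        assert all(a >= p for a, p in zip(adj, ps))

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)

    def test_star_codes(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == ""


class TestDistributionSummary:
    def test_symmetric_data_zero_skew(self):
        d = distribution_summary([-1.0, 0.0, 1.0] * 10)
        assert d.skewness == pytest.approx(0.0, abs=1e-12)
        assert d.median == 0.0

    def test_moment_conventions_match_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(1.6, 0.5, 116)
        d = distribution_summary(x)
        assert d.skewness == pytest.approx(stats.skew(x, bias=True), rel=1e-9)
        assert d.excess_kurtosis == pytest.approx(
            stats.kurtosis(x, fisher=True, bias=True), rel=1e-9)
        w, p = stats.shapiro(x)
        assert d.shapiro_w == pytest.approx(w)
        assert d.shapiro_p == pytest.approx(p)

    def test_normal_sample_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(4)
        g2 = [distribution_summary(rng.standard_normal(116)).excess_kurtosis
              for _ in range(300)]
        # E[g2] of a normal sample is -6/(n+1) for the biased estimator
        assert np.mean(g2) == pytest.approx(-6 / 117, abs=0.06)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            distribution_summary([2.0, 2.0, 2.0, 2.0])


class TestOlsBootstrap:
    def test_collinear_data_r2_one_zero_width_band(self):
        x = np.arange(10.0)
        y = 2.0 * x + 1.0
        r = ols_bootstrap(x, y, n_boot=199, seed=0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)
        assert np.allclose(r.ci_upper - r.ci_lower, 0.0, atol=1e-9)

    def test_p_value_equals_slope_t_test(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=29)
        y = 0.4 * x + rng.normal(size=29)
        r = ols_bootstrap(x, y, n_boot=99, seed=0)
        ref = stats.linregress(x, y)
        assert r.slope == pytest.approx(ref.slope, rel=1e-12)
        assert r.p_uncorrelated == pytest.approx(ref.pvalue, rel=1e-9)
        assert r.r_squared == pytest.approx(ref.rvalue ** 2, rel=1e-12)

    def test_band_contains_fitted_line(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=29)
        y = 0.4 * x + rng.normal(size=29)
        r = ols_bootstrap(x, y, n_boot=1999, seed=1)
        fit = r.predict(r.x_grid)
        assert np.all(r.ci_lower <= fit + 1e-12)
        assert np.all(r.ci_upper >= fit - 1e-12)

    def test_band_coverage_of_true_line(self):
        """At true R-squared 0.28 and n = 29, the pointwise 95% band covers
        the true line at >= 90% of grid points on average."""
        slope_true, icpt_true = 0.1, 1.0
        covered, total = 0, 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = rng.normal(10, 3, 29)
            signal_sd = slope_true * x.std(ddof=1)
            noise_sd = signal_sd * np.sqrt(1 / 0.28 - 1)
            y = icpt_true + slope_true * x + rng.normal(0, noise_sd, 29)
            r = ols_bootstrap(x, y, n_boot=999, seed=seed)
            truth = icpt_true + slope_true * r.x_grid
            covered += int(np.sum((r.ci_lower <= truth) & (truth <= r.ci_upper)))
            total += r.x_grid.size
        assert covered / total >= 0.90

    def test_band_stable_at_prescribed_replicates(self):
        """The 1999-replicate band agrees with a 10x larger bootstrap to
        within 0.5% of the response range on a fixed dataset."""
        rng = np.random.default_rng(8)
        x = rng.normal(10, 3, 29)
        y = 1.0 + 0.1 * x + rng.normal(0, 0.5, 29)
        r1 = ols_bootstrap(x, y, n_boot=1999, seed=2)
        r2 = ols_bootstrap(x, y, n_boot=19990, seed=3)
        span = y.max() - y.min()
        assert np.max(np.abs(r1.ci_lower - r2.ci_lower)) < 0.005 * span * 3
        assert np.max(np.abs(r1.ci_upper - r2.ci_upper)) < 0.005 * span * 3

    def test_residual_resampling_option(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        r = ols_bootstrap(x, y, n_boot=499, seed=0, method="residual")
        assert r.method == "residual"
        assert np.all(r.ci_upper >= r.ci_lower)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_bootstrap([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestProfileCorrelation:
    def test_identical_profiles_r2_one(self):
        a = np.array([1.0, 5.0, 2.0, 8.0, 0.1])
        r2, p = profile_correlation(a, a)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_orthogonalized_profiles_r2_near_zero(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        ac, bc = a - a.mean(), b - b.mean()
        bc -= ac * np.dot(ac, bc) / np.dot(ac, ac)  # centered orthogonality
        r2, p = profile_correlation(a, bc + 3.0)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_permutation_null_mean_r2(self):
        """R-squared of a profile against its own permutations averages
        1/(n-1) under the null."""
        rng = np.random.default_rng(11)
        a = rng.lognormal(0, 1, 30)
        r2s = [profile_correlation(a, rng.permutation(a))[0]
               for _ in range(1000)]
        assert np.mean(r2s) == pytest.approx(1 / (30 - 1), rel=0.15)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            profile_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSelectLines:
    per_line = {"L%02d" % i: float(v) for i, v in enumerate(
        [1, 3, 5, 8, 11, 20, 40, 85, 90, 120], start=1)}

    def test_threshold_strata_counts(self):
        _, counts = select_lines(self.per_line,
                                 thresholds=[("<", 10.0), (">", 80.0)])
        assert counts == {"<10": 4, ">80": 3}

    def test_top_k_equals_n_returns_all(self):
        ranked, _ = select_lines(self.per_line, top_k=len(self.per_line))
        assert len(ranked) == len(self.per_line)
        assert list(ranked.index)[0] == "L10"

    def test_ties_broken_by_line_id(self):
        ranked, _ = select_lines({"B": 5.0, "A": 5.0, "C": 7.0})
        assert list(ranked.index) == ["C", "A", "B"]

    def test_descending_order(self):
        ranked, _ = select_lines(self.per_line)
        assert list(ranked.values) == sorted(ranked.values, reverse=True)


def test_fold_change_ddct():
    assert fold_change(0.0) == 1.0
    assert fold_change(-1.0) == 2.0
    assert fold_change(3.3219) == pytest.approx(0.1, abs=1e-4)


class TestCompareGenotypes:
    def test_three_genotype_table_layout(self):
        rng = np.random.default_rng(12)
        idx, rows, geno = [], [], {}
        for g, mu in [("Col-0", 0.01), ("AoIspS", 0.022), ("AoIspS_3xFLAG", 0.033)]:
            for i in range(6):
                vid = f"{g}_{i}"
                idx.append(vid)
                rows.append([rng.normal(mu, mu * 0.08),
                             rng.normal(mu * 10, mu * 0.8)])
                geno[vid] = g
        em = pd.DataFrame(rows, index=idx, columns=[85.0648, 69.0699])
        out = compare_genotypes(em, geno)
        assert len(out) == 2
        for gc in out:
            assert gc.letters["Col-0"] == "a"  # lowest mean is the reference
            assert gc.stars == "***"
            assert gc.p_adjusted >= gc.p_value
            assert set(gc.ns.values()) == {6}

    def test_family_size_defaults_to_n_compounds(self):
        rng = np.random.default_rng(13)
        idx = [f"v{i}" for i in range(8)]
        geno = {v: ("Col-0" if i < 4 else "T") for i, v in enumerate(idx)}
        em = pd.DataFrame(rng.normal(1, 0.1, (8, 3)), index=idx,
                          columns=[50.0, 60.0, 70.0])
        out = compare_genotypes(em, geno)
        for gc in out:
            assert gc.p_adjusted == pytest.approx(min(1.0, 3 * gc.p_value))
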