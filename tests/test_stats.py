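import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from bonespm.stats import (
    CollinearDesignError,
    adjusted_group_difference,
    correlation_difference_map,
    correlation_map,
    fdr_correct,
    fisher_z_compare,
    partial_spearman,
)
from bonespm.synthetic import correlated_pair_cohort


def brute_force_partial_spearman(x, y, covariates):
    """Independent oracle: explicit ranking + two OLS fits + Pearson."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    C = np.column_stack([np.ones(len(x)), np.atleast_2d(covariates.T).T])
    bx = np.linalg.lstsq(C, rx, rcond=None)[0]
    by = np.linalg.lstsq(C, ry, rcond=None)[0]
    ex = rx - C @ bx
    ey = ry - C @ by
    return float(np.sum(ex * ey) / np.sqrt(np.sum(ex**2) * np.sum(ey**2)))


class TestAdjustedGroupDifference:
    def test_reduces_to_t_test_without_covariate_signal(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=40)
        g = np.repeat(["a", "b"], 20)
        coef, p = adjusted_group_difference(y, g, None)
        t, p_ref = sps.ttest_ind(y[20:], y[:20])
        assert p == pytest.approx(p_ref, abs=1e-10)
        assert coef == pytest.approx(y[20:].mean() - y[:20].mean(), abs=1e-12)

    def test_perfect_separation_p_zero(self):
        g = np.repeat(["a", "b"], 10)
        y = (g == "b").astype(float)
        _, p = adjusted_group_difference(y, g, None)
        assert p < 1e-12

    def test_monte_carlo_shift_recovery(self):
        """Group shift of 1 SD recovered without bias at n=50/50."""
        rng = np.random.default_rng(1)
        g = np.repeat(["ctl", "fx"], 50)
        coefs = []
        for _ in range(300):
            cov = rng.normal(size=(100, 3))
            y = rng.normal(size=100) + (g == "fx") + cov @ [0.2, -0.1, 0.3]
            coef, _ = adjusted_group_difference(y, g, cov)
            coefs.append(coef)
        assert np.mean(coefs) == pytest.approx(1.0, abs=0.05)

    def test_collinear_design_raises(self):
        g = np.repeat(["a", "b"], 10)
        cov = np.column_stack([np.arange(20), 2 * np.arange(20)])
        with pytest.raises(CollinearDesignError):
            adjusted_group_difference(np.random.default_rng(2).normal(size=20),
                                      g, cov)


class TestPartialSpearman:
    def test_equals_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        rho, _ = partial_spearman(x, y, None)
        assert rho == pytest.approx(sps.spearmanr(x, y)[0], abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        r1, p1 = partial_spearman(x, y, cov)
        r2, p2 = partial_spearman(np.exp(x), y**3 + 5 * y, cov)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_identity_monotone_pair_is_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        rho, _ = partial_spearman(x, np.exp(x), None)
        assert rho == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        """Random instances (n <= 30, with ties): equality to 1e-12."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = rng.integers(8, 31)
            k = rng.integers(1, 4)
            x = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = np.round(rng.normal(size=n), 1)
            cov = rng.normal(size=(n, k))
            rho, _ = partial_spearman(x, y, cov)
            assert rho == pytest.approx(
                brute_force_partial_spearman(x, y, cov), abs=1e-12
            )

    def test_fixed_small_instance(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        cov = np.array([1.0, 1, 2, 2, 3, 3])
        rho, _ = partial_spearman(x, y, cov)
        assert rho == pytest.approx(
            brute_force_partial_spearman(x, y, cov), abs=1e-12
        )

    def test_constant_input_returns_nan(self):
        rho, p = partial_spearman(np.ones(10), np.arange(10), None)
        assert np.isnan(rho) and np.isnan(p)


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.5, 40, 0.5, 60)
        assert z == 0.0
        assert p == 1.0

    def test_published_group_sizes_formula_oracle(self):
        """rho 0.83 (n=98) vs 0.93 (n=84), k=3: matches a direct arithmetic
        evaluation of the Fisher-Z formula to 1e-12."""
        z, p = fisher_z_compare(0.83, 98, 0.93, 84, n_covariates=3)
        z_ref = (np.arctanh(0.83) - np.arctanh(0.93)) / np.sqrt(
            1 / (98 - 3 - 3) + 1 / (84 - 3 - 3)
        )
        assert z == pytest.approx(z_ref, abs=1e-12)
        assert p == pytest.approx(2 * sps.norm.sf(abs(z_ref)), abs=1e-12)
        assert p < 0.05  # the published comparison is significant

    def test_antisymmetry(self):
        z1, p1 = fisher_z_compare(0.3, 50, 0.7, 45)
        z2, p2 = fisher_z_compare(0.7, 45, 0.3, 50)
        assert z1 == pytest.approx(-z2, abs=1e-14)
        assert p1 == pytest.approx(p2, abs=1e-14)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.5, 50)

    def test_type_one_error_calibrated(self):
        """Nominal 0.05 within the binomial CI over null simulations
        (n=50/50, common rho=0.5)."""
        rng = np.random.default_rng(6)
        n_sims = 500
        rejections = 0
        for _ in range(n_sims):
            a1, b1 = correlated_pair_cohort(50, (1,), 0.5, rng)
            a2, b2 = correlated_pair_cohort(50, (1,), 0.5, rng)
            r1 = sps.spearmanr(a1[:, 0], b1[:, 0])[0]
            r2 = sps.spearmanr(a2[:, 0], b2[:, 0])[0]
            _, p = fisher_z_compare(r1, 50, r2, 50)
            rejections += p < 0.05
        rate = rejections / n_sims
        ci = 3 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < ci + 0.005


class TestFDR:
    def test_hand_step_up_example(self):
        flags = fdr_correct(np.array([0.01, 0.02, 0.03]), q=0.05)
        assert flags.all()  # 0.03 <= 3*0.05/3

    def test_all_ones_unflagged(self):
        assert not fdr_correct(np.ones(10)).any()

    def test_empty_input(self):
        assert fdr_correct(np.array([])).size == 0

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            ours = fdr_correct(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    @settings(max_examples=100, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=40),
        q=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_step_up_matches_reference_for_arbitrary_vectors(self, p, q):
        p = np.asarray(p)
        ours = fdr_correct(p, q=q)
        ref = multipletests(p, alpha=q, method="fdr_bh")[0]
        assert np.array_equal(ours, ref)

    def test_nans_ignored(self):
        p = np.array([0.001, np.nan, 0.002, np.nan])
        flags = fdr_correct(p)
        assert flags[0] and flags[2]
        assert not flags[1] and not flags[3]


class TestCorrelationMaps:
    def test_uniform_latent_correlation_is_spatially_uniform(self):
        rng = np.random.default_rng(8)
        x, y = correlated_pair_cohort(80, (400,), 0.5, rng)
        sm = correlation_map(x, y, covariates=None)
        # rho spread consistent with sampling error (sd of z ~ 1/sqrt(n-3))
        z = np.arctanh(sm.rho)
        assert z.std() == pytest.approx(1 / np.sqrt(77), rel=0.25)
        assert np.nanmean(sm.rho) == pytest.approx(0.5, abs=0.03)

    def test_independent_maps_fdr_calibrated(self):
        rng = np.random.default_rng(9)
        fracs = []
        for _ in range(20):
            x = rng.standard_normal((40, 300))
            y = rng.standard_normal((40, 300))
            sm = correlation_map(x, y, covariates=None)
            fracs.append(sm.significant.mean())
        assert np.mean(fracs) <= 0.05 + 0.02

    def test_clone_cohort_rho_one(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal(50)
        x = base[:, None] + 1e-9 * rng.standard_normal((50, 30))
        sm = correlation_map(x, x.copy(), covariates=None)
        assert np.nanmin(sm.rho) > 0.999

    def test_minimum_subject_rule_masks_sparse_locations(self):
        rng = np.random.default_rng(11)
        x, y = correlated_pair_cohort(30, (50,), 0.4, rng)
        x[:20, 0] = np.nan  # first location defined for only 1/3 of subjects
        sm = correlation_map(x, y, covariates=None, min_fraction=0.9)
        assert np.isnan(sm.rho[0])
        assert not sm.significant[0]
        assert np.isfinite(sm.rho[1:]).all()

    def test_all_locations_sparse_raises(self):
        x = np.full((20, 10), np.nan)
        with pytest.raises(ValueError):
            correlation_map(x, x, covariates=None)


class TestCorrelationDifferenceMaps:
    def test_identical_groups_no_flags(self):
        rng = np.random.default_rng(12)
        x, y = correlated_pair_cohort(60, (200,), 0.5, rng)
        m1 = correlation_map(x, y, None)
        m2 = correlation_map(x.copy(), y.copy(), None)
        diff = correlation_difference_map(m1, m2)
        assert np.allclose(diff.delta_rho, 0.0)
        assert not diff.significant.any()

    def test_planted_cluster_detected_with_dice(self):
        """rho 0.8 vs 0.2 planted in a region, n=100/100: FDR-flagged
        cluster overlaps the truth with Dice > 0.5."""
        rng = np.random.default_rng(13)
        n_loc = 512
        region = np.zeros(n_loc, bool)
        region[100:180] = True
        rho_ctl = np.where(region, 0.8, 0.5)
        rho_fx = np.where(region, 0.2, 0.5)
        xc, yc = correlated_pair_cohort(100, (n_loc,), rho_ctl, rng)
        xf, yf = correlated_pair_cohort(100, (n_loc,), rho_fx, rng)
        mc = correlation_map(xc, yc, None)
        mf = correlation_map(xf, yf, None)
        diff = correlation_difference_map(mc, mf)
        flagged = diff.significant
        dice = 2 * (flagged & region).sum() / (flagged.sum() + region.sum())
        assert dice > 0.5
        # sign convention: fracture minus control
        assert np.nanmean(diff.delta_rho[region]) < -0.3

    def test_null_difference_fdr_calibrated(self):
        rng = np.random.default_rng(14)
        fracs = []
        for _ in range(10):
            x1, y1 = correlated_pair_cohort(50, (300,), 0.5, rng)
            x2, y2 = correlated_pair_cohort(50, (300,), 0.5, rng)
            diff = correlation_difference_map(
                correlation_map(x1, y1, None), correlation_map(x2, y2, None)
            )
            fracs.append(diff.significant.mean())
        assert np.mean(fracs) <= 0.05 + 0.02

    def test_mismatched_domains_rejected(self):
        rng = np.random.default_rng(15)
        x, y = correlated_pair_cohort(30, (20,), 0.3, rng)
        m1 = correlation_map(x, y, None)
        x2, y2 = correlated_pair_cohort(30, (25,), 0.3, rng)
        m2 = correlation_map(x2, y2, None)
        with pytest.raises(ValueError):
            correlation_difference_map(m1, m2)


class TestParameterRecovery:
    def test_location_dependent_rho_profile_recovered(self):
        """Planted rho(x) ramp recovered within 0.05 at n=100.

        The estimator is a Spearman correlation, whose population value for
        a bivariate normal with Pearson correlation r is (6/pi) asin(r/2).
        """
        rng = np.random.default_rng(16)
        rho_true = np.linspace(0.1, 0.8, 40)
        rho_spearman = 6 / np.pi * np.arcsin(rho_true / 2)
        reps = []
        for _ in range(60):
            x, y = correlated_pair_cohort(100, (40,), rho_true, rng)
            sm = correlation_map(x, y, None)
            reps.append(sm.rho)
        mean_rho = np.mean(reps, axis=0)
        assert np.max(np.abs(mean_rho - rho_spearman)) < 0.05
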