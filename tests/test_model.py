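import numpy as np
import pytest

from afckit.correction import normalize_log
from afckit.model import (
    AFC_BOUND,
    confidence_intervals,
    fit_afc,
    fit_afc_single,
    fit_ancestry_afc,
    predict_log_total,
)
from afckit.simulation import SimParams, simulate_cohort, simulate_counts, simulate_haplotypes
from tests.conftest import make_design


class TestPredictLogTotal:
    @pytest.mark.parametrize(
        "h1,h2,expected",
        [
            ([0], [0], np.log2(100)),  # hom ref: 2 * e_R
            ([1], [1], np.log2(200)),  # hom alt: 2 * e_R * 2^s
            ([0], [1], np.log2(150)),  # het: e_R * (1 + 2^s)
        ],
    )
    def test_closed_forms_single_eqtl(self, h1, h2, expected):
        got = predict_log_total([1.0], np.log2(50), np.array(h1), np.array(h2))
        assert got == pytest.approx(expected)

    def test_overflow_safe_for_extreme_effects(self):
        val = predict_log_total([4000.0], 0.0, np.array([1.0]), np.array([1.0]))
        assert np.isfinite(val) and val == pytest.approx(4001.0)


class TestFitAfc:
    def test_noiseless_two_group_closed_form(self):
        # hom-ref samples at expression 100, hom-alt at 400 -> aFC ratio 2^2
        H = np.array([[0], [0], [1], [1], [0], [1]], float)
        y = np.where(H[:, 0] == 1, np.log2(400.0), np.log2(100.0))
        m = fit_afc(make_design(H, H), y)
        assert m.converged
        assert m.s[0] == pytest.approx(2.0, abs=1e-6)
        assert m.log2_e_ref == pytest.approx(np.log2(50.0), abs=1e-6)

    def test_extreme_ratio_clamps_at_bound(self):
        H = np.array([[0], [0], [0], [1], [1], [1]], float)
        y = np.where(H[:, 0] == 1, np.log2(100_000.0), np.log2(100.0))
        m = fit_afc(make_design(H, H), y)
        assert m.s[0] == pytest.approx(AFC_BOUND, abs=1e-6)  # log2(100) ~ 6.644

    def test_optimum_agrees_with_grid_search_oracle(self):
        """Dense profiled grid search over s finds the same optimum."""
        rng = np.random.default_rng(12)
        s_true = np.array([0.8, -1.2])
        H1, H2 = simulate_haplotypes(300, [0.3, 0.4], rng)
        tot, *_ = simulate_counts(H1, H2, s_true, np.log2(200.0), rng)
        y = np.log2(tot + 1.0)
        d = make_design(H1, H2)
        m = fit_afc(d, y, compute_ci=False)

        def profiled_obj(s):
            g = np.logaddexp2(H1 @ s, H2 @ s)
            return float(np.sum((y - g - np.mean(y - g)) ** 2))

        grid = np.arange(-3.0, 3.0001, 0.02)
        best = min(
            ((a, b) for a in grid for b in grid), key=lambda ab: profiled_obj(np.array(ab))
        )
        assert m.objective_final <= profiled_obj(np.array(best)) + 1e-9
        np.testing.assert_allclose(m.s, best, atol=0.02 + 1e-9)

    def test_single_eqtl_matches_profiled_closed_computation(self):
        """With one eQTL the joint fit equals the single-variant estimator."""
        cohort = simulate_cohort(
            SimParams(n_individuals=300, n_eqtls=1, n_genes=10, seed=4)
        )
        y = normalize_log(cohort.counts)
        for g in cohort.true_s:
            d = cohort.design_for(g)
            yv = y.loc[g, d.sample_ids].to_numpy(float)
            m_joint = fit_afc(d, yv, compute_ci=False)
            m_single = fit_afc_single(d, yv)
            assert abs(m_joint.s[0] - m_single.s[0]) < 1e-3

    def test_allele_relabeling_flips_sign_and_preserves_predictions(self, cohort3_y):
        d, y = cohort3_y
        m = fit_afc(d, y, compute_ci=False)
        # recode eQTL 1: swap ref/alt
        H1f, H2f = d.H1.copy(), d.H2.copy()
        H1f[:, 1] = 1 - H1f[:, 1]
        H2f[:, 1] = 1 - H2f[:, 1]
        mf = fit_afc(make_design(H1f, H2f), y, compute_ci=False)
        assert mf.s[1] == pytest.approx(-m.s[1], abs=1e-5)
        assert mf.log2_e_ref == pytest.approx(m.log2_e_ref + m.s[1], abs=1e-5)
        pred = predict_log_total(m.s, m.log2_e_ref, d.H1, d.H2)
        predf = predict_log_total(mf.s, mf.log2_e_ref, H1f, H2f)
        np.testing.assert_allclose(predf, pred, atol=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_never_worse_than_initialization(self, seed):
        rng = np.random.default_rng(seed)
        H1, H2 = simulate_haplotypes(150, [0.2, 0.35, 0.5], rng)
        tot, *_ = simulate_counts(H1, H2, rng.normal(0, 1, 3), np.log2(150.0), rng)
        m = fit_afc(make_design(H1, H2), np.log2(tot + 1.0), compute_ci=False)
        assert m.objective_final <= m.objective_init + 1e-9

    def test_monomorphic_eqtl_fixed_at_zero_rest_fitted(self):
        rng = np.random.default_rng(8)
        H1, H2 = simulate_haplotypes(400, [0.4], rng)
        tot, *_ = simulate_counts(H1, H2, np.array([1.5]), np.log2(200.0), rng)
        zeros = np.zeros((400, 1))
        d = make_design(np.hstack([H1, zeros]), np.hstack([H2, zeros]))
        m = fit_afc(d, np.log2(tot + 1.0))
        assert m.fixed_zero == [d.variant_ids[1]]
        assert m.s[1] == 0.0 and np.isnan(m.ci_low[1])
        assert m.s[0] == pytest.approx(1.5, abs=0.1)

    def test_too_few_samples_raises(self):
        H = np.array([[0], [1]], float)
        with pytest.raises(ValueError, match="samples"):
            fit_afc(make_design(H, H), np.array([1.0, 2.0]))

    def test_barely_identified_gene_fits_without_crash(self):
        # n just above N+1: expect a wide CI, not a failure
        rng = np.random.default_rng(9)
        H1 = np.array([[0], [1], [0], [1]], float)
        H2 = np.array([[0], [0], [0], [1]], float)
        y = rng.normal(np.log2(100), 0.5, size=4)
        m = fit_afc(make_design(H1, H2), y)
        assert np.isfinite(m.s[0])
        if np.isfinite(m.ci_low[0]):
            assert m.ci_high[0] - m.ci_low[0] > 1.0


class TestConfidenceIntervals:
    def test_strong_effect_large_n_excludes_zero(self):
        rng = np.random.default_rng(10)
        H1, H2 = simulate_haplotypes(800, [0.4], rng)
        tot, *_ = simulate_counts(H1, H2, np.array([1.0]), np.log2(400.0), rng)
        m = fit_afc(make_design(H1, H2), np.log2(tot + 1.0))
        assert m.ci_low[0] > 0.0
        assert not m.ci_overlaps_zero()[0]

    def test_null_effect_coverage_near_nominal(self):
        """True s = 0: the 95% CI should cover zero in ~95% of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 120
        for _ in range(reps):
            H1, H2 = simulate_haplotypes(200, [0.4], rng)
            tot, *_ = simulate_counts(H1, H2, np.array([0.0]), np.log2(300.0), rng)
            m = fit_afc(make_design(H1, H2), np.log2(tot + 1.0))
            hits += bool(m.ci_overlaps_zero()[0])
        # binomial(120, .95) 3-sigma band
        assert 0.88 <= hits / reps <= 1.0

    def test_requires_converged_model(self, cohort3_y):
        d, y = cohort3_y
        m = fit_afc(d, y, compute_ci=False)
        m.converged = False
        with pytest.raises(ValueError, match="not converged"):
            confidence_intervals(m)


class TestAncestryModel:
    def _data(self, s0, s1, n_per=400, seed=13):
        rng = np.random.default_rng(seed)
        H1, H2 = simulate_haplotypes(2 * n_per, [0.4], rng)
        I = np.repeat([0.0, 1.0], n_per)
        s_eff = np.where(I[:, None] == 1, s1, s0)
        e1 = np.exp2(np.log2(200.0) + (H1 * s_eff).sum(1))
        e2 = np.exp2(np.log2(200.0) + (H2 * s_eff).sum(1))
        tot = rng.poisson(e1 + e2)
        return make_design(H1, H2), np.log2(tot + 1.0), I

    def test_identical_strata_select_shared_estimate(self):
        d, y, I = self._data(np.array([1.0]), np.array([1.0]))
        am = fit_ancestry_afc(d, y, I)
        assert am.stratified_fit_performed
        assert not am.stratified_selected.any()
        assert am.selected_s(0)[0] == pytest.approx(am.s_shared[0])

    def test_distinct_strata_recovered_and_selected(self):
        d, y, I = self._data(np.array([0.0]), np.array([2.0]))
        am = fit_ancestry_afc(d, y, I)
        assert am.stratified_selected[0]
        assert am.s_strat0[0] == pytest.approx(0.0, abs=0.15)
        assert am.s_strat1[0] == pytest.approx(2.0, abs=0.15)
        assert am.selected_s(1)[0] == pytest.approx(am.s_strat1[0])

    def test_constant_indicator_rejected(self):
        d, y, I = self._data(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="constant"):
            fit_ancestry_afc(d, y, np.zeros_like(I))

    def test_tiny_stratum_refuses_stratification(self):
        d, y, I = self._data(np.array([1.0]), np.array([1.0]))
        I2 = np.zeros_like(I)
        I2[:2] = 1.0  # 2 samples cannot identify s + e_R
        with pytest.warns(UserWarning, match="too small"):
            am = fit_ancestry_afc(d, y, I2)
        assert not am.stratified_fit_performed
        np.testing.assert_array_equal(am.s_strat1, am.s_shared)
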