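import numpy as np
import pandas as pd
import pytest
from scipy import stats

from afckit.io_formats import HaplotypeCountTable
from afckit.power import (
    _binom_pvalues_all_k,
    audit_sample,
    compute_power,
    detect_excess,
    gene_power,
    logit2,
    power_grid,
    ref_ratio_from_afc,
)


class TestRefRatio:
    def test_balanced_null(self):
        assert ref_ratio_from_afc(0.0) == 0.5

    @pytest.mark.parametrize(
        "s,expected", [(0.5, 0.59), (-0.5, 0.41), (1.0, 0.67), (-1.0, 0.33)]
    )
    def test_printed_fold_resolution_correspondence(self, s, expected):
        assert round(ref_ratio_from_afc(s), 2) == expected

    def test_symmetry_and_logit_inverse(self):
        for s in np.linspace(-5, 5, 21):
            assert ref_ratio_from_afc(s) + ref_ratio_from_afc(-s) == pytest.approx(1.0)
            assert logit2(ref_ratio_from_afc(s)) == pytest.approx(s, abs=1e-12)


class TestBinomPvalues:
    @pytest.mark.parametrize("n,p0", [(20, 0.5), (37, 0.3), (100, 0.67)])
    def test_matches_scipy_binomtest(self, n, p0):
        pv = _binom_pvalues_all_k(n, p0)
        for k in range(0, n + 1, max(1, n // 10)):
            ref = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
            assert pv[k] == pytest.approx(ref, rel=1e-8)


class TestComputePower:
    def test_null_fold_change_bounded_by_alpha(self):
        pw = compute_power(100, 0.5, 0.0, alpha=0.01, n_sim=2000, seed=1)
        mc = 3 * np.sqrt(0.01 * 0.99 / 2000)
        assert pw <= 0.01 + mc  # conservative: exact test is discrete

    def test_huge_coverage_saturates(self):
        assert compute_power(5000, 0.5, 1.0, n_sim=500, seed=2) == pytest.approx(1.0)

    def test_simulation_agrees_with_enumeration(self):
        exact = compute_power(100, 0.5, 0.5, method="enumeration")
        sim = compute_power(100, 0.5, 0.5, n_sim=1000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 1000)
        assert abs(sim - exact) <= 3 * se

    def test_monotone_in_coverage_and_fc(self):
        pws = [compute_power(c, 0.5, 0.5, method="enumeration") for c in (20, 100, 500)]
        assert pws == sorted(pws)
        assert compute_power(100, 0.5, 1.0, method="enumeration") >= pws[1]

    def test_zero_coverage_has_no_power(self):
        assert compute_power(0, 0.5, 1.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_power(10, 1.5, 0.5)
        with pytest.raises(ValueError):
            compute_power(10, 0.5, 0.5, method="bogus")

    def test_grid_shape_and_range(self):
        grid = power_grid([20, 50], [0.5], [0.5, 1.0], n_sim=200, seed=4)
        assert len(grid) == 4
        assert grid["power"].between(0, 1).all()


class TestGenePower:
    def test_balanced_prediction_reduces_to_global_null(self):
        assert gene_power(100, 0.0, 0.5) == pytest.approx(
            compute_power(100, 0.5, 0.5, method="enumeration")
        )

    def test_extreme_imbalance_costs_power(self):
        balanced = gene_power(100, 0.0, 0.5)
        skewed = gene_power(100, 3.5, 0.5)  # null ratio ~0.92
        assert skewed < balanced

    def test_zero_coverage(self):
        assert gene_power(0, 0.0, 0.5) == 0.0


class TestDetectExcess:
    def test_counts_at_predicted_ratio_not_flagged(self):
        call = detect_excess("g", "s", 60, 60, predicted_ai=0.0)
        assert not call.flagged and call.p_value > 0.5

    def test_strong_deviation_flagged(self):
        call = detect_excess("g", "s", 90, 10, predicted_ai=0.0, fc_cutoff=0.5)
        assert call.flagged
        assert call.observed_ai == pytest.approx(np.log2(90.5 / 10.5))
        assert call.p_value < 1e-10

    def test_fold_cutoff_gates_significant_but_small_deviations(self):
        # (60, 40): delta ~0.57 < 1, never flagged at onefold resolution
        call = detect_excess("g", "s", 60, 40, predicted_ai=0.0, fc_cutoff=1.0)
        assert not call.flagged
        # (600, 400): p-value is tiny but delta ~0.58 still below the cutoff
        call2 = detect_excess("g", "s", 600, 400, predicted_ai=0.0, fc_cutoff=1.0)
        assert call2.p_value < 1e-9 and not call2.flagged

    def test_matches_predicted_nonzero_null(self):
        # counts exactly at the predicted 2:1 imbalance
        call = detect_excess("g", "s", 200, 100, predicted_ai=1.0)
        assert not call.flagged

    def test_zero_coverage_is_safe(self):
        call = detect_excess("g", "s", 0, 0, predicted_ai=0.0)
        assert call.p_value == 1.0 and not call.flagged


class TestAuditSample:
    def _fixtures(self):
        preds = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "sample_id": ["S1", "S1"],
                "predicted_ai": [0.0, 1.0],
            }
        )
        ase = HaplotypeCountTable(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2"],
                    "sample_id": ["S1", "S1"],
                    "hap1_count": [900, 600],
                    "hap2_count": [100, 300],
                }
            )
        )
        tpm = pd.Series({"g1": 10.0, "g2": 5.0})
        return preds, ase, tpm

    def test_flags_unexplained_imbalance_only(self):
        preds, ase, tpm = self._fixtures()
        summary, calls = audit_sample(preds, ase, tpm)
        eqtl = calls[calls["mode"] == "eqtl"].set_index("gene_id")
        assert bool(eqtl.loc["g1", "flagged"])  # 9:1 vs balanced prediction
        assert not bool(eqtl.loc["g2", "flagged"])  # 2:1 matches predicted AI 1
        base = calls[calls["mode"] == "baseline"].set_index("gene_id")
        assert bool(base.loc["g2", "flagged"])  # baseline ignores the eQTL
        row = summary.iloc[0]
        assert row["frac_flagged_baseline"] == 1.0
        assert row["frac_flagged_eqtl"] == 0.5
        assert row["eqtl_gain"] == pytest.approx(0.5)

    def test_low_tpm_genes_excluded(self):
        preds, ase, tpm = self._fixtures()
        tpm["g2"] = 0.5
        _, calls = audit_sample(preds, ase, tpm)
        assert set(calls["gene_id"]) == {"g1"}

    def test_unattainable_power_threshold_yields_empty_summary(self):
        preds, ase, tpm = self._fixtures()
        summary, calls = audit_sample(preds, ase, tpm, power_threshold=1.01)
        assert calls.empty
        assert summary["n_genes_eqtl"].sum() == 0
        assert np.isnan(summary["frac_flagged_eqtl"]).all()
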