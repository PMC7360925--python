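"""Performance metrics, summary t tests, BH correction, the two-stage screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from symbiofba import (
    GroupSummary,
    ValidationError,
    bh_adjust,
    gen_metabolomics_matrix,
    gen_performance_samples,
    intrinsic_rate,
    metabolite_screen,
    pooled_t_summary,
    relative_growth_rate,
    two_sample_test,
)


class TestPooledTSummary:
    def test_printed_performance_summaries_reproduce_t(self):
        """Intrinsic-rate summaries (0.351±0.005 vs 0.347±0.010, n=10 each)
        give t₁₈ ≈ 0.36; exactness is limited by the inputs' rounding."""
        res = pooled_t_summary(
            GroupSummary(0.351, 0.005, 10), GroupSummary(0.347, 0.010, 10)
        )
        assert res.df == 18
        assert res.statistic == pytest.approx(0.360, rel=0.01)
        assert res.p > 0.7

    def test_identical_summaries(self):
        g = GroupSummary(1.0, 0.1, 5)
        res = pooled_t_summary(g, g)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_se_cases(self):
        same = pooled_t_summary(GroupSummary(1.0, 0.0, 5), GroupSummary(1.0, 0.0, 5))
        assert same.statistic == 0.0
        with pytest.raises(ValidationError, match="infinite"):
            pooled_t_summary(GroupSummary(1.0, 0.0, 5), GroupSummary(2.0, 0.0, 5))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_summary_form_equals_raw_pooled_t_for_equal_n(self, seed):
        """Brute-force identity: summarize-then-test == scipy on raws."""
        x1 = gen_performance_samples(0.35, 0.02, 10, seed=seed)
        x2 = gen_performance_samples(0.33, 0.03, 10, seed=seed + 100)
        res = pooled_t_summary(GroupSummary.from_samples(x1), GroupSummary.from_samples(x2))
        direct = sps.ttest_ind(x1, x2, equal_var=True)
        assert res.statistic == pytest.approx(direct.statistic, abs=1e-12)
        assert res.p == pytest.approx(direct.pvalue, abs=1e-12)

    def test_invalid_group_summaries_rejected(self):
        with pytest.raises(ValidationError):
            GroupSummary(1.0, -0.1, 5)
        with pytest.raises(ValidationError):
            GroupSummary(1.0, 0.1, 1)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_stepup_hand_example_all_tie(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_stepup_hand_example_mixed(self):
        assert bh_adjust([0.005, 0.03, 0.5]) == pytest.approx([0.015, 0.045, 0.5])

    def test_order_preserving_with_input(self):
        p = [0.5, 0.005, 0.03]
        adj = bh_adjust(p)
        assert adj == pytest.approx([0.5, 0.015, 0.045])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.5])

    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_is_monotone(self, p):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(list(theirs), abs=1e-12)
        order = np.argsort(p, kind="stable")
        sorted_adj = np.asarray(ours)[order]
        assert np.all(np.diff(sorted_adj) >= -1e-12)
        assert max(ours) == pytest.approx(max(p))


class TestPerformanceMetrics:
    def test_rgr_no_growth_is_zero(self):
        assert relative_growth_rate(5.0, 5.0) == 0.0

    def test_rgr_doubling_over_assay(self):
        assert relative_growth_rate(1.0, 2.0) == pytest.approx(math.log(2) / 5)

    def test_rgr_invariant_to_weight_units(self):
        assert relative_growth_rate(1.3, 2.9) == pytest.approx(
            relative_growth_rate(1.3e3, 2.9e3)
        )

    def test_rgr_rejects_nonpositive_weights(self):
        with pytest.raises(ValidationError):
            relative_growth_rate(0.0, 2.0)

    def test_rm_single_offspring_is_zero(self):
        assert intrinsic_rate(1, 9.0) == 0.0

    def test_rm_reference_value(self):
        assert intrinsic_rate(50, 9.0) == pytest.approx(0.745 * math.log(50) / 9, abs=1e-9)
        assert intrinsic_rate(50, 9.0) == pytest.approx(0.3238, abs=2e-4)

    def test_rm_halves_when_d_doubles(self):
        assert intrinsic_rate(50, 18.0) == pytest.approx(intrinsic_rate(50, 9.0) / 2)

    @pytest.mark.parametrize("Md,d", [(0.5, 9.0), (50, 0.0), (50, -1.0)])
    def test_rm_rejects_degenerate_inputs(self, Md, d):
        with pytest.raises(ValidationError):
            intrinsic_rate(Md, d)


class TestTwoSampleTest:
    def test_welch_and_mann_whitney_available_explicitly(self):
        x1 = gen_performance_samples(1.0, 0.2, 12, seed=1)
        x2 = gen_performance_samples(1.5, 0.6, 12, seed=2)
        for method in ("pooled-t", "welch-t", "mann-whitney"):
            res = two_sample_test(x1, x2, method=method)
            assert res.method == method
            assert 0.0 <= res.p <= 1.0


class TestMetaboliteScreen:
    def test_planted_large_effect_survives_both_stages(self):
        effects = np.zeros(50)
        effects[7] = 3.0
        matrix, design = gen_metabolomics_matrix(
            n_genotypes=6, n_reps=5, genotype_sd=1.0,
            status_effects=effects, noise_sd=0.5, seed=2,
        )
        out = metabolite_screen(matrix, design)
        assert bool(out.loc["metab_8", "candidate"])
        assert bool(out.loc["metab_8", "significant"])
        assert out["significant"].sum() == 1

    def test_structured_null_yields_no_bh_hits(self):
        """Genotype structure inflates stage-1 flags, but the mixed stage
        with a genotype random effect leaves nothing BH-significant."""
        matrix, design = gen_metabolomics_matrix(
            n_genotypes=6, n_reps=5, genotype_sd=1.0,
            status_effects=np.zeros(120), noise_sd=0.5, seed=1,
        )
        out = metabolite_screen(matrix, design)
        assert out["candidate"].sum() > 120 * 0.05  # confounding inflates stage 1
        assert out["significant"].sum() == 0

    def test_constant_feature_reported_not_applicable(self):
        matrix, design = gen_metabolomics_matrix(
            n_genotypes=4, n_reps=3, genotype_sd=0.5,
            status_effects=np.zeros(5), noise_sd=0.3, seed=5,
        )
        matrix.iloc[0, :] = 7.0
        out = metabolite_screen(matrix, design)
        first = out.iloc[0]
        assert "constant" in first["note"]
        assert math.isnan(first["p_t"])
        assert not first["significant"]

    def test_single_genotype_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(
            rng.normal(size=(10, 8)),
            index=[f"m{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(8)],
        )
        matrix.iloc[3, 4:] += 5.0
        design = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(8)],
                "status": [0] * 4 + [1] * 4,
                "genotype": ["G1"] * 8,
            }
        )
        with pytest.warns(UserWarning, match="one genotype"):
            out = metabolite_screen(matrix, design)
        assert bool(out.loc["m3", "significant"])
        assert (out.loc[out["candidate"], "note"] == "t-only fallback (single genotype)").all()

    def test_bad_designs_rejected(self):
        matrix, design = gen_metabolomics_matrix(
            n_genotypes=4, n_reps=3, status_effects=np.zeros(3), seed=0
        )
        three_level = design.copy()
        three_level.loc[0, "status"] = 2
        with pytest.raises(ValidationError, match="status levels"):
            metabolite_screen(matrix, three_level)
        with pytest.raises(ValidationError, match="missing from design"):
            metabolite_screen(matrix, design.iloc[:-2])
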