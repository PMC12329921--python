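"""Thresholds, type selection, balancing, mode comparison, pruning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import txpattern as tp
from txpattern.labeling import labels_for_settings
from txpattern.modes import (
    ModeStats,
    balance_types,
    compare_modes,
    derive_threshold,
    prune_types,
    select_tumour_types,
)


def _inv_norm(p):
    """Acklam rational approximation of the standard normal quantile —
    independent of scipy, used as the oracle."""
    a = [-3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
         1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00]
    b = [-5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
         6.680131188771972e01, -1.328068155288572e01]
    c = [-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
         -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00]
    d = [7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
         3.754408661907416e00]
    plow, phigh = 0.02425, 1 - 0.02425
    if p < plow:
        q = math.sqrt(-2 * math.log(p))
        return (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / (
            (((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1
        )
    if p > phigh:
        return -_inv_norm(1 - p)
    q = p - 0.5
    r = q * q
    return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / (
        ((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1
    )


class TestDeriveThreshold:
    def test_documented_example_against_independent_quantile(self):
        values = [0.6, 0.6, 0.6, 0.6, 0.9]
        spec = derive_threshold(values, alpha=0.1, side="upper")
        mean = np.mean(values)
        sd = np.std(values, ddof=1)
        expected = mean + _inv_norm(0.9) * sd
        assert spec.value == pytest.approx(expected, abs=1e-6)
        assert spec.value == pytest.approx(0.832, abs=1e-3)

    def test_degenerate_all_equal(self):
        spec = derive_threshold([0.7, 0.7, 0.7], alpha=0.1)
        assert spec.degenerate
        assert spec.value == pytest.approx(0.7)

    def test_alpha_half_gives_mean(self):
        spec = derive_threshold([0.2, 0.5, 0.8], alpha=0.5, side="upper")
        assert spec.value == pytest.approx(0.5)

    def test_lower_side(self):
        spec = derive_threshold([0.6, 0.6, 0.6, 0.6, 0.9], alpha=0.1, side="lower")
        assert spec.value == pytest.approx(0.66 - _inv_norm(0.9) * np.std(
            [0.6, 0.6, 0.6, 0.6, 0.9], ddof=1), abs=1e-6)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 3"):
            derive_threshold([0.5, 0.6], alpha=0.1)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=20),
        st.sampled_from([0.05, 0.1, 0.25, 0.5]),
        st.sampled_from(["upper", "lower"]),
    )
    def test_recomputable_from_stored_population(self, values, alpha, side):
        spec = derive_threshold(values, alpha=alpha, side=side)
        assert spec.recompute() == pytest.approx(spec.value, abs=1e-9)


def _ptf1(rows):
    return pd.DataFrame(
        rows, columns=["tumour_type", "f1", "ratio", "n_mutant", "n_wildtype", "n"]
    ).set_index("tumour_type")


class TestSelectTumourTypes:
    def test_types_above_threshold_selected(self):
        table = _ptf1([("A", 0.9, 0.5, 10, 20, 30), ("B", 0.85, 0.5, 10, 20, 30),
                       ("C", 0.5, 0.5, 10, 20, 30)])
        spec = derive_threshold([0.5, 0.5, 0.6, 0.7], alpha=0.5)
        assert select_tumour_types(table, spec) == ["A", "B"]

    def test_none_above_falls_back_to_argmax(self):
        table = _ptf1([("A", 0.6, 0.5, 10, 20, 30), ("B", 0.5, 0.5, 10, 20, 30)])
        spec = tp.ThresholdSpec("f1", 0.1, "upper", 0.9, [0.5] * 3)
        assert select_tumour_types(table, spec) == ["A"]

    def test_tie_breaks_by_sample_count_then_name(self):
        table = _ptf1([("B", 0.6, 0.5, 10, 20, 30), ("A", 0.6, 0.5, 20, 40, 60)])
        spec = tp.ThresholdSpec("f1", 0.1, "upper", 0.9, [0.5] * 3)
        assert select_tumour_types(table, spec) == ["A"]  # larger n wins
        table2 = _ptf1([("B", 0.6, 0.5, 10, 20, 30), ("A", 0.6, 0.5, 10, 20, 30)])
        assert select_tumour_types(table2, spec) == ["A"]  # lexicographic

    def test_single_class_types_never_selected(self):
        table = _ptf1([("A", np.nan, np.nan, 10, 0, 10), ("B", 0.5, 0.5, 10, 20, 30)])
        spec = tp.ThresholdSpec("f1", 0.1, "upper", 0.9, [0.5] * 3)
        assert select_tumour_types(table, spec) == ["B"]


class TestBalanceTypes:
    def _setup(self):
        samples = [f"s{i}" for i in range(100)]
        y = pd.Series(["mutant"] * 30 + ["wildtype"] * 70, index=samples)
        metadata = pd.DataFrame({"tumour_type": ["T1"] * 100}, index=samples)
        return y, metadata

    def test_downsampled_to_minority(self):
        y, metadata = self._setup()
        idx = balance_types(y, metadata, ["T1"], seed=0)
        counts = y.loc[idx].value_counts()
        assert counts["mutant"] == 30 and counts["wildtype"] == 30

    def test_already_balanced_unchanged(self):
        y, metadata = self._setup()
        y.iloc[:] = ["mutant"] * 50 + ["wildtype"] * 50
        idx = balance_types(y, metadata, ["T1"], seed=0)
        assert len(idx) == 100

    def test_determinism(self):
        y, metadata = self._setup()
        a = balance_types(y, metadata, ["T1"], seed=5)
        b = balance_types(y, metadata, ["T1"], seed=5)
        assert a.equals(b)

    def test_single_class_type_dropped_with_warning(self):
        y, metadata = self._setup()
        metadata["tumour_type"] = ["T1"] * 50 + ["T2"] * 50
        y.iloc[50:] = "wildtype"  # T2 has no mutants
        with pytest.warns(UserWarning, match="single class"):
            idx = balance_types(y, metadata, ["T1", "T2"], seed=0)
        assert set(metadata.loc[idx, "tumour_type"]) == {"T1"}

    @settings(max_examples=30, deadline=None)
    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 2**16))
    def test_sizes_property(self, n_mut, n_wt, seed):
        samples = [f"s{i}" for i in range(n_mut + n_wt)]
        y = pd.Series(["mutant"] * n_mut + ["wildtype"] * n_wt, index=samples)
        metadata = pd.DataFrame({"tumour_type": ["T"] * len(samples)}, index=samples)
        idx = balance_types(y, metadata, ["T"], seed=seed)
        counts = y.loc[idx].value_counts()
        assert counts["mutant"] == counts["wildtype"] == min(n_mut, n_wt)


class TestChooseAlterationSetting:
    def test_empty_sv_table_identical_f1(self, small_params, trio_cohort):
        labels = labels_for_settings(
            "PAN", trio_cohort.variants, trio_cohort.cna, trio_cohort.sv,
            trio_cohort.metadata, settings=("snv", "snv_sv"),
        )
        X = trio_cohort.expression.log_values()
        setting, means = tp.choose_alteration_setting(
            "PAN", X, labels, seed=0, params=small_params
        )
        assert setting == "snv"
        assert means["snv"] == pytest.approx(means["snv_sv"])

    def test_zero_cna_fraction_retains_snv(self, small_params, trio_cohort):
        labels = labels_for_settings(
            "PAN", trio_cohort.variants, trio_cohort.cna, trio_cohort.sv,
            trio_cohort.metadata, settings=("snv", "snv_cna"),
        )
        setting, means = tp.choose_alteration_setting(
            "PAN", trio_cohort.expression.log_values(), labels, seed=0, params=small_params
        )
        assert setting == "snv"
        assert means["snv"] == pytest.approx(means["snv_cna"])


class TestCompareModesAndPrune:
    def test_margin_arithmetic_documented_example(self):
        # (0.76 - 0.70) / 0.70 ~ 8.6% > 5%
        assert (0.76 - 0.70) / 0.70 == pytest.approx(0.0857, abs=1e-3)

    def test_chosen_mode_satisfies_its_margin(self, small_params, trio_cohort):
        labels = tp.build_labels(
            "SPEC", "snv", trio_cohort.variants, trio_cohort.cna, trio_cohort.sv,
            trio_cohort.metadata,
        )
        X = trio_cohort.expression.log_values().loc[labels.analysis_samples]
        y = labels.labels.loc[labels.analysis_samples]
        decision = compare_modes(
            "SPEC", X, y, trio_cohort.metadata, n_perm=2, seed=0,
            params=small_params, select_alpha=0.5,
        )
        assert decision.mode in ("specific_types", "balanced_specific")
        assert decision.margins["specific_vs_pan"] > 0.05
        # stats recorded for every feasible mode, with SD over permutations
        assert set(decision.stats) >= {"pan_cancer", "specific_types"}
        for stats_ in decision.stats.values():
            assert len(stats_.f1_values) == 2

    def test_modes_within_margin_keep_pan(self, small_params, trio_cohort):
        labels = tp.build_labels(
            "PAN", "snv", trio_cohort.variants, trio_cohort.cna, trio_cohort.sv,
            trio_cohort.metadata,
        )
        X = trio_cohort.expression.log_values().loc[labels.analysis_samples]
        y = labels.labels.loc[labels.analysis_samples]
        decision = compare_modes(
            "PAN", X, y, trio_cohort.metadata, n_perm=2, seed=0,
            params=small_params, select_alpha=0.5,
        )
        assert decision.mode == "pan_cancer"

    def test_prune_removes_unaffected_type(self, small_params, trio_cohort):
        labels = tp.build_labels(
            "SPEC", "snv", trio_cohort.variants, trio_cohort.cna, trio_cohort.sv,
            trio_cohort.metadata,
        )
        X = trio_cohort.expression.log_values().loc[labels.analysis_samples]
        y = labels.labels.loc[labels.analysis_samples]
        decision = compare_modes(
            "SPEC", X, y, trio_cohort.metadata, n_perm=2, seed=0,
            params=small_params, select_alpha=0.5,
        )
        # force an unaffected type into the selection, then prune it back out
        decision.mode = "specific_types"
        decision.selected_types = sorted(set(decision.selected_types) | {"TTD"})
        pruned = prune_types(
            decision, X, y, trio_cohort.metadata, seed=0, params=small_params, n_perm=2
        )
        assert "TTD" not in pruned.selected_types
        assert pruned.pruning_history
        assert pruned.pruning_history[0]["removed"]

    def test_prune_noop_within_delta(self):
        decision = tp.ModeDecision(
            gene_id="G", setting="snv", mode="pan_cancer", selected_types=["A", "B"],
            stats={"pan_cancer": ModeStats([0.8, 0.8])}, margins={}, threshold=None,
        )
        out = prune_types(decision, None, None, None)
        assert out.selected_types == ["A", "B"]
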