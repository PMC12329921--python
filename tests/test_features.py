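"""Proximity filter, Gini permutation null, categorization, attribution,
expression tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import txpattern as tp
from txpattern.classifier import RFParams
from txpattern.features import (
    GiniNullResult,
    PatternReport,
    _clusters,
    _path_contributions,
    categorize_pattern,
    expression_test,
    gini_null,
    proximity_filter,
    ranked_importances,
    signed_attribution,
    top_features,
)
from txpattern.modes import ModeDecision, ModeStats


def _fake_decision(mode="pan_cancer", types=("A", "B", "C")):
    return ModeDecision(
        gene_id="G", setting="snv", mode=mode, selected_types=list(types),
        stats={mode: ModeStats([0.8, 0.8])}, margins={}, threshold=None,
    )


def _fake_report(gene, f1, gini, n_sig, mode="pan_cancer", types=("A", "B", "C")):
    return PatternReport(
        gene_id=gene, final_f1=f1, top_gini=gini, n_significant=n_sig,
        top_features=pd.DataFrame(), mode_decision=_fake_decision(mode, types),
    )


class TestRankingHelpers:
    def test_tie_break_lexicographic_stable(self):
        imp = pd.Series({"gB": 0.5, "gA": 0.5, "gC": 0.2})
        ranked = ranked_importances(imp)
        assert list(ranked.index) == ["gA", "gB", "gC"]

    def test_top_features_fewer_than_k_warns(self, small_params):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 10)),
                         index=[f"s{i}" for i in range(40)],
                         columns=[f"g{j}" for j in range(10)])
        y = pd.Series(["mutant", "wildtype"] * 20, index=X.index)
        model = tp.fit_final(X, y, seed=0, params=small_params)
        with pytest.warns(UserWarning, match="fewer than k"):
            table = top_features(model, k=15)
        assert len(table) == 10

    def test_clusters_split_on_gap(self):
        positions = np.array([1e6, 1.5e6, 2.2e6, 9e6, 9.5e6])
        runs = _clusters(positions, gap_bp=1e6)
        assert [len(r) for r in runs] == [3, 2]


class TestProximityFilter:
    def test_no_nearby_features_noop(self, small_params, trio_cohort, trio_pan_cv):
        _, X, y, cv = trio_pan_cv
        model = tp.fit_final(X, y, seed=0, params=small_params, cv=cv)
        locus = trio_cohort.expression.locus("PAN")
        Xf, fmodel, regions, iters = proximity_filter(
            model, X, y, trio_cohort.expression.annotation, locus,
            seed=0, params=small_params,
        )
        assert iters == 0
        assert regions == []
        assert Xf.columns.equals(X.columns)

    def test_missing_coordinates_hard_error(self, small_params):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 6)),
                         index=[f"s{i}" for i in range(40)],
                         columns=[f"g{j}" for j in range(6)])
        y = pd.Series(["mutant", "wildtype"] * 20, index=X.index)
        model = tp.fit_final(X, y, seed=0, params=small_params)
        annotation = pd.DataFrame(
            {"chrom": "chr1", "start": 1, "end": 2, "coding": True}, index=["g0"]
        )
        with pytest.raises(KeyError, match="coordinates"):
            proximity_filter(model, X, y, annotation, ("chr1", 1, 2), params=small_params)


class TestGiniNull:
    def test_zero_permutations_rejected(self, small_params):
        X = pd.DataFrame(np.zeros((10, 3)), columns=list("abc"))
        y = pd.Series(["mutant", "wildtype"] * 5, index=X.index)
        with pytest.raises(ValueError, match="n_perm"):
            gini_null(X, y, n_perm=0, params=small_params)

    def test_single_class_rejected(self, small_params):
        X = pd.DataFrame(np.zeros((10, 3)), columns=list("abc"))
        y = pd.Series(["mutant"] * 10, index=X.index)
        with pytest.raises(ValueError, match="both classes"):
            gini_null(X, y, n_perm=5, params=small_params)

    def test_planted_signature_yields_significant_features(self, small_params, trio_pan_cv):
        _, X, y, cv = trio_pan_cv
        result = gini_null(X, y, n_perm=10, seed=0, alpha=0.05, params=small_params)
        assert result.n_significant >= 10
        assert result.top_gini == result.true_sorted.iloc[0]

    def test_significant_count_counts_from_rank_one(self):
        true_sorted = pd.Series([0.5, 0.3, 0.01], index=["a", "b", "c"])
        result = GiniNullResult(
            true_sorted=true_sorted, rank_quantiles=np.array([0.1, 0.05, 0.04]),
            n_significant=2, significant_features=["a", "b"], alpha=0.05, n_perm=10,
        )
        # frozen semantics: rank 3 fails (0.01 < 0.04), counting stops there
        assert result.n_significant == 2


class TestCategorizePattern:
    def test_requires_three_genes_or_explicit_thresholds(self):
        with pytest.raises(ValueError, match=">= 3"):
            categorize_pattern([_fake_report("G1", 0.8, 0.05, 5)])
        out = categorize_pattern(
            [_fake_report("G1", 0.8, 0.05, 5)], f1_threshold=0.686, gini_threshold=0.0021
        )
        assert out == {"G1": "pan_cancer"}

    def test_low_f1_at_gini_floor_is_no_or_weak(self):
        # mirrors a weak-pattern gene: F1 0.64 with top Gini at the cohort floor
        out = categorize_pattern(
            [_fake_report("weak", 0.64, 0.0021, 0)],
            f1_threshold=0.686, gini_threshold=0.0021,
        )
        assert out["weak"] == "no_or_weak"

    def test_adequate_f1_but_gini_below_floor_is_no_or_weak(self):
        # F1 0.71 clears the floor but top Gini 0.0014 < 0.0021
        out = categorize_pattern(
            [_fake_report("weak2", 0.71, 0.0014, 3)],
            f1_threshold=0.686, gini_threshold=0.0021,
        )
        assert out["weak2"] == "no_or_weak"

    def test_overfit_requires_balanced_small_cohort(self):
        overfit = _fake_report("of", 0.9, 0.001, 3, mode="balanced_specific", types=("A",))
        not_overfit = _fake_report("now", 0.9, 0.001, 3, mode="balanced_specific",
                                   types=("A", "B", "C"))
        out = categorize_pattern(
            [overfit, not_overfit], f1_threshold=0.686, gini_threshold=0.0021
        )
        assert out["of"] == "potential_overfit"
        assert out["now"] == "no_or_weak"

    def test_zero_significant_features_is_no_or_weak(self):
        out = categorize_pattern(
            [_fake_report("z", 0.9, 0.05, 0)], f1_threshold=0.686, gini_threshold=0.0021
        )
        assert out["z"] == "no_or_weak"

    def test_mode_maps_to_category(self):
        reports = [
            _fake_report("pan", 0.9, 0.05, 5, mode="pan_cancer"),
            _fake_report("spec", 0.9, 0.05, 5, mode="specific_types"),
            _fake_report("balspec", 0.9, 0.05, 5, mode="balanced_specific",
                         types=("A", "B", "C")),
        ]
        out = categorize_pattern(reports, f1_threshold=0.686, gini_threshold=0.0021)
        assert out == {"pan": "pan_cancer", "spec": "tumour_specific",
                       "balspec": "tumour_specific"}

    def test_cohort_thresholds_derived_when_not_given(self):
        reports = [
            _fake_report("a", 0.95, 0.05, 5),
            _fake_report("b", 0.93, 0.04, 5),
            _fake_report("c", 0.40, 0.001, 0),
        ]
        out = categorize_pattern(reports)
        assert out["c"] == "no_or_weak"
        assert out["a"] == "pan_cancer"


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(1)
    n = 200
    y = pd.Series(["mutant"] * 80 + ["wildtype"] * 120,
                  index=[f"s{i}" for i in range(n)])
    X = pd.DataFrame(rng.normal(size=(n, 20)), index=y.index,
                     columns=[f"g{j}" for j in range(20)])
    X["up_in_mut"] = rng.normal(size=n) + np.where(y == "mutant", 2.0, 0.0)
    X["down_in_mut"] = rng.normal(size=n) - np.where(y == "mutant", 2.0, 0.0)
    X["const"] = 1.0
    model = tp.fit_final(X, y, seed=0, params=RFParams(n_estimators=80))
    return model, X


class TestSignedAttribution:
    def test_planted_directions(self, planted):
        model, X = planted
        signs = signed_attribution(model, X, features=["up_in_mut", "down_in_mut"])
        assert signs.loc["up_in_mut", "direction"] == "higher_mutant"
        assert signs.loc["down_in_mut", "direction"] == "higher_wildtype"
        assert signs["agree"].all()

    def test_constant_feature_undefined(self, planted):
        model, X = planted
        signs = signed_attribution(model, X, features=["const"])
        assert signs.loc["const", "direction"] == "undefined"
        assert signs.loc["const", "attribution"] == 0.0

    def test_contributions_reconstruct_probability(self, planted):
        # path contributions + root prior must equal the forest probability
        model, X = planted
        contrib = _path_contributions(model, X.iloc[:30])
        pos = list(model.forest.classes_).index(model.positive_class)
        priors = np.mean(
            [est.tree_.value[0, 0, pos] / est.tree_.value[0, 0, :].sum()
             for est in model.forest.estimators_]
        )
        reconstructed = contrib.sum(axis=1) + priors
        expected = model.predict_proba_positive(X.iloc[:30])
        assert np.allclose(reconstructed, expected, atol=1e-9)

    def test_non_tree_model_rejected(self):
        class NotAForest:
            feature_ids = pd.Index([])
            forest = object()

        with pytest.raises(TypeError, match="tree ensemble"):
            signed_attribution(NotAForest(), pd.DataFrame())


class TestExpressionTest:
    def _frame(self, a, b):
        values = pd.DataFrame({"g": np.concatenate([a, b])},
                              index=[f"s{i}" for i in range(len(a) + len(b))])
        ga = values.index[: len(a)]
        gb = values.index[len(a):]
        return values, ga, gb

    def test_identical_groups_p_one(self):
        values, ga, gb = self._frame(np.ones(10), np.ones(10))
        out = expression_test(values, ga, gb, ["g"])
        assert out.loc["g", "p_adj"] == 1.0

    def test_planted_shift_highly_significant(self):
        rng = np.random.default_rng(0)
        values, ga, gb = self._frame(rng.normal(2, 1, 100), rng.normal(0, 1, 100))
        out = expression_test(values, ga, gb, ["g"])
        assert out.loc["g", "p_adj"] < 1e-4  # "****" band
        assert out.loc["g", "median_a"] > out.loc["g", "median_b"]

    def test_small_group_missing(self):
        values, ga, gb = self._frame(np.ones(2), np.zeros(10))
        out = expression_test(values, ga, gb, ["g"])
        assert np.isnan(out.loc["g", "p_raw"])

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(size=(40, 5)),
                              index=[f"s{i}" for i in range(40)],
                              columns=[f"g{j}" for j in range(5)])
        ga, gb = values.index[:20], values.index[20:]
        out = expression_test(values, ga, gb, list(values.columns))
        raw = out["p_raw"]
        adj = out["p_adj"]
        assert np.allclose(adj, np.minimum(1.0, raw * 5))

    def test_exact_pvalue_matches_enumeration(self):
        # brute force over all label assignments at n=4/4 (no ties)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 5.0, 6.0, 7.0])
        values, ga, gb = self._frame(a, b)
        out = expression_test(values, ga, gb, ["g"], correction="none")
        pooled = np.concatenate([a, b])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        n1 = len(a)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        u_null = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
            u_null.append(r)
        u_null = np.array(u_null)
        n2 = len(b)
        # two-sided exact p: fraction of assignments at least as extreme
        dev = np.abs(u_null - n1 * n2 / 2)
        p_exact = float((dev >= abs(u_obs - n1 * n2 / 2)).mean())
        assert out.loc["g", "p_raw"] == pytest.approx(p_exact, abs=1e-12)

    def test_unknown_correction_rejected(self):
        values, ga, gb = self._frame(np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="correction"):
            expression_test(values, ga, gb, ["g"], correction="fdr")
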