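"""Post-hoc analysis of a fitted classifier.

Covers: removal of chromosomally proximal features (cis-dosage confounds of
copy-number events), permutation-calibrated significance of Gini
importances, categorization of per-gene transcriptional patterns, top-15
feature extraction, signed per-feature attribution, and rank-sum expression
comparisons between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .classifier import FittedModel, RFParams
from .modes import ModeDecision, derive_threshold

CATEGORIES = ("pan_cancer", "tumour_specific", "no_or_weak", "potential_overfit")


@dataclass
class ExcisedRegion:
    chrom: str
    start: int
    end: int
    n_transcripts: int
    transcripts: list[str]

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "n_transcripts": self.n_transcripts,
            "transcripts": list(self.transcripts),
        }


@dataclass
class GiniNullResult:
    """Permutation null for ranked Gini importances."""

    true_sorted: pd.Series  # true importances, descending
    rank_quantiles: np.ndarray  # (1-alpha) null quantile per rank
    n_significant: int
    significant_features: list[str]
    alpha: float
    n_perm: int

    @property
    def top_gini(self) -> float:
        return float(self.true_sorted.iloc[0])


@dataclass
class PatternReport:
    """Final per-driver summary feeding the category call."""

    gene_id: str
    final_f1: float
    top_gini: float
    n_significant: int
    top_features: pd.DataFrame  # rank, gini, sign columns
    mode_decision: ModeDecision
    category: str | None = None
    excised_regions: list[ExcisedRegion] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "final_f1": self.final_f1,
            "top_gini": self.top_gini,
            "n_significant": self.n_significant,
            "category": self.category,
            "top_features": self.top_features.reset_index().to_dict("records"),
            "mode_decision": self.mode_decision.to_dict(),
            "excised_regions": [r.to_dict() for r in self.excised_regions],
        }


def ranked_importances(importances: pd.Series) -> pd.Series:
    """Importances sorted descending, ties broken by transcript id."""
    order = sorted(importances.index, key=lambda g: (-importances[g], g))
    return importances.loc[order]


def top_features(model: FittedModel, k: int = 15) -> pd.DataFrame:
    """Top-k features by Gini importance (stable lexicographic tie-break)."""
    ranked = ranked_importances(model.importances)
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} features available, fewer than k={k}")
    head = ranked.head(k)
    return pd.DataFrame(
        {"gini": head.to_numpy(), "rank": np.arange(1, len(head) + 1)},
        index=pd.Index(head.index, name="feature"),
    )


def _clusters(positions: np.ndarray, gap_bp: float) -> list[np.ndarray]:
    """Split sorted positions into runs with consecutive gaps <= gap_bp."""
    if len(positions) == 0:
        return []
    breaks = np.where(np.diff(positions) > gap_bp)[0]
    return np.split(positions, breaks + 1)


def proximity_filter(
    model: FittedModel,
    X: pd.DataFrame,
    y: pd.Series,
    annotation: pd.DataFrame,
    target_locus: tuple[str, int, int],
    top_k: int = 15,
    window_mb: float = 10.0,
    gap_mb: float = 1.0,
    cluster_min: int = 3,
    max_iter: int = 5,
    seed: int = 0,
    params: RFParams | None = None,
) -> tuple[pd.DataFrame, FittedModel, list[ExcisedRegion], int]:
    """Iteratively excise clusters of top-ranked features physically adjacent
    to the target gene, refitting after each excision.

    A cluster is >= ``cluster_min`` of the top ``top_k`` features on the
    target chromosome, within ``window_mb`` of the target locus, with
    pairwise gaps <= ``gap_mb``.  The excised genomic span is the cluster
    extent padded by ``gap_mb`` on both sides, so immediate neighbours of
    detected confounds leave with them.  Returns the filtered feature matrix,
    the refit model, the excision log, and the iteration count.
    """
    params = params or model.params
    chrom, t_start, t_end = target_locus
    centre = (t_start + t_end) / 2.0
    window_bp = window_mb * 1e6
    gap_bp = gap_mb * 1e6

    current_X = X
    current_model = model
    regions: list[ExcisedRegion] = []
    iterations = 0
    while iterations < max_iter:
        ranked = ranked_importances(current_model.importances).head(top_k)
        missing = [g for g in ranked.index if g not in annotation.index]
        if missing:
            raise KeyError(
                f"missing genomic coordinates for top feature(s) {missing[:3]}; "
                "proximity filtering cannot proceed"
            )
        ann = annotation.loc[list(ranked.index)]
        mids = (ann["start"] + ann["end"]) / 2.0
        near = ann[(ann["chrom"] == chrom) & ((mids - centre).abs() <= window_bp)]
        if near.empty:
            break
        near_mids = np.sort(((near["start"] + near["end"]) / 2.0).to_numpy())
        cluster = max(_clusters(near_mids, gap_bp), key=len)
        if len(cluster) < cluster_min:
            break
        span_lo = float(cluster.min()) - gap_bp
        span_hi = float(cluster.max()) + gap_bp
        all_mids = (annotation["start"] + annotation["end"]) / 2.0
        to_remove = annotation.index[
            (annotation["chrom"] == chrom)
            & (all_mids >= span_lo)
            & (all_mids <= span_hi)
            & annotation.index.isin(current_X.columns)
        ]
        regions.append(
            ExcisedRegion(
                chrom=chrom,
                start=int(span_lo),
                end=int(span_hi),
                n_transcripts=len(to_remove),
                transcripts=sorted(to_remove),
            )
        )
        current_X = current_X.drop(columns=list(to_remove))
        forest = params.build(seed)
        forest.fit(current_X.to_numpy(), y.loc[current_X.index].to_numpy())
        current_model = FittedModel(
            forest=forest,
            feature_ids=current_X.columns,
            importances=pd.Series(forest.feature_importances_, index=current_X.columns),
            positive_class=current_model.positive_class,
            seed=seed,
            params=params,
        )
        iterations += 1
    return current_X, current_model, regions, iterations


def gini_null(
    X: pd.DataFrame,
    y: pd.Series,
    n_perm: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    params: RFParams = RFParams(),
    model: FittedModel | None = None,
) -> GiniNullResult:
    """Permutation null for the number of significant features.

    Labels are shuffled ``n_perm`` times with a forest refit each time.  For
    rank r the null quantile is the (1-alpha) empirical quantile of the r-th
    largest null Gini; true features count as significant from rank 1 down
    until the first rank whose Gini fails to exceed its null quantile.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    y = y.reindex(X.index)
    if y.nunique() < 2:
        raise ValueError("need both classes to build a permutation null")

    if model is not None and model.feature_ids.equals(X.columns):
        true_imp = model.importances
    else:
        forest = params.build(seed)
        forest.fit(X.to_numpy(), y.to_numpy())
        true_imp = pd.Series(forest.feature_importances_, index=X.columns)
    true_sorted = ranked_importances(true_imp)

    rng = np.random.default_rng(seed)
    null_sorted = np.empty((n_perm, X.shape[1]))
    Xv = X.to_numpy()
    yv = y.to_numpy()
    for i in range(n_perm):
        y_perm = rng.permutation(yv)
        forest = params.build(seed + 1 + i)
        forest.fit(Xv, y_perm)
        null_sorted[i] = np.sort(forest.feature_importances_)[::-1]
    quantiles = np.quantile(null_sorted, 1.0 - alpha, axis=0)

    true_values = true_sorted.to_numpy()
    n_sig = 0
    while n_sig < len(true_values) and true_values[n_sig] > quantiles[n_sig]:
        n_sig += 1
    return GiniNullResult(
        true_sorted=true_sorted,
        rank_quantiles=quantiles,
        n_significant=n_sig,
        significant_features=list(true_sorted.index[:n_sig]),
        alpha=alpha,
        n_perm=n_perm,
    )


def categorize_pattern(
    reports: list[PatternReport],
    alpha_f1: float = 0.1,
    alpha_gini: float = 0.25,
    f1_threshold: float | None = None,
    gini_threshold: float | None = None,
) -> dict[str, str]:
    """Assign each gene a pattern category from cohort-level thresholds.

    The F1 floor is a z-test lower bound (``alpha_f1``) on the cross-gene
    final-F1 distribution; the Gini floor is the ``alpha_gini`` empirical
    lower percentile of cross-gene top-Gini values.  With fewer than 3 genes
    both thresholds must be supplied explicitly.  Mutates ``report.category``
    and returns gene -> category.
    """
    if f1_threshold is None or gini_threshold is None:
        if len(reports) < 3:
            raise ValueError(
                "cohort-level thresholds need >= 3 analyzed genes; "
                "supply f1_threshold and gini_threshold explicitly"
            )
        if f1_threshold is None:
            f1_threshold = derive_threshold(
                [r.final_f1 for r in reports], alpha=alpha_f1, side="lower"
            ).value
        if gini_threshold is None:
            gini_threshold = float(
                np.quantile([r.top_gini for r in reports], alpha_gini)
            )

    out: dict[str, str] = {}
    for report in reports:
        weak_gini = report.top_gini < gini_threshold
        weak_f1 = report.final_f1 < f1_threshold
        if not weak_f1 and weak_gini and report.mode_decision.balanced_small:
            category = "potential_overfit"
        elif weak_f1 or weak_gini or report.n_significant == 0:
            category = "no_or_weak"
        elif report.mode_decision.mode in ("specific_types", "balanced_specific"):
            category = "tumour_specific"
        else:
            category = "pan_cancer"
        report.category = category
        out[report.gene_id] = category
    return out


def _path_contributions(model: FittedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-feature decision-path contributions to P(positive).

    For every tree, walking a sample from root to leaf, the change in the
    node-level positive-class fraction at each split is credited to the split
    feature; contributions are averaged over trees.  Contributions plus the
    root prior reconstruct each tree's predicted probability exactly.
    """
    forest = model.forest
    pos = list(forest.classes_).index(model.positive_class)
    n, p = X.shape
    total = np.zeros((n, p))
    Xv = X.to_numpy().astype(np.float32)
    for est in forest.estimators_:
        tree = est.tree_
        value = tree.value[:, 0, :]
        prob = value[:, pos] / value.sum(axis=1)
        n_nodes = tree.node_count
        parent = np.full(n_nodes, -1)
        for node in range(n_nodes):
            for child in (tree.children_left[node], tree.children_right[node]):
                if child != -1:
                    parent[child] = node
        delta = np.zeros(n_nodes)
        parent_feature = np.zeros(n_nodes, dtype=int)
        nonroot = parent >= 0
        delta[nonroot] = prob[nonroot] - prob[parent[nonroot]]
        parent_feature[nonroot] = tree.feature[parent[nonroot]]
        M = sparse.csr_matrix(
            (delta[nonroot], (np.where(nonroot)[0], parent_feature[nonroot])),
            shape=(n_nodes, p),
        )
        indicator = est.decision_path(Xv)
        total += np.asarray((indicator @ M).todense())
    return pd.DataFrame(total / len(forest.estimators_), index=X.index, columns=X.columns)


def signed_attribution(
    model: FittedModel,
    X: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Direction of association for each feature.

    Sign +1 ("higher_wildtype"): higher expression pushes predictions toward
    the positive (wild-type) class; -1 ("higher_mutant"): toward mutant.
    The primary signal is the rank correlation between a feature's values and
    its decision-path attribution; a rank-correlation of expression against
    the predicted wild-type probability serves as an independent fallback and
    the agreement of the two is reported per feature.
    """
    if not hasattr(model.forest, "estimators_"):
        raise TypeError("signed attribution requires a fitted tree ensemble")
    features = list(features) if features is not None else list(model.feature_ids)
    contrib = _path_contributions(model, X)
    proba = model.predict_proba_positive(X)

    rows = []
    for feature in features:
        x = X[feature].to_numpy()
        c = contrib[feature].to_numpy()
        score = float(np.abs(c).mean())
        if np.ptp(x) == 0 or score == 0.0:
            rows.append(
                {
                    "feature": feature,
                    "sign": 0,
                    "direction": "undefined",
                    "attribution": score,
                    "fallback_sign": 0,
                    "agree": True,
                }
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(x, c).statistic
            rho_fb = stats.spearmanr(x, proba.to_numpy()).statistic
        sign = int(np.sign(rho)) if np.isfinite(rho) else 0
        fb = int(np.sign(rho_fb)) if np.isfinite(rho_fb) else 0
        rows.append(
            {
                "feature": feature,
                "sign": sign,
                "direction": {1: "higher_wildtype", -1: "higher_mutant", 0: "undefined"}[sign],
                "attribution": score,
                "fallback_sign": fb,
                "agree": bool(sign == fb or sign == 0 or fb == 0),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def expression_test(
    values: pd.DataFrame,
    group_a: pd.Index,
    group_b: pd.Index,
    genes: list[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Two-sided Mann-Whitney rank-sum comparison of TPM per gene.

    ``values`` is a samples x transcripts TPM frame.  P-values are Bonferroni
    multiplied by the number of tests (capped at 1).  Groups smaller than 3
    yield missing p-values.  Group medians are reported alongside.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unsupported correction {correction!r}")
    n_tests = len(genes)
    rows = []
    for gene in genes:
        a = values.loc[group_a, gene].to_numpy()
        b = values.loc[group_b, gene].to_numpy()
        if len(a) < 3 or len(b) < 3:
            p_raw = float("nan")
        elif np.ptp(np.concatenate([a, b])) == 0:
            p_raw = 1.0
        else:
            p_raw = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_adj = p_raw if correction == "none" else min(1.0, p_raw * n_tests)
        rows.append(
            {
                "gene": gene,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "median_a": float(np.median(a)) if len(a) else float("nan"),
                "median_b": float(np.median(b)) if len(b) else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
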