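"""End-to-end per-gene pipeline, excluded-sample prediction, QC, reporting.

``run_pipeline`` composes: labeling -> alteration-setting choice -> mode
selection -> type pruning -> final fit -> proximity filtering -> permutation
Gini null -> top features + signed attribution -> pattern categorization ->
prediction of samples carrying only non-impactful variants.  Every decision
object lands in a JSON-serializable run ledger; per-gene failures are
isolated and recorded.  Wall-clock timings go to a separate log so repeated
runs under one seed produce byte-identical ledgers.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import __version__
from .classifier import FittedModel, RFParams, fit_final, run_cv, safe_f1
from .cohort import Cohort
from .features import (
    PatternReport,
    categorize_pattern,
    gini_null,
    proximity_filter,
    signed_attribution,
    top_features,
)
from .labeling import LabelingError, LabelSet, labels_for_settings
from .modes import (
    AnalyzabilityError,
    ThresholdSpec,
    analysis_index,
    choose_alteration_setting,
    compare_modes,
    derive_threshold,
    prune_types,
)


@dataclass
class NonImpactfulReport:
    """Predictions for samples whose only variants are non-impactful."""

    gene_id: str
    predictions: pd.DataFrame  # sample_id index: predicted, p_wildtype, consequences
    summary: pd.DataFrame  # consequence term index: n, n_mutant, fraction_mutant
    flagged_terms: list[str]

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "predictions": self.predictions.reset_index().to_dict("records"),
            "summary": self.summary.reset_index().to_dict("records"),
            "flagged_terms": list(self.flagged_terms),
        }


def predict_excluded(
    model: FittedModel,
    X_excluded: pd.DataFrame,
    variants: pd.DataFrame,
    gene_id: str,
    flag_fraction: float = 0.5,
    flag_min_n: int = 5,
) -> NonImpactfulReport:
    """Apply the final model to held-out non-impactful-variant samples.

    Summarizes predictions per consequence term; terms where more than
    ``flag_fraction`` of >= ``flag_min_n`` samples are called mutant are
    flagged for inspection.  Class call is the forest vote (0.5 cutoff).
    """
    if len(X_excluded) == 0:
        empty = pd.DataFrame(columns=["predicted", "p_wildtype", "consequences"])
        summary = pd.DataFrame(columns=["n", "n_mutant", "fraction_mutant"])
        return NonImpactfulReport(gene_id, empty, summary, [])
    predicted = model.predict(X_excluded)
    p_wt = model.predict_proba_positive(X_excluded)
    gene_variants = variants[
        (variants["gene_id"] == gene_id) & variants["sample_id"].isin(X_excluded.index)
    ]
    terms = gene_variants.groupby("sample_id")["consequence"].agg(
        lambda s: ",".join(sorted(set(s)))
    )
    predictions = pd.DataFrame(
        {
            "predicted": predicted,
            "p_wildtype": p_wt,
            "consequences": terms.reindex(X_excluded.index).fillna(""),
        }
    )
    predictions.index.name = "sample_id"

    rows = []
    for term, group in gene_variants.groupby("consequence"):
        samples = group["sample_id"].unique()
        calls = predicted.loc[[s for s in samples if s in predicted.index]]
        n_mut = int((calls == "mutant").sum())
        rows.append(
            {
                "consequence": term,
                "n": len(calls),
                "n_mutant": n_mut,
                "fraction_mutant": n_mut / len(calls) if len(calls) else float("nan"),
            }
        )
    summary = pd.DataFrame(rows).set_index("consequence") if rows else pd.DataFrame(
        columns=["n", "n_mutant", "fraction_mutant"]
    )
    flagged = [
        t
        for t, row in summary.iterrows()
        if row["n"] >= flag_min_n and row["fraction_mutant"] > flag_fraction
    ]
    return NonImpactfulReport(gene_id, predictions, summary, flagged)


def cross_cohort_predict(
    model: FittedModel,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_external: pd.DataFrame,
    y_external: pd.Series,
    restrict_coding: bool = False,
    annotation: pd.DataFrame | None = None,
    min_overlap: int = 10,
    seed: int = 0,
) -> dict:
    """Score a model on an external cohort, retraining on shared features.

    When the external feature space differs (or ``restrict_coding`` is set),
    the forest is refit on the training data restricted to the shared (and
    optionally coding-only) transcripts before predicting.
    """
    shared = model.feature_ids.intersection(X_external.columns)
    if restrict_coding:
        if annotation is None:
            raise ValueError("restrict_coding requires an annotation table")
        coding = annotation.index[annotation["coding"].astype(bool)]
        shared = shared.intersection(coding)
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} shared features (< {min_overlap}); "
            "external cohort not comparable"
        )
    retrained = len(shared) < len(model.feature_ids)
    if retrained:
        forest = model.params.build(seed)
        forest.fit(X_train[shared].to_numpy(), y_train.loc[X_train.index].to_numpy())
        pred = pd.Series(forest.predict(X_external[shared].to_numpy()), index=X_external.index)
    else:
        pred = model.predict(X_external[model.feature_ids])
    f1 = safe_f1(
        y_external.reindex(X_external.index).to_numpy(), pred.to_numpy(), model.positive_class
    )
    return {"f1": f1, "n_shared_features": int(len(shared)), "retrained": retrained}


def qc_pca(
    expression,
    metadata: pd.DataFrame,
    n_components: int = 2,
) -> dict:
    """PCA of log2(TPM+1) with cohort/tumour-type separation diagnostics."""
    X = expression.log_values()
    if len(X) < 2:
        raise ValueError("need at least 2 samples for PCA")
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    degenerate = bool(np.allclose(Xc, 0))
    n_components = min(n_components, len(X) - 1, X.shape[1])
    if degenerate:
        coords = pd.DataFrame(
            np.zeros((len(X), n_components)),
            index=X.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )
        variance = [0.0] * n_components
    else:
        pca = PCA(n_components=n_components, random_state=0)
        coords = pd.DataFrame(
            pca.fit_transform(Xc),
            index=X.index,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )
        variance = [float(v) for v in pca.explained_variance_ratio_]

    def _silhouette(labels: pd.Series) -> float:
        if degenerate or labels.nunique() < 2 or labels.value_counts().min() < 2:
            return float("nan")
        return float(silhouette_score(coords.to_numpy(), labels.to_numpy()))

    meta = metadata.loc[X.index]
    return {
        "coordinates": coords,
        "variance_explained": variance,
        "degenerate": degenerate,
        "silhouette_cohort": _silhouette(meta["cohort"]),
        "silhouette_tumour_type": _silhouette(meta["tumour_type"]),
    }


@dataclass
class PipelineConfig:
    """Tunable knobs of the per-gene analysis."""

    settings: tuple[str, ...] = ("snv", "snv_cna")
    k_folds: int = 5
    rf: RFParams = field(default_factory=RFParams)
    cna_epsilon: float = 0.01
    n_perm_modes: int = 30
    select_alpha: float = 0.1
    improvement: float = 0.05
    relative_improvement: bool = True
    prune_delta: float = 0.05
    prune_n_perm: int = 5
    pooled_type_threshold: bool = True
    proximity_top_k: int = 15
    proximity_window_mb: float = 10.0
    proximity_gap_mb: float = 1.0
    proximity_cluster_min: int = 3
    proximity_max_iter: int = 5
    gini_n_perm: int = 50
    gini_alpha: float = 0.05
    alpha_f1: float = 0.1
    alpha_gini: float = 0.25
    top_k: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rf = RFParams(**raw.pop("rf", {}))
        if "settings" in raw:
            raw["settings"] = tuple(raw["settings"])
        return cls(rf=rf, **raw)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "rf"}
        out["settings"] = list(self.settings)
        out["rf"] = self.rf.to_dict()
        return out


@dataclass
class GeneResult:
    gene_id: str
    report: PatternReport | None
    non_impactful: NonImpactfulReport | None
    model: FittedModel | None
    labels: LabelSet | None
    error: str | None = None


@dataclass
class RunLedger:
    """Audit trail sufficient to re-run any stage bit-identically."""

    config: dict
    seed: int
    version: str
    genes: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "genes": self.genes,
            "thresholds": self.thresholds,
            "categories": self.categories,
            "errors": self.errors,
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (pd.Index, np.ndarray)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _gene_seed(master: int, gene_id: str) -> int:
    # stable per-gene child seed (never Python's salted hash())
    digest = 0
    for ch in gene_id:
        digest = (digest * 131 + ord(ch)) % 1_000_003
    return master * 1_000_003 + digest


def analyze_gene(
    gene_id: str,
    cohort: Cohort,
    config: PipelineConfig,
    type_threshold: ThresholdSpec | None = None,
) -> GeneResult:
    """Run the full decision procedure for one driver gene."""
    seed = _gene_seed(config.seed, gene_id)
    X_all = cohort.expression.log_values()
    meta = cohort.metadata

    labels_by_setting = labels_for_settings(
        gene_id, cohort.variants, cohort.cna, cohort.sv, meta, settings=config.settings
    )
    setting, setting_means = choose_alteration_setting(
        gene_id,
        X_all,
        labels_by_setting,
        seed=seed,
        k=config.k_folds,
        params=config.rf,
        epsilon=config.cna_epsilon,
    )
    labels = labels_by_setting[setting]
    train_samples = labels.analysis_samples
    y = labels.labels.loc[train_samples]
    X = X_all.loc[train_samples]

    decision = compare_modes(
        gene_id,
        X,
        y,
        meta,
        n_perm=config.n_perm_modes,
        seed=seed + 1,
        k=config.k_folds,
        params=config.rf,
        threshold=type_threshold,
        select_alpha=config.select_alpha,
        improvement=config.improvement,
        relative=config.relative_improvement,
    )
    decision.setting = setting
    decision.notes.append(f"setting_means={json.dumps(setting_means, sort_keys=True)}")
    decision = prune_types(
        decision,
        X,
        y,
        meta,
        seed=seed + 2,
        k=config.k_folds,
        params=config.rf,
        delta=config.prune_delta,
        n_perm=config.prune_n_perm,
    )

    idx = analysis_index(decision, y, meta, seed=seed + 3)
    X_mode, y_mode = X.loc[idx], y.loc[idx]
    final_cv = run_cv(X_mode, y_mode, k=config.k_folds, seed=seed + 4, params=config.rf)
    model = fit_final(X_mode, y_mode, seed=seed + 4, params=config.rf, cv=final_cv)

    locus = cohort.expression.locus(gene_id)
    X_filtered, model, regions, _ = proximity_filter(
        model,
        X_mode,
        y_mode,
        cohort.expression.annotation,
        locus,
        top_k=config.proximity_top_k,
        window_mb=config.proximity_window_mb,
        gap_mb=config.proximity_gap_mb,
        cluster_min=config.proximity_cluster_min,
        max_iter=config.proximity_max_iter,
        seed=seed + 5,
        params=config.rf,
    )
    if regions:
        final_cv = run_cv(
            X_filtered, y_mode, k=config.k_folds, seed=seed + 4, params=config.rf
        )
        model.cv_f1 = final_cv.mean_f1

    null = gini_null(
        X_filtered,
        y_mode,
        n_perm=config.gini_n_perm,
        seed=seed + 6,
        alpha=config.gini_alpha,
        params=config.rf,
        model=model,
    )
    top = top_features(model, k=config.top_k)
    signs = signed_attribution(model, X_filtered, features=list(top.index))
    top = top.join(signs[["sign", "direction", "agree"]])

    report = PatternReport(
        gene_id=gene_id,
        final_f1=float(model.cv_f1),
        top_gini=null.top_gini,
        n_significant=null.n_significant,
        top_features=top,
        mode_decision=decision,
        excised_regions=regions,
    )

    excluded = labels.excluded
    X_excl = X_all.loc[excluded, model.feature_ids]
    non_impactful = predict_excluded(model, X_excl, cohort.variants, gene_id)
    return GeneResult(
        gene_id=gene_id,
        report=report,
        non_impactful=non_impactful,
        model=model,
        labels=labels,
    )


def pooled_type_threshold(
    genes: list[str],
    cohort: Cohort,
    config: PipelineConfig,
) -> ThresholdSpec | None:
    """First-pass pan-cancer per-type F1 pooled over genes -> selection
    threshold, mirroring a cohort-wide z-test on the type-level F1
    distribution.  Returns None when too few values exist."""
    from .classifier import per_type_f1

    pool: list[float] = []
    for gene_id in genes:
        seed = _gene_seed(config.seed, gene_id)
        try:
            labels_by_setting = labels_for_settings(
                gene_id, cohort.variants, cohort.cna, cohort.sv, cohort.metadata,
                settings=config.settings,
            )
        except LabelingError:
            continue
        labels = next(iter(labels_by_setting.values()))
        samples = labels.analysis_samples
        y = labels.labels.loc[samples]
        try:
            cv = run_cv(
                cohort.expression.log_values().loc[samples],
                y,
                k=config.k_folds,
                seed=seed,
                params=config.rf,
            )
        except Exception:
            continue
        table = per_type_f1(cv, cohort.metadata)
        pool.extend(v for v in table["f1"] if np.isfinite(v))
    if len(pool) < 3:
        return None
    return derive_threshold(pool, alpha=config.select_alpha, side="upper")


def run_pipeline(
    cohort: Cohort,
    genes: list[str],
    config: PipelineConfig | None = None,
) -> tuple[dict[str, GeneResult], RunLedger]:
    """Analyze every gene, categorize patterns, and assemble the run ledger.

    Per-gene failures abort only that gene and are recorded in the ledger.
    """
    config = config or PipelineConfig()
    ledger = RunLedger(config=config.to_dict(), seed=config.seed, version=__version__)
    threshold = None
    if config.pooled_type_threshold:
        threshold = pooled_type_threshold(genes, cohort, config)
        if threshold is not None:
            ledger.thresholds["type_selection"] = threshold.to_dict()

    results: dict[str, GeneResult] = {}
    timings: dict[str, float] = {}
    for gene_id in genes:
        t0 = time.perf_counter()
        try:
            results[gene_id] = analyze_gene(gene_id, cohort, config, type_threshold=threshold)
        except (LabelingError, AnalyzabilityError, ValueError, KeyError) as err:
            results[gene_id] = GeneResult(
                gene_id=gene_id, report=None, non_impactful=None, model=None,
                labels=None, error=str(err),
            )
            ledger.errors[gene_id] = str(err)
        timings[gene_id] = time.perf_counter() - t0

    reports = [r.report for r in results.values() if r.report is not None]
    if len(reports) >= 3:
        categories = categorize_pattern(
            reports, alpha_f1=config.alpha_f1, alpha_gini=config.alpha_gini
        )
        ledger.categories = categories
        ledger.thresholds["category_f1"] = derive_threshold(
            [r.final_f1 for r in reports], alpha=config.alpha_f1, side="lower"
        ).to_dict()
        ledger.thresholds["category_gini"] = float(
            np.quantile([r.top_gini for r in reports], config.alpha_gini)
        )
    elif reports:
        warnings.warn("fewer than 3 analyzable genes; categories not assigned")

    for gene_id, result in results.items():
        if result.report is not None:
            ledger.genes[gene_id] = result.report.to_dict()
            ledger.genes[gene_id]["non_impactful"] = result.non_impactful.to_dict()
    ledger.config["_timings_note"] = "wall-clock timings logged separately"
    setattr(ledger, "_timings", timings)
    return results, ledger


def write_outputs(outdir: str | Path, results: dict[str, GeneResult], ledger: RunLedger) -> None:
    """Write ledger JSON, per-gene report JSONs, and ranked-feature TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ledger.json").write_text(ledger.to_json())
    timings = getattr(ledger, "_timings", {})
    with open(outdir / "timings.log", "w") as fh:
        for gene, dt in timings.items():
            fh.write(f"{gene}\t{dt:.3f}s\n")
    for gene_id, result in results.items():
        if result.report is None:
            continue
        (outdir / f"{gene_id}.report.json").write_text(
            json.dumps(result.report.to_dict(), indent=1, sort_keys=True, default=_json_default)
        )
        result.report.top_features.to_csv(outdir / f"{gene_id}.features.tsv", sep="\t")
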