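"""Per-gene choice of alteration setting and analysis mode.

The decision procedure:

1. adopt the CNA-augmented labeling only when it improves mean CV F1 by more
   than ``epsilon`` over SNV/INDEL-only labels;
2. derive a z-threshold on per-tumour-type F1 and select types above it
   (falling back to the single best type);
3. evaluate four modes — all samples, selected types, class-balanced
   down-samples of all types, balanced selected types — each as mean +/- SD
   of F1 over ``n_perm`` re-randomized repeats;
4. adopt a narrower mode only on a relative mean-F1 improvement above
   ``improvement`` (default 5%); otherwise keep the broadest mode;
5. iteratively prune selected tumour types whose own F1 drags well below the
   pooled F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CVResult, FoldError, RFParams, per_type_f1, run_cv

MODES = ("pan_cancer", "specific_types", "balanced_all", "balanced_specific")


class AnalyzabilityError(ValueError):
    """No feasible alteration setting or mode for this gene."""


@dataclass
class ThresholdSpec:
    """A z-score threshold derived from an empirical value population."""

    statistic: str
    alpha: float
    side: str  # upper | lower
    value: float
    population: list[float]
    degenerate: bool = False

    def recompute(self) -> float:
        values = np.asarray(self.population, dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        if sd < 1e-12:
            return mean
        z = float(stats.norm.ppf(1.0 - self.alpha))
        return mean + z * sd if self.side == "upper" else mean - z * sd

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "alpha": self.alpha,
            "side": self.side,
            "value": self.value,
            "degenerate": self.degenerate,
            "population": list(map(float, self.population)),
        }


def derive_threshold(values, alpha: float, side: str = "upper", statistic: str = "f1") -> ThresholdSpec:
    """Gaussian z-threshold (sample SD, ddof=1) on an empirical distribution."""
    values = [float(v) for v in values if np.isfinite(v)]
    if len(values) < 3:
        raise ValueError(f"need >= 3 values to derive a threshold, got {len(values)}")
    if side not in ("upper", "lower"):
        raise ValueError(f"side must be upper or lower, got {side!r}")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1))
    degenerate = sd < 1e-12
    if degenerate:
        value = float(arr.mean())
    else:
        z = float(stats.norm.ppf(1.0 - alpha))
        value = float(arr.mean() + z * sd) if side == "upper" else float(arr.mean() - z * sd)
    return ThresholdSpec(
        statistic=statistic, alpha=alpha, side=side, value=value,
        population=values, degenerate=degenerate,
    )


@dataclass
class ModeStats:
    f1_values: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.f1_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.f1_values, ddof=1)) if len(self.f1_values) > 1 else 0.0

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "f1_values": list(map(float, self.f1_values))}


@dataclass
class ModeDecision:
    gene_id: str
    setting: str
    mode: str
    selected_types: list[str]
    stats: dict[str, ModeStats]
    margins: dict[str, float]
    threshold: ThresholdSpec | None
    per_type: pd.DataFrame | None = None
    pruning_history: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return self.stats[self.mode].mean

    @property
    def balanced_small(self) -> bool:
        """Balanced mode restricted to at most two tumour types (overfit risk)."""
        return self.mode == "balanced_specific" and len(self.selected_types) <= 2

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "setting": self.setting,
            "mode": self.mode,
            "selected_types": list(self.selected_types),
            "stats": {m: s.to_dict() for m, s in self.stats.items()},
            "margins": self.margins,
            "threshold": self.threshold.to_dict() if self.threshold else None,
            "per_type": self.per_type.reset_index().to_dict("records")
            if self.per_type is not None
            else None,
            "pruning_history": self.pruning_history,
            "notes": self.notes,
        }


def choose_alteration_setting(
    gene_id: str,
    X: pd.DataFrame,
    labels_by_setting: dict,
    seed: int = 0,
    k: int = 5,
    params: RFParams = RFParams(),
    epsilon: float = 0.01,
    positive_class: str = "mutant",
) -> tuple[str, dict[str, float]]:
    """Compare mean CV F1 across alteration settings; adopt CNA labels only
    when they beat SNV-only labels by more than ``epsilon`` absolute F1.

    The comparison scores the *mutant* class by default: CNA labels help by
    enlarging a scarce mutant class, which the wild-type-positive F1 cannot
    register (it is inflated by the very imbalance CNA inclusion mitigates).

    Returns (chosen setting, mean F1 per feasible setting).
    """
    means: dict[str, float] = {}
    for setting, labels in labels_by_setting.items():
        samples = labels.analysis_samples
        y = labels.labels.loc[samples]
        try:
            means[setting] = run_cv(
                X.loc[samples], y, k=k, seed=seed, params=params,
                positive_class=positive_class,
            ).mean_f1
        except FoldError:
            continue
    if not means:
        raise AnalyzabilityError(f"{gene_id}: no feasible alteration setting")
    if "snv" not in means:
        # no SNV baseline — fall back to the best feasible setting
        return max(means, key=lambda s: (means[s], s)), means
    chosen = "snv"
    if "snv_cna" in means and means["snv_cna"] - means["snv"] > epsilon:
        chosen = "snv_cna"
    return chosen, means


def select_tumour_types(ptf1: pd.DataFrame, threshold: ThresholdSpec) -> list[str]:
    """Types with F1 above the threshold; else the single best type.

    Ties break by larger sample count, then lexicographic type name.
    """
    if ptf1.empty:
        raise ValueError("per-type F1 table is empty")
    usable = ptf1[ptf1["f1"].notna()]
    if usable.empty:
        raise ValueError("no tumour type with both classes present")
    above = usable.index[usable["f1"] > threshold.value]
    if len(above):
        return sorted(above)
    best = usable.sort_values(["f1", "n"], ascending=False)
    top_f1 = best["f1"].iloc[0]
    contenders = best[best["f1"] == top_f1].sort_values(
        ["n"], ascending=False, kind="stable"
    )
    top_n = contenders["n"].iloc[0]
    return [sorted(contenders.index[contenders["n"] == top_n])[0]]


def balance_types(
    y: pd.Series,
    metadata: pd.DataFrame,
    types: list[str],
    seed: int = 0,
) -> pd.Index:
    """Down-sample the majority class to the minority size within each type.

    Types holding a single class are dropped with a warning note (returned
    index simply omits them).  Sampling is without replacement.
    """
    rng = np.random.default_rng(seed)
    keep: list = []
    sample_types = metadata.loc[y.index, "tumour_type"]
    for t in types:
        members = y.index[sample_types == t]
        y_t = y.loc[members]
        mut = list(y_t.index[y_t == "mutant"])
        wt = list(y_t.index[y_t == "wildtype"])
        if not mut or not wt:
            import warnings

            warnings.warn(f"type {t} has a single class; dropped from balanced set")
            continue
        size = min(len(mut), len(wt))
        if len(mut) > size:
            mut = list(rng.choice(mut, size=size, replace=False))
        if len(wt) > size:
            wt = list(rng.choice(wt, size=size, replace=False))
        keep.extend(sorted(mut) if len(mut) == size else mut)
        keep.extend(sorted(wt) if len(wt) == size else wt)
    return pd.Index([s for s in y.index if s in set(keep)])


def _repeat_cv(
    X: pd.DataFrame,
    y: pd.Series,
    index: pd.Index | None,
    n_perm: int,
    seed: int,
    k: int,
    params: RFParams,
    metadata: pd.DataFrame | None = None,
    balance: list[str] | None = None,
) -> ModeStats | None:
    """Mean/SD of CV F1 over n_perm repeats; folds (and down-samples when
    ``balance`` is given) are re-randomized each repeat."""
    values = []
    for i in range(n_perm):
        idx = index
        if balance is not None:
            idx = balance_types(y if index is None else y.loc[index], metadata, balance,
                                seed=seed + 7919 * (i + 1))
        X_i = X if idx is None else X.loc[idx]
        y_i = y if idx is None else y.loc[idx]
        try:
            values.append(run_cv(X_i, y_i, k=k, seed=seed + i, params=params).mean_f1)
        except FoldError:
            return None
    return ModeStats(f1_values=values)


def compare_modes(
    gene_id: str,
    X: pd.DataFrame,
    y: pd.Series,
    metadata: pd.DataFrame,
    n_perm: int = 30,
    seed: int = 0,
    k: int = 5,
    params: RFParams = RFParams(),
    threshold: ThresholdSpec | None = None,
    select_alpha: float = 0.1,
    improvement: float = 0.05,
    relative: bool = True,
) -> ModeDecision:
    """Evaluate the four analysis modes and pick one.

    ``y`` holds mutant/wildtype labels for the chosen alteration setting
    (excluded samples already removed).  A narrower mode is adopted only when
    its mean F1 beats the incumbent by more than ``improvement`` (relative by
    default).  ``threshold`` for tumour-type selection may be supplied (e.g.
    pooled across genes); otherwise it is derived from this gene's own
    per-type F1 values.
    """
    notes: list[str] = []
    stats_by_mode: dict[str, ModeStats] = {}

    # pan-cancer repeats double as the source of per-type F1 tables
    pan_values, tables = [], []
    try:
        for i in range(n_perm):
            cv = run_cv(X, y, k=k, seed=seed + i, params=params)
            pan_values.append(cv.mean_f1)
            tables.append(per_type_f1(cv, metadata))
    except FoldError as err:
        raise AnalyzabilityError(f"{gene_id}: pan-cancer CV infeasible: {err}") from err
    pan = ModeStats(f1_values=pan_values)
    stats_by_mode["pan_cancer"] = pan

    ptf1 = tables[0].copy()
    ptf1["f1"] = pd.concat([t["f1"] for t in tables], axis=1).mean(axis=1)

    if threshold is None:
        pool = [v for v in ptf1["f1"] if np.isfinite(v)]
        if len(pool) >= 3:
            threshold = derive_threshold(pool, alpha=select_alpha, side="upper")
        else:
            threshold = ThresholdSpec("f1", select_alpha, "upper",
                                      float(np.nanmax(ptf1["f1"])) - 1e-9, pool, degenerate=True)
            notes.append("fewer than 3 per-type F1 values; argmax threshold used")
    selected = select_tumour_types(ptf1, threshold)

    sample_types = metadata.loc[y.index, "tumour_type"]
    sel_index = y.index[sample_types.isin(selected)]
    all_types = sorted(sample_types.unique())

    spec = _repeat_cv(X, y, sel_index, n_perm, seed, k, params)
    if spec is not None:
        stats_by_mode["specific_types"] = spec
    else:
        notes.append("specific_types infeasible; excluded from comparison")

    bal_all = _repeat_cv(X, y, None, n_perm, seed, k, params, metadata, balance=all_types)
    if bal_all is not None:
        stats_by_mode["balanced_all"] = bal_all
    else:
        notes.append("balanced_all infeasible; excluded from comparison")

    bal_spec = _repeat_cv(X, y, None, n_perm, seed, k, params, metadata, balance=selected)
    if bal_spec is not None:
        stats_by_mode["balanced_specific"] = bal_spec
    else:
        notes.append("balanced_specific infeasible; excluded from comparison")

    def margin(candidate: float, incumbent: float) -> float:
        return (candidate - incumbent) / incumbent if relative else candidate - incumbent

    margins: dict[str, float] = {}
    mode = "pan_cancer"
    if "specific_types" in stats_by_mode:
        margins["specific_vs_pan"] = margin(stats_by_mode["specific_types"].mean, pan.mean)
        if margins["specific_vs_pan"] > improvement:
            mode = "specific_types"
    if "balanced_specific" in stats_by_mode:
        incumbent = stats_by_mode[mode].mean
        margins["balanced_specific_vs_best"] = margin(
            stats_by_mode["balanced_specific"].mean, incumbent
        )
        if margins["balanced_specific_vs_best"] > improvement:
            mode = "balanced_specific"
    if "balanced_all" in stats_by_mode:
        margins["balanced_all_vs_pan"] = margin(stats_by_mode["balanced_all"].mean, pan.mean)

    if mode == "pan_cancer":
        chosen_types = all_types
    else:
        chosen_types = selected
    return ModeDecision(
        gene_id=gene_id,
        setting="",
        mode=mode,
        selected_types=chosen_types,
        stats=stats_by_mode,
        margins=margins,
        threshold=threshold,
        per_type=ptf1,
        notes=notes,
    )


def analysis_index(
    decision: ModeDecision, y: pd.Series, metadata: pd.DataFrame, seed: int = 0
) -> pd.Index:
    """Sample index implied by a mode decision (restriction + balancing)."""
    sample_types = metadata.loc[y.index, "tumour_type"]
    if decision.mode == "pan_cancer":
        idx = y.index
    elif decision.mode == "specific_types":
        idx = y.index[sample_types.isin(decision.selected_types)]
    elif decision.mode == "balanced_all":
        idx = balance_types(y, metadata, sorted(sample_types.unique()), seed=seed)
    else:
        idx = balance_types(y, metadata, decision.selected_types, seed=seed)
    return idx


def prune_types(
    decision: ModeDecision,
    X: pd.DataFrame,
    y: pd.Series,
    metadata: pd.DataFrame,
    seed: int = 0,
    k: int = 5,
    params: RFParams = RFParams(),
    delta: float = 0.05,
    n_perm: int = 5,
) -> ModeDecision:
    """Iteratively drop the worst selected type while its F1 < pooled - delta.

    Stops at a single type; every step is appended to ``pruning_history``.
    Only meaningful for type-restricted modes with >= 2 selected types.
    """
    if decision.mode in ("pan_cancer", "balanced_all") or len(decision.selected_types) < 2:
        return decision
    balance = decision.mode == "balanced_specific"
    types = list(decision.selected_types)
    sample_types = metadata.loc[y.index, "tumour_type"]
    step = 0
    while len(types) >= 2:
        idx = y.index[sample_types.isin(types)]
        pooled_values, tables = [], []
        for i in range(n_perm):
            sub_idx = idx
            if balance:
                sub_idx = balance_types(y.loc[idx], metadata, types, seed=seed + 7919 * (i + 1))
            try:
                cv = run_cv(X.loc[sub_idx], y.loc[sub_idx], k=k, seed=seed + i, params=params)
            except FoldError:
                return decision
            pooled_values.append(cv.mean_f1)
            tables.append(per_type_f1(cv, metadata))
        pooled = float(np.mean(pooled_values))
        by_type = pd.concat([t["f1"] for t in tables], axis=1).mean(axis=1)
        by_type = by_type[by_type.index.isin(types)].dropna()
        if by_type.empty:
            break
        worst = by_type.idxmin()
        record = {
            "step": step,
            "types": list(types),
            "pooled_f1": pooled,
            "per_type_f1": {t: float(v) for t, v in by_type.items()},
            "worst": worst,
            "removed": bool(by_type[worst] < pooled - delta),
        }
        decision.pruning_history.append(record)
        if not record["removed"]:
            break
        types.remove(worst)
        step += 1
    decision.selected_types = sorted(types)
    return decision
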