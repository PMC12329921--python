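"""Variant impact classification and per-gene sample labeling.

For a driver gene and an *alteration setting* (which alteration types count
toward mutant status), every sample in the cohort is assigned exactly one of
three labels:

``mutant``
    carries at least one qualifying alteration: an impactful SNV/INDEL, a
    qualifying (by default high-level) CNA when the setting includes ``cna``,
    or any SV when the setting includes ``sv``;
``wildtype``
    carries no alteration record at all for the gene;
``excluded_non_impactful``
    carries only non-impactful SNVs/INDELs — or only alteration types the
    setting ignores / CNA magnitudes that do not qualify.  These samples are
    held out of training and later re-examined by prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

SETTINGS = ("snv", "snv_cna", "snv_sv", "snv_cna_sv")
LABELS = ("mutant", "wildtype", "excluded_non_impactful")

IMPACTFUL = "impactful"
NON_IMPACTFUL = "non_impactful"


class VocabularyError(KeyError):
    """An unknown consequence term (never silently dropped)."""


class LabelingError(ValueError):
    """The gene is not analyzable under the requested setting."""


def load_vocabulary(path: str | Path | None = None) -> dict[str, str]:
    """Load a consequence->impact mapping; defaults to the packaged YAML."""
    if path is None:
        source = resources.files("txpattern.data").joinpath("consequence_impact.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    vocab: dict[str, str] = {}
    for impact in (IMPACTFUL, NON_IMPACTFUL):
        for term in raw.get(impact, []):
            vocab[str(term).lower()] = impact
    return vocab


_DEFAULT_VOCAB: dict[str, str] | None = None


def _default_vocab() -> dict[str, str]:
    global _DEFAULT_VOCAB
    if _DEFAULT_VOCAB is None:
        _DEFAULT_VOCAB = load_vocabulary()
    return _DEFAULT_VOCAB


def classify_consequence(term: str, vocab: dict[str, str] | None = None) -> str:
    """Map a consequence term to ``impactful`` / ``non_impactful``."""
    vocab = vocab if vocab is not None else _default_vocab()
    try:
        return vocab[str(term).lower()]
    except KeyError:
        raise VocabularyError(
            f"unknown consequence term {term!r}; add it to the vocabulary mapping"
        ) from None


@dataclass
class LabelSet:
    """Per-sample class labels for one gene under one alteration setting."""

    gene_id: str
    setting: str
    labels: pd.Series  # index = sample_id, values in LABELS

    @property
    def mutant(self) -> pd.Index:
        return self.labels.index[self.labels == "mutant"]

    @property
    def wildtype(self) -> pd.Index:
        return self.labels.index[self.labels == "wildtype"]

    @property
    def excluded(self) -> pd.Index:
        return self.labels.index[self.labels == "excluded_non_impactful"]

    @property
    def analysis_samples(self) -> pd.Index:
        """Samples entering training: mutant + wildtype."""
        return self.labels.index[self.labels != "excluded_non_impactful"]

    def counts(self) -> dict[str, int]:
        return {label: int((self.labels == label).sum()) for label in LABELS}

    def ratio(self) -> float:
        """mutant / wildtype sample-count ratio."""
        n_wt = len(self.wildtype)
        return len(self.mutant) / n_wt if n_wt else float("inf")


def qualifying_cna(copy_number: int, high_level_only: bool = True) -> bool:
    """Whether a copy-number call makes a sample mutant (cn==2 never does)."""
    if copy_number == 2:
        return False
    if high_level_only:
        return copy_number == 0 or copy_number >= 4
    return True


def build_labels(
    gene_id: str,
    setting: str,
    variants: pd.DataFrame,
    cna: pd.DataFrame,
    sv: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    vocab: dict[str, str] | None = None,
    high_level_only: bool = True,
    origins: tuple[str, ...] = ("somatic", "germline"),
    allow_empty: bool = False,
) -> LabelSet:
    """Partition every metadata sample into mutant / wildtype / excluded.

    Samples whose only alteration is of a type the setting ignores (or a CNA
    that does not qualify) are excluded rather than wildtype, keeping the
    wildtype class clean.  Multiple variants per sample: worst impact wins.
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}; expected one of {SETTINGS}")
    use_cna = "cna" in setting.split("_")
    use_sv = "sv" in setting.split("_")

    gene_variants = variants[
        (variants["gene_id"] == gene_id) & (variants["origin"].isin(origins))
    ]
    impact = gene_variants["consequence"].map(lambda t: classify_consequence(t, vocab))
    impactful_snv = set(gene_variants.loc[impact == IMPACTFUL, "sample_id"])
    nonimpactful_snv = set(gene_variants.loc[impact == NON_IMPACTFUL, "sample_id"])

    gene_cna = cna[(cna["gene_id"] == gene_id) & (cna["copy_number"] != 2)]
    qualifying = set(
        gene_cna.loc[
            gene_cna["copy_number"].map(lambda c: qualifying_cna(int(c), high_level_only)),
            "sample_id",
        ]
    )
    any_cna = set(gene_cna["sample_id"])
    any_sv = set(sv.loc[sv["gene_id"] == gene_id, "sample_id"])

    labels = {}
    for sample in metadata.index:
        mutant = sample in impactful_snv
        if use_cna and sample in qualifying:
            mutant = True
        if use_sv and sample in any_sv:
            mutant = True
        if mutant:
            labels[sample] = "mutant"
        elif sample in nonimpactful_snv or sample in any_cna or sample in any_sv:
            labels[sample] = "excluded_non_impactful"
        else:
            labels[sample] = "wildtype"

    series = pd.Series(labels, name=gene_id).reindex(metadata.index)
    result = LabelSet(gene_id=gene_id, setting=setting, labels=series)
    if not allow_empty and (len(result.mutant) == 0 or len(result.wildtype) == 0):
        raise LabelingError(
            f"{gene_id} under {setting}: mutant={len(result.mutant)} "
            f"wildtype={len(result.wildtype)}; gene not analyzable"
        )
    return result


def labels_for_settings(
    gene_id: str,
    variants: pd.DataFrame,
    cna: pd.DataFrame,
    sv: pd.DataFrame,
    metadata: pd.DataFrame,
    settings: tuple[str, ...] = ("snv", "snv_cna"),
    **kwargs,
) -> dict[str, LabelSet]:
    """Build label sets for several settings, skipping unanalyzable ones."""
    out: dict[str, LabelSet] = {}
    for setting in settings:
        try:
            out[setting] = build_labels(gene_id, setting, variants, cna, sv, metadata, **kwargs)
        except LabelingError:
            continue
    if not out:
        raise LabelingError(f"{gene_id}: no feasible alteration setting")
    return out
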