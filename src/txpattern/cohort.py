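"""Core cohort containers and tab-separated file round-tripping.

A *cohort* bundles everything one analysis run consumes: a TPM expression
matrix with genomic annotation, sample metadata, and per-sample alteration
tables (SNV/INDEL, gene-level copy number, structural variants).  All tables
are plain pandas DataFrames so the rest of the package can stay thin.

On-disk layout (one directory, all tab-separated, uncompressed)::

    expression.tsv   rows = transcripts (gene_id, chrom, start, end, coding,
                     then one TPM column per sample)
    metadata.tsv     sample_id, cohort, tumour_type, site_class
    variants.tsv     sample_id, gene_id, consequence, origin
    cna.tsv          sample_id, gene_id, copy_number
    sv.tsv           sample_id, gene_id, sv_type
    truth.json       optional simulation ground truth
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ANNOTATION_COLS = ["gene_id", "chrom", "start", "end", "coding"]
METADATA_COLS = ["sample_id", "cohort", "tumour_type", "site_class"]
VARIANT_COLS = ["sample_id", "gene_id", "consequence", "origin"]
CNA_COLS = ["sample_id", "gene_id", "copy_number"]
SV_COLS = ["sample_id", "gene_id", "sv_type"]

SITE_CLASSES = ("primary", "metastatic")
ORIGINS = ("somatic", "germline")


class CohortParseError(ValueError):
    """Raised when a cohort file violates its schema."""


@dataclass
class ExpressionMatrix:
    """Samples x transcripts TPM matrix plus transcript genomic annotation.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per transcript, TPM.
    annotation
        DataFrame indexed by transcript/gene id with columns
        ``chrom, start, end, coding``; column order matches ``values``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.annotation.index):
            raise CohortParseError("annotation rows must match expression columns")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise CohortParseError(f"duplicate sample id: {dup}")
        if self.annotation.index.has_duplicates:
            dup = self.annotation.index[self.annotation.index.duplicated()][0]
            raise CohortParseError(f"duplicate transcript id: {dup}")
        if (self.values.to_numpy() < 0).any():
            bad = self.values.columns[(self.values.to_numpy() < 0).any(axis=0)][0]
            raise CohortParseError(f"negative TPM value in transcript {bad}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.columns

    def log_values(self) -> pd.DataFrame:
        """log2(TPM + 1), the classifier feature space."""
        return np.log2(self.values + 1.0)

    def locus(self, gene_id: str) -> tuple[str, int, int]:
        if gene_id not in self.annotation.index:
            raise KeyError(f"no annotation for {gene_id}")
        row = self.annotation.loc[gene_id]
        return str(row["chrom"]), int(row["start"]), int(row["end"])

    def equals(self, other: "ExpressionMatrix") -> bool:
        # atol covers the 6-decimal TPM text format
        return bool(
            np.allclose(self.values.to_numpy(), other.values.to_numpy(), atol=1e-6)
            and self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and self.annotation.equals(other.annotation)
        )


@dataclass
class Cohort:
    expression: ExpressionMatrix
    metadata: pd.DataFrame  # indexed by sample_id
    variants: pd.DataFrame
    cna: pd.DataFrame
    sv: pd.DataFrame
    truth: "object | None" = None  # SyntheticTruth when simulated

    def __post_init__(self) -> None:
        if self.metadata.index.has_duplicates:
            dup = self.metadata.index[self.metadata.index.duplicated()][0]
            raise CohortParseError(f"duplicate sample id in metadata: {dup}")
        missing = self.expression.sample_ids.difference(self.metadata.index)
        if len(missing):
            raise CohortParseError(f"expression sample missing from metadata: {missing[0]}")
        for name, table in (("variants", self.variants), ("cna", self.cna), ("sv", self.sv)):
            unknown = set(table["sample_id"]) - set(self.metadata.index)
            if unknown:
                raise CohortParseError(
                    f"{name} references unknown sample: {sorted(unknown)[0]}"
                )

    @property
    def tumour_types(self) -> list[str]:
        return sorted(self.metadata["tumour_type"].unique())


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing column(s) {missing}")


def write_cohort(outdir: str | Path, cohort: Cohort) -> dict[str, Path]:
    """Write every table of ``cohort`` under ``outdir``; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    expr = cohort.expression
    table = expr.annotation.copy()
    table.insert(0, "gene_id", table.index)
    table["coding"] = table["coding"].astype(int)
    table = pd.concat([table, expr.values.T.set_axis(table.index)], axis=1)
    paths["expression"] = outdir / "expression.tsv"
    table.to_csv(paths["expression"], sep="\t", index=False, float_format="%.6f")

    meta = cohort.metadata.copy()
    meta.insert(0, "sample_id", meta.index)
    paths["metadata"] = outdir / "metadata.tsv"
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    for name, table_, cols in (
        ("variants", cohort.variants, VARIANT_COLS),
        ("cna", cohort.cna, CNA_COLS),
        ("sv", cohort.sv, SV_COLS),
    ):
        paths[name] = outdir / f"{name}.tsv"
        table_.reindex(columns=cols).to_csv(paths[name], sep="\t", index=False)

    if cohort.truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(cohort.truth.to_dict(), indent=1, sort_keys=True))
    return paths


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Raises :class:`CohortParseError` on malformed headers, duplicate sample
    ids or negative TPM values, naming the offending row or column.
    """
    from .synthetic import SyntheticTruth  # local import to avoid a cycle

    indir = Path(indir)
    expr_path = indir / "expression.tsv"
    # keep_default_na: gene ids like "NULL" or "NA" are legitimate names
    raw = pd.read_csv(expr_path, sep="\t", keep_default_na=False, na_values=[])
    _require_columns(raw, ANNOTATION_COLS, expr_path)
    if raw["gene_id"].duplicated().any():
        dup = raw.loc[raw["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise CohortParseError(f"{expr_path}: duplicate transcript id {dup}")
    annotation = raw[ANNOTATION_COLS].set_index("gene_id")
    annotation["coding"] = annotation["coding"].astype(bool)
    sample_cols = [c for c in raw.columns if c not in ANNOTATION_COLS]
    values = raw[sample_cols].T
    values.columns = raw["gene_id"].to_numpy()
    values.index.name = "sample_id"
    values = values.astype(float)
    expression = ExpressionMatrix(values=values, annotation=annotation)

    meta_path = indir / "metadata.tsv"
    meta = pd.read_csv(meta_path, sep="\t", keep_default_na=False, na_values=[])
    _require_columns(meta, METADATA_COLS, meta_path)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CohortParseError(f"{meta_path}: duplicate sample id {dup}")
    bad_site = ~meta["site_class"].isin(SITE_CLASSES)
    if bad_site.any():
        raise CohortParseError(
            f"{meta_path}: invalid site_class {meta.loc[bad_site, 'site_class'].iloc[0]!r}"
        )
    metadata = meta.set_index("sample_id")

    def _read_table(name: str, cols: list[str]) -> pd.DataFrame:
        path = indir / f"{name}.tsv"
        table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        _require_columns(table, cols, path)
        return table.reindex(columns=cols)

    variants = _read_table("variants", VARIANT_COLS)
    bad_origin = ~variants["origin"].isin(ORIGINS)
    if bad_origin.any():
        raise CohortParseError(
            f"variants.tsv: invalid origin {variants.loc[bad_origin, 'origin'].iloc[0]!r}"
        )
    cna = _read_table("cna", CNA_COLS)
    cna["copy_number"] = cna["copy_number"].astype(int)
    if (cna["copy_number"] < 0).any():
        raise CohortParseError("cna.tsv: negative copy number")
    sv = _read_table("sv", SV_COLS)

    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        truth = SyntheticTruth.from_dict(json.loads(truth_path.read_text()))

    return Cohort(
        expression=expression, metadata=metadata, variants=variants, cna=cna, sv=sv, truth=truth
    )


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    """Loose equality used for round-trip checks (float TPM to 1e-6)."""
    if not a.expression.equals(b.expression):
        return False
    if not a.metadata.equals(b.metadata):
        return False
    for ta, tb in ((a.variants, b.variants), (a.cna, b.cna), (a.sv, b.sv)):
        try:
            pd.testing.assert_frame_equal(
                ta.reset_index(drop=True), tb.reset_index(drop=True), check_dtype=False
            )
        except AssertionError:
            return False
    return True
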