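"""Synthetic tumour-cohort generator.

Emits expression, variant, copy-number, SV and metadata tables with the
statistical structure the downstream analysis assumes:

* per-tumour-type baseline expression offsets,
* driver-conditional signature shifts (pan-cancer or restricted to a subset
  of tumour types),
* cis dosage of chromosomal neighbours around copy-number events,
* configurable class imbalance per tumour type,
* "non-impactful" variant carriers, a fraction of which are cryptically
  impactful (they carry the mutant expression shift).

Expression is additive in log2(TPM+1): for sample *s* and transcript *g*,

    x[s, g] = baseline[g] + type_offset[type(s), g]
              + signature shift (mutant/cryptic samples, eligible types)
              + cis_dosage_coef * (copy_number - 2)   (in-window transcripts)
              + Normal(0, noise_sd)

and TPM = max(2**x - 1, 0).  One master seed; each table draws from a child
generator at a fixed offset, so adding a table never perturbs the others.

Gene-level "biology" (transcript layout, coding flags, baselines, per-type
offsets, signature gene identity and directions) is seeded by a separate
``biology_seed`` so that two cohorts generated from the same config with
different master seeds share their biology: models trained on one transfer
to the other, as for two real cohorts drawn from the same population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, ExpressionMatrix

IMPACTFUL_TERMS = ("stop_gained", "missense", "frameshift", "splice_site")
NON_IMPACTFUL_TERMS = ("synonymous", "intron", "3_utr", "5_utr")
HIGH_LEVEL_COPY_NUMBERS = (0, 4)

_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_GENE_SPACING = 200_000  # bp between transcript starts
_GENE_LENGTH = 1_000

# fixed child-seed offsets, one per independent random stream;
# "layout"/"baseline"/"offsets"/"signature" draw from biology_seed,
# "noise"/"drivers"/... from the per-cohort master seed
_STREAMS = {
    "layout": 11,
    "baseline": 23,
    "offsets": 37,
    "noise": 41,
    "drivers": 53,
    "signature": 67,
    "site": 71,
}


class ConfigError(ValueError):
    """Raised for an internally inconsistent cohort configuration."""


@dataclass
class DriverSpec:
    """One simulated driver gene and the transcriptional pattern it plants."""

    gene_id: str
    pattern_kind: str  # pan_cancer | tumour_specific | null
    gene_locus: tuple[str, int, int] | None = None
    affected_types: tuple[str, ...] = ()
    signature_genes: "int | tuple[str, ...]" = 20
    effect_size: float = 1.5
    direction_mix: float = 0.5  # fraction of signature genes shifted up
    mutant_fraction_per_type: "float | dict[str, float]" = 0.3
    cna_fraction: float = 0.0
    sv_fraction: float = 0.0
    cis_window_mb: float = 6.0
    cis_dosage_coef: float = 0.0
    nonimpactful_fraction: float = 0.1
    cryptic_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern_kind not in ("pan_cancer", "tumour_specific", "null"):
            raise ConfigError(f"{self.gene_id}: unknown pattern_kind {self.pattern_kind!r}")
        if self.pattern_kind == "null" and self.effect_size != 0:
            raise ConfigError(f"{self.gene_id}: pattern_kind=null requires effect_size=0")
        if self.pattern_kind == "tumour_specific" and not self.affected_types:
            raise ConfigError(f"{self.gene_id}: tumour_specific requires affected_types")
        for name in (
            "direction_mix",
            "cna_fraction",
            "sv_fraction",
            "nonimpactful_fraction",
            "cryptic_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{self.gene_id}: {name}={value} outside [0, 1]")
        fracs = self.mutant_fraction_per_type
        values = fracs.values() if isinstance(fracs, dict) else [fracs]
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ConfigError(f"{self.gene_id}: mutant fraction outside [0, 1]")

    def mutant_fraction(self, tumour_type: str) -> float:
        if isinstance(self.mutant_fraction_per_type, dict):
            return float(self.mutant_fraction_per_type.get(tumour_type, 0.0))
        return float(self.mutant_fraction_per_type)


@dataclass
class CohortConfig:
    n_samples: int = 600
    tumour_types: tuple[tuple[str, float], ...] = (
        ("TTA", 0.25),
        ("TTB", 0.25),
        ("TTC", 0.25),
        ("TTD", 0.25),
    )
    n_genes: int = 2000
    n_coding: int = 600
    drivers: tuple[DriverSpec, ...] = ()
    noise_sd: float = 1.0
    baseline_sd: float = 0.5
    cohort_label: str = "SIM"
    seed: int = 0
    biology_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_coding) <= 0:
            raise ConfigError("all counts must be positive")
        if self.n_coding > self.n_genes:
            raise ConfigError("n_coding exceeds n_genes")
        total = sum(p for _, p in self.tumour_types)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"tumour type proportions sum to {total}, not 1")
        names = [t for t, _ in self.tumour_types]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate tumour type name")
        for spec in self.drivers:
            unknown = set(spec.affected_types) - set(names)
            if unknown:
                raise ConfigError(f"{spec.gene_id}: unknown affected type {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        drivers = tuple(
            DriverSpec(
                **{
                    **d,
                    "gene_locus": tuple(d["gene_locus"]) if d.get("gene_locus") else None,
                    "affected_types": tuple(d.get("affected_types", ())),
                    "signature_genes": (
                        tuple(d["signature_genes"])
                        if isinstance(d.get("signature_genes"), (list, tuple))
                        else d.get("signature_genes", 20)
                    ),
                }
            )
            for d in raw.pop("drivers", [])
        )
        raw["tumour_types"] = tuple((t["name"], float(t["proportion"])) for t in raw["tumour_types"])
        return cls(drivers=drivers, **raw)


@dataclass
class SyntheticTruth:
    """Ground truth for one generated cohort.

    ``drivers`` maps driver gene -> dict with keys ``pattern_kind``,
    ``affected_types``, ``signature_genes``, ``signature_directions``,
    ``cis_genes``.  ``sample_labels`` maps driver gene -> sample ->
    {"label": mutant|wildtype|excluded_non_impactful, "cryptic": bool}.
    """

    drivers: dict = field(default_factory=dict)
    sample_labels: dict = field(default_factory=dict)

    def labels(self, gene: str) -> pd.Series:
        rows = self.sample_labels[gene]
        return pd.Series({s: r["label"] for s, r in rows.items()}, name=gene)

    def cryptic_samples(self, gene: str) -> list[str]:
        return [s for s, r in self.sample_labels[gene].items() if r["cryptic"]]

    def class_counts(self, gene: str) -> dict[str, int]:
        return self.labels(gene).value_counts().to_dict()

    def to_dict(self) -> dict:
        return {"drivers": self.drivers, "sample_labels": self.sample_labels}

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticTruth":
        return cls(drivers=raw["drivers"], sample_labels=raw["sample_labels"])


def _child_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream], index])


def _type_counts(config: CohortConfig) -> dict[str, int]:
    # largest-remainder apportionment so counts sum exactly to n_samples
    quotas = {t: config.n_samples * p for t, p in config.tumour_types}
    counts = {t: int(np.floor(q)) for t, q in quotas.items()}
    short = config.n_samples - sum(counts.values())
    order = sorted(quotas, key=lambda t: (-(quotas[t] - counts[t]), t))
    for t in order[:short]:
        counts[t] += 1
    return counts


def _build_annotation(config: CohortConfig) -> pd.DataFrame:
    rng = _child_rng(config.biology_seed, "layout")
    per_chrom = np.full(len(_CHROMS), config.n_genes // len(_CHROMS))
    per_chrom[: config.n_genes % len(_CHROMS)] += 1
    rows = []
    gene_no = 0
    for chrom, count in zip(_CHROMS, per_chrom):
        for j in range(count):
            start = 1 + j * _GENE_SPACING
            rows.append((f"T{gene_no:05d}", chrom, start, start + _GENE_LENGTH - 1))
            gene_no += 1
    ann = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]).set_index("gene_id")
    coding = np.zeros(config.n_genes, dtype=bool)
    coding[rng.choice(config.n_genes, size=config.n_coding, replace=False)] = True
    ann["coding"] = coding
    return ann


def _driver_locus(spec: DriverSpec, index: int, ann: pd.DataFrame) -> tuple[str, int, int]:
    if spec.gene_locus is not None:
        return spec.gene_locus
    chrom = _CHROMS[index % len(_CHROMS)]
    on_chrom = ann[ann["chrom"] == chrom]
    mid = (on_chrom["start"].min() + on_chrom["end"].max()) // 2
    return chrom, int(mid), int(mid + _GENE_LENGTH - 1)


def _in_window(ann: pd.DataFrame, locus: tuple[str, int, int], half_width_bp: float) -> pd.Index:
    chrom, start, end = locus
    centre = (start + end) / 2.0
    mid = (ann["start"] + ann["end"]) / 2.0
    return ann.index[(ann["chrom"] == chrom) & ((mid - centre).abs() <= half_width_bp)]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    ann = _build_annotation(config)

    # driver transcripts appended to the feature space at their loci
    driver_rows = []
    loci: dict[str, tuple[str, int, int]] = {}
    for i, spec in enumerate(config.drivers):
        if spec.gene_id in ann.index:
            raise ConfigError(f"driver id {spec.gene_id} collides with a transcript id")
        locus = _driver_locus(spec, i, ann)
        loci[spec.gene_id] = locus
        driver_rows.append((spec.gene_id, *locus, True))
    if driver_rows:
        extra = pd.DataFrame(
            driver_rows, columns=["gene_id", "chrom", "start", "end", "coding"]
        ).set_index("gene_id")
        ann = pd.concat([ann, extra])

    counts = _type_counts(config)
    sample_ids, sample_types = [], []
    n = 0
    for t, _ in config.tumour_types:
        for _ in range(counts[t]):
            sample_ids.append(f"S{n:04d}")
            sample_types.append(t)
            n += 1
    site_rng = _child_rng(config.seed, "site")  # 30% metastatic
    metadata = pd.DataFrame(
        {
            "cohort": config.cohort_label,
            "tumour_type": sample_types,
            "site_class": np.where(
                site_rng.random(len(sample_ids)) < 0.3, "metastatic", "primary"
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    p = len(ann)
    baseline = _child_rng(config.biology_seed, "baseline").normal(4.0, 1.5, size=p)
    type_offsets = {
        t: _child_rng(config.biology_seed, "offsets", i).normal(0.0, config.baseline_sd, size=p)
        for i, (t, _) in enumerate(config.tumour_types)
    }
    x = np.empty((len(sample_ids), p))
    for i, t in enumerate(sample_types):
        x[i] = baseline + type_offsets[t]
    x += _child_rng(config.seed, "noise").normal(0.0, config.noise_sd, size=x.shape)

    col_index = {g: j for j, g in enumerate(ann.index)}
    row_index = {s: i for i, s in enumerate(sample_ids)}
    type_of = dict(zip(sample_ids, sample_types))

    variant_rows, cna_rows, sv_rows = [], [], []
    truth = SyntheticTruth()
    used_signature: set[str] = set()

    for d_idx, spec in enumerate(config.drivers):
        rng = _child_rng(config.biology_seed, "signature", d_idx)
        locus = loci[spec.gene_id]
        window = _in_window(ann, locus, spec.cis_window_mb * 1e6 / 2.0)

        if isinstance(spec.signature_genes, int):
            pool = [
                g
                for g in ann.index
                if g not in window
                and g not in used_signature
                and g not in loci
                and ann.loc[g, "coding"]
            ]
            if len(pool) < spec.signature_genes:
                raise ConfigError(f"{spec.gene_id}: not enough off-window coding transcripts")
            signature = list(rng.choice(pool, size=spec.signature_genes, replace=False))
        else:
            signature = list(spec.signature_genes)
            inside = set(signature) & set(window)
            if inside:
                raise ConfigError(
                    f"{spec.gene_id}: signature genes inside cis window: {sorted(inside)}"
                )
            missing = set(signature) - set(ann.index)
            if missing:
                raise ConfigError(f"{spec.gene_id}: unknown signature genes {sorted(missing)}")
        used_signature.update(signature)

        n_up = int(round(spec.direction_mix * len(signature)))
        order = rng.permutation(len(signature))
        directions = {signature[j]: (+1 if k < n_up else -1) for k, j in enumerate(order)}

        shifted_types = (
            set(spec.affected_types)
            if spec.pattern_kind == "tumour_specific"
            else {t for t, _ in config.tumour_types}
        )

        labels: dict[str, dict] = {
            s: {"label": "wildtype", "cryptic": False} for s in sample_ids
        }
        for t_idx, (t, _) in enumerate(config.tumour_types):
            members = [s for s in sample_ids if type_of[s] == t]
            rng_t = np.random.default_rng([config.seed, _STREAMS["drivers"], d_idx, t_idx])
            n_mut = int(round(spec.mutant_fraction(t) * len(members)))
            picked = list(rng_t.choice(members, size=n_mut, replace=False))
            n_cna = int(round(spec.cna_fraction * n_mut))
            n_sv = int(round(spec.sv_fraction * (n_mut - n_cna)))
            cna_samples = picked[:n_cna]
            sv_samples = picked[n_cna : n_cna + n_sv]
            snv_samples = picked[n_cna + n_sv :]

            for s in snv_samples:
                term = IMPACTFUL_TERMS[rng_t.integers(len(IMPACTFUL_TERMS))]
                origin = "germline" if rng_t.random() < 0.1 else "somatic"
                variant_rows.append((s, spec.gene_id, term, origin))
            for s in cna_samples:
                cn = int(rng_t.choice(HIGH_LEVEL_COPY_NUMBERS))
                cna_rows.append((s, spec.gene_id, cn))
                dosage = spec.cis_dosage_coef * (cn - 2)
                if dosage:
                    for g in window:
                        x[row_index[s], col_index[g]] += dosage
            for s in sv_samples:
                sv_rows.append((s, spec.gene_id, "deletion"))
            for s in picked:
                labels[s] = {"label": "mutant", "cryptic": False}

            remaining = [s for s in members if s not in set(picked)]
            n_ni = min(int(round(spec.nonimpactful_fraction * len(members))), len(remaining))
            ni_samples = list(rng_t.choice(remaining, size=n_ni, replace=False))
            n_cryptic = int(round(spec.cryptic_fraction * n_ni))
            for k, s in enumerate(ni_samples):
                cryptic = k < n_cryptic
                # cryptic carriers mimic intron-retention style events
                if cryptic:
                    term = "intron" if rng_t.random() < 0.8 else "synonymous"
                else:
                    term = NON_IMPACTFUL_TERMS[rng_t.integers(len(NON_IMPACTFUL_TERMS))]
                variant_rows.append((s, spec.gene_id, term, "somatic"))
                labels[s] = {"label": "excluded_non_impactful", "cryptic": cryptic}

            # plant the signature shift for mutant + cryptic carriers
            if spec.effect_size and t in shifted_types:
                shifted = picked + [s for s in ni_samples if labels[s]["cryptic"]]
                for s in shifted:
                    for g, sign in directions.items():
                        x[row_index[s], col_index[g]] += sign * spec.effect_size

        truth.drivers[spec.gene_id] = {
            "pattern_kind": spec.pattern_kind,
            "affected_types": sorted(spec.affected_types),
            "signature_genes": sorted(signature),
            "signature_directions": {g: int(v) for g, v in directions.items()},
            "cis_genes": sorted(g for g in window if g != spec.gene_id),
            "locus": list(locus),
        }
        truth.sample_labels[spec.gene_id] = labels

    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)
    expression = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=pd.Index(sample_ids, name="sample_id"), columns=ann.index),
        annotation=ann,
    )
    variants = pd.DataFrame(variant_rows, columns=["sample_id", "gene_id", "consequence", "origin"])
    cna = pd.DataFrame(cna_rows, columns=["sample_id", "gene_id", "copy_number"])
    sv = pd.DataFrame(sv_rows, columns=["sample_id", "gene_id", "sv_type"])
    return Cohort(
        expression=expression, metadata=metadata, variants=variants, cna=cna, sv=sv, truth=truth
    )
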