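import warnings

import pytest

import txpattern as tp

warnings.filterwarnings("ignore", message="F1 undefined")


@pytest.fixture(scope="session")
def small_params():
    """Forest small enough for fast tests; signal strengths make size moot."""
    return tp.RFParams(n_estimators=60)


def trio_config(seed: int = 2, n_samples: int = 320, n_genes: int = 600) -> tp.CohortConfig:
    """One pan-cancer, one tumour-specific, one null driver."""
    return tp.CohortConfig(
        n_samples=n_samples,
        n_genes=n_genes,
        n_coding=n_genes // 2,
        seed=seed,
        drivers=(
            tp.DriverSpec(
                gene_id="PAN",
                pattern_kind="pan_cancer",
                signature_genes=20,
                effect_size=1.5,
                mutant_fraction_per_type=0.35,
            ),
            tp.DriverSpec(
                gene_id="SPEC",
                pattern_kind="tumour_specific",
                affected_types=("TTA", "TTB"),
                signature_genes=20,
                effect_size=1.5,
                mutant_fraction_per_type=0.35,
            ),
            tp.DriverSpec(
                gene_id="NULL",
                pattern_kind="null",
                effect_size=0.0,
                mutant_fraction_per_type=0.35,
            ),
        ),
    )


@pytest.fixture(scope="session")
def trio_cohort():
    return tp.generate_cohort(trio_config())


@pytest.fixture(scope="session")
def trio_pan_cv(trio_cohort, small_params):
    """Shared CV result for the pan-cancer driver (expensive, reused)."""
    labels = tp.build_labels(
        "PAN", "snv", trio_cohort.variants, trio_cohort.cna, trio_cohort.sv, trio_cohort.metadata
    )
    X = trio_cohort.expression.log_values().loc[labels.analysis_samples]
    y = labels.labels.loc[labels.analysis_samples]
    cv = tp.run_cv(X, y, seed=0, params=small_params)
    return labels, X, y, cv
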