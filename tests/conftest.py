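import pytest

from cimpscan.pipeline import PipelineConfig, run_pipeline
from cimpscan.synthetic_cohort import generate_default_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort: 40 pairs, 2000 genes, planted core of 132."""
    cfg, manifest, ds, truth = generate_default_cohort(seed=1)
    return cfg, manifest, ds, truth


@pytest.fixture(scope="session")
def default_run(default_cohort):
    """Full pipeline result on the standard cohort."""
    cfg, manifest, ds, truth = default_cohort
    result = run_pipeline(
        PipelineConfig.default_synthetic(sam_seed=1), ds=ds, manifest=manifest
    )
    return truth, result


def small_cohort_config(seed: int = 3, **overrides):
    """A miniature cohort for fast structural tests."""
    from cimpscan.synthetic_cohort import CohortConfig

    kwargs = dict(
        n_pairs=10,
        n_genes=150,
        core_set_size=20,
        n_open_sea_probes=600,
        n_hypo_probes=120,
        n_sex_probes=40,
        n_cross_reactive=30,
        n_negative_controls=40,
        n_internal_controls=20,
        background_rate_mean={"CIMP-H": 12.0, "CIMP-L": 5.0, "CIMP-N": 4.0},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)
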