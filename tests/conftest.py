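"""Shared fixtures: small synthetic cohorts generated at test time."""

import pytest

from regdriver import BackgroundCoefs, DriverSpec, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def null_cohort(tmp_path_factory):
    """Small cohort with no spiked drivers."""
    cfg = GeneratorConfig(
        seed=11, n_tumors=30, n_genes=40,
        chrom_lengths={"chr1": 600_000, "chr2": 600_000})
    outdir = tmp_path_factory.mktemp("null_cohort")
    paths, truth = generate_cohort(cfg, outdir)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def spiked_cohort(tmp_path_factory):
    """Cohort with one promoter and one CRE driver plus expression effects.

    The baseline mutation rate is low so driver regions stay mutated in a
    minority of tumors, leaving an unmutated comparison group for the
    expression tests (as in a patient cohort)."""
    cfg = GeneratorConfig(
        seed=23, n_tumors=60, n_genes=40,
        chrom_lengths={"chr1": 600_000, "chr2": 600_000, "chr3": 600_000},
        background_coefs=BackgroundCoefs(intercept=-9.5),
        driver_spec=[
            DriverSpec(region="promoter:G00003", multiplier=12.0,
                       concentration=0.6, expression_fold_change=1/4.6),
            DriverSpec(region="cre:F00004", multiplier=12.0,
                       concentration=0.6, expression_fold_change=2.3),
        ])
    outdir = tmp_path_factory.mktemp("spiked_cohort")
    paths, truth = generate_cohort(cfg, outdir)
    return cfg, paths, truth
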