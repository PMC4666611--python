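"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pytest

import isletqtl as iq


@pytest.fixture(scope="session")
def small_config():
    return iq.paired_study_config(
        n_samples=150,
        n_genes=6,
        n_exons=4,
        variants_per_block=30,
        planted_fraction=1 / 3,
        n_hidden_factors=3,
        factor_sd=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Genotypes + counts + truth for a 150-sample, 6-gene study."""
    gm = iq.simulate_genotypes(small_config)
    counts, truth = iq.simulate_expression(gm, small_config)
    return gm, counts, truth


@pytest.fixture(scope="session")
def small_scan(small_study):
    """Normalized expression, covariates, and the cis scan of small_study."""
    gm, counts, truth = small_study
    expr = iq.normalize_counts(counts)
    cov = iq.infer_hidden_factors(expr, k=3, sex=truth.sex)
    scan = iq.scan_cis(expr, gm, cov.to_numpy())
    return expr, cov, scan


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
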