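import numpy as np
import pytest

from glfd import (
    ExpressionMatrix,
    SimulationConfig,
    simulate_dataset,
    standardize_genes,
    whiten_clinical,
)

#: small simulation design used throughout the unit tests: 400 genes,
#: 60 samples, three 80-gene modules (one clinical + background dims 2, 3),
#: 160 noise genes — same structure as the full benchmark, ~25x cheaper.
SMALL_SIM = dict(
    n_genes=400,
    n_samples=60,
    module_size=80,
    background_module_dims=(2, 3),
    n_noise_genes=160,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_dataset():
    cfg = SimulationConfig(snr=2.0, n_coreg_latent=1, seed=42, **SMALL_SIM)
    return simulate_dataset(cfg)


@pytest.fixture
def small_standardized(small_dataset):
    expr, clin_raw, truth = small_dataset
    expr_std = standardize_genes(expr)
    clin = whiten_clinical(clin_raw, sample_ids=expr.sample_ids)
    return expr_std, clin, truth


def random_expression(rng, p=10, n=6):
    values = rng.standard_normal((p, n))
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(p)], [f"s{j}" for j in range(n)]
    )
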