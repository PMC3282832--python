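"""Synthetic expression data with planted clinical and latent factor modules.

The generator reproduces the benchmark design used throughout this package:
2000 genes by 100 samples, where a first module of 200 genes is governed by
one observed clinical factor together with 0-3 hidden latent factors, four
further 200-gene modules are governed by 2-4 latent factors each
(independent of module one), and the remaining 1000 genes are pure noise.
All factor scores are drawn i.i.d. standard normal.  Within a module every
gene loads on all of the module's factors, giving the combinatorial
structure the subspace search relies on.

Per gene, the loading vector is normalized to unit length so the signal
has unit expected variance, and Gaussian noise with standard deviation
1/sqrt(S/N) is added; the signal-to-noise ratio is therefore the ratio of
expected signal variance to noise variance for every module gene.  The
downstream pipeline standardizes each gene row, so per-gene scale carries
no information and this normalization is without loss of generality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .preprocessing import ExpressionMatrix


@dataclass
class SimulationConfig:
    """Design of one synthetic dataset.

    n_coreg_latent is the number of hidden factors that share module one
    with the clinical factor; 0 gives the null configuration used for
    false-positive experiments.
    """

    n_genes: int = 2000
    n_samples: int = 100
    module_size: int = 200
    n_coreg_latent: int = 1
    background_module_dims: Tuple[int, ...] = (2, 3, 4, 2)
    n_noise_genes: int = 1000
    snr: float = 1.0
    seed: int = 0
    loading_dist: str = "normal"  # or "uniform": |U(0.5, 1.5)| with random sign

    def __post_init__(self) -> None:
        if not 0 <= self.n_coreg_latent <= 3:
            raise ValueError("n_coreg_latent must be in 0..3")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        n_modules = 1 + len(self.background_module_dims)
        if n_modules * self.module_size + self.n_noise_genes != self.n_genes:
            raise ValueError(
                f"inconsistent sizes: {n_modules} modules x {self.module_size} "
                f"+ {self.n_noise_genes} noise genes != {self.n_genes} genes"
            )
        if self.loading_dist not in ("normal", "uniform"):
            raise ValueError(f"unknown loading_dist {self.loading_dist!r}")


@dataclass
class SimulationTruth:
    """Ground truth bookkeeping for one simulated dataset."""

    clinical_scores: np.ndarray  # (n,)
    latent_scores: np.ndarray  # (n, total latent factors)
    latent_module: np.ndarray  # module index (1-based) of each latent column
    loadings: Dict[int, np.ndarray]  # module index -> (q, n_factors) matrix
    module_membership: Dict[str, int]  # gene id -> module index (0 = noise)
    noise_sd: float

    @property
    def coreg_latent_scores(self) -> np.ndarray:
        """Latent factor scores planted in module one (n x k_true)."""
        return self.latent_scores[:, self.latent_module == 1]


def _draw_loadings(rng: np.random.Generator, q: int, k: int, dist: str) -> np.ndarray:
    if dist == "normal":
        L = rng.standard_normal((q, k))
    else:
        L = rng.uniform(0.5, 1.5, (q, k)) * rng.choice([-1.0, 1.0], (q, k))
    # unit-norm rows: unit expected signal variance per gene
    return L / np.linalg.norm(L, axis=1, keepdims=True)


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[ExpressionMatrix, np.ndarray, SimulationTruth]:
    """Generate one dataset; returns (expression, clinical n x 1, truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    q = config.module_size

    clinical = rng.standard_normal(n)
    module_dims = [1 + config.n_coreg_latent] + [
        int(d) for d in config.background_module_dims
    ]
    total_latent = config.n_coreg_latent + sum(config.background_module_dims)
    latent = rng.standard_normal((n, total_latent))
    latent_module = np.concatenate(
        [
            np.full(config.n_coreg_latent, 1, dtype=int),
            np.concatenate(
                [
                    np.full(d, j + 2, dtype=int)
                    for j, d in enumerate(config.background_module_dims)
                ]
            )
            if config.background_module_dims
            else np.empty(0, dtype=int),
        ]
    )

    noise_sd = 1.0 / np.sqrt(config.snr)
    blocks: List[np.ndarray] = []
    gene_ids: List[str] = []
    membership: Dict[str, int] = {}
    loadings: Dict[int, np.ndarray] = {}

    col = 0
    for j, k_j in enumerate(module_dims, start=1):
        if j == 1:
            scores = np.column_stack(
                [clinical, latent[:, : config.n_coreg_latent]]
            )
            col = config.n_coreg_latent
        else:
            scores = latent[:, col : col + k_j]
            col += k_j
        L = _draw_loadings(rng, q, k_j, config.loading_dist)
        loadings[j] = L
        signal = L @ scores.T  # (q, n)
        blocks.append(signal + noise_sd * rng.standard_normal((q, n)))
        ids = [f"M{j}_G{i + 1:04d}" for i in range(q)]
        gene_ids.extend(ids)
        membership.update({g: j for g in ids})

    noise_block = rng.standard_normal((config.n_noise_genes, n))
    blocks.append(noise_block)
    noise_ids = [f"N_G{i + 1:04d}" for i in range(config.n_noise_genes)]
    gene_ids.extend(noise_ids)
    membership.update({g: 0 for g in noise_ids})

    values = np.vstack(blocks)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    expr = ExpressionMatrix(values, gene_ids, sample_ids, standardized=False)
    truth = SimulationTruth(
        clinical_scores=clinical,
        latent_scores=latent,
        latent_module=latent_module,
        loadings=loadings,
        module_membership=membership,
        noise_sd=noise_sd,
    )
    return expr, clinical[:, None], truth


def simulate_null(
    config: SimulationConfig,
) -> Tuple[ExpressionMatrix, np.ndarray, SimulationTruth]:
    """Null configuration: module one is governed by the clinical factor only."""
    return simulate_dataset(replace(config, n_coreg_latent=0))
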