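"""Standardization, whitening, and clinically guided weighted residualization.

The first stage of guided latent factor discovery removes each gene's
component along the observed clinical factors and down-weights genes that
show no significant first-order association with them, so that the
downstream subspace search operates only on the clinically responsive part
of the transcriptome.

Every gene expression vector is centered and scaled to unit length, so a
projection length onto an orthonormal factor basis behaves like a multiple
correlation coefficient: for a gene independent of an m-dimensional basis,

    F = (l^2 / m) * (n - m - 1) / (1 - l^2)  ~  F(m, n - m - 1),

which gives an exact significance threshold ``delta`` on the projection
length at any level ``alpha``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

logger = logging.getLogger("glfd")

#: rows whose centered norm falls below this are treated as constant
_CONSTANT_TOL = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene expression values, genes in rows, samples in columns.

    Parameters
    ----------
    values
        Real matrix of shape (p genes, n samples), finite.
    gene_ids, sample_ids
        Unique identifiers for the rows / columns.
    standardized
        True once every row has mean 0 and Euclidean length 1.
    """

    values: np.ndarray
    gene_ids: Sequence[str]
    sample_ids: Sequence[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-d matrix")
        p, n = self.values.shape
        if p < 1 or n < 3:
            raise ValueError(f"need at least 1 gene and 3 samples, got {p}x{n}")
        if len(self.gene_ids) != p or len(self.sample_ids) != n:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene identifiers are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample identifiers are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ClinicalFactorSet:
    """Observed clinical factor scores and their whitened orthonormal basis.

    ``whitened`` has orthonormal columns spanning the same subspace as the
    column-centered raw scores; projection lengths onto it are invariant to
    any invertible recoding of the raw factors.
    """

    raw: np.ndarray
    whitened: np.ndarray
    sample_ids: Sequence[str]
    factor_names: Sequence[str]

    @property
    def n_samples(self) -> int:
        return self.raw.shape[0]

    @property
    def n_factors(self) -> int:
        return self.raw.shape[1]


@dataclass
class WeightedResidualMatrix:
    """Per-gene residuals after removing the clinical subspace.

    ``residuals`` holds the raw residual rows, ``projection_lengths`` the
    length of each standardized gene's projection onto the whitened clinical
    basis, ``weights`` the sigmoid weight of each gene, and ``weighted`` the
    elementwise product weights[i] * residuals[i].
    """

    residuals: np.ndarray
    projection_lengths: np.ndarray
    gene_ids: Sequence[str]
    sample_ids: Sequence[str]
    weighted: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None
    delta: Optional[float] = None
    phi: Optional[float] = None
    alpha: Optional[float] = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def standardize_genes(
    expr: ExpressionMatrix, constant_policy: str = "drop"
) -> ExpressionMatrix:
    """Center each gene row to mean 0 and scale it to unit Euclidean length.

    Constant rows have no direction and cannot be standardized; under the
    default ``constant_policy="drop"`` they are removed with a logged
    warning, under ``"error"`` they raise, naming the offending genes.
    """
    if expr.standardized:
        return expr
    values = expr.values
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms < _CONSTANT_TOL
    if constant.any():
        bad = [expr.gene_ids[i] for i in np.flatnonzero(constant)]
        if constant_policy == "error":
            raise ValueError(f"constant expression rows: {bad}")
        if constant_policy != "drop":
            raise ValueError(f"unknown constant_policy {constant_policy!r}")
        logger.warning("dropping %d constant gene rows: %s", len(bad), bad)
        keep = ~constant
        centered = centered[keep]
        norms = norms[keep]
        gene_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    else:
        gene_ids = list(expr.gene_ids)
    out = centered / norms[:, None]
    return ExpressionMatrix(out, gene_ids, list(expr.sample_ids), standardized=True)


def whiten_clinical(
    B_raw: np.ndarray,
    sample_ids: Optional[Sequence[str]] = None,
    factor_names: Optional[Sequence[str]] = None,
) -> ClinicalFactorSet:
    """Whiten the clinical factor matrix into an orthonormal basis.

    Columns are centered, then transformed as B* = B Phi Lambda^{-1/2} where
    Lambda, Phi are the eigenvalues/eigenvectors of B^T B of the centered
    matrix.  Column centering makes the F-distribution null of the
    projection-length test exact for centered unit-length genes.
    """
    B_raw = np.asarray(B_raw, dtype=float)
    if B_raw.ndim == 1:
        B_raw = B_raw[:, None]
    n, m = B_raw.shape
    if m < 1:
        raise ValueError("need at least one clinical factor")
    if n <= m + 1:
        raise ValueError(
            f"need n > m + 1 samples for the F null (n={n}, m={m})"
        )
    if not np.all(np.isfinite(B_raw)):
        raise ValueError("clinical factor matrix contains non-finite values")
    centered = B_raw - B_raw.mean(axis=0, keepdims=True)
    gram = centered.T @ centered
    evals, evecs = np.linalg.eigh(gram)
    rank = int(np.sum(evals > max(evals[-1], _CONSTANT_TOL) * 1e-10))
    if rank < m:
        raise ValueError(
            f"clinical factor matrix is rank deficient: numerical rank {rank} < {m}"
        )
    whitened = centered @ evecs / np.sqrt(evals)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n)]
    if factor_names is None:
        factor_names = [f"B{j + 1}" for j in range(m)]
    return ClinicalFactorSet(B_raw, whitened, list(sample_ids), list(factor_names))


def projection_length(g: np.ndarray, basis: np.ndarray) -> float:
    """Length of the projection of a unit vector onto an orthonormal basis."""
    g = np.asarray(g, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if basis.ndim == 1:
        basis = basis[:, None]
    if abs(np.linalg.norm(g) - 1.0) > 1e-8:
        raise ValueError("g must have unit length")
    k = basis.shape[1]
    if np.max(np.abs(basis.T @ basis - np.eye(k))) > 1e-8:
        raise ValueError("basis columns must be orthonormal")
    return float(np.linalg.norm(basis.T @ g))


def residualize(
    expr_std: ExpressionMatrix, clin: ClinicalFactorSet
) -> WeightedResidualMatrix:
    """Remove each standardized gene's projection onto the clinical basis.

    Returns residual rows r_i = g_i - B* (B*^T g_i) together with the
    projection lengths l_i; by Pythagoras ||r_i||^2 = 1 - l_i^2.
    """
    if not expr_std.standardized:
        raise ValueError("expression matrix must be standardized first")
    if list(expr_std.sample_ids) != list(clin.sample_ids):
        extra = set(expr_std.sample_ids) ^ set(clin.sample_ids)
        raise ValueError(
            "sample identifiers of expression and clinical data disagree "
            f"(set or order); differing ids: {sorted(extra) if extra else 'order only'}"
        )
    G = expr_std.values
    Bstar = clin.whitened
    coords = G @ Bstar
    residuals = G - coords @ Bstar.T
    lengths = np.minimum(np.linalg.norm(coords, axis=1), 1.0)
    return WeightedResidualMatrix(
        residuals=residuals,
        projection_lengths=lengths,
        gene_ids=list(expr_std.gene_ids),
        sample_ids=list(expr_std.sample_ids),
    )


def delta_threshold(alpha: float, m: int, n: int) -> float:
    """Projection-length cutoff matching an F-test at level ``alpha``.

    delta = sqrt( m F_q / ((n-m-1) + m F_q) ) with F_q the (1-alpha)
    quantile of F(m, n-m-1); a gene independent of the m-dimensional basis
    exceeds delta with probability alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1 or n <= m + 1:
        raise ValueError(f"degenerate degrees of freedom (m={m}, n={n})")
    # isf is accurate for small alpha where ppf(1 - alpha) loses precision
    fq = stats.f.isf(alpha, m, n - m - 1)
    if np.isinf(fq):  # alpha below quantile underflow: delta -> 1
        return 1.0
    return float(np.sqrt(m * fq / ((n - m - 1) + m * fq)))


def sigmoid_weights(lengths: np.ndarray, phi: float, delta: float) -> np.ndarray:
    """Sigmoid weight 1 - 1/(1 + exp(phi (l - delta))) for each length.

    With a steep slope (phi ~ 100) this approximates a step at ``delta``:
    significantly associated genes keep weight ~1, the rest ~0.  ``expit``
    saturates cleanly, so extreme arguments never produce non-finite output.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    lengths = np.asarray(lengths, dtype=float)
    return expit(phi * (lengths - delta))


def weight_residuals(
    wr: WeightedResidualMatrix,
    alpha: float = 0.001,
    phi: float = 100.0,
    delta: Optional[float] = None,
    m: Optional[int] = None,
) -> WeightedResidualMatrix:
    """Populate sigmoid weights and the weighted residual rows.

    ``delta`` defaults to the alpha-level threshold for the clinical
    dimensionality ``m`` (inferred from the Pythagoras relation is not
    possible, so pass ``m`` when delta is not given).
    """
    n = len(wr.sample_ids)
    if delta is None:
        if m is None:
            raise ValueError("either delta or the clinical dimensionality m is required")
        delta = delta_threshold(alpha, m, n)
    weights = sigmoid_weights(wr.projection_lengths, phi, delta)
    weighted = weights[:, None] * wr.residuals
    return replace(
        wr, weighted=weighted, weights=weights, delta=delta, phi=phi, alpha=alpha
    )


def weighted_residual_matrix(
    expr_std: ExpressionMatrix,
    clin: ClinicalFactorSet,
    alpha: float = 0.001,
    phi: float = 100.0,
) -> WeightedResidualMatrix:
    """Convenience: residualize then weight in one call."""
    wr = residualize(expr_std, clin)
    return weight_residuals(wr, alpha=alpha, phi=phi, m=clin.n_factors)
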