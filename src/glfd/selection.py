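"""Selecting latent factors that co-regulate genes with the clinical factors.

After module search, every candidate factor set is taken back to the
ORIGINAL standardized expression matrix: the genes associated with the
clinical basis and with each factor set are found by the projection-length
F-test at an FDR cutoff, and the overlap of the two gene sets is scored
with a conservative hypergeometric tail probability whose counts are
deflated for the expected false discoveries.  Factor sets with significant
overlap are then retested factor by factor, and only individually
significant factors are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .mlsa import LatentModule, SearchConfig, extract_all_modules, scale_to_unit_max
from .preprocessing import (
    ClinicalFactorSet,
    ExpressionMatrix,
    weighted_residual_matrix,
)

logger = logging.getLogger("glfd")


@dataclass
class AssociationResult:
    """Per-gene association of standardized expression with a factor basis."""

    gene_ids: Sequence[str]
    projection_lengths: np.ndarray
    f_statistics: np.ndarray
    p_values: np.ndarray
    fdr: np.ndarray
    significant: np.ndarray  # boolean, fdr <= lambda
    fdr_cutoff: float

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def significant_indices(self) -> np.ndarray:
        return np.flatnonzero(self.significant)


@dataclass
class OverlapTest:
    """Conservative hypergeometric overlap test between two gene sets.

    Raw counts (m1, m2, r_overlap) are deflated by the FDR cutoff lambda —
    m' = ceiling(m (1-lambda)), r' = floor(r (1-lambda)^2) — before the
    hypergeometric tail sum, so expected false discoveries in either set
    cannot manufacture significance.
    """

    p_total: int
    m1: int
    m2: int
    r_overlap: int
    m1_adj: int
    m2_adj: int
    r_adj: int
    p_value: float
    significant: bool


@dataclass
class RetainedFactor:
    """A single retained latent factor with its provenance."""

    scores: np.ndarray  # (n,)
    module_index: int  # 0-based index into GLFDResult.modules
    factor_index: int  # 0-based column within the module
    overlap: OverlapTest

    @property
    def label(self) -> str:
        return f"M{self.module_index + 1}.F{self.factor_index + 1}"


@dataclass
class GLFDResult:
    """Full output of a guided latent factor discovery run."""

    clinical: ClinicalFactorSet
    modules: List[LatentModule]
    retained: List[RetainedFactor]
    clinical_association: AssociationResult
    module_associations: List[AssociationResult]
    set_overlaps: List[OverlapTest]
    factor_overlaps: List[List[Optional[OverlapTest]]]
    params: Dict[str, object]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def retained_factors(self) -> np.ndarray:
        """Retained factor scores as an (n, n_retained) matrix."""
        n = self.clinical.n_samples
        if not self.retained:
            return np.empty((n, 0))
        return np.column_stack([rf.scores for rf in self.retained])


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def f_statistic(l, k: int, n: int):
    """Projection-length F statistic (l^2/k) * (n-k-1)/(1-l^2).

    Under independence of a centered unit gene vector and the k-dimensional
    basis it follows F(k, n-k-1).  ``l`` may be a scalar or array; l = 1
    maps to +inf.
    """
    if k < 1 or n <= k + 1:
        raise ValueError(f"degenerate degrees of freedom (k={k}, n={n})")
    l2 = np.square(np.asarray(l, dtype=float))
    with np.errstate(divide="ignore"):
        out = (l2 / k) * ((n - k - 1) / (1.0 - l2))
    return float(out) if np.isscalar(l) else out


def associated_genes(
    expr_std: ExpressionMatrix, basis: np.ndarray, fdr_cutoff: float = 0.1
) -> AssociationResult:
    """Genes associated with a factor subspace at an FDR cutoff.

    Projection lengths of the standardized genes onto the orthonormal basis
    are converted to F-test p-values and then to Benjamini-Hochberg FDR;
    the result depends only on the span of the basis.
    """
    if not expr_std.standardized:
        raise ValueError("expression matrix must be standardized")
    basis = np.asarray(basis, dtype=float)
    if basis.ndim == 1:
        basis = basis[:, None]
    n, k = basis.shape
    if np.max(np.abs(basis.T @ basis - np.eye(k))) > 1e-8:
        raise ValueError("basis columns must be orthonormal")
    lengths = np.minimum(np.linalg.norm(expr_std.values @ basis, axis=1), 1.0)
    fstat = f_statistic(lengths, k, n)
    pvals = stats.f.sf(fstat, k, n - k - 1)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    significant = fdr <= fdr_cutoff
    return AssociationResult(
        gene_ids=list(expr_std.gene_ids),
        projection_lengths=lengths,
        f_statistics=fstat,
        p_values=pvals,
        fdr=fdr,
        significant=significant,
        fdr_cutoff=fdr_cutoff,
    )


def _adjust_count_ceil(count: int, lam: float) -> int:
    # guard float noise so e.g. 10 * 0.9 = 9.000000000000002 still ceils to 9
    return int(math.ceil(count * (1.0 - lam) - 1e-9))


def _adjust_count_floor(count: int, lam: float) -> int:
    return int(math.floor(count * (1.0 - lam) ** 2 + 1e-9))


def hypergeometric_overlap(
    p_total: int,
    m1: int,
    m2: int,
    r_overlap: int,
    fdr_cutoff: float,
    p_cutoff: float = 0.01,
) -> OverlapTest:
    """Conservative hypergeometric tail probability of the observed overlap.

    The tail sum P[X >= r'] with X ~ Hypergeom(p_total, m1', m2') is
    accumulated in log space for numerical stability.
    """
    if not (0 <= r_overlap <= min(m1, m2) <= max(m1, m2) <= p_total):
        raise ValueError(
            f"inconsistent counts: p={p_total}, m1={m1}, m2={m2}, r={r_overlap}"
        )
    if not 0.0 <= fdr_cutoff < 1.0:
        raise ValueError("fdr_cutoff must be in [0, 1)")
    m1a = _adjust_count_ceil(m1, fdr_cutoff)
    m2a = _adjust_count_ceil(m2, fdr_cutoff)
    ra = _adjust_count_floor(r_overlap, fdr_cutoff)
    upper = min(m1a, m2a)
    if ra <= 0:
        pval = 1.0
    elif ra > upper:
        pval = 0.0
    else:
        support = np.arange(ra, upper + 1)
        logp = stats.hypergeom.logpmf(support, p_total, m1a, m2a)
        pval = float(min(np.exp(logsumexp(logp)), 1.0))
    return OverlapTest(
        p_total=p_total,
        m1=m1,
        m2=m2,
        r_overlap=r_overlap,
        m1_adj=m1a,
        m2_adj=m2a,
        r_adj=ra,
        p_value=pval,
        significant=pval < p_cutoff,
    )


# ---------------------------------------------------------------------------
# factor selection
# ---------------------------------------------------------------------------

def select_latent_factors(
    expr_std: ExpressionMatrix,
    clin: ClinicalFactorSet,
    modules: Sequence[LatentModule],
    fdr_cutoff: float = 0.1,
    overlap_p_cutoff: float = 0.01,
    params: Optional[Dict[str, object]] = None,
) -> GLFDResult:
    """Retain latent factors whose associated genes overlap the clinical set.

    Associations are computed on the original standardized expression.  A
    module's whole factor set must pass the overlap test first; its factors
    are then retested one at a time (k = 1 subspaces) and only individually
    significant factors are kept.
    """
    p_total = expr_std.n_genes
    assoc_clin = associated_genes(expr_std, clin.whitened, fdr_cutoff)
    clin_set = set(assoc_clin.significant_indices().tolist())

    module_assocs: List[AssociationResult] = []
    set_overlaps: List[OverlapTest] = []
    factor_overlaps: List[List[Optional[OverlapTest]]] = []
    retained: List[RetainedFactor] = []

    for j, mod in enumerate(modules):
        assoc_mod = associated_genes(expr_std, mod.factors, fdr_cutoff)
        module_assocs.append(assoc_mod)
        mod_set = set(assoc_mod.significant_indices().tolist())
        ov = hypergeometric_overlap(
            p_total,
            len(clin_set),
            len(mod_set),
            len(clin_set & mod_set),
            fdr_cutoff,
            overlap_p_cutoff,
        )
        set_overlaps.append(ov)
        per_factor: List[Optional[OverlapTest]] = [None] * mod.dimensionality
        if ov.significant:
            for c in range(mod.dimensionality):
                assoc_f = associated_genes(
                    expr_std, mod.factors[:, c : c + 1], fdr_cutoff
                )
                f_set = set(assoc_f.significant_indices().tolist())
                ov_f = hypergeometric_overlap(
                    p_total,
                    len(clin_set),
                    len(f_set),
                    len(clin_set & f_set),
                    fdr_cutoff,
                    overlap_p_cutoff,
                )
                per_factor[c] = ov_f
                if ov_f.significant:
                    retained.append(
                        RetainedFactor(
                            scores=mod.factors[:, c].copy(),
                            module_index=j,
                            factor_index=c,
                            overlap=ov_f,
                        )
                    )
        factor_overlaps.append(per_factor)

    logger.info(
        "factor selection: %d modules tested, %d factors retained",
        len(modules),
        len(retained),
    )
    return GLFDResult(
        clinical=clin,
        modules=list(modules),
        retained=retained,
        clinical_association=assoc_clin,
        module_associations=module_assocs,
        set_overlaps=set_overlaps,
        factor_overlaps=factor_overlaps,
        params=dict(params or {}),
    )


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def fit_glfd(
    expr_std: ExpressionMatrix,
    clin: ClinicalFactorSet,
    config: Optional[SearchConfig] = None,
    alpha: float = 0.001,
    phi: float = 100.0,
    fdr_cutoff: float = 0.1,
    overlap_p_cutoff: float = 0.01,
) -> GLFDResult:
    """Run the full guided pipeline on standardized expression.

    Steps: weighted residualization against the clinical basis, scaling by
    the longest residual, iterative module extraction, then overlap-based
    factor selection on the original expression matrix.
    """
    config = config or SearchConfig()
    wr = weighted_residual_matrix(expr_std, clin, alpha=alpha, phi=phi)
    n_guided = int(np.sum(wr.projection_lengths > wr.delta))
    logger.info(
        "guided gene set: %d of %d genes exceed the projection-length "
        "threshold delta=%.4f",
        n_guided,
        expr_std.n_genes,
        wr.delta,
    )
    Rstar = scale_to_unit_max(wr.weighted)
    modules = extract_all_modules(Rstar, config)
    params = {
        "alpha": alpha,
        "phi": phi,
        "fdr_cutoff": fdr_cutoff,
        "overlap_p_cutoff": overlap_p_cutoff,
        "max_dim": config.max_dim,
        "min_module_genes": config.min_module_genes,
        "search_mode": config.search_mode,
        "pipeline": "glfd",
        "n_guided_genes": n_guided,
    }
    return select_latent_factors(
        expr_std, clin, modules, fdr_cutoff, overlap_p_cutoff, params
    )


def direct_mlsa_pipeline(
    expr_std: ExpressionMatrix,
    clin: ClinicalFactorSet,
    config: Optional[SearchConfig] = None,
    fdr_cutoff: float = 0.1,
    overlap_p_cutoff: float = 0.01,
) -> GLFDResult:
    """Alternative pipeline: modular search on the expression matrix itself.

    Modules are extracted from the standardized expression (no clinical
    residualization or weighting); each module's factors are then forced
    orthogonal to the clinical span by subtracting their projection and
    re-orthonormalizing, before the same overlap-based selection.
    """
    config = config or SearchConfig()
    Rstar = scale_to_unit_max(expr_std.values)
    modules = extract_all_modules(Rstar, config)
    Bstar = clin.whitened
    ortho_modules: List[LatentModule] = []
    for mod in modules:
        F = mod.factors - Bstar @ (Bstar.T @ mod.factors)
        norms = np.linalg.norm(F, axis=0)
        keep = norms > 1e-10
        if not keep.any():
            continue
        Q, _ = np.linalg.qr(F[:, keep])
        ortho_modules.append(
            LatentModule(
                factors=Q,
                dimensionality=Q.shape[1],
                member_genes=mod.member_genes,
                converged=mod.converged,
                n_iterations=mod.n_iterations,
            )
        )
    params = {
        "fdr_cutoff": fdr_cutoff,
        "overlap_p_cutoff": overlap_p_cutoff,
        "max_dim": config.max_dim,
        "min_module_genes": config.min_module_genes,
        "search_mode": config.search_mode,
        "pipeline": "direct_mlsa",
    }
    return select_latent_factors(
        expr_std, clin, ortho_modules, fdr_cutoff, overlap_p_cutoff, params
    )
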