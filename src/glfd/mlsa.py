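"""Modular latent structure search on the weighted residual matrix.

A gene module is a group of rows whose directions have large projection
length onto a shared low-dimensional subspace of sample space.  Modules are
found one at a time by an EM-style fixed-point iteration: the E-step gives
each row a sigmoid weight based on the projection length of its direction
onto the current factor estimate, and the M-step re-estimates the factors
as the leading right singular vectors of the row-weighted matrix.  The
dimensionality of each module is chosen either exhaustively (try every
k = 1..K, keep the module with the most member genes) or by step-forward
search (grow k while membership strictly increases).  Extracted modules are
projected out of the working matrix, which makes successive factor sets
mutually orthogonal.

The inner iteration deliberately does not re-standardize rows to unit
length: the matrix enters scaled by its longest row (``scale_to_unit_max``),
so rows that were down-weighted by the clinical association step contribute
essentially nothing to factor estimation, while projection lengths for
weighting and membership are always computed on row directions so the
F-distribution threshold applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import expit

from .preprocessing import delta_threshold

logger = logging.getLogger("glfd")

#: rows with norm below this have no direction and are excluded from
#: membership testing and weighting
_ZERO_ROW_TOL = 1e-12


@dataclass
class LatentModule:
    """An estimated module: factor scores, dimensionality and member genes."""

    factors: np.ndarray  # (n, k), orthonormal columns
    dimensionality: int
    member_genes: np.ndarray  # sorted row indices into the input matrix
    converged: bool
    n_iterations: int

    @property
    def member_count(self) -> int:
        return int(len(self.member_genes))


@dataclass
class SearchConfig:
    """Tuning parameters of the module search.

    max_dim
        Largest module dimensionality K tried (default 10).
    min_module_genes
        Modules with fewer member genes stop the extraction loop (default 10).
    alpha_module
        Per-gene significance level of the projection-length F-test used for
        weighting and membership inside the search (default 0.001).
    phi
        Steepness of the sigmoid weighting (default 100).
    max_iter, tol
        Fixed-point iteration cap and convergence tolerance on the largest
        principal angle between successive factor subspaces.
    search_mode
        "exhaustive" or "sequential" dimensionality selection.
    """

    max_dim: int = 10
    min_module_genes: int = 10
    alpha_module: float = 0.001
    phi: float = 100.0
    max_iter: int = 500
    tol: float = 1e-6
    search_mode: str = "exhaustive"

    def __post_init__(self) -> None:
        if self.max_dim < 1:
            raise ValueError("max_dim must be >= 1")
        if self.min_module_genes < 1:
            raise ValueError("min_module_genes must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.search_mode not in ("exhaustive", "sequential"):
            raise ValueError(f"unknown search_mode {self.search_mode!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def canonicalize_signs(F: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    F = F.copy()
    for j in range(F.shape[1]):
        i = int(np.argmax(np.abs(F[:, j])))
        if F[i, j] < 0:
            F[:, j] = -F[:, j]
    return F


def max_principal_angle(F1: np.ndarray, F2: np.ndarray) -> float:
    """Largest principal angle (radians) between two orthonormal spans."""
    s = np.linalg.svd(F1.T @ F2, compute_uv=False)
    return float(np.arccos(np.clip(np.min(s), -1.0, 1.0)))


def _top_right_singular_vectors(M: np.ndarray, k: int) -> np.ndarray:
    """Leading k right singular vectors of M via the n x n Gram matrix."""
    gram = M.T @ M
    evals, evecs = np.linalg.eigh(gram)
    return evecs[:, ::-1][:, :k]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _loo_members(
    Rstar: np.ndarray,
    idx_valid: np.ndarray,
    F: np.ndarray,
    w: np.ndarray,
    active: np.ndarray,
    delta_k: float,
    k: int,
) -> np.ndarray:
    """Module membership with leave-one-out correction of self-selection.

    A row is a member only if its projection length still exceeds the
    dimensionality-dependent threshold when the factors are re-estimated
    without that row's own contribution.  Testing against the self-inclusive
    fit is biased: a k-dimensional subspace can be pulled to span any k
    long rows exactly, making each of them appear perfectly associated.
    The leave-one-out projection removes that circularity; for a genuine
    module (many rows sharing a subspace) it changes projections only
    marginally.

    Rows that did not influence the fit (relative weight contribution below
    1e-8 of the Gram trace) keep their ordinary projection length.
    """
    lengths_all = np.linalg.norm(Rstar[idx_valid] @ F, axis=1)
    candidates = idx_valid[lengths_all > delta_k]
    if candidates.size == 0:
        return candidates
    # weighted Gram of the converged M-step input
    w_full = np.zeros(Rstar.shape[0])
    w_full[np.flatnonzero(active)] = w
    M = w_full[:, None] * Rstar
    G = M.T @ M
    trace = np.trace(G)
    members = []
    for i in candidates:
        contrib = float(M[i] @ M[i])
        if trace > 0 and contrib / trace > 1e-8:
            Gi = G - np.outer(M[i], M[i])
            evals_i, evecs_i = np.linalg.eigh(Gi)
            Fi = evecs_i[:, ::-1][:, :k]
            l_i = np.linalg.norm(Fi.T @ Rstar[i])
        else:
            l_i = np.linalg.norm(F.T @ Rstar[i])
        if l_i > delta_k:
            members.append(i)
    return np.asarray(members, dtype=int)


def scale_to_unit_max(R: np.ndarray) -> np.ndarray:
    """Divide the matrix by its longest row norm so the max row length is 1.

    This replaces per-row standardization: relative row lengths (hence the
    clinical-association weighting) are preserved, and rows that were
    zeroed out stay negligible.
    """
    R = np.asarray(R, dtype=float)
    norms = np.linalg.norm(R, axis=1)
    lmax = norms.max(initial=0.0)
    if lmax <= _ZERO_ROW_TOL:
        raise ValueError(
            "no gene passes the clinical-association weighting "
            "(all weighted residual rows are zero)"
        )
    return R / lmax


def em_module_search(
    Rstar: np.ndarray,
    k: int,
    init_factors: np.ndarray,
    config: SearchConfig,
) -> LatentModule:
    """Find one k-dimensional module by the EM-like fixed-point iteration.

    E-step: weight each non-degenerate row by a sigmoid of the projection
    length of its unit direction onto the current factors, with threshold
    delta_k = delta_threshold(alpha_module, k, n).  M-step: factors become
    the top-k right singular vectors of the row-weighted matrix.  Members
    are the rows whose (unweighted) directions exceed delta_k under the
    final factors.
    """
    Rstar = np.asarray(Rstar, dtype=float)
    p, n = Rstar.shape
    if k > config.max_dim:
        raise ValueError(f"k={k} exceeds max_dim={config.max_dim}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    norms = np.linalg.norm(Rstar, axis=1)
    valid = norms > _ZERO_ROW_TOL
    idx_valid = np.flatnonzero(valid)
    if idx_valid.size == 0 or idx_valid.size < k:
        return LatentModule(
            factors=canonicalize_signs(np.asarray(init_factors, dtype=float)),
            dimensionality=k,
            member_genes=np.empty(0, dtype=int),
            converged=True,
            n_iterations=0,
        )
    delta_k = delta_threshold(config.alpha_module, k, n)

    # Projection lengths are taken on the scaled rows as they are — the
    # max-row-norm scaling stands in for per-row standardization, so genes
    # down-weighted by the clinical association step have short rows and can
    # neither be weighted up nor become members.  Rows whose norm is
    # negligible relative to the longest row contribute < 1e-18 (relative)
    # to the Gram matrix of the weighted M-step and are left out of the
    # iteration; they are still membership-tested at the end.
    active = norms > norms.max() * 1e-9
    rows = Rstar[active]

    F = np.asarray(init_factors, dtype=float)
    converged = False
    it = 0
    w_prev = None
    for it in range(1, config.max_iter + 1):
        lengths = np.linalg.norm(rows @ F, axis=1)
        w = expit(config.phi * (lengths - delta_k))
        F_new = _top_right_singular_vectors(w[:, None] * rows, k)
        gap = max_principal_angle(F, F_new)
        F = F_new
        if gap < config.tol:
            converged = True
            break
        # weight fixed point: trailing factor dimensions may wobble in
        # directions of (near-)degenerate eigenvalues without affecting the
        # module, so a stable weight vector also counts as convergence
        if w_prev is not None and np.max(np.abs(w - w_prev)) < 1e-13:
            converged = True
            lengths = np.linalg.norm(rows @ F, axis=1)
            w = expit(config.phi * (lengths - delta_k))
            break
        w_prev = w
    F = canonicalize_signs(F)
    if not converged:
        logger.warning(
            "module search (k=%d) did not converge in %d iterations", k, config.max_iter
        )
    members = _loo_members(Rstar, idx_valid, F, w, active, delta_k, k)
    return LatentModule(
        factors=F,
        dimensionality=k,
        member_genes=np.sort(members),
        converged=converged,
        n_iterations=it,
    )


def select_dimensionality(Rstar: np.ndarray, config: SearchConfig) -> LatentModule:
    """Exhaustive dimensionality choice: largest module over k = 1..K.

    Each k is initialized from the first k right singular vectors of the
    matrix itself; ties in member count break toward the smallest k.
    """
    Rstar = np.asarray(Rstar, dtype=float)
    K = min(config.max_dim, Rstar.shape[1] - 2)
    V = _top_right_singular_vectors(Rstar, K)
    best: Optional[LatentModule] = None
    for k in range(1, K + 1):
        mod = em_module_search(Rstar, k, V[:, :k], config)
        if best is None or mod.member_count > best.member_count:
            best = mod
    assert best is not None
    return best


def select_dimensionality_sequential(
    Rstar: np.ndarray, config: SearchConfig
) -> LatentModule:
    """Step-forward dimensionality choice.

    Starts at k = 1; each increment initializes from the current factors
    augmented with the leading right singular vector of the matrix residual
    after removing the current subspace, and is accepted only if the member
    count strictly increases.
    """
    Rstar = np.asarray(Rstar, dtype=float)
    K = min(config.max_dim, Rstar.shape[1] - 2)
    V1 = _top_right_singular_vectors(Rstar, 1)
    best = em_module_search(Rstar, 1, V1, config)
    for k in range(2, K + 1):
        F = best.factors
        resid = Rstar - (Rstar @ F) @ F.T
        v = _top_right_singular_vectors(resid, 1)
        # v lies in the row space of resid, hence orthogonal to F already
        v = v - F @ (F.T @ v)
        nv = np.linalg.norm(v)
        if nv < _ZERO_ROW_TOL:
            break
        init = np.hstack([F, v / nv])
        cand = em_module_search(Rstar, k, init, config)
        if cand.member_count > best.member_count:
            best = cand
        else:
            break
    return best


def extract_all_modules(Rstar: np.ndarray, config: SearchConfig) -> List[LatentModule]:
    """Iteratively extract modules until one falls below the size threshold.

    After each accepted module, every row of the working matrix is replaced
    by its residual after projection onto the module's factors, so factor
    sets of successive modules are mutually orthogonal.
    """
    Rstar = np.asarray(Rstar, dtype=float)
    select = (
        select_dimensionality
        if config.search_mode == "exhaustive"
        else select_dimensionality_sequential
    )
    W = Rstar.copy()
    modules: List[LatentModule] = []
    max_modules = W.shape[1]  # cannot exceed the sample-space dimension
    while len(modules) < max_modules:
        mod = select(W, config)
        if mod.member_count < config.min_module_genes:
            break
        modules.append(mod)
        logger.info(
            "module %d: k=%d, %d member genes (%s after %d iterations)",
            len(modules),
            mod.dimensionality,
            mod.member_count,
            "converged" if mod.converged else "not converged",
            mod.n_iterations,
        )
        F = mod.factors
        W = W - (W @ F) @ F.T
    return modules
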