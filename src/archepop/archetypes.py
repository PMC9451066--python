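"""Archetypal Analysis by alternating constrained non-negative least squares.

The model approximates each data row x_i as a convex combination of K
archetypes, X ~ alpha Z, where the archetypes are themselves convex
combinations of the rows, Z = beta^T X.  Both weight matrices are
therefore simplex-constrained: alpha rows and beta columns are
non-negative and sum to one.  The objective is the residual sum of
squares RSS = ||X - alpha Z||_F^2.

The simplex constraint is enforced inside an ordinary NNLS solve by
augmenting the system with a sum-to-one row weighted by 1/C: the smaller
the constraint coefficient C, the harder the constraint.  With the
default C = 1e-3 the solved weights sum to one to within ~1e-6 and are
renormalized exactly afterwards.

Because the objective and every sub-solve depend on the data only
through inner products, fitting on full-rank SVD scores gives the same
RSS as fitting on the centered SNP-space matrix (a rotation), which is
what makes the projected pipeline lossless.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from archepop.genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AAConfig",
    "AAFit",
    "furthest_sum_init",
    "random_init",
    "constrained_simplex_nnls",
    "fit",
    "rss_of",
    "explained_variance",
    "archetypes_in_snp_space",
]

_ALPHA_EPS = 1e-10  # total alpha mass below this marks a dead archetype


@dataclass
class AAConfig:
    """Solver configuration.

    K         : number of archetypes (clusters); an input, not inferred.
    C         : constraint coefficient; the sum-to-one row carries weight
                1/C, so smaller C enforces the simplex harder.
    tol       : relative RSS change |RSS_c - RSS_p| / RSS_p below which
                the alternation stops.
    max_iter  : cap on alternating iterations.
    init      : 'furthest_sum' (default), 'random_uniform' or 'random_sample'.
    seed      : single integer seed; all randomness flows from it.
    restarts  : number of independent (re-seeded) runs; best RSS wins.
    """

    K: int
    C: float = 0.001
    tol: float = 0.001
    max_iter: int = 50
    init: str = "furthest_sum"
    seed: int = 0
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("furthest_sum", "random_uniform", "random_sample"):
            raise ValueError(f"unknown init method {self.init!r}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class AAFit:
    """Result of an Archetypal Analysis fit.

    alpha : N x K row-stochastic ancestry fractions
    beta  : N x K column-stochastic archetype weights over samples
    Z     : K x D archetypes in fit space (Z = (data^T beta)^T)
    """

    alpha: np.ndarray
    beta: np.ndarray
    Z: np.ndarray
    rss_trace: list[float]
    explained_variance: float
    converged: bool
    n_iter: int
    config: AAConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def K(self) -> int:
        return self.alpha.shape[1]

    @property
    def rss(self) -> float:
        return self.rss_trace[-1]

    @property
    def n_free_parameters(self) -> int:
        """Model degrees of freedom: N(K-1) from alpha plus K(N-1) from beta."""
        n, k = self.alpha.shape
        return 2 * n * k - n - k


def furthest_sum_init(
    data: np.ndarray,
    K: int,
    seed: int | np.random.Generator = 0,
    first_index: int | None = None,
    reselect_first: bool = False,
) -> np.ndarray:
    """FurthestSum selection of K initial archetype rows.

    The first row is drawn uniformly at random; each subsequent pick
    maximizes the summed Euclidean distance to everything picked so far
    (ties broken toward the lower index).  With ``reselect_first`` the
    arbitrary random pick is discarded once K rows are held and replaced
    by one more greedy pick, as in the original formulation of the
    heuristic; off by default.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    first = int(rng.integers(n)) if first_index is None else int(first_index)
    selected = [first]
    dist_sum = np.zeros(n)

    def _grow() -> None:
        nonlocal dist_sum
        dist_sum = dist_sum + np.linalg.norm(data - data[selected[-1]], axis=1)
        masked = dist_sum.copy()
        masked[selected] = -np.inf
        selected.append(int(np.argmax(masked)))

    while len(selected) < K:
        _grow()
    if reselect_first and K < n and K > 1:
        dist_sum = dist_sum + np.linalg.norm(data - data[selected[-1]], axis=1)
        dist_sum -= np.linalg.norm(data - data[first], axis=1)  # drop the random pick's pull
        selected = selected[1:]
        masked = dist_sum.copy()
        masked[selected] = -np.inf
        selected.append(int(np.argmax(masked)))
    return np.asarray(selected, dtype=int)


def random_init(
    data: np.ndarray, K: int, mode: str = "uniform", seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Random K x D initial archetypes.

    mode='uniform' draws every archetype coordinate uniformly within the
    per-dimension [min, max] of the data; mode='sample' picks K distinct
    data rows.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "uniform":
        lo, hi = data.min(axis=0), data.max(axis=0)
        return lo + (hi - lo) * rng.random((K, data.shape[1]))
    if mode == "sample":
        if K > n:
            raise ValueError(f"K={K} exceeds N={n} in sample mode")
        return data[rng.choice(n, size=K, replace=False)].copy()
    raise ValueError(f"unknown mode {mode!r}")


def constrained_simplex_nnls(A: np.ndarray, b: np.ndarray, C: float = 0.001) -> np.ndarray:
    """Non-negative least squares with a soft sum-to-one constraint.

    Solves min_w ||A w - b||^2 + (1/C)^2 (sum(w) - 1)^2 over w >= 0 by
    appending a row of ones (and a matching 1 on the target) weighted by
    1/C to a standard NNLS system; lower C weights the constraint more
    strongly.  The result is renormalized to sum exactly to one.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != b.shape[0]:
        raise ValueError(f"shape mismatch: A is {A.shape}, b has length {b.shape[0]}")
    if C <= 0:
        raise ValueError("C must be > 0")
    k = A.shape[1]
    if k == 1:
        return np.ones(1)
    if not A.any():
        warnings.warn("all-zero design matrix; returning uniform weights", stacklevel=2)
        return np.full(k, 1.0 / k)
    w_con = 1.0 / C
    A_aug = np.vstack([A, np.full((1, k), w_con)])
    b_aug = np.append(b, w_con)
    w, _ = nnls(A_aug, b_aug)
    s = w.sum()
    if s <= 0:
        warnings.warn("NNLS returned the zero vector; returning uniform weights", stacklevel=2)
        return np.full(k, 1.0 / k)
    return w / s


def _solve_alpha(data: np.ndarray, Z: np.ndarray, C: float) -> np.ndarray:
    """Row-wise simplex-NNLS of each sample against the archetypes."""
    n = data.shape[0]
    k = Z.shape[0]
    design = Z.T  # D x K
    alpha = np.empty((n, k))
    for i in range(n):
        alpha[i] = constrained_simplex_nnls(design, data[i], C)
    return alpha


def _solve_beta(data: np.ndarray, alpha: np.ndarray, C: float) -> np.ndarray:
    """Update beta so Z = data^T beta best reconstructs the data given alpha.

    The unconstrained optimum Z* solves the least-squares problem
    alpha Z ~ data; each of its rows is then projected onto the convex
    hull of the data rows by a simplex-NNLS over samples.
    """
    z_star, *_ = np.linalg.lstsq(alpha, data, rcond=None)
    design = data.T  # D x N
    n, k = data.shape[0], alpha.shape[1]
    beta = np.empty((n, k))
    for j in range(k):
        beta[:, j] = constrained_simplex_nnls(design, z_star[j], C)
    return beta


def rss_of(data: np.ndarray, alpha: np.ndarray, Z: np.ndarray) -> float:
    """Residual sum of squares ||data - alpha Z||_F^2."""
    data = np.asarray(data, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if alpha.shape[0] != data.shape[0] or alpha.shape[1] != Z.shape[0] or Z.shape[1] != data.shape[1]:
        raise ValueError(f"shape mismatch: data {data.shape}, alpha {alpha.shape}, Z {Z.shape}")
    resid = data - alpha @ Z
    return float(np.einsum("ij,ij->", resid, resid))


def explained_variance(y: np.ndarray, yhat: np.ndarray) -> float:
    """EV(Y, Yhat) = 1 - Var(Y - Yhat) / Var(Y), variances pooled over all entries."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("Var(y) is zero; explained variance undefined")
    return 1.0 - float(np.var(y - yhat)) / var_y


def _initial_archetypes(data: np.ndarray, cfg: AAConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.init == "furthest_sum":
        idx = furthest_sum_init(data, cfg.K, rng)
        return data[idx].copy()
    mode = "uniform" if cfg.init == "random_uniform" else "sample"
    return random_init(data, cfg.K, mode=mode, seed=rng)


def _fit_once(data: np.ndarray, cfg: AAConfig, Z0: np.ndarray) -> AAFit:
    n = data.shape[0]
    # express the initial archetypes through beta so Z = data^T beta holds
    # from iteration zero (exact when Z0 rows are data rows)
    beta = np.empty((n, cfg.K))
    for j in range(cfg.K):
        beta[:, j] = constrained_simplex_nnls(data.T, Z0[j], cfg.C)
    Z = (data.T @ beta).T
    alpha = _solve_alpha(data, Z, cfg.C)
    rss = rss_of(data, alpha, Z)
    trace = [rss]
    converged = False
    for _ in range(cfg.max_iter):
        # dead-archetype rescue: re-seed unused archetypes to the worst-fit sample
        mass = alpha.sum(axis=0)
        if (mass < _ALPHA_EPS).any():
            resid = np.linalg.norm(data - alpha @ Z, axis=1)
            for j in np.flatnonzero(mass < _ALPHA_EPS):
                beta = beta.copy()
                beta[:, j] = 0.0
                beta[int(np.argmax(resid)), j] = 1.0
                logger.debug("re-seeded dead archetype %d", j)
            Z = (data.T @ beta).T
            alpha = _solve_alpha(data, Z, cfg.C)

        beta_new = _solve_beta(data, alpha, cfg.C)
        Z_new = (data.T @ beta_new).T
        alpha_new = _solve_alpha(data, Z_new, cfg.C)
        rss_new = rss_of(data, alpha_new, Z_new)
        if rss_new > rss:
            # constrained sub-solves are approximate; never accept an uphill step
            converged = True
            break
        alpha, beta, Z = alpha_new, beta_new, Z_new
        rss_prev, rss = rss, rss_new
        trace.append(rss)
        if rss_prev <= 0 or abs(rss - rss_prev) / rss_prev <= cfg.tol:
            converged = True
            break
    ev = explained_variance(data, alpha @ Z) if np.var(data) > 0 else float("nan")
    return AAFit(
        alpha=alpha,
        beta=beta,
        Z=Z,
        rss_trace=trace,
        explained_variance=ev,
        converged=converged,
        n_iter=len(trace) - 1,
        config=cfg,
    )


def fit(
    data: np.ndarray,
    cfg: AAConfig,
    init_indices: np.ndarray | None = None,
) -> AAFit:
    """Fit Archetypal Analysis to an N x D data matrix.

    Alternates (i) solving every alpha row by simplex-NNLS against the
    current archetypes and (ii) updating beta (hence Z = data^T beta) by
    least squares followed by a simplex-NNLS projection of each archetype
    onto the convex hull of the rows.  RSS is recomputed each iteration
    and the alternation stops when its relative change drops to ``tol``
    or after ``max_iter`` iterations; the trace of accepted RSS values is
    non-increasing by construction.

    ``init_indices`` overrides the configured initializer with explicit
    sample indices, which is how two runs on rotated copies of the same
    data can be started identically.

    With ``cfg.restarts > 1`` the fit is repeated with independent
    sub-seeds and the lowest-RSS result is returned.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D")
    if not np.isfinite(data).all():
        raise ValueError("data contains non-finite values")
    n = data.shape[0]
    if cfg.K > n:
        raise ValueError(f"K={cfg.K} exceeds N={n}")

    best: AAFit | None = None
    for r in range(cfg.restarts):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(r,)))
        if init_indices is not None:
            idx = np.asarray(init_indices, dtype=int)
            if idx.shape != (cfg.K,):
                raise ValueError(f"init_indices must have shape ({cfg.K},)")
            Z0 = data[idx].copy()
        else:
            Z0 = _initial_archetypes(data, cfg, rng)
        result = _fit_once(data, cfg, Z0)
        if best is None or result.rss < best.rss:
            best = result
    assert best is not None
    return best


def archetypes_in_snp_space(g: GenotypeMatrix, beta: np.ndarray) -> np.ndarray:
    """Express archetypes as K x M dosage-like rows: row k = sum_i beta_ik x_i.

    Convexity of the beta columns guarantees every entry lies within the
    observed per-variant dosage range — archetypes are mixtures of real
    individuals, never extrapolations.
    """
    beta = np.asarray(beta, dtype=float)
    if (beta < -1e-12).any():
        raise ValueError("beta has negative entries")
    sums = beta.sum(axis=0)
    if np.abs(sums - 1.0).max() > 1e-4:
        raise ValueError("beta columns must sum to 1")
    return (g.dosages.T @ beta).T
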