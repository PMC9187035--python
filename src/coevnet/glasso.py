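"""Sparse inverse covariance estimation of coupling matrices.

The empirical coupling matrix S is regularized by the graphical LASSO,

    Theta_hat = argmin_Theta  tr(S Theta) - log det(Theta) + rho * ||Theta||_1,

which yields both an estimated covariance matrix Sigma_hat and its sparse
inverse Theta_hat. The penalty weight rho is selected automatically as the
smallest value on a 0.01 grid inside (0.01, 0.99) at which the solver
converges with fully finite outputs, located by bisection under the
assumption that feasibility is monotone in rho (stronger regularization can
only make the problem better conditioned).

The solver is scikit-learn's coordinate-descent graphical lasso, which (like
PSICOV) leaves the diagonal of Theta unpenalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .covariance import CovarianceMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_ITER = 100
RHO_LO = 0.01
RHO_HI = 0.99


class InfeasibleError(RuntimeError):
    """No penalty in the search range produced fully defined estimates."""


@dataclass
class GlassoResult:
    """Graphical-LASSO estimates for one input matrix and penalty."""

    S: np.ndarray
    sigma: np.ndarray
    theta: np.ndarray
    rho: float
    converged: bool
    n_iter: int

    @property
    def feasible(self) -> bool:
        """Converged with no NaN/Inf anywhere in either estimate."""
        return (
            self.converged
            and bool(np.isfinite(self.sigma).all())
            and bool(np.isfinite(self.theta).all())
        )


def glasso_estimate(
    S: np.ndarray,
    rho: float,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = 1e-6,
    enet_tol: float = 1e-8,
) -> GlassoResult:
    """Estimate (Sigma_hat, Theta_hat) at a fixed penalty.

    Solver failures (non-convergence within ``max_iter``, numerical blow-ups,
    non-SPD intermediate results) are reported through the ``converged`` flag
    and NaN-filled outputs rather than raised, so callers can probe
    feasibility. Structural input problems (asymmetry, NaN) do raise.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("input matrix must be square")
    if not np.allclose(S, S.T, atol=1e-10, rtol=0):
        raise ValueError("input matrix must be symmetric")
    if np.isnan(S).any():
        raise ValueError("input matrix contains NaN; impute masked entries first")
    S = (S + S.T) / 2.0
    nan = np.full_like(S, np.nan)
    try:
        with warnings.catch_warnings():
            # inner-lasso ConvergenceWarnings are advisory; convergence of the
            # outer problem is judged from the returned iteration count
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            sigma, theta, n_iter = graphical_lasso(
                S, alpha=rho, max_iter=max_iter, tol=tol, enet_tol=enet_tol,
                return_n_iter=True,
            )
    except (FloatingPointError, ValueError, np.linalg.LinAlgError) as exc:
        logger.debug("glasso failed at rho=%.3f: %s", rho, exc)
        return GlassoResult(S, nan, nan, rho, converged=False, n_iter=max_iter)
    return GlassoResult(S, sigma, theta, rho, converged=n_iter < max_iter, n_iter=n_iter)


def auto_rho(
    S: np.ndarray,
    resolution: float = 0.01,
    lo: float = RHO_LO,
    hi: float = RHO_HI,
    max_iter: int = DEFAULT_MAX_ITER,
) -> float:
    """Smallest grid penalty in (lo, hi) with fully defined estimates.

    Bisection over the ``resolution``-spaced grid, assuming feasibility is
    monotone in rho; equivalent to a linear grid scan under that assumption
    but logarithmically cheaper.
    """
    scale = round(1.0 / resolution)
    k_lo = max(1, round(lo * scale))
    k_hi = round(hi * scale)

    def feasible(k: int) -> bool:
        return glasso_estimate(S, k / scale, max_iter=max_iter).feasible

    if feasible(k_lo):
        return k_lo / scale
    if not feasible(k_hi):
        raise InfeasibleError(
            f"graphical lasso produced undefined estimates for every rho in "
            f"({lo}, {hi}) at resolution {resolution}"
        )
    # invariant: k_lo infeasible, k_hi feasible
    while k_hi - k_lo > 1:
        mid = (k_lo + k_hi) // 2
        if feasible(mid):
            k_hi = mid
        else:
            k_lo = mid
    return k_hi / scale


@dataclass
class RegularizedMatrices:
    """gLASSO-processed coupling matrix plus its sparse inverse."""

    covariance: CovarianceMatrix
    precision: np.ndarray
    rho: float
    n_imputed: int


def impute_masked(matrix: CovarianceMatrix) -> tuple[np.ndarray, int]:
    """Replace masked entries: 0 off-diagonal (independence), 1 on the diagonal.

    A zero diagonal would make the log-det objective undefined at every rho,
    so masked self-couplings take the metric's natural self-coupling scale.
    """
    S = np.where(matrix.mask, 0.0, matrix.values)
    n_imputed = int(matrix.mask.sum())
    diag_masked = np.diag(matrix.mask)
    if diag_masked.any():
        idx = np.where(diag_masked)[0]
        S[idx, idx] = 1.0
    return S, n_imputed


def regularized_matrix(
    matrix: CovarianceMatrix,
    rho: float | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RegularizedMatrices:
    """Apply the graphical LASSO to a coupling matrix.

    When ``rho`` is None it is selected by :func:`auto_rho`. Masked input
    entries are imputed (and counted) before estimation. The returned
    covariance matrix carries provenance ``glasso(rho=...)`` in its metadata.
    """
    S, n_imputed = impute_masked(matrix)
    if n_imputed:
        logger.info("imputed %d masked entries before gLASSO", n_imputed)
    if rho is None:
        rho = auto_rho(S, max_iter=max_iter)
    result = glasso_estimate(S, rho, max_iter=max_iter)
    if not result.feasible:
        raise InfeasibleError(f"graphical lasso failed at rho={rho}")
    meta = dict(matrix.meta)
    meta["regularization"] = f"glasso(rho={rho:g})"
    meta["rho"] = rho
    meta["n_imputed"] = n_imputed
    out = CovarianceMatrix(
        values=result.sigma,
        metric=matrix.metric,
        alphabet=matrix.alphabet,
        post_processed=matrix.post_processed,
        mask=np.zeros_like(matrix.mask),
        residues=matrix.residues,
        meta=meta,
    )
    return RegularizedMatrices(
        covariance=out, precision=result.theta, rho=rho, n_imputed=n_imputed
    )
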