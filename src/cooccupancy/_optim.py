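"""Shared maximum-likelihood machinery: multi-start quasi-Newton optimisation,
observed-information variance matrices, and exact pattern aggregation.

Occupancy likelihoods factor over sites, so sites with identical (design row,
history) patterns contribute identical terms; collapsing duplicates to
weighted unique rows makes intercept-only and categorical-covariate fits
O(#patterns) per evaluation without changing the objective.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

# |logit-scale parameter| above this is treated as a boundary estimate
LOGIT_BOUND = 15.0
_TINY = 1e-300


def aggregate_patterns(*arrays: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Collapse rows identical across all given per-site arrays.

    Each array has first dimension n_sites.  Returns the subset arrays
    (unique patterns) and a weight vector of multiplicities.  NaNs compare
    equal (encoded by a sentinel) so missing-data patterns aggregate too.
    """
    n = arrays[0].shape[0]
    flat = []
    for a in arrays:
        a2 = np.asarray(a, dtype=float).reshape(n, -1).copy()
        a2[np.isnan(a2)] = -9.87654321e30
        flat.append(a2)
    key = np.concatenate(flat, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return [np.asarray(a)[idx] for a in arrays], counts.astype(float)


def numerical_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    m = x.size
    h = step * (1.0 + np.abs(x))
    hess = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                hess[i, i] = (fun(xp) - 2.0 * fun(x) + fun(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] += [-h[i], -h[j]]
                hess[i, j] = hess[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return hess


def safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, _TINY))


def multistart_minimize(nll, n_params: int, n_starts: int, seed: int):
    """Minimise ``nll`` from dispersed starting points; best optimum wins.

    Start 1 is the origin (all probabilities 0.5 on the logit scale); the
    rest are seeded N(0, 1.5) draws.  Coefficients are box-bounded at the
    logit boundary so separation-prone sparse data stay finite.
    """
    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_params)]
    starts += [rng.normal(0.0, 1.5, size=n_params) for _ in range(max(0, n_starts - 1))]
    bounds = [(-LOGIT_BOUND, LOGIT_BOUND)] * n_params
    best = None
    for x0 in starts:
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or (res.fun < best.fun - 1e-10):
            best = res
    return best


def fit_summary(nll, result, boundary_tol: float = 0.01):
    """Hessian-based variance matrix and convergence diagnosis at an optimum.

    Returns (vcov, converged, boundary, message).  Non-convergence means:
    optimiser failure, a boundary estimate (|coef| at the logit bound), or a
    non-invertible / non-PD observed information.
    """
    x = result.x
    boundary = bool(np.any(np.abs(x) >= LOGIT_BOUND - boundary_tol))
    vcov = None
    message = "converged"
    converged = bool(result.success)
    if not converged:
        message = f"optimizer failure: {result.message}"
    if boundary:
        converged = False
        message = "boundary estimate (|logit parameter| at bound)"
    if converged:
        try:
            hess = numerical_hessian(nll, x)
            if not np.all(np.isfinite(hess)):
                raise np.linalg.LinAlgError("non-finite Hessian")
            vcov = np.linalg.inv(hess)
            if np.any(np.diag(vcov) <= 0):
                raise np.linalg.LinAlgError("information matrix not positive definite")
            vcov = 0.5 * (vcov + vcov.T)
        except np.linalg.LinAlgError as exc:
            converged = False
            vcov = None
            message = f"Hessian not usable: {exc}"
    return vcov, converged, boundary, message
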