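"""Shared bounded least-squares machinery for the kinetic fitters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares


@dataclass
class LsqFit:
    """Best-of-multistart bounded least-squares solution."""

    x: np.ndarray
    rss: float
    se: np.ndarray            # Gauss-Newton standard errors (nan if singular)
    converged: bool
    at_bound: np.ndarray      # per-parameter: within 1% of a box edge
    n_obs: int


def _standard_errors(jac: np.ndarray, rss: float, n_obs: int) -> np.ndarray:
    n_par = jac.shape[1]
    dof = max(n_obs - n_par, 1)
    try:
        # pinv tolerates frozen parameters (all-zero jacobian columns)
        jtj_inv = np.linalg.pinv(jac.T @ jac)
        var = np.diag(jtj_inv) * rss / dof
        return np.sqrt(np.maximum(var, 0.0))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


def multistart_least_squares(residual: Callable[[np.ndarray], np.ndarray],
                             starts: Sequence[Sequence[float]],
                             lower: Sequence[float],
                             upper: Sequence[float]) -> LsqFit:
    """Run bounded trust-region least squares from several starts, keep the best.

    ``residual`` returns the weighted residual vector; standard errors come
    from the Gauss-Newton covariance approximation at the optimum.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    best = None
    any_ok = False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        try:
            res = least_squares(residual, x0, bounds=(lower, upper),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        any_ok = any_ok or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        n_par = len(lower)
        return LsqFit(x=np.full(n_par, np.nan), rss=np.nan,
                      se=np.full(n_par, np.nan), converged=False,
                      at_bound=np.zeros(n_par, dtype=bool), n_obs=0)
    rss = float(2.0 * best.cost)
    se = _standard_errors(best.jac, rss, best.fun.size)
    span = upper - lower
    at_bound = ((best.x - lower) < 0.01 * span) | ((upper - best.x) < 0.01 * span)
    return LsqFit(x=best.x, rss=rss, se=se, converged=bool(any_ok),
                  at_bound=at_bound, n_obs=int(best.fun.size))
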