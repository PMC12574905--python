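"""Shared quantitative metrics.

Conventions: relative error RE(a) = ||a_emp - a_est|| / ||a_emp|| with the l2
norm for vectors and the Frobenius norm for matrices; for structural
connectivity matrices the (structurally zero) diagonal is excluded via
``selection='offdiag'``.  Functional connectivity is the Pearson correlation
matrix; FC similarity is the Pearson correlation of strictly-upper-triangle
entries.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import OptimizeWarning, curve_fit

from .exceptions import StabilityError, ValidationError

__all__ = [
    "relative_error",
    "lyapunov_covariance",
    "functional_connectivity",
    "fc_similarity",
    "element_correlation",
    "autocorr_timescale",
]


def _select(a: np.ndarray, selection: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if selection == "vector":
        return a.ravel()
    if selection == "full":
        return a.ravel()
    if selection == "offdiag":
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("offdiag selection needs a square matrix")
        mask = ~np.eye(a.shape[0], dtype=bool)
        return a[mask]
    raise ValidationError(f"unknown selection {selection!r}")


def relative_error(a_emp, a_est, selection: str = "full") -> float:
    """RE = ||a_emp - a_est|| / ||a_emp|| over the selected elements."""
    x = _select(np.asarray(a_emp), selection)
    y = _select(np.asarray(a_est), selection)
    if x.shape != y.shape:
        raise ValidationError("shapes do not match")
    ref = np.linalg.norm(x)
    if ref == 0:
        raise ValidationError("zero-norm reference: relative error undefined")
    return float(np.linalg.norm(x - y) / ref)


def lyapunov_covariance(J: np.ndarray, sigma: float) -> np.ndarray:
    """Stationary covariance of dx = J x dt + sigma dW: solves J S + S J^T + sigma^2 I = 0."""
    J = np.asarray(J, dtype=float)
    abscissa = float(np.max(np.linalg.eigvals(J).real))
    if abscissa >= 0:
        raise StabilityError(f"J is not stable (max Re lambda = {abscissa:.3e})")
    S = solve_continuous_lyapunov(J, -sigma**2 * np.eye(J.shape[0]))
    S = 0.5 * (S + S.T)
    if np.min(np.linalg.eigvalsh(S)) <= 0:
        raise StabilityError("Lyapunov solution is not positive definite")
    return S


def functional_connectivity(arg) -> np.ndarray:
    """Pearson correlation matrix from a trajectory or a covariance matrix.

    Channels with zero variance yield NaN rows/columns (unit diagonal kept).
    """
    if hasattr(arg, "S"):
        X = np.asarray(arg.S, dtype=float)
        if X.shape[0] < 2:
            raise ValidationError("need at least 2 samples")
        Sig = np.cov(X, rowvar=False)
    else:
        Sig = np.asarray(arg, dtype=float)
        if Sig.ndim != 2 or Sig.shape[0] != Sig.shape[1]:
            raise ValidationError("covariance must be square")
    sd = np.sqrt(np.diag(Sig))
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = Sig / np.outer(sd, sd)
    np.fill_diagonal(fc, 1.0)
    return fc


def _upper(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    iu, ju = np.triu_indices(a.shape[0], k=1)
    return a[iu, ju]


def fc_similarity(fc_a: np.ndarray, fc_b: np.ndarray) -> float:
    """Pearson correlation between strictly-upper-triangle FC entries."""
    x, y = _upper(fc_a), _upper(fc_b)
    if x.shape != y.shape:
        raise ValidationError("FC shapes differ")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("degenerate variance in FC comparison")
    return float(np.corrcoef(x, y)[0, 1])


def element_correlation(A: np.ndarray, B: np.ndarray, selection: str = "full") -> float:
    """Pearson correlation of matrix elements over the chosen selection."""
    x = _select(np.asarray(A), selection)
    y = _select(np.asarray(B), selection)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("degenerate variance in element correlation")
    return float(np.corrcoef(x, y)[0, 1])


def autocorr_timescale(traj, max_lag_seconds: float | None = None) -> np.ndarray:
    """Per-region autocorrelation timescale (s) by exponential fit.

    The autocorrelation of each channel is fit with exp(-lag/tau) over lags up
    to three times its first 1/e crossing (amplitude-invariant by
    construction).  Raises if a channel's autocorrelation never decays below
    1/e within the usable lag range.
    """
    X = np.asarray(traj.S, dtype=float)
    dt = traj.dt
    T, n = X.shape
    max_lag = T // 4 if max_lag_seconds is None else min(int(max_lag_seconds / dt), T // 2)
    taus = np.empty(n)
    X = X - X.mean(axis=0)
    for i in range(n):
        x = X[:, i]
        var = np.dot(x, x) / T
        if var == 0:
            raise ValidationError(f"zero-variance channel {i}")
        lags = np.arange(1, max_lag)
        ac = np.array([np.dot(x[:-k], x[k:]) / ((T - k) * var) for k in lags])
        below = np.flatnonzero(ac < np.exp(-1.0))
        if below.size == 0:
            raise ValidationError(f"autocorrelation of channel {i} does not decay within range")
        k_e = below[0] + 1
        k_fit = min(3 * k_e, max_lag - 1)
        t_fit = lags[:k_fit] * dt
        y_fit = ac[:k_fit]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            (tau,), _ = curve_fit(lambda t, tau: np.exp(-t / tau), t_fit, y_fit,
                                  p0=[k_e * dt], maxfev=10000)
        taus[i] = tau
    return taus
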