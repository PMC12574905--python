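"""Temporal and spatial reconstruction.

Temporal step (dynamical differential covariance): for activity fluctuating
around a stable fixed point, ``J_hat = <dS/dt, S> <S, S>^{-1}`` is an unbiased
estimate of the Jacobian of the linearized dynamics.

Spatial step: with the symmetric structural constraint
``W = (C + C^T)/2`` and the factorization ``J_ij = h_i C_ij`` (i != j), the
unknown inverse heterogeneities ``y_i = 1/h_i`` satisfy the overdetermined
linear system ``J_hat_ij y_i + J_hat_ji y_j = 2 W_ij``, solved by least
squares; then ``h_i = 1/y_i`` and ``C_hat_ij = y_i J_hat_ij``.

Two degenerate baselines quantify what each ingredient buys: ignoring
asymmetry (per-row scalar regression of J onto W) and ignoring heterogeneity
(scalar h, alternating minimization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import simulate as _sim
from .dynamics import _invert_gain, activation_gain
from .exceptions import (
    IdentifiabilityError,
    StabilityError,
    ValidationError,
)
__all__ = [
    "Decomposition",
    "RegressionSystem",
    "ddc_estimate",
    "build_regression",
    "spatial_separation",
    "baseline_no_asymmetry",
    "baseline_no_heterogeneity",
    "recover_modelA_params",
    "recover_modelB_params",
    "resimulate_linear",
]


@dataclass
class Decomposition:
    """Estimated Jacobian and its separation into heterogeneity and asymmetry."""

    J_hat: np.ndarray
    y_hat: np.ndarray  # 1/h
    h_hat: np.ndarray
    C_hat: np.ndarray  # zero diagonal
    cond_M: float
    residual: float
    negative_y: bool = False

    def save(self, path) -> None:
        with h5py.File(str(path), "w") as f:
            g = f.create_group("decomposition")
            for name in ("J_hat", "y_hat", "h_hat", "C_hat"):
                g.create_dataset(name, data=getattr(self, name))
            g.attrs["cond_M"] = self.cond_M
            g.attrs["residual"] = self.residual
            g.attrs["negative_y"] = self.negative_y

    @classmethod
    def load(cls, path) -> "Decomposition":
        with h5py.File(str(path), "r") as f:
            g = f["decomposition"]
            return cls(
                J_hat=g["J_hat"][()],
                y_hat=g["y_hat"][()],
                h_hat=g["h_hat"][()],
                C_hat=g["C_hat"][()],
                cond_M=float(g.attrs["cond_M"]),
                residual=float(g.attrs["residual"]),
                negative_y=bool(g.attrs["negative_y"]),
            )


@dataclass
class RegressionSystem:
    """Design of the spatial-separation least squares, one row per node pair."""

    M: np.ndarray
    W_vec: np.ndarray
    pairs: list = field(default_factory=list)


def ddc_estimate(traj, derivative: str = "forward") -> np.ndarray:
    """Jacobian estimate J_hat = <dS/dt, S> <S, S>^{-1} from a trajectory.

    S is mean-centered; the derivative is a forward difference
    (S(t+dt) - S(t))/dt paired with S(t) (``derivative='central'`` pairs a
    central difference with the midpoint sample).  Raises on an
    ill-conditioned sample covariance (cond > 1e12).
    """
    X = np.asarray(traj.S, dtype=float)
    T, n = X.shape
    if T < 10 * n:
        raise ValidationError(f"need at least {10 * n} samples, got {T}")
    X = X - X.mean(axis=0)
    dt = traj.dt
    if derivative == "forward":
        D = (X[1:] - X[:-1]) / dt
        B = X[:-1]
    elif derivative == "central":
        D = (X[2:] - X[:-2]) / (2.0 * dt)
        B = X[1:-1]
    else:
        raise ValidationError(f"unknown derivative scheme {derivative!r}")
    m = B.shape[0]
    cross = D.T @ B / m
    cov = B.T @ B / m
    cond = np.linalg.cond(cov)
    if cond > 1e12:
        raise IdentifiabilityError(f"sample covariance ill-conditioned (cond = {cond:.3e})")
    return np.linalg.solve(cov.T, cross.T).T


def build_regression(J_hat: np.ndarray, W: np.ndarray) -> RegressionSystem:
    """Assemble M y = W_vec, one row J_ij y_i + J_ji y_j = 2 W_ij per pair i < j.

    Unordered pairs are used once: the ordered duplicates carry the same
    equation and would only rescale the normal equations.
    """
    J_hat = np.asarray(J_hat, dtype=float)
    W = np.asarray(W, dtype=float)
    if J_hat.shape != W.shape or J_hat.ndim != 2 or J_hat.shape[0] != J_hat.shape[1]:
        raise ValidationError("J_hat and W must be square matrices of equal shape")
    if not np.allclose(W, W.T, rtol=0, atol=1e-10):
        raise ValidationError("W must be symmetric")
    n = J_hat.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    M = np.zeros((iu.size, n))
    M[np.arange(iu.size), iu] = J_hat[iu, ju]
    M[np.arange(iu.size), ju] = J_hat[ju, iu]
    return RegressionSystem(M=M, W_vec=2.0 * W[iu, ju], pairs=list(zip(iu, ju)))


def spatial_separation(J_hat: np.ndarray, W: np.ndarray) -> Decomposition:
    """Least-squares separation of J_hat into h (heterogeneity) and C (asymmetry).

    Negative y entries are surfaced through ``negative_y`` (they arise in
    noise-dominated regimes), never clipped.
    """
    reg = build_regression(J_hat, W)
    n = J_hat.shape[0]
    y, res, rank, _ = np.linalg.lstsq(reg.M, reg.W_vec, rcond=None)
    if rank < n:
        raise IdentifiabilityError(f"design rank {rank} < {n}: separation not identifiable")
    cond_M = float(np.linalg.cond(reg.M))
    residual = float(np.linalg.norm(reg.M @ y - reg.W_vec))
    negative = bool(np.any(y <= 0))
    if negative:
        warnings.warn("spatial separation produced non-positive y entries")
    with np.errstate(divide="ignore"):
        h = 1.0 / y
    C_hat = y[:, None] * J_hat
    np.fill_diagonal(C_hat, 0.0)
    return Decomposition(
        J_hat=np.asarray(J_hat, float),
        y_hat=y,
        h_hat=h,
        C_hat=C_hat,
        cond_M=cond_M,
        residual=residual,
        negative_y=negative,
    )


def baseline_no_asymmetry(J_hat: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Heterogeneity under the (mis)assumption of symmetric ground-truth SC.

    Per-row scalar least squares of the off-diagonal J row onto the W row:
    h_i = (W_i W_i^T)^{-1} W_i J_i.
    """
    J_hat = np.asarray(J_hat, dtype=float)
    W = np.asarray(W, dtype=float)
    n = J_hat.shape[0]
    h = np.empty(n)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        wi = W[i][mask[i]]
        ji = J_hat[i][mask[i]]
        denom = wi @ wi
        if denom == 0:
            raise ValidationError(f"all-zero W row {i}: h undefined for that region")
        h[i] = (wi @ ji) / denom
    return h


def baseline_no_heterogeneity(
    J_hat: np.ndarray,
    W: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
):
    """Asymmetric SC under the (mis)assumption of homogeneous nodes.

    Minimizes L(C; J, W) = ||J - h C||_F^2 + ||C + C^T - 2 W||_F^2 over a
    scalar h and a zero-diagonal C, restricted to off-diagonal entries, by
    alternating exact solves: C given h is a per-pair 2x2 linear system, h
    given C a scalar projection.  Returns (h, C_hat, loss_history); the loss
    is non-increasing by construction.
    """
    J = np.asarray(J_hat, dtype=float)
    W = np.asarray(W, dtype=float)
    n = J.shape[0]
    off = ~np.eye(n, dtype=bool)

    def loss(h, C):
        return float(
            np.sum((J[off] - h * C[off]) ** 2) + np.sum(((C + C.T - 2.0 * W)[off]) ** 2)
        )

    C = W.copy()
    np.fill_diagonal(C, 0.0)
    h = float(np.sum(J[off] * C[off]) / np.sum(C[off] ** 2))
    history = [loss(h, C)]
    iu, ju = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        # exact C update: per unordered pair, solve the symmetric 2x2 system
        a_diag = h * h + 2.0
        rhs_u = h * J[iu, ju] + 4.0 * W[iu, ju]
        rhs_l = h * J[ju, iu] + 4.0 * W[iu, ju]
        det = a_diag**2 - 4.0
        cu = (a_diag * rhs_u - 2.0 * rhs_l) / det
        cl = (a_diag * rhs_l - 2.0 * rhs_u) / det
        C = np.zeros_like(C)
        C[iu, ju] = cu
        C[ju, iu] = cl
        # exact h update: scalar projection of J onto C
        denom = np.sum(C[off] ** 2)
        if denom == 0:
            break
        h = float(np.sum(J[off] * C[off]) / denom)
        history.append(loss(h, C))
        if history[-1] > history[-2] * (1 + 1e-12) + 1e-300:
            raise ValidationError("alternating minimization increased the loss")
        if history[-2] - history[-1] <= tol * max(history[-2], 1e-300):
            break
    return h, C, np.asarray(history)


def _known(params_known, name):
    if isinstance(params_known, dict):
        return params_known[name]
    return getattr(params_known, name)


@dataclass
class ParameterRecovery:
    """Recovered per-region parameters with per-region failure reporting."""

    first: np.ndarray  # w_hat (Model A) or tau_hat (Model B)
    second: np.ndarray  # I_hat (Model A) or b_hat (Model B)
    x_star_hat: np.ndarray
    failed: list = field(default_factory=list)


def recover_modelA_params(
    dec: Decomposition,
    S_bar: np.ndarray,
    params_known,
    C_hat: np.ndarray | None = None,
) -> ParameterRecovery:
    """Recover Model A's w_i and I_i from a decomposition and the mean state.

    w_hat_i = G y_i J_ii + G y_i / (tau_s (1 - S_i)); the steady input x_i* is
    the unique root of H'(x) = 1/(gamma G (1 - S_i) y_i) (the gain is strictly
    increasing); then I_hat_i = x_i* - w_hat_i S_i - G sum_j C_hat_ij S_j.
    Regions whose target gain falls outside (0, a) are reported in ``failed``
    (NaN entries) while the rest proceed.
    """
    tau_s = _known(params_known, "tau_s")
    gamma = _known(params_known, "gamma")
    a = _known(params_known, "a")
    d = _known(params_known, "d")
    G = _known(params_known, "G")
    S_bar = np.asarray(S_bar, dtype=float)
    if np.any((S_bar <= 0) | (S_bar >= 1)):
        raise ValidationError("S_bar must lie in (0, 1)")
    if C_hat is None:
        C_hat = dec.C_hat
    y = dec.y_hat
    J_diag = np.diag(dec.J_hat)
    n = S_bar.size
    w_hat = G * y * J_diag + G * y / (tau_s * (1.0 - S_bar))
    x_hat = np.full(n, np.nan)
    I_hat = np.full(n, np.nan)
    failed = []
    coupling = G * (C_hat @ S_bar)
    for i in range(n):
        target = 1.0 / (gamma * G * (1.0 - S_bar[i]) * y[i])
        if not (0.0 < target < a):
            failed.append((i, f"target gain {target:.4g} outside (0, {a})"))
            w_hat[i] = np.nan
            continue
        v = _invert_gain(target, a, d)
        x_hat[i] = (v / d + _known(params_known, "b")) / a
        I_hat[i] = x_hat[i] - w_hat[i] * S_bar[i] - coupling[i]
    return ParameterRecovery(first=w_hat, second=I_hat, x_star_hat=x_hat, failed=failed)


def recover_modelB_params(dec: Decomposition, S_bar: np.ndarray, params_known) -> ParameterRecovery:
    """Recover Model B's tau_i and b_i from a decomposition and the mean state.

    1/tau_i = (1 - S_i)(w h_i / G - J_ii); b_i solves
    H'(x'_i; b_i) = h_i / (gamma G (1 - S_i)) at the known steady input
    x'_i = w S_i + G sum_j C_hat_ij S_j + I (monotone in b_i, unique root).
    """
    w = _known(params_known, "w")
    I = _known(params_known, "I")
    gamma = _known(params_known, "gamma")
    a = _known(params_known, "a")
    d = _known(params_known, "d")
    G = _known(params_known, "G")
    S_bar = np.asarray(S_bar, dtype=float)
    h = dec.h_hat
    if np.any(h <= 0):
        raise ValidationError("non-positive h_hat: Model B recovery requires h > 0")
    J_diag = np.diag(dec.J_hat)
    inv_tau = (1.0 - S_bar) * (w * h / G - J_diag)
    if np.any(inv_tau <= 0):
        raise ValidationError("recovered 1/tau non-positive")
    tau_hat = 1.0 / inv_tau
    x_prime = w * S_bar + G * (dec.C_hat @ S_bar) + I
    n = S_bar.size
    b_hat = np.full(n, np.nan)
    failed = []
    for i in range(n):
        target = h[i] / (gamma * G * (1.0 - S_bar[i]))
        if not (0.0 < target < a):
            failed.append((i, f"target gain {target:.4g} outside (0, {a})"))
            continue
        v = _invert_gain(target, a, d)
        b_hat[i] = a * x_prime[i] - v / d
    return ParameterRecovery(first=tau_hat, second=b_hat, x_star_hat=x_prime, failed=failed)


def resimulate_linear(dec: Decomposition, sigma: float, duration: float,
                      dt: float = 0.001, seed: int = 0, burn_in: float = 50.0):
    """Simulate dx/dt = J_hat x + sigma nu around 0 (x is S - S*)."""
    abscissa = float(np.max(np.linalg.eigvals(dec.J_hat).real))
    if abscissa >= 0:
        raise StabilityError(f"estimated Jacobian unstable (max Re lambda = {abscissa:.3e})")
    return _sim.simulate_linear(dec.J_hat, sigma, duration, dt=dt, seed=seed, burn_in=burn_in)
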