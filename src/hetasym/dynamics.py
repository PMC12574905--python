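"""Heterogeneous mean-field cortical models and their linearizations.

Three reduced population models on a directed connectome ``C`` (``C[i, j]``
is the j -> i weight, ``G`` the global coupling):

* **Model A** -- one gating variable per region,
  ``dS_i/dt = -S_i/tau_s + gamma (1 - S_i) H(x_i) + sigma nu_i``,
  with transfer function ``H(x) = (a x - b) / (1 - exp(-d (a x - b)))`` and
  total current ``x_i = w_i S_i + G sum_j C_ij S_j + I_i``.  Heterogeneity
  lives in the recurrent strengths ``w_i`` and external currents ``I_i``.
* **Model B** -- same structure but heterogeneous time constants ``tau_i``
  and firing thresholds ``b_i``, with homogeneous scalar ``w`` and ``I``.
* **Model C** -- an excitatory and an inhibitory population per region; only
  excitatory populations project long range.

At a stable fixed point ``S*`` the Jacobian factorizes off the diagonal as
``J_ij = h_i C_ij`` with the effective heterogeneity
``h_i = gamma G (1 - S_i*) H'(x_i*)`` -- a single per-region scalar that
absorbs gain, gating saturation, and global coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .connectome import Connectome, GradientSpec, hierarchy_gradient
from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "ModelAParams",
    "ModelBParams",
    "ModelCParams",
    "FixedPoint",
    "GroundTruth",
    "default_modelA",
    "default_modelB",
    "default_modelC",
    "activation",
    "activation_gain",
    "drift",
    "find_fixed_point",
    "jacobian_modelA",
    "jacobian_modelB",
    "jacobian_modelC_full",
    "jeff_ground_truth",
    "effective_heterogeneity",
    "map_A_to_B",
    "bistability_scan",
    "eigen_frequencies",
]

# Table-level constants shared by the reduced models (units: s, nA, Hz).
TAU_S = 0.1
GAMMA = 0.641
SIGMA = 0.01
A_GAIN = 270.0
B_THRESH = 108.0
D_NONLIN = 0.154

W_RANGE = (0.0652, 0.1581)  # nA, ascending along the hierarchy
I_RANGE = (0.30, 0.33)  # nA, descending along the hierarchy

# Excitatory / inhibitory constants for the two-population model.
MODEL_C_CONST = dict(
    tau_E=0.1,
    tau_I=0.01,
    a_E=310.0,
    b_E=125.0,
    d_E=0.16,
    a_I=615.0,
    b_I=177.0,
    d_I=0.087,
    I_E=0.382,
    I_I=0.2674,
)
W_EE_RANGE = (0.126, 0.210)  # nA
W_IE_RANGE = (0.090, 0.150)  # nA


# ---------------------------------------------------------------------------
# Transfer function
# ---------------------------------------------------------------------------

_SERIES_CUTOFF = 1e-7


def _phi(v):
    """phi(v) = v / (1 - exp(-v)), evaluated stably on both tails.

    Removable singularity at v = 0 handled by a 2nd-order series to avoid
    catastrophic cancellation.
    """
    shape = np.shape(v)
    v = np.atleast_1d(np.asarray(v, dtype=float))
    out = np.empty_like(v)
    small = np.abs(v) < _SERIES_CUTOFF
    pos = (~small) & (v > 0)
    neg = (~small) & (v < 0)
    out[small] = 1.0 + v[small] / 2.0 + v[small] ** 2 / 12.0
    out[pos] = v[pos] / (1.0 - np.exp(-v[pos]))
    ev = np.exp(v[neg])  # multiply through by exp(v): avoids overflow for v << 0
    out[neg] = v[neg] * ev / (ev - 1.0)
    return out.reshape(shape)


def _phi_prime(v):
    """Derivative of phi; in (0, 1), monotone increasing, phi'(0) = 1/2."""
    shape = np.shape(v)
    v = np.atleast_1d(np.asarray(v, dtype=float))
    out = np.empty_like(v)
    small = np.abs(v) < _SERIES_CUTOFF
    pos = (~small) & (v > 0)
    neg = (~small) & (v < 0)
    out[small] = 0.5 + v[small] / 6.0
    e = np.exp(-v[pos])
    out[pos] = (1.0 - e - v[pos] * e) / (1.0 - e) ** 2
    ev = np.exp(v[neg])  # multiply num and denom by exp(2v)
    out[neg] = (ev * ev - ev - v[neg] * ev) / (ev - 1.0) ** 2
    return out.reshape(shape)


def activation(x, a=A_GAIN, b=B_THRESH, d=D_NONLIN):
    """Population transfer function H(x) = (ax - b)/(1 - exp(-d(ax - b))) in Hz.

    Total function of the input current x (nA); the removable singularity at
    ax = b evaluates to 1/d.
    """
    x = np.asarray(x, dtype=float)
    u = a * x - b
    res = _phi(d * u) / d
    return res if res.ndim else float(res)


def activation_gain(x, a=A_GAIN, b=B_THRESH, d=D_NONLIN):
    """Slope dH/dx in Hz/nA: strictly positive, increasing, a/2 at ax = b, -> a."""
    x = np.asarray(x, dtype=float)
    u = a * x - b
    res = a * _phi_prime(d * u)
    return res if res.ndim else float(res)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ModelAParams:
    """Model A: heterogeneous recurrent strength w_i and external current I_i."""

    conn: Connectome
    w: np.ndarray
    I: np.ndarray
    G: float = 0.8
    tau_s: float = TAU_S
    gamma: float = GAMMA
    sigma: float = SIGMA
    a: float = A_GAIN
    b: float = B_THRESH
    d: float = D_NONLIN

    def __post_init__(self):
        self.w = np.broadcast_to(np.asarray(self.w, float), (self.conn.n,)).copy()
        self.I = np.broadcast_to(np.asarray(self.I, float), (self.conn.n,)).copy()
        if self.tau_s <= 0 or self.gamma <= 0 or self.d <= 0 or self.a <= 0:
            raise ValidationError("tau_s, gamma, d, a must be positive")

    @property
    def n_state(self) -> int:
        return self.conn.n

    def total_input(self, S):
        return self.w * S + self.G * (self.conn.C @ S) + self.I

    def drift(self, S):
        S = np.asarray(S, float)
        if S.shape != (self.conn.n,):
            raise ValidationError(f"state must have shape ({self.conn.n},)")
        H = activation(self.total_input(S), self.a, self.b, self.d)
        return -S / self.tau_s + self.gamma * (1.0 - S) * H


@dataclass
class ModelBParams:
    """Model B: heterogeneous time constants tau_i and thresholds b_i."""

    conn: Connectome
    tau: np.ndarray
    b_vec: np.ndarray
    w: float
    I: float
    G: float = 0.8
    gamma: float = GAMMA
    sigma: float = SIGMA
    a: float = A_GAIN
    d: float = D_NONLIN

    def __post_init__(self):
        self.tau = np.broadcast_to(np.asarray(self.tau, float), (self.conn.n,)).copy()
        self.b_vec = np.broadcast_to(np.asarray(self.b_vec, float), (self.conn.n,)).copy()
        if np.any(self.tau <= 0):
            raise ValidationError("all tau must be positive")

    @property
    def n_state(self) -> int:
        return self.conn.n

    def total_input(self, S):
        return self.w * S + self.G * (self.conn.C @ S) + self.I

    def drift(self, S):
        S = np.asarray(S, float)
        if S.shape != (self.conn.n,):
            raise ValidationError(f"state must have shape ({self.conn.n},)")
        H = activation(self.total_input(S), self.a, self.b_vec, self.d)
        return -S / self.tau + self.gamma * (1.0 - S) * H


@dataclass
class ModelCParams:
    """Model C: coupled excitatory/inhibitory populations per region.

    Only the excitatory populations communicate long range; the state vector
    stacks the E block before the I block (length 2N).  ``w_EI`` (the
    inhibitory-to-excitatory weight) is stored as a vector so that feedback
    inhibition control can calibrate it per region.
    """

    conn: Connectome
    w_EE: np.ndarray
    w_IE: np.ndarray
    w_EI: np.ndarray = None
    G: float = 1.0
    gamma: float = GAMMA
    sigma: float = SIGMA
    tau_E: float = MODEL_C_CONST["tau_E"]
    tau_I: float = MODEL_C_CONST["tau_I"]
    a_E: float = MODEL_C_CONST["a_E"]
    b_E: float = MODEL_C_CONST["b_E"]
    d_E: float = MODEL_C_CONST["d_E"]
    a_I: float = MODEL_C_CONST["a_I"]
    b_I: float = MODEL_C_CONST["b_I"]
    d_I: float = MODEL_C_CONST["d_I"]
    I_E: float = MODEL_C_CONST["I_E"]
    I_I: float = MODEL_C_CONST["I_I"]

    def __post_init__(self):
        n = self.conn.n
        self.w_EE = np.broadcast_to(np.asarray(self.w_EE, float), (n,)).copy()
        self.w_IE = np.broadcast_to(np.asarray(self.w_IE, float), (n,)).copy()
        if self.w_EI is None:
            self.w_EI = np.ones(n)
        self.w_EI = np.broadcast_to(np.asarray(self.w_EI, float), (n,)).copy()
        if not (0 < self.tau_I < self.tau_E):
            raise ValidationError("need 0 < tau_I < tau_E")
        if min(self.a_E, self.a_I) <= 0:
            raise ValidationError("gains must be positive")

    @property
    def n_state(self) -> int:
        return 2 * self.conn.n

    def split(self, S):
        n = self.conn.n
        S = np.asarray(S, float)
        if S.shape != (2 * n,):
            raise ValidationError(f"state must have shape ({2 * n},)")
        return S[:n], S[n:]

    def inputs(self, S):
        SE, SI = self.split(S)
        xE = self.w_EE * SE + self.G * (self.conn.C @ SE) - self.w_EI * SI + self.I_E
        xI = self.w_IE * SE - SI + self.I_I
        return xE, xI

    def drift(self, S):
        SE, SI = self.split(S)
        xE, xI = self.inputs(S)
        HE = activation(xE, self.a_E, self.b_E, self.d_E)
        HI = activation(xI, self.a_I, self.b_I, self.d_I)
        dE = -SE / self.tau_E + self.gamma * (1.0 - SE) * HE
        dI = -SI / self.tau_I + HI  # inhibitory gating relaxes linearly, no (1 - S) factor
        return np.concatenate([dE, dI])


def default_modelA(conn: Connectome, G: float = 0.8, sigma: float = SIGMA) -> ModelAParams:
    """Model A with the standard constants and hierarchy gradients on ``conn``."""
    w = hierarchy_gradient(GradientSpec(*W_RANGE, n=conn.n, direction="ascending"))
    I = hierarchy_gradient(GradientSpec(*I_RANGE, n=conn.n, direction="descending"))
    return ModelAParams(conn=conn, w=w, I=I, G=G, sigma=sigma)


def default_modelC(conn: Connectome, G: float = 1.0, sigma: float = SIGMA) -> ModelCParams:
    """Model C with the standard E/I constants and ascending w_EE, w_IE gradients."""
    w_EE = hierarchy_gradient(GradientSpec(*W_EE_RANGE, n=conn.n, direction="ascending"))
    w_IE = hierarchy_gradient(GradientSpec(*W_IE_RANGE, n=conn.n, direction="ascending"))
    return ModelCParams(conn=conn, w_EE=w_EE, w_IE=w_IE, G=G, sigma=sigma)


# ---------------------------------------------------------------------------
# Fixed points and ground truth
# ---------------------------------------------------------------------------


@dataclass
class FixedPoint:
    """Steady state of a model instance with its derived local quantities."""

    S_star: np.ndarray
    x_star: np.ndarray
    H_star: np.ndarray  # rates at the fixed point (Hz)
    gain: np.ndarray  # dH/dx at x_star (Hz/nA)
    residual: float


@dataclass
class GroundTruth:
    """Exact Jacobian, effective heterogeneity and fixed point of a model."""

    J: np.ndarray
    h: np.ndarray
    fixed_point: FixedPoint


def drift(params, S):
    """Deterministic drift dS/dt of the given model at state S (noise excluded)."""
    return params.drift(S)


def _derived_at(params, S_star):
    if isinstance(params, ModelCParams):
        xE, xI = params.inputs(S_star)
        x = np.concatenate([xE, xI])
        H = np.concatenate(
            [
                activation(xE, params.a_E, params.b_E, params.d_E),
                activation(xI, params.a_I, params.b_I, params.d_I),
            ]
        )
        g = np.concatenate(
            [
                activation_gain(xE, params.a_E, params.b_E, params.d_E),
                activation_gain(xI, params.a_I, params.b_I, params.d_I),
            ]
        )
    else:
        x = params.total_input(S_star)
        b = params.b_vec if isinstance(params, ModelBParams) else params.b
        H = activation(x, params.a, b, params.d)
        g = activation_gain(x, params.a, b, params.d)
    return x, H, g


def find_fixed_point(
    params,
    S_init=None,
    method: str = "relax",
    tol: float = 1e-10,
    relax_time: float = 100.0,
) -> FixedPoint:
    """Locate a stable fixed point S* with max |drift| below ``tol``.

    ``method='relax'`` integrates the noiseless dynamics for ``relax_time``
    seconds of model time and then polishes with a damped multivariate root
    solve; ``method='root'`` goes straight to the root solve from ``S_init``.
    """
    m = params.n_state
    if S_init is None:
        S_init = np.full(m, 1e-3)
    S = np.asarray(S_init, float)
    if method not in ("relax", "root"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "relax":
        sol = solve_ivp(
            lambda t, y: params.drift(y),
            (0.0, relax_time),
            S,
            method="BDF",
            rtol=1e-10,
            atol=1e-12,
        )
        S = sol.y[:, -1]
    res = root(params.drift, S, method="hybr", tol=1e-13)
    S = res.x
    r = float(np.max(np.abs(params.drift(S))))
    if r > tol:
        raise ConvergenceError(f"fixed point residual {r:.3e} above tolerance {tol:.1e}", residual=r)
    x, H, g = _derived_at(params, S)
    return FixedPoint(S_star=S, x_star=x, H_star=H, gain=g, residual=r)


def effective_heterogeneity(params, fp: FixedPoint) -> np.ndarray:
    """h_i = gamma G (1 - S_i*) dH/dx|x* (for Model C, the excitatory block)."""
    if params.G == 0:
        raise ValidationError("h is degenerate at G = 0 (h == 0; separation undefined)")
    if isinstance(params, ModelCParams):
        n = params.conn.n
        return params.gamma * params.G * (1.0 - fp.S_star[:n]) * fp.gain[:n]
    return params.gamma * params.G * (1.0 - fp.S_star) * fp.gain


def jacobian_modelA(params: ModelAParams, fp: FixedPoint) -> np.ndarray:
    """Exact Jacobian of Model A at the fixed point.

    Diagonal: -1/tau_s - gamma H(x_i*) + w_i gamma (1 - S_i*) H'(x_i*);
    off-diagonal: gamma G (1 - S_i*) H'(x_i*) C_ij.
    """
    S, H, g = fp.S_star, fp.H_star, fp.gain
    row = params.gamma * (1.0 - S) * g
    J = row[:, None] * (params.G * params.conn.C)
    np.fill_diagonal(J, -1.0 / params.tau_s - params.gamma * H + params.w * row)
    return J


def jacobian_modelB(params: ModelBParams, fp: FixedPoint) -> np.ndarray:
    """Exact Jacobian of Model B (region-specific H_i and tau_i)."""
    S, H, g = fp.S_star, fp.H_star, fp.gain
    row = params.gamma * (1.0 - S) * g
    J = row[:, None] * (params.G * params.conn.C)
    np.fill_diagonal(J, -1.0 / params.tau - params.gamma * H + params.w * row)
    return J


def _modelC_blocks(params: ModelCParams, fp: FixedPoint):
    n = params.conn.n
    SE = fp.S_star[:n]
    HE = fp.H_star[:n]
    gE, gI = fp.gain[:n], fp.gain[n:]
    rowE = params.gamma * (1.0 - SE) * gE
    J_EE = rowE[:, None] * (params.G * params.conn.C)
    np.fill_diagonal(J_EE, -1.0 / params.tau_E - params.gamma * HE + params.w_EE * rowE)
    j_EI = -params.w_EI * rowE
    j_IE = params.w_IE * gI
    j_II = -1.0 / params.tau_I - gI
    return J_EE, j_EI, j_IE, j_II


def jacobian_modelC_full(params: ModelCParams, fp: FixedPoint) -> np.ndarray:
    """Full 2N x 2N Jacobian [[J_EE, J_EI], [J_IE, J_II]] of Model C.

    J_EI, J_IE and J_II are diagonal because only excitatory populations
    participate in long-range communication.
    """
    n = params.conn.n
    J_EE, j_EI, j_IE, j_II = _modelC_blocks(params, fp)
    J = np.zeros((2 * n, 2 * n))
    J[:n, :n] = J_EE
    J[:n, n:] = np.diag(j_EI)
    J[n:, :n] = np.diag(j_IE)
    J[n:, n:] = np.diag(j_II)
    return J


def jeff_ground_truth(params: ModelCParams, fp: FixedPoint):
    """Effective excitatory-only Jacobian of Model C and its heterogeneity.

    Hidden inhibition only corrects the diagonal:
    J_eff,ii = J_EE,ii - gamma (1 - S_Ei*) w_EI w_IE g_Ei g_Ii / (1/tau_I + g_Ii);
    off-diagonal entries equal those of J_EE, so J_eff,ij = h_i C_ij with
    h_i = gamma G (1 - S_Ei*) g_Ei.
    """
    J_EE, j_EI, j_IE, j_II = _modelC_blocks(params, fp)
    J_eff = J_EE.copy()
    J_eff[np.diag_indices_from(J_eff)] -= j_EI * j_IE / j_II
    h = effective_heterogeneity(params, fp)
    return J_eff, h


def ground_truth(params, fp: FixedPoint | None = None, **fp_kwargs) -> GroundTruth:
    """Convenience bundle: fixed point, exact (effective) Jacobian, and h."""
    if fp is None:
        fp = find_fixed_point(params, **fp_kwargs)
    if isinstance(params, ModelAParams):
        J = jacobian_modelA(params, fp)
        h = effective_heterogeneity(params, fp)
    elif isinstance(params, ModelBParams):
        J = jacobian_modelB(params, fp)
        h = effective_heterogeneity(params, fp)
    elif isinstance(params, ModelCParams):
        J, h = jeff_ground_truth(params, fp)
    else:
        raise ValidationError(f"unsupported params type {type(params)!r}")
    return GroundTruth(J=J, h=h, fixed_point=fp)


# ---------------------------------------------------------------------------
# Model A -> Model B mapping
# ---------------------------------------------------------------------------


def _invert_gain(target_gain: float, a: float, d: float) -> float:
    """Solve a phi'(v) = target_gain for v (phi' is strictly increasing on R)."""
    if not (0.0 < target_gain < a):
        raise ConvergenceError(f"target gain {target_gain} outside (0, {a})")
    f = lambda v: a * float(_phi_prime(np.array(v))) - target_gain
    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2.0
        if lo < -1e4:
            raise ConvergenceError("gain inversion bracket failure (low)")
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise ConvergenceError("gain inversion bracket failure (high)")
    return brentq(f, lo, hi, xtol=1e-14)


def map_A_to_B(paramsA: ModelAParams, fpA: FixedPoint) -> ModelBParams:
    """Map Model A heterogeneity (w_i, I_i) onto Model B heterogeneity (tau_i, b_i).

    The scalar w and I of Model B are the means of Model A's vectors.  Each
    b_i is chosen so that Model B's gain at its steady input x'_i equals
    Model A's gain at x_i* (making the off-diagonal Jacobians identical); each
    tau_i then matches the diagonal entries.  Steady-state self-consistency of
    the mapped model is approximate and can be checked via its own drift.
    """
    w_bar = float(np.mean(paramsA.w))
    I_bar = float(np.mean(paramsA.I))
    S = fpA.S_star
    x_prime = w_bar * S + paramsA.G * (paramsA.conn.C @ S) + I_bar
    a, d = paramsA.a, paramsA.d
    b_vec = np.empty(paramsA.conn.n)
    for i in range(paramsA.conn.n):
        v = _invert_gain(fpA.gain[i], a, d)
        b_vec[i] = a * x_prime[i] - v / d
    H_prime = activation(x_prime, a, b_vec, d)
    J_A = jacobian_modelA(paramsA, fpA)
    row = paramsA.gamma * (1.0 - S) * fpA.gain
    inv_tau = -np.diag(J_A) - paramsA.gamma * H_prime + w_bar * row
    if np.any(inv_tau <= 0):
        raise ConvergenceError("diagonal matching produced a non-positive 1/tau")
    return ModelBParams(
        conn=paramsA.conn,
        tau=1.0 / inv_tau,
        b_vec=b_vec,
        w=w_bar,
        I=I_bar,
        G=paramsA.G,
        gamma=paramsA.gamma,
        sigma=paramsA.sigma,
        a=a,
        d=d,
    )


def default_modelB(conn: Connectome, G: float = 0.8, sigma: float = SIGMA) -> ModelBParams:
    """Model B ground truth obtained by mapping the default Model A instance."""
    pa = default_modelA(conn, G=G, sigma=sigma)
    fpa = find_fixed_point(pa)
    return map_A_to_B(pa, fpa)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def bistability_scan(
    params,
    G_grid,
    S_low: float = 1e-3,
    S_high: float = 0.9,
    sep_threshold: float = 0.05,
) -> list[dict]:
    """Fixed points reached from low vs high initial states across a G grid.

    Rows carry the two fixed points (or the error message per init) and a
    ``bistable`` flag set when any region's steady gating differs by more
    than ``sep_threshold``.  Solver failures are recorded, not raised.
    """
    G_grid = np.atleast_1d(np.asarray(G_grid, float))
    if G_grid.size == 0:
        raise ValidationError("G_grid must be nonempty")
    rows = []
    for G in G_grid:
        p = replace(params, G=float(G))
        entry = {"G": float(G), "bistable": False, "error": None}
        fps = []
        for s0 in (S_low, S_high):
            try:
                fps.append(find_fixed_point(p, S_init=np.full(p.n_state, s0)).S_star)
            except ConvergenceError as e:  # record and continue the scan
                fps.append(None)
                entry["error"] = str(e)
        entry["fp_low"], entry["fp_high"] = fps
        if fps[0] is not None and fps[1] is not None:
            entry["separation"] = float(np.max(np.abs(fps[0] - fps[1])))
            entry["bistable"] = entry["separation"] > sep_threshold
        rows.append(entry)
    return rows


def eigen_frequencies(J: np.ndarray):
    """Intrinsic oscillation frequencies |Im lambda| / (2 pi) and max Re lambda."""
    J = np.asarray(J, float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValidationError("J must be square")
    lam = np.linalg.eigvals(J)
    freqs = np.abs(lam.imag) / (2.0 * np.pi)
    return freqs, float(np.max(lam.real))
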