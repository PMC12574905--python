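"""Stochastic integration of the mean-field models.

Euler-Maruyama with additive noise:
``S(t + dt) = S(t) + f(S) dt + sigma sqrt(dt) xi``, xi i.i.d. standard
normal per region per step.  Integration runs in fixed-size chunks (noise
drawn chunk by chunk from a single seeded generator, so trajectories are
bitwise reproducible) with numba-compiled inner loops.

Default step 0.001 s: the inhibitory time constant of the two-population
model (0.01 s) requires dt <= 0.001 s for a comfortably stable explicit
scheme; the one-population models tolerate 0.005 s in fast test profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import h5py
import numpy as np
from numba import njit

from .dynamics import ModelAParams, ModelBParams, ModelCParams, find_fixed_point
from .exceptions import IntegrationError, ValidationError

__all__ = ["Trajectory", "simulate", "simulate_linear", "decimate"]

_CHUNK = 200_000
_BAND = (-0.2, 1.2)  # sanity band for gating variables


@dataclass
class Trajectory:
    """Regularly sampled multivariate activity.

    ``S`` has shape (T_samples, M) with M = N (Models A/B, linear) or 2N
    (Model C, E block first).  ``t0`` is the burn-in already discarded (s);
    ``excursion_fraction`` is the fraction of samples outside the gating
    sanity band (0 for linear simulations).
    """

    S: np.ndarray
    dt: float
    t0: float
    seed: int
    model_tag: str
    sigma: float
    parent_dt: float | None = None
    excursion_fraction: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.S.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def save(self, path) -> None:
        with h5py.File(str(path), "w") as f:
            g = f.create_group("trajectory")
            g.create_dataset("S", data=self.S)
            meta = dict(
                dt=self.dt,
                t0=self.t0,
                seed=self.seed,
                model_tag=self.model_tag,
                sigma=self.sigma,
                excursion_fraction=self.excursion_fraction,
            )
            if self.parent_dt is not None:
                meta["parent_dt"] = self.parent_dt
            for k, v in meta.items():
                g.attrs[k] = v

    @classmethod
    def load(cls, path) -> "Trajectory":
        with h5py.File(str(path), "r") as f:
            g = f["trajectory"]
            return cls(
                S=g["S"][()],
                dt=float(g.attrs["dt"]),
                t0=float(g.attrs["t0"]),
                seed=int(g.attrs["seed"]),
                model_tag=str(g.attrs["model_tag"]),
                sigma=float(g.attrs["sigma"]),
                parent_dt=float(g.attrs["parent_dt"]) if "parent_dt" in g.attrs else None,
                excursion_fraction=float(g.attrs.get("excursion_fraction", 0.0)),
            )


@njit(cache=True, inline="always")
def _H(u, d):
    v = d * u
    if abs(v) < 1e-7:
        return (1.0 + 0.5 * v + v * v / 12.0) / d
    if v > 0.0:
        return u / (1.0 - math.exp(-v))
    ev = math.exp(v)
    return u * ev / (ev - 1.0)


@njit(cache=True)
def _euler_gating(S, tau, gamma, w, I_ext, GC, a, b, d, dt, sdt, noise, out):
    n = S.shape[0]
    for k in range(noise.shape[0]):
        for i in range(n):
            xi = w[i] * S[i] + I_ext[i]
            for j in range(n):
                xi += GC[i, j] * S[j]
            out[k, i] = -S[i] / tau[i] + gamma * (1.0 - S[i]) * _H(a * xi - b[i], d)
        for i in range(n):
            S[i] = S[i] + out[k, i] * dt + sdt * noise[k, i]
            out[k, i] = S[i]


@njit(cache=True)
def _euler_ei(S, nE, gamma, w_EE, w_IE, w_EI, GC, tau_E, tau_I, a_E, b_E, d_E,
              a_I, b_I, d_I, I_E, I_I, dt, sdt, noise, out):
    for k in range(noise.shape[0]):
        for i in range(nE):
            xE = w_EE[i] * S[i] - w_EI[i] * S[nE + i] + I_E
            for j in range(nE):
                xE += GC[i, j] * S[j]
            xI = w_IE[i] * S[i] - S[nE + i] + I_I
            out[k, i] = -S[i] / tau_E + gamma * (1.0 - S[i]) * _H(a_E * xE - b_E, d_E)
            out[k, nE + i] = -S[nE + i] / tau_I + _H(a_I * xI - b_I, d_I)
        for i in range(2 * nE):
            S[i] = S[i] + out[k, i] * dt + sdt * noise[k, i]
            out[k, i] = S[i]


@njit(cache=True)
def _euler_linear(x, J, dt, sdt, noise, out):
    n = x.shape[0]
    for k in range(noise.shape[0]):
        for i in range(n):
            di = 0.0
            for j in range(n):
                di += J[i, j] * x[j]
            out[k, i] = di
        for i in range(n):
            x[i] = x[i] + out[k, i] * dt + sdt * noise[k, i]
            out[k, i] = x[i]


def _run_chunks(step, S0, m, n_total, n_burn, dt, sigma, seed):
    rng = np.random.default_rng(seed)
    sdt = sigma * math.sqrt(dt)
    S = np.array(S0, dtype=float).copy()
    out = np.empty((n_total - n_burn, m))
    done = 0
    while done < n_total:
        k = min(_CHUNK, n_total - done)
        noise = rng.standard_normal((k, m))
        buf = np.empty((k, m))
        step(S, noise, sdt, buf)
        lo = max(n_burn - done, 0)
        if lo < k:
            out[done + lo - n_burn : done + k - n_burn] = buf[lo:]
        if not np.all(np.isfinite(S)):
            t_bad = (done + int(np.argmax(~np.isfinite(buf).all(axis=1)))) * dt
            raise IntegrationError(f"non-finite state at t = {t_bad:.3f} s")
        done += k
    return out


def simulate(
    params,
    duration: float,
    dt: float = 0.001,
    seed: int = 0,
    S0="fixed_point",
    burn_in: float = 50.0,
) -> Trajectory:
    """Integrate a model for ``duration`` seconds; the burn-in is discarded.

    ``S0 = 'fixed_point'`` starts at the fixed point reached from a low
    initial state.  Raises :class:`IntegrationError` if the state leaves the
    gating sanity band persistently (> 1% of samples) or becomes non-finite.
    """
    if dt <= 0 or dt > 0.01:
        raise ValidationError("require 0 < dt <= 0.01 s")
    if duration < burn_in:
        raise ValidationError("duration must cover the burn-in")
    if isinstance(S0, str) and S0 == "fixed_point":
        S0 = find_fixed_point(params).S_star
    S0 = np.asarray(S0, dtype=float)
    if S0.shape != (params.n_state,):
        raise ValidationError(f"S0 must have shape ({params.n_state},)")
    n_total = int(round(duration / dt))
    n_burn = int(round(burn_in / dt))
    GC = params.G * params.conn.C

    if isinstance(params, (ModelAParams, ModelBParams)):
        if isinstance(params, ModelAParams):
            tau = np.full(params.conn.n, params.tau_s)
            b = np.full(params.conn.n, params.b)
            w = params.w
            I_ext = params.I
            tag = "A"
        else:
            tau, b = params.tau, params.b_vec
            w = np.full(params.conn.n, params.w)
            I_ext = np.full(params.conn.n, params.I)
            tag = "B"

        def step(S, noise, sdt, buf):
            _euler_gating(S, tau, params.gamma, w, I_ext, GC, params.a, b,
                          params.d, dt, sdt, noise, buf)

    elif isinstance(params, ModelCParams):
        tag = "C"

        def step(S, noise, sdt, buf):
            _euler_ei(S, params.conn.n, params.gamma, params.w_EE, params.w_IE,
                      params.w_EI, GC, params.tau_E, params.tau_I,
                      params.a_E, params.b_E, params.d_E,
                      params.a_I, params.b_I, params.d_I,
                      params.I_E, params.I_I, dt, sdt, noise, buf)

    else:
        raise ValidationError(f"unsupported params type {type(params)!r}")

    out = _run_chunks(step, S0, params.n_state, n_total, n_burn, dt, params.sigma, seed)
    frac = float(np.mean((out < _BAND[0]) | (out > _BAND[1])))
    if frac > 0.01:
        t_first = float(np.argmax(((out < _BAND[0]) | (out > _BAND[1])).any(axis=1))) * dt
        raise IntegrationError(
            f"state persistently outside sanity band {_BAND}; first excursion at t0+{t_first:.3f} s"
        )
    return Trajectory(S=out, dt=dt, t0=burn_in, seed=seed, model_tag=tag,
                      sigma=params.sigma, excursion_fraction=frac)


def simulate_linear(
    J: np.ndarray,
    sigma: float,
    duration: float,
    dt: float = 0.001,
    seed: int = 0,
    burn_in: float = 50.0,
    x0=None,
) -> Trajectory:
    """Integrate the linear (Ornstein-Uhlenbeck) system dx/dt = J x + sigma nu."""
    J = np.ascontiguousarray(J, dtype=float)
    n = J.shape[0]
    if x0 is None:
        x0 = np.zeros(n)
    n_total = int(round(duration / dt))
    n_burn = int(round(burn_in / dt))

    def step(x, noise, sdt, buf):
        _euler_linear(x, J, dt, sdt, noise, buf)

    out = _run_chunks(step, x0, n, n_total, n_burn, dt, sigma, seed)
    return Trajectory(S=out, dt=dt, t0=burn_in, seed=seed, model_tag="linear", sigma=sigma)


def decimate(traj: Trajectory, n_step: int) -> Trajectory:
    """Keep every ``n_step``-th sample; dt becomes T = n_step * dt."""
    if n_step < 1:
        raise ValidationError("n_step must be >= 1")
    if n_step > traj.n_samples:
        raise ValidationError("n_step exceeds the number of samples")
    if n_step == 1:
        return traj
    return _dc_replace(
        traj,
        S=traj.S[::n_step],
        dt=traj.dt * n_step,
        parent_dt=traj.parent_dt if traj.parent_dt is not None else traj.dt,
    )
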