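"""Continuous-time stochastic simulation of the depression-rumination-stressor system.

The model is a three-stock system-dynamics model of one adolescent:

* ``D`` -- depressive symptoms (CDI scale, 0-52),
* ``R`` -- rumination (rescaled response-styles subscale, 0-39),
* ``S`` -- past stressors kept alive (life-event units, >= 0).

Each stock adjusts with a first-order delay toward an *indicated* value,
a linear function of the other stocks plus an autocorrelated noise term:

    indicated R = theta1 + theta2*D + theta3*G + theta4*S + theta5*R + epsR
    indicated D = theta6 + theta7*R + theta8*D + epsD

``S`` is a bathtub: it fills at the ongoing-stressor rate ``u`` and drains
at the *let it go* rate ``S / M`` where the memory time ``M = theta9 * R``
(floored at ``M_min``).  Two reinforcing loops arise: rumination keeps
stressors alive, which feeds back into rumination (R1), and rumination and
depressive symptoms amplify each other (R2).  Process noise is a pair of
stationary first-order autocorrelated (Ornstein-Uhlenbeck type) processes
entering the indicated values.

Integration is explicit Euler(-Maruyama) with step ``params.dt``; stocks
are clamped to instrument bounds after every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .params import ModelParams

__all__ = [
    "IndividualProfile",
    "SystemState",
    "Trajectory",
    "SteadyState",
    "indicated_rumination",
    "indicated_depression",
    "memory_time",
    "let_it_go",
    "ou_step",
    "ou_path",
    "step",
    "simulate",
    "simulate_batch",
    "steady_state",
    "loop_gain",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class IndividualProfile:
    """Initial conditions and stressor exposure of one simulated adolescent.

    ``gender`` is 1 for girls, 0 for boys (the gender coefficient theta3 is
    added to indicated rumination for girls).  ``inflow`` is the ongoing
    stressor rate in events/month, either a constant or a function of time.
    """

    gender: int
    D0: float
    R0: float
    S0: float
    inflow: float | Callable[[float], float] = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gender not in (0, 1):
            raise ValueError("gender must be 0 (boy) or 1 (girl)")
        for name in ("D0", "R0", "S0"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.S0 < 0 or self.R0 < 0:
            raise ValueError("R0 and S0 must be >= 0")
        if not callable(self.inflow) and self.inflow < 0:
            raise ValueError("inflow rate must be >= 0")

    def inflow_at(self, t: float) -> float:
        u = self.inflow(t) if callable(self.inflow) else self.inflow
        if u < 0:
            raise ValueError(f"inflow rate is negative at t={t}")
        return float(u)


@dataclass
class SystemState:
    """The three stocks plus the two noise states at one instant."""

    t: float
    D: float
    R: float
    S: float
    epsR: float = 0.0
    epsD: float = 0.0


@dataclass
class SteadyState:
    """Noise-free fixed point of the linear system, or a divergence flag.

    When the combined reinforcing-loop gain is >= 1 the system has no
    finite stable fixed point (trajectories grow until clamped) and
    ``diverges`` is True with the stock values set to NaN.
    """

    D: float
    R: float
    S: float
    loop_gain: float
    diverges: bool


class Trajectory:
    """A simulated path on a uniform time grid.

    Carries the three stocks, the two noise states, and the derived
    memory-time ``M(t) = max(theta9*R, M_min)`` and let-it-go ``L = S/M``
    series.  ``to_frame`` returns the tidy representation.
    """

    def __init__(self, t: np.ndarray, D: np.ndarray, R: np.ndarray, S: np.ndarray,
                 epsR: np.ndarray, epsD: np.ndarray, params: ModelParams):
        self.t = t
        self.D = D
        self.R = R
        self.S = S
        self.epsR = epsR
        self.epsD = epsD
        self.M = memory_time(R, params)
        self.L = S / self.M

    def __len__(self) -> int:
        return len(self.t)

    def at(self, time: float) -> SystemState:
        """State at the grid point nearest ``time``."""
        i = int(np.argmin(np.abs(self.t - time)))
        return SystemState(float(self.t[i]), float(self.D[i]), float(self.R[i]),
                           float(self.S[i]), float(self.epsR[i]), float(self.epsD[i]))

    def mean_memory_time(self) -> float:
        """Time-average of M(t) over the whole grid."""
        return float(np.mean(self.M))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "D": self.D, "R": self.R, "S": self.S,
            "epsR": self.epsR, "epsD": self.epsD, "M": self.M, "L": self.L,
        })


# ---------------------------------------------------------------------------
# elementary rate equations


def _check_finite(**kwargs) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite input: {name}")


def indicated_rumination(D, R, S, G, epsR, params: ModelParams):
    """Target value toward which the rumination stock adjusts (unclamped)."""
    _check_finite(D=D, R=R, S=S, G=G, epsR=epsR)
    p = params
    return p.theta1 + p.theta2 * D + p.theta3 * G + p.theta4 * S + p.theta5 * R + epsR


def indicated_depression(D, R, epsD, params: ModelParams):
    """Target value toward which the depressive-symptom stock adjusts."""
    _check_finite(D=D, R=R, epsD=epsD)
    return params.theta6 + params.theta7 * R + params.theta8 * D + epsD


def memory_time(R, params: ModelParams):
    """Months a stressor is kept alive: theta9 * R, floored at M_min."""
    _check_finite(R=R)
    return np.maximum(params.theta9 * R, params.M_min)


def let_it_go(S, M):
    """Outflow rate of the past-stressors stock (events/month)."""
    _check_finite(S=S, M=M)
    if np.any(np.asarray(S) < 0):
        raise ValueError("S must be >= 0")
    if np.any(np.asarray(M) <= 0):
        raise ValueError("memory time must be positive (>= M_min)")
    return S / M


# ---------------------------------------------------------------------------
# autocorrelated process noise


def _ou_coeffs(sigma: float, corr_time: float, dt: float) -> tuple[float, float]:
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if corr_time <= 0:
        raise ValueError("corr_time must be > 0")
    if not 0 < dt < corr_time:
        raise ValueError("require 0 < dt < corr_time for a stable noise update")
    a = 1.0 - dt / corr_time
    # innovation scaled so the AR(1) stationary SD is exactly sigma
    q = sigma * math.sqrt((dt / corr_time) * (2.0 - dt / corr_time))
    return a, q


def ou_step(eps: float, sigma: float, corr_time: float, dt: float, draw: float) -> float:
    """One Euler step of the stationary autocorrelated noise process.

    The update ``eps' = eps*(1 - dt/corr_time) + q*draw`` uses an innovation
    SD ``q`` chosen so the stationary SD equals ``sigma`` exactly; the
    autocorrelation at lag ``k*dt`` is ``(1 - dt/corr_time)**k``, the Euler
    approximation of ``exp(-lag/corr_time)``.  ``draw`` is a standard-normal
    variate.
    """
    a, q = _ou_coeffs(sigma, corr_time, dt)
    return a * eps + q * draw


def ou_path(n_steps: int, sigma: float, corr_time: float, dt: float,
            rng: np.random.Generator, eps0: float = 0.0) -> np.ndarray:
    """Length ``n_steps + 1`` path of repeated :func:`ou_step` applications.

    Vectorized with a linear filter; identical (to floating-point round-off)
    to calling ``ou_step`` in a loop with the same draws.
    """
    a, q = _ou_coeffs(sigma, corr_time, dt)
    z = rng.standard_normal(n_steps)
    out = np.empty(n_steps + 1)
    out[0] = eps0
    out[1:], _ = lfilter([q], [1.0, -a], z, zi=np.array([a * eps0]))
    return out


# ---------------------------------------------------------------------------
# integration


def _clamp(x, bounds):
    return np.clip(x, bounds[0], bounds[1])


def step(state: SystemState, profile: IndividualProfile, params: ModelParams,
         rng: np.random.Generator | None = None) -> SystemState:
    """Advance one Euler step of length ``params.dt``.

    Stocks move toward their indicated values with first-order adjustment
    times ``tau_R``/``tau_D``; the stressor stock integrates inflow minus
    let-it-go; stocks are clamped to instrument bounds afterwards; the noise
    states are advanced by :func:`ou_step` (decaying deterministically when
    ``rng`` is None).
    """
    p = params
    u = profile.inflow_at(state.t)
    M = memory_time(state.R, p)
    dR = (indicated_rumination(state.D, state.R, state.S, profile.gender,
                               state.epsR, p) - state.R) / p.tau_R
    dD = (indicated_depression(state.D, state.R, state.epsD, p) - state.D) / p.tau_D
    dS = u - let_it_go(state.S, M)
    D = float(_clamp(state.D + p.dt * dD, p.D_bounds))
    R = float(_clamp(state.R + p.dt * dR, p.R_bounds))
    S = float(_clamp(state.S + p.dt * dS, p.S_bounds))
    if rng is None:
        zR = zD = 0.0
    else:
        zR, zD = rng.standard_normal(2)
    epsR = ou_step(state.epsR, p.theta10, p.theta12, p.dt, zR)
    epsD = ou_step(state.epsD, p.theta11, p.theta12, p.dt, zD)
    return SystemState(state.t + p.dt, D, R, S, epsR, epsD)


def simulate(profile: IndividualProfile, params: ModelParams,
             horizon_months: float, seed: int | np.random.Generator | None = None,
             noise: bool = True) -> Trajectory:
    """Simulate one individual over ``horizon_months``.

    Deterministic given ``(profile, params, seed)``.  With ``noise=False``
    (or both noise SDs zero) the path is the deterministic skeleton.  The
    noise states start from a stationary draw so the process has no burn-in
    transient.
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    p = params
    for name, v, bounds in (("D0", profile.D0, p.D_bounds),
                            ("R0", profile.R0, p.R_bounds),
                            ("S0", profile.S0, p.S_bounds)):
        if not bounds[0] <= v <= bounds[1]:
            raise ValueError(f"{name}={v} outside clamp bounds {bounds}")
    n_steps = int(round(horizon_months / p.dt))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    use_noise = noise and (p.theta10 > 0 or p.theta11 > 0)

    t = np.arange(n_steps + 1) * p.dt
    D = np.empty(n_steps + 1); R = np.empty(n_steps + 1); S = np.empty(n_steps + 1)
    D[0], R[0], S[0] = profile.D0, profile.R0, profile.S0

    if use_noise:
        epsR = ou_path(n_steps, p.theta10, p.theta12, p.dt, rng,
                       eps0=rng.standard_normal() * p.theta10)
        epsD = ou_path(n_steps, p.theta11, p.theta12, p.dt, rng,
                       eps0=rng.standard_normal() * p.theta11)
    else:
        epsR = np.zeros(n_steps + 1)
        epsD = np.zeros(n_steps + 1)

    for i in range(n_steps):
        u = profile.inflow_at(t[i])
        M = max(p.theta9 * R[i], p.M_min)
        indR = (p.theta1 + p.theta2 * D[i] + p.theta3 * profile.gender
                + p.theta4 * S[i] + p.theta5 * R[i] + epsR[i])
        indD = p.theta6 + p.theta7 * R[i] + p.theta8 * D[i] + epsD[i]
        D[i + 1] = min(max(D[i] + p.dt * (indD - D[i]) / p.tau_D, p.D_bounds[0]), p.D_bounds[1])
        R[i + 1] = min(max(R[i] + p.dt * (indR - R[i]) / p.tau_R, p.R_bounds[0]), p.R_bounds[1])
        S[i + 1] = min(max(S[i] + p.dt * (u - S[i] / M), p.S_bounds[0]), p.S_bounds[1])
    return Trajectory(t, D, R, S, epsR, epsD, params)


def simulate_batch(D0: np.ndarray, R0: np.ndarray, S0: np.ndarray,
                   G: np.ndarray, u: np.ndarray, params: ModelParams,
                   horizon_months: float,
                   rng: np.random.Generator | None = None,
                   record_steps: Sequence[int] | None = None,
                   noise_paths: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> dict[str, np.ndarray]:
    """Vectorized simulation of many individuals with constant inflows.

    All initial-condition arrays share shape ``(n,)``; individual ``j``
    evolves exactly as ``simulate`` would evolve it (same equations and
    clamping), with independent noise streams drawn from ``rng`` (noise-free
    when ``rng`` is None).  Alternatively ``noise_paths = (epsR, epsD)`` with
    shape ``(n_steps + 1, n)`` supplies precomputed noise (e.g. one
    :func:`ou_path` per individual from an individually seeded stream).
    ``record_steps`` selects which step indices to store (default: all).
    Returns arrays of shape ``(len(record_steps), n)`` for ``D``, ``R``,
    ``S`` and ``M``, plus the recorded times ``t`` and the horizon-average
    memory time ``mean_M`` over the full grid.
    """
    p = params
    D = np.array(D0, dtype=float).copy()
    R = np.array(R0, dtype=float).copy()
    S = np.array(S0, dtype=float).copy()
    G = np.asarray(G, dtype=float)
    u = np.asarray(u, dtype=float)
    n = D.shape[0]
    n_steps = int(round(horizon_months / p.dt))
    if record_steps is None:
        record_steps = range(n_steps + 1)
    record = {s: k for k, s in enumerate(record_steps)}

    aR, qR = _ou_coeffs(p.theta10, p.theta12, p.dt)
    aD, qD = _ou_coeffs(p.theta11, p.theta12, p.dt)
    if noise_paths is not None:
        pathR, pathD = noise_paths
        if pathR.shape != (n_steps + 1, n) or pathD.shape != (n_steps + 1, n):
            raise ValueError("noise_paths must have shape (n_steps + 1, n)")
        epsR = pathR[0]
        epsD = pathD[0]
    elif rng is None:
        epsR = np.zeros(n)
        epsD = np.zeros(n)
    else:
        epsR = rng.standard_normal(n) * p.theta10
        epsD = rng.standard_normal(n) * p.theta11

    out = {k: np.empty((len(record), n)) for k in ("D", "R", "S", "M")}
    t_rec = np.empty(len(record))
    mean_M = np.zeros(n)

    for i in range(n_steps + 1):
        M = np.maximum(p.theta9 * R, p.M_min)
        mean_M += M
        if i in record:
            k = record[i]
            out["D"][k] = D; out["R"][k] = R; out["S"][k] = S; out["M"][k] = M
            t_rec[k] = i * p.dt
        if i == n_steps:
            break
        indR = (p.theta1 + p.theta2 * D + p.theta3 * G + p.theta4 * S
                + p.theta5 * R + epsR)
        indD = p.theta6 + p.theta7 * R + p.theta8 * D + epsD
        D = np.clip(D + p.dt * (indD - D) / p.tau_D, *p.D_bounds)
        R = np.clip(R + p.dt * (indR - R) / p.tau_R, *p.R_bounds)
        S = np.clip(S + p.dt * (u - S / M), *p.S_bounds)
        if noise_paths is not None:
            epsR = pathR[i + 1]
            epsD = pathD[i + 1]
        elif rng is not None:
            z = rng.standard_normal((2, n))
            epsR = aR * epsR + qR * z[0]
            epsD = aD * epsD + qD * z[1]
        else:
            epsR = aR * epsR
            epsD = aD * epsD
    out["t"] = t_rec
    out["mean_M"] = mean_M / (n_steps + 1)
    return out


# ---------------------------------------------------------------------------
# analytic fixed point


def loop_gain(params: ModelParams, u: float) -> float:
    """Combined gain of the reinforcing loops at constant inflow ``u``.

    ``g = theta5 + theta2*theta7/(1-theta8) + theta4*u*theta9``; a gain
    >= 1 means the linearized system has no finite stable fixed point.
    """
    p = params
    if p.theta8 >= 1:
        raise ValueError("theta8 must be < 1 for a finite depression fixed point")
    return p.theta5 + p.theta2 * p.theta7 / (1.0 - p.theta8) + p.theta4 * u * p.theta9


def steady_state(params: ModelParams, G: int, u: float) -> SteadyState:
    """Noise-free fixed point for gender ``G`` and constant inflow ``u``.

    Solves the linear system ``R*(1-theta5) = theta1 + theta2*D + theta3*G +
    theta4*S`` with ``D = (theta6 + theta7*R)/(1-theta8)`` and the stressor
    balance ``S = u * M``, ``M = max(theta9*R, M_min)``.  Clamps are ignored
    (this is the oracle for the unclamped dynamics).
    """
    p = params
    g = loop_gain(params, u)
    if g >= 1.0:
        return SteadyState(math.nan, math.nan, math.nan, g, True)
    one_m8 = 1.0 - p.theta8
    const = p.theta1 + p.theta3 * G + p.theta2 * p.theta6 / one_m8
    R = const / (1.0 - g)
    if p.theta9 * R < p.M_min:
        # memory-time floor engaged: S = u*M_min is constant, loop R1 opens
        g2 = p.theta5 + p.theta2 * p.theta7 / one_m8
        R = (const + p.theta4 * u * p.M_min) / (1.0 - g2)
        S = u * p.M_min
    else:
        S = u * p.theta9 * R
    D = (p.theta6 + p.theta7 * R) / one_m8
    return SteadyState(D, R, S, g, False)
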