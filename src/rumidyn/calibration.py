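"""Indirect-inference estimation of the model parameters from a three-wave panel.

The likelihood of the stochastic stock-flow model is intractable, so the
parameters are estimated by simulated moment matching: a vector of
*auxiliary statistics* (per-gender wave means, SDs, and cross-wave /
cross-construct correlations) is computed from the observed panel, the same
statistics are computed from panels simulated at candidate parameters, and
a weighted quadratic distance between the two is minimized.

Common random numbers make the objective deterministic in theta: the same
seed set drives every simulated panel, so the surface is smooth enough for
a derivative-free simplex search with restarts.  The diagonal weight matrix
holds inverse nonparametric-bootstrap variances of the empirical statistics.
Standard errors come from a parametric bootstrap: resimulate panels at the
point estimate, re-estimate each, and take the spread of the replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .cohort import CohortPanel, CohortSpec, generate_panel, generate_wide, sample_profiles
from .params import ModelParams
from .seeds import child_rng

__all__ = ["AuxStatVector", "CalibrationOptions", "CalibrationResult",
           "aux_stats", "bootstrap_weights", "objective", "calibrate",
           "bootstrap_se", "THETA_NAMES", "default_bounds"]

THETA_NAMES = tuple(f"theta{i}" for i in range(1, 13))

_PENALTY = 1e12

# statistics computed per gender, in fixed order (the estimator's contract)
_MOMENT_VARS = ("R1", "R2", "R3", "D1", "D3", "S1", "S3")
_CORR_PAIRS = (("R1", "R2"), ("R2", "R3"), ("D1", "D3"), ("S1", "S3"),
               ("R1", "D3"), ("D1", "R3"), ("S1", "R3"), ("S1", "D3"))


@dataclass(frozen=True)
class AuxStatVector:
    """Named, ordered auxiliary-statistic vector (the moment-matching target)."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _stats_from_wide(wide: dict[str, np.ndarray]) -> tuple[tuple[str, ...], np.ndarray]:
    names: list[str] = []
    vals: list[float] = []
    gender = wide["gender"]
    for g, label in ((1, "girls"), (0, "boys")):
        m = gender == g
        if m.sum() < 2:
            raise ValueError(f"need >= 2 individuals per gender; {label} has {m.sum()}")
        cols = {v: wide[v][m] for v in _MOMENT_VARS}
        for v in _MOMENT_VARS:
            names.append(f"{label}_mean_{v}")
            vals.append(float(np.mean(cols[v])))
        for v in _MOMENT_VARS:
            names.append(f"{label}_sd_{v}")
            vals.append(float(np.std(cols[v], ddof=1)))
        for a, b in _CORR_PAIRS:
            names.append(f"{label}_corr_{a}_{b}")
            xa, xb = cols[a], cols[b]
            sa, sb = np.std(xa, ddof=1), np.std(xb, ddof=1)
            if sa == 0 or sb == 0:
                warnings.warn(f"degenerate variance in {label} {a}/{b}; "
                              "correlation recorded as 0", stacklevel=3)
                vals.append(0.0)
            else:
                vals.append(float(np.corrcoef(xa, xb)[0, 1]))
    return tuple(names), np.array(vals)


def aux_stats(panel_or_wide: CohortPanel | dict) -> AuxStatVector:
    """Auxiliary statistics of a panel (or of its wide-format arrays).

    Per gender: means and sample SDs of rumination at all three waves and of
    depression and stressors at waves 1 and 3, plus the cross-wave and
    cross-construct correlations listed in ``_CORR_PAIRS``.
    """
    wide = panel_or_wide.wide() if isinstance(panel_or_wide, CohortPanel) else panel_or_wide
    names, vals = _stats_from_wide(wide)
    return AuxStatVector(names, vals)


def bootstrap_weights(panel: CohortPanel, n_boot: int = 500,
                      seed: int | None = None) -> np.ndarray:
    """Diagonal weights: inverse bootstrap variances of the empirical statistics.

    Nonparametric bootstrap over individuals (within gender, preserving the
    group sizes).  Statistics with (numerically) zero bootstrap variance get
    weight 0 rather than an infinite weight.
    """
    wide = panel.wide()
    rng = child_rng(seed, 97)
    gender = wide["gender"]
    idx_g = np.flatnonzero(gender == 1)
    idx_b = np.flatnonzero(gender == 0)
    reps = np.empty((n_boot, len(_stats_from_wide(wide)[0])))
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx_g, size=len(idx_g), replace=True),
                               rng.choice(idx_b, size=len(idx_b), replace=True)])
        sub = {k: v[take] for k, v in wide.items()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reps[b] = _stats_from_wide(sub)[1]
    var = reps.var(axis=0, ddof=1)
    w = np.zeros_like(var)
    ok = var > 1e-12
    w[ok] = 1.0 / var[ok]
    return w


def default_bounds() -> dict[str, tuple[float, float]]:
    """Generous box bounds keeping every parameter in its admissible region."""
    return {
        "theta1": (-20.0, 20.0), "theta2": (-5.0, 5.0), "theta3": (-20.0, 20.0),
        "theta4": (-5.0, 5.0), "theta5": (-0.99, 0.99), "theta6": (-20.0, 20.0),
        "theta7": (-2.0, 2.0), "theta8": (-0.99, 0.99), "theta9": (1e-3, 20.0),
        "theta10": (0.0, 30.0), "theta11": (0.0, 30.0), "theta12": (0.55, 20.0),
    }


@dataclass
class CalibrationOptions:
    """Tuning knobs for :func:`calibrate`.

    ``free`` names the parameters to estimate (others stay at their initial
    values); ``n_sim`` synthetic panel copies are averaged per objective
    evaluation; ``n_restarts`` perturbed simplex restarts follow the run
    from the initial point.
    """

    free: tuple[str, ...] = THETA_NAMES
    n_sim: int = 5
    n_restarts: int = 10
    max_evals: int = 400
    xatol: float = 1e-3
    fatol: float = 1e-4
    seed: int = 0
    n_boot_weights: int = 500
    restart_scale: float = 0.3


@dataclass
class CalibrationResult:
    """Point estimates plus diagnostics (and bootstrap SEs when requested)."""

    theta: np.ndarray
    se: np.ndarray | None
    objective_value: float
    n_evaluations: int
    converged: bool
    seed_set: tuple[int, ...]
    weight_desc: str
    free: tuple[str, ...]

    def as_table(self) -> dict:
        out = {}
        for i, name in enumerate(THETA_NAMES):
            out[name] = {"estimate": float(self.theta[i]),
                         "se": None if self.se is None else float(self.se[i]),
                         "free": name in self.free}
        return out

    def __post_init__(self) -> None:
        if self.objective_value < 0:
            raise ValueError("objective value must be >= 0")
        if self.se is not None and np.any(self.se < 0):
            raise ValueError("standard errors must be >= 0")


def _theta_to_params(theta: np.ndarray, base: ModelParams) -> ModelParams:
    return base.with_theta(**dict(zip(THETA_NAMES, map(float, theta))))


def simulated_stats(theta: np.ndarray, spec: CohortSpec, n_sim: int,
                    seed_set: tuple[int, ...],
                    base_params: ModelParams) -> np.ndarray:
    """Average auxiliary statistics over ``n_sim`` panels simulated at theta."""
    params = _theta_to_params(theta, base_params)
    acc = None
    for s in seed_set[:n_sim]:
        profiles = sample_profiles(spec, seed=s)
        wide = generate_wide(profiles, params, spec, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = _stats_from_wide(wide)[1]
        acc = vals if acc is None else acc + vals
    return acc / min(n_sim, len(seed_set))


def objective(theta: np.ndarray, empirical_stats: AuxStatVector | np.ndarray,
              spec: CohortSpec, n_sim: int = 5,
              seed_set: tuple[int, ...] = (0,),
              weights: np.ndarray | None = None,
              base_params: ModelParams | None = None,
              bounds: dict[str, tuple[float, float]] | None = None) -> float:
    """Weighted quadratic moment distance, deterministic in theta.

    ``(s_sim(theta) - s_emp)' W (s_sim(theta) - s_emp)`` with diagonal ``W``.
    The same ``seed_set`` is reused at every theta (common random numbers).
    Out-of-bounds or inadmissible theta returns a large penalty rather than
    raising, so simplex search can recover.
    """
    theta = np.asarray(theta, dtype=float)
    base = base_params if base_params is not None else ModelParams.defaults()
    bnds = bounds if bounds is not None else default_bounds()
    excess = 0.0
    for i, name in enumerate(THETA_NAMES):
        lo, hi = bnds[name]
        excess += max(0.0, lo - theta[i]) + max(0.0, theta[i] - hi)
    if excess > 0:
        return _PENALTY * (1.0 + excess)
    try:
        sim = simulated_stats(theta, spec, n_sim, seed_set, base)
    except ValueError:
        return _PENALTY
    emp = empirical_stats.values if isinstance(empirical_stats, AuxStatVector) \
        else np.asarray(empirical_stats, dtype=float)
    diff = sim - emp
    w = np.ones_like(diff) if weights is None else weights
    return float(diff @ (w * diff))


def calibrate(panel: CohortPanel, init_theta: np.ndarray | dict,
              bounds: dict[str, tuple[float, float]] | None = None,
              options: CalibrationOptions | None = None,
              spec: CohortSpec | None = None,
              base_params: ModelParams | None = None,
              weights: np.ndarray | None = None) -> CalibrationResult:
    """Estimate theta by simplex minimization of the moment distance.

    The cohort design is inferred from the panel's wave-1 records unless a
    ``spec`` is given.  Nelder-Mead runs once from ``init_theta`` and then
    from ``options.n_restarts`` perturbed starts; the best point is returned
    with a convergence flag (False when no start improved on the initial
    objective).
    """
    opts = options or CalibrationOptions()
    bnds = bounds if bounds is not None else default_bounds()
    base = base_params if base_params is not None else ModelParams.defaults()
    if isinstance(init_theta, dict):
        init_theta = np.array([init_theta[n] for n in THETA_NAMES])
    init_theta = np.asarray(init_theta, dtype=float)
    for i, name in enumerate(THETA_NAMES):
        lo, hi = bnds[name]
        if not lo <= init_theta[i] <= hi:
            raise ValueError(f"initial {name}={init_theta[i]} violates bounds [{lo},{hi}]")
    if spec is None:
        spec = CohortSpec.from_panel(panel)
    emp = aux_stats(panel)
    if weights is None:
        weights = bootstrap_weights(panel, n_boot=opts.n_boot_weights, seed=opts.seed)
        weight_desc = f"diagonal inverse-variance ({opts.n_boot_weights}-rep bootstrap)"
    else:
        weight_desc = "user-supplied diagonal"
    seed_set = tuple(int(x) for x in
                     child_rng(opts.seed, 11).integers(0, 2**31 - 1, size=opts.n_sim))

    free_idx = [THETA_NAMES.index(n) for n in opts.free]
    n_evals = 0

    def f(free_vals: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        th = init_theta.copy()
        th[free_idx] = free_vals
        return objective(th, emp, spec, opts.n_sim, seed_set, weights, base, bnds)

    rng = child_rng(opts.seed, 13)
    x0 = init_theta[free_idx]
    f0 = f(x0)
    best_x, best_f = x0.copy(), f0
    starts = [x0]
    for _ in range(opts.n_restarts):
        pert = best_x * (1.0 + opts.restart_scale * rng.standard_normal(len(free_idx))) \
            + 0.05 * opts.restart_scale * rng.standard_normal(len(free_idx))
        for k, i in enumerate(free_idx):
            lo, hi = bnds[THETA_NAMES[i]]
            pert[k] = min(max(pert[k], lo), hi)
        starts.append(pert)
    for x_start in starts:
        res = minimize(f, x_start, method="Nelder-Mead",
                       options={"maxfev": opts.max_evals, "xatol": opts.xatol,
                                "fatol": opts.fatol})
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.asarray(res.x)
    theta_hat = init_theta.copy()
    theta_hat[free_idx] = best_x
    converged = best_f < f0 or best_f <= opts.fatol
    if not converged:
        warnings.warn("no simplex start improved on the initial objective")
    return CalibrationResult(theta=theta_hat, se=None, objective_value=best_f,
                             n_evaluations=n_evals, converged=converged,
                             seed_set=seed_set, weight_desc=weight_desc,
                             free=tuple(opts.free))


def bootstrap_se(panel: CohortPanel, theta_hat: np.ndarray, B: int,
                 options: CalibrationOptions | None = None,
                 spec: CohortSpec | None = None,
                 base_params: ModelParams | None = None,
                 replicate_seeds: list[int] | None = None) -> np.ndarray:
    """Parametric-bootstrap standard errors.

    Simulates ``B`` fresh panels at ``theta_hat``, re-estimates each, and
    returns the per-parameter SD of the replicate estimates (0 for fixed
    parameters).  Non-convergent replicates are dropped with a warning;
    fewer than ``B/2`` usable replicates is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    opts = options or CalibrationOptions()
    base = base_params if base_params is not None else ModelParams.defaults()
    theta_hat = np.asarray(theta_hat, dtype=float)
    if spec is None:
        spec = CohortSpec.from_panel(panel)
    params_hat = _theta_to_params(theta_hat, base)
    if replicate_seeds is None:
        replicate_seeds = [int(x) for x in
                           child_rng(opts.seed, 29).integers(0, 2**31 - 1, size=B)]
    if len(replicate_seeds) != B:
        raise ValueError("replicate_seeds must have length B")
    estimates = []
    for b, sb in enumerate(replicate_seeds):
        profiles = sample_profiles(spec, seed=sb)
        panel_b = generate_panel(profiles, params_hat, spec, seed=sb)
        # re-estimation options derive from the replicate seed (not the index),
        # so identical replicate seeds yield identical estimates
        rep_opts = CalibrationOptions(**{**opts.__dict__,
                                         "seed": int(sb % (2**31 - 1))})
        try:
            res = calibrate(panel_b, theta_hat, options=rep_opts, spec=spec,
                            base_params=base)
        except ValueError:
            res = None
        if res is None or not res.converged:
            warnings.warn(f"bootstrap replicate {b} did not converge; excluded")
            continue
        estimates.append(res.theta)
    if len(estimates) < B / 2:
        raise RuntimeError(f"only {len(estimates)}/{B} bootstrap replicates usable")
    return np.std(np.array(estimates), axis=0, ddof=1)
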