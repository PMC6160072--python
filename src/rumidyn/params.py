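"""Model parameters for the depression-rumination-stressor system.

The model has twelve estimated parameters (``theta1`` ... ``theta12``)
plus a handful of numerical settings (stock adjustment times, integration
step, clamp bounds, memory-time floor) that define the simulation scheme
rather than the behavioural theory.

Parameter meanings
------------------
theta1   rumination constant (score units)
theta2   effect of depressive symptoms on rumination (dimensionless)
theta3   gender coefficient, added for girls (score units)
theta4   effect of active stressors on rumination (score per event)
theta5   rumination self-coefficient (dimensionless)
theta6   depression constant (score units)
theta7   effect of rumination on depressive symptoms (dimensionless)
theta8   depression self-coefficient (dimensionless)
theta9   effect of rumination on memory time (months per rumination unit)
theta10  stationary SD of the rumination process noise (score units)
theta11  stationary SD of the depression process noise (score units)
theta12  correlation time of both noise processes (months)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

__all__ = ["ModelParams", "load_params", "save_params"]

_THETA_NAMES = tuple(f"theta{i}" for i in range(1, 13))


@dataclass(frozen=True)
class ModelParams:
    """The twelve behavioural parameters plus integration settings.

    Defaults are the point estimates obtained by indirect inference on the
    661-adolescent three-wave panel; clamp bounds are the instrument ranges
    (CDI 0-52, rescaled rumination subscale 0-39, stressor stock >= 0).
    """

    theta1: float = -1.2504
    theta2: float = 0.4236
    theta3: float = 2.5152
    theta4: float = 0.2518
    theta5: float = 0.1639
    theta6: float = 0.3730
    theta7: float = 0.0699
    theta8: float = 0.8894
    theta9: float = 1.4741
    theta10: float = 7.8735
    theta11: float = 0.0002
    theta12: float = 1.6008
    tau_R: float = 1.0
    tau_D: float = 1.0
    M_min: float = 0.25
    dt: float = 0.125
    D_bounds: tuple[float, float] = (0.0, 52.0)
    R_bounds: tuple[float, float] = (0.0, 39.0)
    S_bounds: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if not all(math.isfinite(getattr(self, n)) for n in _THETA_NAMES[:9]):
            raise ValueError("theta1..theta9 must be finite")
        if self.theta9 <= 0:
            raise ValueError("theta9 (memory-time slope) must be > 0")
        if self.theta12 <= 0:
            raise ValueError("theta12 (noise correlation time) must be > 0")
        if self.theta10 < 0 or self.theta11 < 0:
            raise ValueError("noise stationary SDs must be >= 0")
        for name in ("tau_R", "tau_D", "M_min", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt > min(self.tau_R, self.tau_D, self.theta12) / 4.0:
            raise ValueError(
                "dt must satisfy dt <= min(tau_R, tau_D, theta12)/4 "
                "for a stable explicit Euler integration"
            )
        for name in ("D_bounds", "R_bounds", "S_bounds"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")

    @property
    def theta(self) -> tuple[float, ...]:
        """The twelve behavioural parameters as an ordered tuple."""
        return tuple(getattr(self, n) for n in _THETA_NAMES)

    def with_theta(self, **updates: float) -> "ModelParams":
        """Return a copy with some parameters replaced."""
        return replace(self, **updates)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = [None if x == math.inf else x for x in v]
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        kw = dict(d)
        for name in ("D_bounds", "R_bounds", "S_bounds"):
            if name in kw:
                lo, hi = kw[name]
                kw[name] = (lo, math.inf if hi is None else hi)
        return cls(**kw)

    @classmethod
    def defaults(cls) -> "ModelParams":
        """The shipped point estimates (``data/default_estimates.json``)."""
        text = resources.files("rumidyn.data").joinpath("default_estimates.json").read_text()
        return cls.from_dict(json.loads(text))


def load_params(path: str | Path) -> ModelParams:
    """Read a flat-JSON parameter file."""
    with open(path) as fh:
        return ModelParams.from_dict(json.load(fh))


def save_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)
        fh.write("\n")
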