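"""Synthetic three-wave cohorts emulating the adolescent panel study.

The empirical study measured 661 middle-schoolers (353 girls, 308 boys)
three times over seven months: rumination at months 0, 4 and 7; depressive
symptoms (CDI) and stressful-life-event counts at months 0 and 7 only.
That dataset is not publicly deposited, so this module generates cohorts
with the same design: initial conditions drawn from gender-specific
truncated normals matched to the published wave-1 moments, each individual
simulated forward with the stock-flow model, and the stocks observed at the
wave months on the instrument scales (rounded to integers, clipped to the
instrument ranges).

Conventions chosen for the generator: the baseline past-stressor stock S0
equals the wave-1 life-event count, and the ongoing-stressor inflow is that
count divided by six (the checklist asks about events in the past six
months), constant over the simulation.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .model import IndividualProfile, simulate_batch
from .params import ModelParams
from .seeds import child_rng

__all__ = ["CohortSpec", "CohortPanel", "sample_profiles", "generate_panel",
           "generate_wide", "write_panel", "read_panel"]

# instrument observation schedule: wave -> month, and which instruments
WAVE_MONTHS = (0.0, 4.0, 7.0)
INSTRUMENT_WAVES = {"cdi": (1, 3), "rumination": (1, 2, 3), "stressors": (1, 3)}
INSTRUMENT_RANGES = {"cdi": (0, 52), "rumination": (0, 39), "stressors": (0, 25)}

PANEL_COLUMNS = ["id", "gender", "wave", "month", "cdi", "rumination", "stressors"]

#: wave-1 moments of the published summary table, (mean, SD) per variable
GIRLS_WAVE1 = {"D0": (9.98, 6.45), "R0": (12.78, 7.71), "S0": (4.97, 3.14)}
BOYS_WAVE1 = {"D0": (8.91, 6.04), "R0": (10.23, 7.06), "S0": (4.96, 3.52)}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling design for a synthetic cohort.

    ``girls``/``boys`` map variable names (``D0``, ``R0``, ``S0``) to
    (mean, SD) pairs for independent truncated normals; ``bounds`` gives
    the truncation interval per variable.  ``inflow_scale`` converts the
    baseline stressor count into a constant events/month inflow (default
    1/6: the checklist covers the past six months).  ``noise_sd`` is
    measurement noise per instrument (default 0: the estimation treats
    process noise only).
    """

    n_girls: int = 353
    n_boys: int = 308
    girls: dict = field(default_factory=lambda: dict(GIRLS_WAVE1))
    boys: dict = field(default_factory=lambda: dict(BOYS_WAVE1))
    bounds: dict = field(default_factory=lambda: {
        "D0": (0.0, 52.0), "R0": (0.0, 39.0), "S0": (0.0, 25.0)})
    inflow_scale: float = 1.0 / 6.0
    s0_mode: str = "count"
    noise_sd: dict = field(default_factory=lambda: {
        "cdi": 0.0, "rumination": 0.0, "stressors": 0.0})
    wave_months: tuple = WAVE_MONTHS
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_girls < 0 or self.n_boys < 0:
            raise ValueError("cohort counts must be >= 0")
        if list(self.wave_months) != sorted(self.wave_months) or self.wave_months[0] != 0:
            raise ValueError("wave months must be strictly increasing from 0")
        for gender, moments in (("girls", self.girls), ("boys", self.boys)):
            for var, (mean, sd) in moments.items():
                if sd < 0:
                    raise ValueError(f"{gender} {var}: SD must be >= 0")
                lo, hi = self.bounds[var]
                if sd > 0 and not (lo - 6 * sd) <= mean <= (hi + 6 * sd):
                    raise ValueError(f"{gender} {var}: mean {mean} infeasibly far "
                                     f"outside truncation bounds {self.bounds[var]}")
                if sd == 0 and not lo <= mean <= hi:
                    raise ValueError(f"{gender} {var}: degenerate mean outside bounds")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("measurement-noise SDs must be >= 0")

    @classmethod
    def from_panel(cls, panel: "CohortPanel", **overrides) -> "CohortSpec":
        """Infer the sampling design from an observed panel's wave-1 records."""
        df = panel.frame
        w1 = df[df["wave"] == 1]
        moments = {}
        counts = {}
        for g, key in ((1, "girls"), (0, "boys")):
            sub = w1[w1["gender"] == g]
            counts[key] = len(sub)
            moments[key] = {
                "D0": (float(sub["cdi"].mean()), float(sub["cdi"].std(ddof=1))),
                "R0": (float(sub["rumination"].mean()), float(sub["rumination"].std(ddof=1))),
                "S0": (float(sub["stressors"].mean()), float(sub["stressors"].std(ddof=1))),
            }
        kw = dict(n_girls=counts["girls"], n_boys=counts["boys"],
                  girls=moments["girls"], boys=moments["boys"])
        kw.update(overrides)
        return cls(**kw)


@dataclass
class CohortPanel:
    """Long-format three-wave measurement panel.

    One row per individual per wave; ``cdi`` and ``stressors`` are missing
    (NaN) at wave 2 by design of the study instruments.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing_cols = set(PANEL_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"panel missing columns: {sorted(missing_cols)}")
        if len(df) == 0:
            return
        if not df["wave"].isin([1, 2, 3]).all():
            raise ValueError("panel column 'wave' must be in {1,2,3}")
        if not df["gender"].isin([0, 1]).all():
            raise ValueError("panel column 'gender' must be 0/1")
        for inst, (lo, hi) in INSTRUMENT_RANGES.items():
            vals = df[inst].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"panel column '{inst}' outside range [{lo},{hi}]")
        for inst, waves in INSTRUMENT_WAVES.items():
            observed = df[df["wave"].isin(waves)][inst]
            if observed.isna().any():
                raise ValueError(f"panel column '{inst}' missing at a scheduled wave")
            off = df[~df["wave"].isin(waves)][inst]
            if off.notna().any():
                raise ValueError(f"panel column '{inst}' recorded at an unscheduled wave")

    def __len__(self) -> int:
        return len(self.frame)

    def wide(self) -> dict[str, np.ndarray]:
        """Pivot to per-individual arrays keyed like ``R1``, ``D3``, ``S1``."""
        df = self.frame
        piv = df.pivot(index="id", columns="wave",
                       values=["cdi", "rumination", "stressors"]).sort_index()
        gender = (df.drop_duplicates("id").set_index("id")["gender"]
                  .reindex(piv.index).to_numpy())
        out = {"gender": gender.astype(float)}
        letter = {"cdi": "D", "rumination": "R", "stressors": "S"}
        for inst, waves in INSTRUMENT_WAVES.items():
            for w in waves:
                out[f"{letter[inst]}{w}"] = piv[(inst, w)].to_numpy(dtype=float)
        return out


def sample_profiles(spec: CohortSpec, seed: int | None = None,
                    params: ModelParams | None = None) -> list[IndividualProfile]:
    """Draw individual initial conditions from the cohort design.

    Truncated-normal marginals per gender and variable, independent across
    variables; constant inflow ``S0 * inflow_scale``.  Deterministic under
    ``seed``.  The sampled ``S0`` is a six-month checklist count; with
    ``spec.s0_mode == "count"`` (default) it is also the initial
    past-stressors stock, while ``"balance"`` sets the stock to the level a
    sustained history at that event rate implies,
    ``(count/6) * max(theta9*R0, M_min)`` (requires ``params``).
    """
    if spec.s0_mode not in ("count", "balance"):
        raise ValueError(f"unknown s0_mode {spec.s0_mode!r}")
    if spec.s0_mode == "balance" and params is None:
        raise ValueError("s0_mode='balance' needs model params (theta9, M_min)")
    rng = child_rng(seed if seed is not None else spec.seed, 0)
    profiles: list[IndividualProfile] = []
    for gender, n, moments in ((1, spec.n_girls, spec.girls),
                               (0, spec.n_boys, spec.boys)):
        draws = {}
        for var in ("D0", "R0", "S0"):
            mean, sd = moments[var]
            lo, hi = spec.bounds[var]
            if sd == 0:
                draws[var] = np.full(n, float(mean))
            else:
                a, b = (lo - mean) / sd, (hi - mean) / sd
                draws[var] = truncnorm.rvs(a, b, loc=mean, scale=sd,
                                           size=n, random_state=rng)
        for j in range(n):
            count = float(draws["S0"][j])
            if spec.s0_mode == "balance":
                stock = (count / 6.0) * max(params.theta9 * float(draws["R0"][j]),
                                            params.M_min)
            else:
                stock = count
            profiles.append(IndividualProfile(
                gender=gender, D0=float(draws["D0"][j]), R0=float(draws["R0"][j]),
                S0=stock, inflow=count * spec.inflow_scale))
    return profiles


def profiles_to_arrays(profiles: list[IndividualProfile]) -> dict[str, np.ndarray]:
    return {
        "D0": np.array([p.D0 for p in profiles]),
        "R0": np.array([p.R0 for p in profiles]),
        "S0": np.array([p.S0 for p in profiles]),
        "G": np.array([p.gender for p in profiles], dtype=float),
        "u": np.array([p.inflow_at(0.0) for p in profiles]),
    }


def generate_wide(profiles: list[IndividualProfile], params: ModelParams,
                  spec: CohortSpec, seed: int | None = None,
                  noise: bool = True) -> dict[str, np.ndarray]:
    """Simulate the cohort and observe it at the wave months (wide format).

    Returns arrays ``gender, D1, D3, R1, R2, R3, S1, S3`` on the instrument
    scales (measurement noise added, rounded to integers, clipped).  This is
    the fast path behind :func:`generate_panel`; both produce identical
    measurements for the same seed.
    """
    arr = profiles_to_arrays(profiles)
    horizon = spec.wave_months[-1]
    record = [int(round(m / params.dt)) for m in spec.wave_months]
    rng = child_rng(seed if seed is not None else spec.seed, 1)
    sim = simulate_batch(arr["D0"], arr["R0"], arr["S0"], arr["G"], arr["u"],
                         params, horizon, rng=rng if noise else None,
                         record_steps=record)
    meas_rng = child_rng(seed if seed is not None else spec.seed, 2)
    letter = {"cdi": "D", "rumination": "R", "stressors": "S"}
    out = {"gender": arr["G"]}
    n = len(profiles)
    for inst, waves in INSTRUMENT_WAVES.items():
        lo, hi = INSTRUMENT_RANGES[inst]
        sd = spec.noise_sd.get(inst, 0.0)
        for w in waves:
            raw = sim[letter[inst]][w - 1]
            if sd > 0:
                raw = raw + meas_rng.standard_normal(n) * sd
            out[f"{letter[inst]}{w}"] = np.clip(np.round(raw), lo, hi)
    return out


def generate_panel(profiles: list[IndividualProfile], params: ModelParams,
                   spec: CohortSpec, seed: int | None = None,
                   noise: bool = True) -> CohortPanel:
    """Simulate each profile and assemble the long-format three-wave panel."""
    wide = generate_wide(profiles, params, spec, seed=seed, noise=noise)
    n = len(profiles)
    rows = []
    for w, month in zip((1, 2, 3), spec.wave_months):
        rec = {
            "id": np.arange(n),
            "gender": wide["gender"].astype(int),
            "wave": np.full(n, w),
            "month": np.full(n, month),
        }
        for inst, waves in INSTRUMENT_WAVES.items():
            letter = {"cdi": "D", "rumination": "R", "stressors": "S"}[inst]
            rec[inst] = wide[f"{letter}{w}"] if w in waves else np.full(n, np.nan)
        rows.append(pd.DataFrame(rec))
    frame = pd.concat(rows, ignore_index=True)
    frame = frame.sort_values(["id", "wave"], kind="stable").reset_index(drop=True)
    return CohortPanel(frame[PANEL_COLUMNS])


def write_panel(panel: CohortPanel, path: str | Path) -> None:
    """Write the panel as CSV; missing observations become empty cells."""
    panel.frame.to_csv(path, index=False)


def read_panel(path: str | Path) -> CohortPanel:
    """Read and validate a panel CSV (inverse of :func:`write_panel`)."""
    df = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel file {path} missing columns: {sorted(missing)}")
    return CohortPanel(df[PANEL_COLUMNS])
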