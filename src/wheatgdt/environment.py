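"""Synthetic daily environment drivers and per-organ stress schedules.

The weather generator produces seasonal sinusoids with seeded Gaussian
noise for air temperature and PAR, an AR(1) process for relative
humidity, constant ambient CO2 and a constant (or linearly depleting)
soil nitrate concentration.  Stress events are turned into per-day,
per-organ, per-stressor intensities following a trapezoidal profile;
overlapping events of the same stressor combine by maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StressEvent, WeatherParams
from .state import OrganKind

#: stress_inputs type: organ -> stressor name -> intensity in [0, 1]
StressInputs = dict[OrganKind, dict[str, float]]


@dataclass
class EnvironmentDay:
    """Daily environmental drivers plus the stress inputs for every organ."""

    day: int
    par: float  # midday-equivalent PAR, umol photons m-2 s-1
    t_air: float  # degC
    t_leaf: float  # degC
    rel_humidity: float  # fraction in [0, 1]
    ca: float  # ambient CO2, umol mol-1
    soil_no3: float  # mol m-3
    stress_inputs: StressInputs = field(default_factory=dict)

    def validate(self) -> None:
        if self.par < 0 or self.ca <= 0 or self.soil_no3 < 0:
            raise ValueError(f"environment day {self.day}: driver out of range")
        if not (0.0 <= self.rel_humidity <= 1.0):
            raise ValueError(f"environment day {self.day}: humidity out of [0,1]")

    def organ_stress(self, kind: OrganKind) -> dict[str, float]:
        return self.stress_inputs.get(kind, {})


def seasonal_temperature(day: int, params: WeatherParams) -> float:
    """Noise-free seasonal air temperature (the closed-form sinusoid)."""
    return params.t_mean + params.t_amp * math.sin(
        2.0 * math.pi * (day + params.t_phase) / params.period
    )


def seasonal_par(day: int, params: WeatherParams) -> float:
    """Noise-free seasonal midday PAR, clipped at zero."""
    raw = params.par_mean + params.par_amp * math.sin(
        2.0 * math.pi * (day + params.t_phase) / params.period
    )
    return max(raw, 0.0)


def generate_weather(
    n_days: int, seed: int, params: WeatherParams | None = None
) -> list[EnvironmentDay]:
    """Generate ``n_days`` of synthetic weather, deterministic for a seed."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    params = params or WeatherParams()
    rng = np.random.default_rng(seed)
    t_noise = rng.normal(0.0, params.t_noise_sd, n_days) if params.t_noise_sd > 0 else np.zeros(n_days)
    p_noise = rng.normal(0.0, params.par_noise_sd, n_days) if params.par_noise_sd > 0 else np.zeros(n_days)
    h_noise = rng.normal(0.0, params.rh_noise_sd, n_days) if params.rh_noise_sd > 0 else np.zeros(n_days)

    days: list[EnvironmentDay] = []
    rh = params.rh_mean
    for d in range(n_days):
        t_air = seasonal_temperature(d, params) + t_noise[d]
        par = max(seasonal_par(d, params) + p_noise[d], 0.0)
        rh = params.rh_mean + params.rh_rho * (rh - params.rh_mean) + h_noise[d]
        rh = min(max(rh, 0.0), 1.0)
        no3 = max(params.soil_no3 - params.soil_no3_depletion * d, 0.0)
        env = EnvironmentDay(
            day=d,
            par=par,
            t_air=t_air,
            t_leaf=t_air + params.t_leaf_offset,
            rel_humidity=rh,
            ca=params.ca,
            soil_no3=no3,
        )
        env.validate()
        days.append(env)
    return days


def apply_stress_schedule(
    events: list[StressEvent], n_days: int
) -> list[StressInputs]:
    """Expand stress events into one stress-input map per day.

    Overlapping events of the same stressor name combine by maximum;
    organs not targeted by any event get no entry (intensity zero).
    """
    for ev in events:
        if ev.start_day >= n_days or ev.start_day < 0:
            raise ValueError(
                f"stress event '{ev.name}' lies outside the horizon [0, {n_days})"
            )
    schedule: list[StressInputs] = []
    for d in range(n_days):
        inputs: StressInputs = {}
        for ev in events:
            x = min(max(ev.intensity(d), 0.0), 1.0)
            if x <= 0.0:
                continue
            for kind in ev.target_organs:
                per_organ = inputs.setdefault(kind, {})
                key = ev.name
                per_organ[key] = max(per_organ.get(key, 0.0), x)
        schedule.append(inputs)
    return schedule


def stressor_classes(events: list[StressEvent]) -> dict[str, str]:
    """Map stressor name -> class ('biotic'/'abiotic') across the event set."""
    classes: dict[str, str] = {}
    for ev in events:
        prev = classes.get(ev.name)
        if prev is not None and prev != ev.stress_class:
            raise ValueError(
                f"stressor '{ev.name}' declared with conflicting classes"
            )
        classes[ev.name] = ev.stress_class
    return classes


def build_environment(
    n_days: int,
    seed: int,
    weather: WeatherParams | None = None,
    events: list[StressEvent] | None = None,
) -> list[EnvironmentDay]:
    """Weather plus stress schedule in one pass."""
    days = generate_weather(n_days, seed, weather)
    if events:
        schedule = apply_stress_schedule(events, n_days)
        for env, inputs in zip(days, schedule):
            env.stress_inputs = inputs
    return days


ENV_CSV_COLUMNS = ["day", "par", "t_air", "t_leaf", "rel_humidity", "ca", "soil_no3"]


def write_environment_csv(days: list[EnvironmentDay], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "day": e.day,
                "par": e.par,
                "t_air": e.t_air,
                "t_leaf": e.t_leaf,
                "rel_humidity": e.rel_humidity,
                "ca": e.ca,
                "soil_no3": e.soil_no3,
            }
            for e in days
        ],
        columns=ENV_CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_environment_csv(path: str | Path) -> list[EnvironmentDay]:
    df = pd.read_csv(path)
    missing = [c for c in ENV_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"environment CSV missing columns: {missing}")
    days = []
    for row in df.itertuples(index=False):
        env = EnvironmentDay(
            day=int(row.day),
            par=float(row.par),
            t_air=float(row.t_air),
            t_leaf=float(row.t_leaf),
            rel_humidity=float(row.rel_humidity),
            ca=float(row.ca),
            soil_no3=float(row.soil_no3),
        )
        env.validate()
        days.append(env)
    return days
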