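"""Stress signals and dynamic defense coefficients.

An organ's local stress signal S0 in [0, 1] is derived from normalized
proxy indicators (stand-ins for hormone concentrations, transcriptional
markers or NIRS profiles) or, in simulation, from the scheduled stress
intensities.  Signals from different stress classes combine through a
configurable rule (additive cap, interaction surface, or dominance).
The defense coefficient D follows a Hill dose-response of S0 and
first-order induction/relaxation dynamics with asymmetric rates, which
produces hysteresis and priming-like behaviour.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .config import DefenseParams


def stress_signal_from_proxies(
    proxies: dict[str, float], weights: dict[str, float] | None = None
) -> float:
    """Weight-normalized mean of proxy values, clamped to [0, 1].

    All proxies default to weight 1; at least one weight must be positive.
    """
    if not proxies:
        raise ValueError("at least one proxy is required")
    if weights is None:
        weights = {name: 1.0 for name in proxies}
    if any(w < 0 for w in weights.values()):
        raise ValueError("proxy weights must be >= 0")
    total_w = sum(weights.get(name, 0.0) for name in proxies)
    if total_w <= 0:
        raise ValueError("at least one proxy weight must be positive")
    s = sum(proxies[name] * weights.get(name, 0.0) for name in proxies) / total_w
    return min(max(s, 0.0), 1.0)


def combine_stress_signals(
    s_a: float, s_b: float, mode: str = "surface", gamma: float = 0.0
) -> float:
    """Combine two stress signals into one, in [0, 1].

    additive:   min(s_a + s_b, 1)
    surface:    min(s_a + s_b + gamma s_a s_b, 1)  (gamma > 0 synergistic,
                gamma < 0 antagonistic)
    dominance:  max(s_a, s_b)  (most limiting factor rules)
    """
    for s in (s_a, s_b):
        if not (0.0 <= s <= 1.0):
            raise ValueError("stress signals must lie in [0, 1]")
    if mode == "additive":
        s = s_a + s_b
    elif mode == "surface":
        s = s_a + s_b + gamma * s_a * s_b
    elif mode == "dominance":
        s = max(s_a, s_b)
    else:
        raise ValueError(f"unknown combination mode '{mode}'")
    return min(max(s, 0.0), 1.0)


def defense_dose_response(s0: float, params: DefenseParams) -> float:
    """Steady-state defense target for a stress level: Hill saturation
    d_max s0^h / (s50^h + s0^h); the categorical3 mode snaps the
    continuous value to {0, d_max/2, d_max} by terciles."""
    if not (0.0 <= s0 <= 1.0):
        raise ValueError("s0 must lie in [0, 1]")
    if s0 == 0.0:
        d = 0.0
    else:
        num = s0**params.hill_h
        d = params.d_max * num / (params.s50**params.hill_h + num)
    if params.mode == "categorical3":
        third = params.d_max / 3.0
        if d < third:
            d = 0.0
        elif d < 2.0 * third:
            d = params.d_max / 2.0
        else:
            d = params.d_max
    return d


def update_defense_coefficient(
    d: float, d_target: float, params: DefenseParams, dt: float = 1.0
) -> float:
    """First-order relaxation of D toward its dose-response target.

    Induction (target above current) uses k_induction, relaxation uses the
    slower k_relaxation, giving the response its hysteresis:
    d' = d + (1 - exp(-k dt)) (d_target - d), clamped to [0, 1].
    """
    k = params.k_induction if d_target > d else params.k_relaxation
    d_new = d + (1.0 - math.exp(-k * dt)) * (d_target - d)
    return min(max(d_new, 0.0), 1.0)


def simulate_defense_series(
    s0_series: Sequence[float], params: DefenseParams, d0: float = 0.0
) -> np.ndarray:
    """Daily D trajectory driven by a stress-signal series (D after each day)."""
    d = d0
    out = np.empty(len(s0_series))
    for i, s0 in enumerate(s0_series):
        d = update_defense_coefficient(d, defense_dose_response(s0, params), params)
        out[i] = d
    return out


def fit_defense_dynamics(
    observed_d: Sequence[float],
    s0_series: Sequence[float],
    params: DefenseParams,
    s50_grid: Iterable[float] | None = None,
    k_induction_grid: Iterable[float] | None = None,
    d0: float = 0.0,
) -> tuple[float, float]:
    """Recover (s50, k_induction) from an observed D time series by
    least-squares grid search, holding the remaining parameters at the
    values in ``params``.  Returns the best (s50, k_induction) pair."""
    observed = np.asarray(observed_d, dtype=float)
    if len(observed) != len(s0_series):
        raise ValueError("observed series and stress series differ in length")
    s50_grid = list(s50_grid) if s50_grid is not None else list(np.linspace(0.1, 0.8, 71))
    k_grid = (
        list(k_induction_grid)
        if k_induction_grid is not None
        else list(np.linspace(0.1, 1.2, 111))
    )
    best = (params.s50, params.k_induction)
    best_sse = math.inf
    for s50 in s50_grid:
        for k in k_grid:
            trial = params.model_copy(update={"s50": float(s50), "k_induction": float(k)})
            pred = simulate_defense_series(s0_series, trial, d0=d0)
            sse = float(np.sum((pred - observed) ** 2))
            if sse < best_sse:
                best_sse = sse
                best = (float(s50), float(k))
    return best
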