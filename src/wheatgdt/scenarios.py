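"""Scenario sets: control vs single vs combined stress, the
non-additivity index, and the sustained-challenge defense accounting.

A scenario set shares one base configuration and seed (hence identical
weather) and varies only in its stress events, so biomass differences
are attributable to the stress treatments alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DefenseOverride, SimulationConfig, StressEvent
from .simulation import run_simulation
from .state import OrganKind, Trajectory

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"
ADDITIVE = "additive"


def _heat_event(start: int = 55, end: int = 85, peak: float = 0.2) -> StressEvent:
    return StressEvent(
        name="heat",
        stress_class="abiotic",
        target_organs=list(OrganKind),
        start_day=start,
        end_day=end,
        peak_intensity=peak,
        ramp_days=5,
    )


def _biotic_event(
    start: int = 60, end: int = 80, peak: float = 0.2
) -> StressEvent:
    return StressEvent(
        name="pathogen",
        stress_class="biotic",
        target_organs=[OrganKind.MATURE_LEAF, OrganKind.GROWING_LEAF],
        start_day=start,
        end_day=end,
        peak_intensity=peak,
        ramp_days=3,
    )


@dataclass
class ScenarioSet:
    """Named config variants sharing base parameters and seed."""

    control: SimulationConfig
    stress_a: SimulationConfig
    stress_b: SimulationConfig
    combined: SimulationConfig

    def as_dict(self) -> dict[str, SimulationConfig]:
        return {
            "control": self.control,
            "stress_a": self.stress_a,
            "stress_b": self.stress_b,
            "combined": self.combined,
        }


def default_scenario_set(
    base: SimulationConfig | None = None, gamma: float | None = None
) -> ScenarioSet:
    """Control, single heat, single pathogen, and combined heat+pathogen
    (overlapping mid-season windows on shared organs)."""
    from .config import default_config

    base = base or default_config()

    def variant(events: list[StressEvent]) -> SimulationConfig:
        cfg = base.model_copy(deep=True)
        cfg.stress.events = events
        if gamma is not None:
            cfg.stress.gamma = gamma
        return cfg

    return ScenarioSet(
        control=variant([]),
        stress_a=variant([_heat_event()]),
        stress_b=variant([_biotic_event()]),
        combined=variant([_heat_event(), _biotic_event()]),
    )


def run_scenario_set(scenarios: ScenarioSet) -> dict[str, Trajectory]:
    return {name: run_simulation(cfg) for name, cfg in scenarios.as_dict().items()}


def final_biomass(traj: Trajectory) -> float:
    return traj.final_total_mass()


def non_additivity_index(
    results: dict[str, Trajectory], scenarios: ScenarioSet | None = None
) -> tuple[float, str]:
    """NAI = [Delta_combined - (Delta_a + Delta_b)] / biomass_control,
    with Delta_x the biomass lost to treatment x relative to control.

    Positive NAI: the combination hurts more than the sum of its parts
    (synergistic damage); negative: antagonistic.
    """
    needed = {"control", "stress_a", "stress_b", "combined"}
    missing = needed - set(results)
    if missing:
        raise ValueError(f"scenario results missing variants: {sorted(missing)}")
    if scenarios is not None:
        cfgs = scenarios.as_dict()
        seeds = {cfgs[k].seed for k in needed}
        horizons = {cfgs[k].horizon_days for k in needed}
        if len(seeds) != 1 or len(horizons) != 1:
            raise ValueError("scenario variants differ in seed or horizon; not comparable")
    b = {k: final_biomass(v) for k, v in results.items()}
    if b["control"] <= 0:
        raise ValueError("control biomass must be positive")
    d_a = b["control"] - b["stress_a"]
    d_b = b["control"] - b["stress_b"]
    d_comb = b["control"] - b["combined"]
    nai = (d_comb - (d_a + d_b)) / b["control"]
    label = SYNERGISTIC if nai > 0 else (ANTAGONISTIC if nai < 0 else ADDITIVE)
    return nai, label


def biotic_challenge_config(
    base: SimulationConfig | None = None,
    start_day: int = 90,
    n_days: int = 20,
    peak: float = 0.8,
) -> SimulationConfig:
    """Sustained biotic challenge on the mature leaf with the defense
    coefficient clamped to full activation over the challenge window."""
    from .config import default_config

    cfg = (base or default_config()).model_copy(deep=True)
    end_day = start_day + n_days - 1
    cfg.stress.events = [
        StressEvent(
            name="pathogen",
            stress_class="biotic",
            target_organs=[OrganKind.MATURE_LEAF],
            start_day=start_day,
            end_day=end_day,
            peak_intensity=peak,
            ramp_days=0,
        )
    ]
    cfg.defense_override = DefenseOverride(
        organs=[OrganKind.MATURE_LEAF], value=1.0, start_day=start_day, end_day=end_day
    )
    return cfg


def defense_consumption_fraction(
    traj: Trajectory,
    kind: OrganKind = OrganKind.MATURE_LEAF,
    start_day: int = 90,
    end_day: int = 109,
) -> float:
    """Share of the organ's photosynthate consumed by defense over a window.

    Numerator: defense respiration (the D x C_defense maintenance term)
    plus defense-compound synthesis substrate; denominator: the organ's
    assimilated carbon.  Returned as a fraction (0.12 = 12 %)."""
    num = 0.0
    den = 0.0
    for rec in traj.records:
        if start_day <= rec.day <= end_day:
            orec = rec.organs[kind]
            num += orec.maintenance_defense_paid_c + orec.defense_synthesis_c
            den += orec.photosynthesis_c
    if den <= 0:
        raise ValueError("no photosynthate assimilated over the challenge window")
    return num / den
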