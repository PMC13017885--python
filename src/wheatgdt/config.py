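"""Scenario configuration: schema, validation, defaults, YAML round-trip.

A simulation is fully described by one :class:`SimulationConfig` object.
The genotype block groups the physiological parameter sets (gas exchange,
nitrogen uptake, respiration, defense dynamics, stoichiometry, allocation
rules); the scenario part holds initial organ states, phenology, weather
generator settings, and the stress event schedule.  ``parse_config``
reads a YAML file and reports every out-of-range key with its path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .state import ALL_KINDS, LEAF_KINDS, OrganKind


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ArrheniusEnergies(_Model):
    """Activation energies (J mol-1) for the photosynthetic parameters."""

    vcmax: float = 65330.0
    jmax: float = 43540.0
    tpu: float = 53100.0
    rd: float = 46390.0
    kc: float = 79430.0
    ko: float = 36380.0
    gamma_star: float = 37830.0


class GasExchangeParams(_Model):
    """FvCB + Ball-Woodrow-Berry leaf parameters, all at 25 degC reference."""

    vcmax25: float = Field(90.0, gt=0, description="max carboxylation, umol m-2 s-1")
    jmax25: float = Field(170.0, gt=0, description="max electron transport, umol m-2 s-1")
    tpu25: float = Field(11.0, gt=0, description="triose-phosphate use, umol m-2 s-1")
    rd25: float = Field(1.0, gt=0, description="day respiration, umol m-2 s-1")
    kc25: float = Field(404.9, gt=0, description="Rubisco Km for CO2, umol mol-1")
    ko25: float = Field(278.4, gt=0, description="Rubisco Km for O2, mmol mol-1")
    gamma_star25: float = Field(42.75, gt=0, description="CO2 compensation point, umol mol-1")
    o2: float = Field(210.0, gt=0, description="O2 mole fraction, mmol mol-1")
    ea: ArrheniusEnergies = Field(default_factory=ArrheniusEnergies)
    alpha: float = Field(0.3, gt=0, description="quantum yield of electron transport")
    theta: float = Field(0.9, ge=0, le=1, description="light-response curvature")
    g0: float = Field(0.01, ge=0, description="residual conductance, mol m-2 s-1")
    g1: float = Field(9.0, gt=0, description="BWB slope, dimensionless")
    t_ref: float = Field(25.0, description="Arrhenius reference temperature, degC")


class NitrogenUptakeParams(_Model):
    """Root nitrate uptake: saturating HATS + linear LATS, C-status regulated."""

    vmax_hats: float = Field(0.02, ge=0, description="HATS Vmax, g N g-1 root d-1")
    km_hats: float = Field(0.05, gt=0, description="HATS Km, mol m-3")
    k_lats: float = Field(0.002, ge=0, description="LATS slope, g N g-1 root d-1 per mol m-3")
    lats_threshold: float = Field(0.0, ge=0, description="optional LATS activation threshold, mol m-3")
    c_reg_k: float = Field(0.05, gt=0, description="half-saturation of C regulation, g C g-1 root")
    f_min: float = Field(0.1, ge=0, lt=1, description="uptake floor of the C-regulation factor")
    regulation: bool = Field(True, description="enable regulation by root carbon status")


class RespirationParams(_Model):
    """Growth/maintenance respiration with the explicit defense term
    R_maintenance = R_basal + D x C_defense."""

    growth_yield: float = Field(0.75, gt=0, le=1, description="g structural DM per g C-substrate")
    m_base: dict[OrganKind, float] = Field(
        default_factory=lambda: {
            OrganKind.ROOTS: 0.010,
            OrganKind.SENESCENT_LEAF: 0.004,
            OrganKind.MATURE_LEAF: 0.015,
            OrganKind.GROWING_LEAF: 0.015,
            OrganKind.EMERGING_LEAF: 0.015,
            OrganKind.GRAIN: 0.008,
        },
        description="basal maintenance coefficient, g C g-1 DM d-1 at 25 degC",
    )
    c_defense: float = Field(
        0.0055, ge=0, description="defense respiratory cost at D=1, g C g-1 DM d-1"
    )
    q10: float = Field(2.0, gt=0, description="maintenance temperature sensitivity")
    t_ref: float = Field(25.0, description="reference temperature for Q10, degC")
    process_costs: dict[str, float] = Field(
        default_factory=dict,
        description="per-process metabolic costs for the itemized accounting mode",
    )

    @model_validator(mode="after")
    def _complete_mbase(self) -> "RespirationParams":
        missing = [k for k in ALL_KINDS if k not in self.m_base]
        if missing:
            raise ValueError(f"m_base missing organ kinds: {[k.value for k in missing]}")
        if any(v < 0 for v in self.m_base.values()):
            raise ValueError("m_base coefficients must be >= 0")
        return self


class StoichiometryParams(_Model):
    """Elemental composition constants coupling the C and N budgets.

    Structural tissue holds ``c_per_g_dm`` g C per g dry matter and a fixed
    C:N mass ratio ``tissue_cn`` per organ kind (leaf tissue sits in the
    10-15 range).  Defense compounds are a two-class mix: a phenolic-like
    class costed in glucose equivalents and a protein-like class with the
    low protein C:N ratio of 3.5.
    """

    c_per_g_dm: dict[OrganKind, float] = Field(
        default_factory=lambda: {
            OrganKind.ROOTS: 0.45,
            OrganKind.SENESCENT_LEAF: 0.45,
            OrganKind.MATURE_LEAF: 0.45,
            OrganKind.GROWING_LEAF: 0.45,
            OrganKind.EMERGING_LEAF: 0.45,
            OrganKind.GRAIN: 0.44,
        }
    )
    tissue_cn: dict[OrganKind, float] = Field(
        default_factory=lambda: {
            OrganKind.ROOTS: 25.0,
            OrganKind.SENESCENT_LEAF: 12.5,
            OrganKind.MATURE_LEAF: 12.5,
            OrganKind.GROWING_LEAF: 12.5,
            OrganKind.EMERGING_LEAF: 12.5,
            OrganKind.GRAIN: 20.0,
        }
    )
    protein_cn: float = Field(3.5, gt=0, description="protein C:N mass ratio")
    phenolic_glucose_cost: float = Field(
        2.5, gt=0, description="g glucose-equivalent per g phenolic compound"
    )
    glucose_c_fraction: float = Field(0.4, gt=0, le=1, description="g C per g glucose")
    protein_c_fraction: float = Field(0.53, gt=0, le=1, description="g C per g protein")
    defense_protein_fraction: float = Field(
        0.3, ge=0, le=1, description="protein-like fraction of the defense compound mix"
    )

    @model_validator(mode="after")
    def _complete(self) -> "StoichiometryParams":
        for name, d in (("c_per_g_dm", self.c_per_g_dm), ("tissue_cn", self.tissue_cn)):
            missing = [k for k in ALL_KINDS if k not in d]
            if missing:
                raise ValueError(f"{name} missing organ kinds: {[k.value for k in missing]}")
            if any(v <= 0 for v in d.values()):
                raise ValueError(f"{name} entries must be > 0")
        return self

    @property
    def defense_c_per_g(self) -> float:
        """g C consumed as substrate per g of defense compound synthesized."""
        fp = self.defense_protein_fraction
        phenolic = self.phenolic_glucose_cost * self.glucose_c_fraction
        return (1.0 - fp) * phenolic + fp * self.protein_c_fraction

    @property
    def defense_n_per_g(self) -> float:
        """g N immobilized per g of defense compound synthesized."""
        fp = self.defense_protein_fraction
        return fp * self.protein_c_fraction / self.protein_cn


class DefenseParams(_Model):
    """Dose-response and induction/relaxation dynamics of the defense
    coefficient D, plus the defense-compound synthesis demand rate."""

    d_max: float = Field(0.8, gt=0, le=1, description="saturating defense level")
    s50: float = Field(0.4, gt=0, lt=1, description="stress level of half-maximal response")
    hill_h: float = Field(2.0, ge=1, description="dose-response steepness")
    k_induction: float = Field(0.5, gt=0, description="induction rate, d-1")
    k_relaxation: float = Field(0.2, gt=0, description="relaxation rate, d-1")
    mode: Literal["continuous", "categorical3"] = "continuous"
    genotype_id: str = "default"
    s_def_rate: float = Field(
        0.016, ge=0, description="defense synthesis demand at D=1, g compound g-1 organ d-1"
    )


class GrowthLaw(_Model):
    """Potential growth of one organ kind with a beta-shaped sink strength."""

    g_rate: float = Field(0.0, ge=0, description="potential growth; d-1 (relative) or g d-1 (absolute)")
    rate_mode: Literal["relative", "absolute"] = "relative"
    beta_a: float = Field(1.0, ge=1)
    beta_b: float = Field(1.0, ge=1)
    duration: float = Field(300.0, gt=0, description="active growth window, days")


def _default_growth() -> dict[OrganKind, "GrowthLaw"]:
    # Leaf and grain sinks are bounded by absolute beta-windowed rates
    # (organ size classes have a finite expansion potential); the root
    # sink scales with root mass over the vegetative window, so the root
    # system keeps absorbing assimilate surplus and whole-plant growth
    # stays source-limited rather than exploding through the leaf-area
    # feedback.
    return {
        OrganKind.ROOTS: GrowthLaw(g_rate=0.09, beta_a=1.0, beta_b=1.0, duration=85.0),
        OrganKind.SENESCENT_LEAF: GrowthLaw(g_rate=0.0),
        OrganKind.MATURE_LEAF: GrowthLaw(g_rate=0.0),
        OrganKind.GROWING_LEAF: GrowthLaw(
            g_rate=0.10, rate_mode="absolute", beta_a=2.0, beta_b=2.0, duration=90.0
        ),
        OrganKind.EMERGING_LEAF: GrowthLaw(
            g_rate=0.05, rate_mode="absolute", beta_a=1.5, beta_b=3.0, duration=70.0
        ),
        OrganKind.GRAIN: GrowthLaw(
            g_rate=0.20, rate_mode="absolute", beta_a=2.0, beta_b=2.0, duration=50.0
        ),
    }


class AllocationParams(_Model):
    """Inter-organ priorities, stress modulation and store targets."""

    priorities_vegetative: dict[OrganKind, float] = Field(
        default_factory=lambda: {
            OrganKind.ROOTS: 0.8,
            OrganKind.SENESCENT_LEAF: 0.2,
            OrganKind.MATURE_LEAF: 0.5,
            OrganKind.GROWING_LEAF: 1.0,
            OrganKind.EMERGING_LEAF: 1.2,
            OrganKind.GRAIN: 0.0,
        }
    )
    priorities_reproductive: dict[OrganKind, float] = Field(
        default_factory=lambda: {
            OrganKind.ROOTS: 0.4,
            OrganKind.SENESCENT_LEAF: 0.2,
            OrganKind.MATURE_LEAF: 0.4,
            OrganKind.GROWING_LEAF: 0.3,
            OrganKind.EMERGING_LEAF: 0.2,
            OrganKind.GRAIN: 1.5,
        }
    )
    stress_boost_beta: float = Field(
        0.5, ge=0, description="priority boost per unit organ stress signal"
    )
    sigma_max: float = Field(
        0.3, ge=0, le=1, description="max source downregulation at s0 = 1"
    )
    growth: dict[OrganKind, GrowthLaw] = Field(default_factory=_default_growth)
    store_target_c: dict[OrganKind, float] = Field(
        default_factory=lambda: {
            OrganKind.ROOTS: 0.10,
            OrganKind.SENESCENT_LEAF: 0.0,
            OrganKind.MATURE_LEAF: 0.05,
            OrganKind.GROWING_LEAF: 0.05,
            OrganKind.EMERGING_LEAF: 0.05,
            OrganKind.GRAIN: 0.02,
        },
        description="target labile C concentration, g C g-1 DM",
    )
    store_target_n: dict[OrganKind, float] = Field(
        default_factory=lambda: {
            OrganKind.ROOTS: 0.02,
            OrganKind.SENESCENT_LEAF: 0.0,
            OrganKind.MATURE_LEAF: 0.02,
            OrganKind.GROWING_LEAF: 0.02,
            OrganKind.EMERGING_LEAF: 0.02,
            OrganKind.GRAIN: 0.005,
        },
        description="target labile N concentration, g N g-1 DM",
    )
    store_refill: bool = True

    @model_validator(mode="after")
    def _check(self) -> "AllocationParams":
        for name, d in (
            ("priorities_vegetative", self.priorities_vegetative),
            ("priorities_reproductive", self.priorities_reproductive),
            ("growth", self.growth),
            ("store_target_c", self.store_target_c),
            ("store_target_n", self.store_target_n),
        ):
            missing = [k for k in ALL_KINDS if k not in d]
            if missing:
                raise ValueError(f"{name} missing organ kinds: {[k.value for k in missing]}")
        for name, d in (
            ("priorities_vegetative", self.priorities_vegetative),
            ("priorities_reproductive", self.priorities_reproductive),
        ):
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name} weights must be >= 0")
            if not any(v > 0 for v in d.values()):
                raise ValueError(f"{name} needs at least one positive weight")
        return self


class RemobilizationParams(_Model):
    """Daily fractional export from senescent-leaf stores back to the pool."""

    r_c: float = Field(0.03, ge=0, le=1, description="C store fraction exported per day")
    r_n: float = Field(0.05, ge=0, le=1, description="N store fraction exported per day")
    a_sen: float = Field(1.0, ge=0, description="stress acceleration of remobilization")


class StressEvent(_Model):
    """One stress episode with a trapezoidal intensity profile: linear ramp
    up over ``ramp_days`` from ``start_day``, plateau at ``peak_intensity``
    until ``end_day``, then linear ramp down over ``ramp_days``."""

    name: str = "stress"
    stress_class: Literal["biotic", "abiotic"]
    target_organs: list[OrganKind]
    start_day: int = Field(ge=0)
    end_day: int = Field(ge=0)
    peak_intensity: float = Field(ge=0, le=1)
    ramp_days: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "StressEvent":
        if self.end_day < self.start_day:
            raise ValueError("end_day must be >= start_day")
        if not self.target_organs:
            raise ValueError("a stress event must name at least one target organ")
        return self

    def intensity(self, day: int) -> float:
        if day < self.start_day or day > self.end_day + self.ramp_days:
            return 0.0
        if self.ramp_days > 0 and day < self.start_day + self.ramp_days:
            return self.peak_intensity * (day - self.start_day) / self.ramp_days
        if day <= self.end_day:
            return self.peak_intensity
        return self.peak_intensity * (1.0 - (day - self.end_day) / self.ramp_days)


class StressConfig(_Model):
    combination_mode: Literal["additive", "surface", "dominance"] = "surface"
    gamma: float = Field(0.0, description="interaction strength of the surface mode")
    events: list[StressEvent] = Field(default_factory=list)


class DefenseOverride(_Model):
    """Clamp the defense coefficient of selected organs over a day window
    (used e.g. to hold D = 1 during a sustained challenge)."""

    organs: list[OrganKind]
    value: float = Field(1.0, ge=0, le=1)
    start_day: int = Field(0, ge=0)
    end_day: int = Field(10**9, ge=0)

    def applies(self, kind: OrganKind, day: int) -> bool:
        return kind in self.organs and self.start_day <= day <= self.end_day


class WeatherParams(_Model):
    """Synthetic daily weather generator settings (seasonal sinusoids +
    seeded noise; AR(1) relative humidity)."""

    t_mean: float = Field(14.0, description="annual mean air temperature, degC")
    t_amp: float = Field(8.0, ge=0, description="seasonal amplitude, degC")
    t_phase: float = Field(-80.0, description="phase shift of the sinusoid, days")
    t_noise_sd: float = Field(1.5, ge=0)
    t_leaf_offset: float = Field(0.0, description="leaf minus air temperature, degC")
    par_mean: float = Field(1100.0, ge=0, description="midday-equivalent PAR, umol m-2 s-1")
    par_amp: float = Field(400.0, ge=0)
    par_noise_sd: float = Field(150.0, ge=0)
    rh_mean: float = Field(0.65, ge=0, le=1)
    rh_rho: float = Field(0.7, ge=0, lt=1, description="AR(1) persistence of humidity")
    rh_noise_sd: float = Field(0.08, ge=0)
    ca: float = Field(420.0, gt=0, description="ambient CO2, umol mol-1")
    soil_no3: float = Field(2.0, ge=0, description="soil nitrate, mol m-3")
    soil_no3_depletion: float = Field(0.0, ge=0, description="linear depletion, mol m-3 d-1")
    period: float = Field(365.0, gt=0, description="seasonal period, days")


class OrganInit(_Model):
    structural_mass: float = Field(ge=0)
    c_store: float = Field(0.0, ge=0)
    n_store: float = Field(0.0, ge=0)
    defense_pool: float = Field(0.0, ge=0)


def _default_organs() -> dict[OrganKind, OrganInit]:
    return {
        OrganKind.ROOTS: OrganInit(structural_mass=0.4, c_store=0.04, n_store=0.008),
        OrganKind.SENESCENT_LEAF: OrganInit(structural_mass=0.2, c_store=0.012, n_store=0.008),
        OrganKind.MATURE_LEAF: OrganInit(structural_mass=1.2, c_store=0.06, n_store=0.024),
        OrganKind.GROWING_LEAF: OrganInit(structural_mass=0.4, c_store=0.02, n_store=0.008),
        OrganKind.EMERGING_LEAF: OrganInit(structural_mass=0.1, c_store=0.005, n_store=0.002),
        OrganKind.GRAIN: OrganInit(structural_mass=0.0),
    }


class SimulationConfig(_Model):
    """Complete scenario description.  ``horizon_days`` is the only key a
    user-supplied file must provide; everything else has a documented
    default forming the reference genotype/scenario."""

    horizon_days: int = Field(ge=0)
    seed: int = Field(42, ge=0)
    anthesis_day: int = Field(80, ge=0, description="vegetative -> reproductive switch")
    daylight_hours: float = Field(12.0, gt=0, le=24)
    sla: dict[OrganKind, float] = Field(
        default_factory=lambda: {k: (0.025 if k in LEAF_KINDS else 0.0) for k in ALL_KINDS},
        description="specific leaf area, m2 g-1 (leaf kinds)",
    )
    organs: dict[OrganKind, OrganInit] = Field(default_factory=_default_organs)
    pool_c: float = Field(0.10, ge=0)
    pool_n: float = Field(0.02, ge=0)
    gas_exchange: GasExchangeParams = Field(default_factory=GasExchangeParams)
    nitrogen_uptake: NitrogenUptakeParams = Field(default_factory=NitrogenUptakeParams)
    respiration: RespirationParams = Field(default_factory=RespirationParams)
    stoichiometry: StoichiometryParams = Field(default_factory=StoichiometryParams)
    defense: DefenseParams = Field(default_factory=DefenseParams)
    allocation: AllocationParams = Field(default_factory=AllocationParams)
    remobilization: RemobilizationParams = Field(default_factory=RemobilizationParams)
    stress: StressConfig = Field(default_factory=StressConfig)
    weather: WeatherParams = Field(default_factory=WeatherParams)
    defense_override: Optional[DefenseOverride] = None
    disable_defense: bool = Field(
        False, description="bypass the stress/defense module entirely (D held at 0)"
    )

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        missing = [k for k in ALL_KINDS if k not in self.organs]
        if missing:
            raise ValueError(
                f"organ initial state missing for: {[k.value for k in missing]}"
            )
        for k in ALL_KINDS:
            if k not in self.sla:
                raise ValueError(f"sla missing organ kind {k.value}")
        for ev in self.stress.events:
            if ev.start_day >= self.horizon_days > 0:
                raise ValueError(
                    f"stress event '{ev.name}' starts outside the horizon"
                )
        return self

    def calibration_warnings(self) -> list[str]:
        """Soft checks against the physiological brackets of the reference
        genotype (leaf C:N in [10, 15], phenolic cost in [2, 3] g glucose/g,
        protein C:N 3.5)."""
        w: list[str] = []
        for kind in (OrganKind.MATURE_LEAF, OrganKind.GROWING_LEAF, OrganKind.EMERGING_LEAF):
            cn = self.stoichiometry.tissue_cn[kind]
            if not (10.0 <= cn <= 15.0):
                w.append(
                    f"stoichiometry.tissue_cn.{kind.value} = {cn} outside the "
                    "leaf-tissue bracket [10, 15]"
                )
        pc = self.stoichiometry.phenolic_glucose_cost
        if not (2.0 <= pc <= 3.0):
            w.append(
                f"stoichiometry.phenolic_glucose_cost = {pc} outside the "
                "glucose-equivalent bracket [2, 3]"
            )
        if self.stoichiometry.protein_cn != 3.5:
            w.append(
                f"stoichiometry.protein_cn = {self.stoichiometry.protein_cn} "
                "differs from the protein C:N reference 3.5"
            )
        return w


class ConfigError(ValueError):
    """Raised when a scenario file fails schema validation."""


def default_config(horizon_days: int = 150, seed: int = 42) -> SimulationConfig:
    """The reference scenario: a 150-day stress-free run of the default genotype."""
    return SimulationConfig(horizon_days=horizon_days, seed=seed)


def config_to_dict(config: SimulationConfig) -> dict:
    return config.model_dump(mode="json")


def dump_config(config: SimulationConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_config(source: str | Path | dict) -> SimulationConfig:
    """Load and validate a scenario from a YAML file (or a pre-parsed dict).

    All schema violations are reported together, each with the dotted path
    of the offending key.
    """
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
    try:
        return SimulationConfig.model_validate(raw)
    except ValidationError as err:
        lines = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"]) or "<root>"
            lines.append(f"{loc}: {e['msg']}")
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(lines)
        ) from err
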