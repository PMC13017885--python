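"""Plant state containers: organs, the common pool, and per-day records.

The plant is represented as six functional organ compartments (roots,
senescent leaf, mature leaf, growing leaf, emerging leaf, grain) that
exchange carbon and nitrogen exclusively through a whole-plant common
pool.  Mature and growing leaves are the photosynthetic sources; roots
are the sole nitrogen-absorbing compartment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum


class OrganKind(str, Enum):
    ROOTS = "roots"
    SENESCENT_LEAF = "senescent_leaf"
    MATURE_LEAF = "mature_leaf"
    GROWING_LEAF = "growing_leaf"
    EMERGING_LEAF = "emerging_leaf"
    GRAIN = "grain"


#: leaf compartments (carry an area = structural_mass x SLA)
LEAF_KINDS = frozenset(
    {
        OrganKind.SENESCENT_LEAF,
        OrganKind.MATURE_LEAF,
        OrganKind.GROWING_LEAF,
        OrganKind.EMERGING_LEAF,
    }
)
#: compartments that assimilate CO2
PHOTOSYNTHETIC_KINDS = frozenset({OrganKind.MATURE_LEAF, OrganKind.GROWING_LEAF})
#: compartments that absorb soil nitrate
NITROGEN_ABSORBING_KINDS = frozenset({OrganKind.ROOTS})

ALL_KINDS = tuple(OrganKind)


@dataclass
class OrganState:
    """One organ compartment.

    Stocks are per plant: ``structural_mass`` in g dry matter, ``c_store``
    and ``n_store`` in g of labile C and N, ``defense_pool`` in g of
    accumulated defense compounds.  ``s0`` is the dimensionless local
    stress signal in [0, 1] and ``d_coef`` the dynamic defense
    coefficient in [0, 1].  ``area`` (m2) is non-zero for leaf kinds only.
    """

    kind: OrganKind
    structural_mass: float = 0.0
    c_store: float = 0.0
    n_store: float = 0.0
    defense_pool: float = 0.0
    area: float = 0.0
    s0: float = 0.0
    d_coef: float = 0.0
    maintenance_deficit_days: int = 0
    maintenance_deficit_c: float = 0.0

    def validate(self) -> None:
        if self.structural_mass < 0 or self.c_store < 0 or self.n_store < 0:
            raise ValueError(f"negative stock in organ {self.kind.value}")
        if self.defense_pool < 0:
            raise ValueError(f"negative defense pool in organ {self.kind.value}")
        if not (0.0 <= self.s0 <= 1.0) or not (0.0 <= self.d_coef <= 1.0):
            raise ValueError(f"s0/d_coef out of [0,1] in organ {self.kind.value}")

    def clone(self) -> "OrganState":
        return dataclasses.replace(self)


@dataclass
class CommonPool:
    """Whole-plant labile C and N stocks; every inter-organ flow passes here."""

    carbon: float = 0.0
    nitrogen: float = 0.0

    def validate(self) -> None:
        if self.carbon < 0 or self.nitrogen < 0:
            raise ValueError("common pool stock went negative")

    def clone(self) -> "CommonPool":
        return CommonPool(self.carbon, self.nitrogen)


VEGETATIVE = "vegetative"
REPRODUCTIVE = "reproductive"


@dataclass
class PlantState:
    """Full plant state at the start of a day."""

    day: int
    organs: dict[OrganKind, OrganState]
    pool: CommonPool
    stage: str = VEGETATIVE
    # directives computed at t+delta of the previous day; applied to the
    # sources at time t of the current day (perception/allocation delay)
    directives: object | None = None

    def organ(self, kind: OrganKind) -> OrganState:
        return self.organs[kind]

    def total_structural_mass(self) -> float:
        return sum(o.structural_mass for o in self.organs.values())

    def validate(self) -> None:
        if set(self.organs) != set(ALL_KINDS):
            missing = set(ALL_KINDS) - set(self.organs)
            raise ValueError(f"organ set incomplete, missing {sorted(k.value for k in missing)}")
        for o in self.organs.values():
            o.validate()
        self.pool.validate()

    def clone(self) -> "PlantState":
        return PlantState(
            day=self.day,
            organs={k: o.clone() for k, o in self.organs.items()},
            pool=self.pool.clone(),
            stage=self.stage,
            directives=self.directives,
        )


@dataclass
class OrganDayRecord:
    """End-of-day organ state plus every flux touching the organ (g, g C, g N)."""

    mass: float = 0.0
    c_store: float = 0.0
    n_store: float = 0.0
    defense_pool: float = 0.0
    area: float = 0.0
    s0: float = 0.0
    d_coef: float = 0.0
    # gas exchange diagnostics (leaf-level, instantaneous units)
    a_net: float = 0.0
    ci: float = 0.0
    gs: float = 0.0
    limitation: str = ""
    # daily fluxes, g C or g N per day
    photosynthesis_c: float = 0.0
    dark_respiration_c: float = 0.0
    n_uptake: float = 0.0
    remobilized_c: float = 0.0
    remobilized_n: float = 0.0
    delivered_c: float = 0.0
    delivered_n: float = 0.0
    maintenance_need_c: float = 0.0
    maintenance_basal_c: float = 0.0
    maintenance_defense_c: float = 0.0
    maintenance_paid_c: float = 0.0
    maintenance_defense_paid_c: float = 0.0
    store_draw_c: float = 0.0
    defense_synthesis_c: float = 0.0
    defense_synthesis_n: float = 0.0
    compound_synthesized: float = 0.0
    growth_mass: float = 0.0
    growth_c_used: float = 0.0
    growth_respiration_c: float = 0.0
    growth_n_used: float = 0.0
    returned_c: float = 0.0
    returned_n: float = 0.0
    store_refill_c: float = 0.0
    store_refill_n: float = 0.0
    maintenance_deficit: bool = False
    unpaid_maintenance_c: float = 0.0


@dataclass
class DayRecord:
    """Audit record for one simulated day (or the initial snapshot)."""

    day: int
    is_initial: bool = False
    stage: str = VEGETATIVE
    pool_c: float = 0.0
    pool_n: float = 0.0
    s_plant_mean: float = 0.0
    s_plant_max: float = 0.0
    total_c: float = 0.0
    total_n: float = 0.0
    assimilation_c: float = 0.0
    respiration_c: float = 0.0
    n_uptake_total: float = 0.0
    organs: dict[OrganKind, OrganDayRecord] = field(default_factory=dict)


@dataclass
class Trajectory:
    """Time-indexed record of a whole run: one initial snapshot + one
    :class:`DayRecord` per simulated day."""

    initial: DayRecord
    records: list[DayRecord] = field(default_factory=list)
    final_state: PlantState | None = None

    def __len__(self) -> int:
        return len(self.records)

    def all_records(self) -> list[DayRecord]:
        return [self.initial, *self.records]

    def final_total_mass(self) -> float:
        last = self.records[-1] if self.records else self.initial
        return sum(o.mass for o in last.organs.values())
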