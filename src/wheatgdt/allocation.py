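"""The integration unit: plant-level signal aggregation, allocation
directives, organ demands, common-pool sharing, and within-organ
maintenance-first partitioning between defense and growth.

Carbon and nitrogen are allocated independently among organs (demand x
priority x stress modulation under the global availability constraint)
and reconciled stoichiometrically inside each organ: structural growth
consumes C and N at the fixed tissue C:N ratio, defense-compound
synthesis at the cost of the phenolic/protein mix, and any surplus of
the non-limiting element is returned to the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import (
    AllocationParams,
    DefenseParams,
    GrowthLaw,
    RespirationParams,
    StoichiometryParams,
)
from .respiration import MaintenanceDemand, maintenance_respiration
from .state import (
    REPRODUCTIVE,
    VEGETATIVE,
    CommonPool,
    OrganKind,
    OrganState,
)

_EPS = 1e-12


@dataclass
class PlantStatus:
    """Aggregated plant physiological state after signal integration."""

    s_plant_mean: float  # structural-mass-weighted mean of organ s0
    s_plant_max: float
    pool_c: float
    pool_n: float
    stage: str


@dataclass
class AllocationDirectives:
    """Output of the integration unit, constant within a time step."""

    priority: dict[OrganKind, float]
    source_downregulation: dict[OrganKind, float]
    stress_boost_beta: float = 0.0

    @classmethod
    def neutral(cls) -> "AllocationDirectives":
        return cls(priority={}, source_downregulation={})

    def downregulation(self, kind: OrganKind) -> float:
        return self.source_downregulation.get(kind, 0.0)


def integrate_plant_status(
    organs: dict[OrganKind, OrganState], pool: CommonPool, stage: str
) -> PlantStatus:
    """Mass-weighted mean and max of the organ stress signals."""
    total_mass = sum(o.structural_mass for o in organs.values())
    if total_mass <= 0:
        raise ValueError("cannot integrate plant status with zero total mass")
    mean = sum(o.s0 * o.structural_mass for o in organs.values()) / total_mass
    s_max = max(o.s0 for o in organs.values())
    return PlantStatus(
        s_plant_mean=mean,
        s_plant_max=s_max,
        pool_c=pool.carbon,
        pool_n=pool.nitrogen,
        stage=stage,
    )


def compute_directives(
    organs: dict[OrganKind, OrganState],
    status: PlantStatus,
    params: AllocationParams,
    photosynthetic: frozenset[OrganKind],
    nitrogen_absorbing: frozenset[OrganKind],
) -> AllocationDirectives:
    """Stage-dependent base priorities modulated by organ stress.

    Effective priority = base(stage, kind) x (1 + beta s0): stressed organs
    attract resources preferentially.  Source organs are downregulated
    proportionally to their own stress signal (sigma_max x s0).
    """
    base = (
        params.priorities_reproductive
        if status.stage == REPRODUCTIVE
        else params.priorities_vegetative
    )
    priority = {
        kind: base[kind] * (1.0 + params.stress_boost_beta * organs[kind].s0)
        for kind in organs
    }
    downreg = {
        kind: min(params.sigma_max * organs[kind].s0, 1.0)
        for kind in organs
        if kind in photosynthetic or kind in nitrogen_absorbing
    }
    return AllocationDirectives(
        priority=priority,
        source_downregulation=downreg,
        stress_boost_beta=params.stress_boost_beta,
    )


def sink_strength(age: float, law: GrowthLaw) -> float:
    """Beta-shaped sink strength over normalized organ age, peak scaled
    to 1.  Outside the active window [0, duration] the strength is zero;
    with both exponents 1 the shape is flat."""
    x = age / law.duration
    if x < 0.0 or x > 1.0:
        return 0.0
    a, b = law.beta_a, law.beta_b
    if a == 1.0 and b == 1.0:
        return 1.0

    def shape(u: float) -> float:
        # 0^0 := 1 at the boundaries
        ua = u ** (a - 1.0) if not (u == 0.0 and a == 1.0) else 1.0
        ub = (1.0 - u) ** (b - 1.0) if not (u == 1.0 and b == 1.0) else 1.0
        return ua * ub

    if a > 1.0 and b > 1.0:
        x_peak = (a - 1.0) / (a + b - 2.0)
    elif a <= 1.0:
        x_peak = 0.0
    else:
        x_peak = 1.0
    peak = shape(x_peak)
    if peak <= 0.0:
        return 0.0
    return shape(x) / peak


@dataclass
class OrganDemand:
    """Daily resource demand of one organ, split by process (g C / g N d-1)."""

    c_maintenance: float = 0.0
    c_defense: float = 0.0
    n_defense: float = 0.0
    c_growth: float = 0.0
    n_growth: float = 0.0
    sink_strength_g: float = 0.0
    compound_potential: float = 0.0  # g defense compound d-1
    growth_potential_mass: float = 0.0  # g DM d-1
    maintenance: MaintenanceDemand = field(
        default_factory=lambda: MaintenanceDemand(0.0, 0.0)
    )

    @property
    def c_total(self) -> float:
        return self.c_maintenance + self.c_defense + self.c_growth

    @property
    def n_total(self) -> float:
        return self.n_defense + self.n_growth


def defense_demand(
    organ: OrganState, s_def_rate: float, stoich: StoichiometryParams
) -> tuple[float, float, float]:
    """Defense sink of one organ: compound potential D x mass x s_def_rate
    (the explicit defense sink scales with D x organ mass), converted to C
    via the glucose-equivalent cost of the phenolic fraction and to N via
    the protein C:N of the protein fraction.

    Returns (compound g d-1, C demand g d-1, N demand g d-1).
    """
    compound = organ.d_coef * organ.structural_mass * s_def_rate
    return compound, compound * stoich.defense_c_per_g, compound * stoich.defense_n_per_g


def organ_demand(
    organ: OrganState,
    age: float,
    t_organ: float,
    resp: RespirationParams,
    stoich: StoichiometryParams,
    defense: DefenseParams,
    growth_law: GrowthLaw,
) -> OrganDemand:
    """Assemble the full daily demand of one organ."""
    maint = maintenance_respiration(organ, t_organ, resp)
    compound, c_def, n_def = defense_demand(organ, defense.s_def_rate, stoich)
    g = sink_strength(age, growth_law)
    if growth_law.rate_mode == "relative":
        dm_pot = growth_law.g_rate * g * organ.structural_mass
    else:
        dm_pot = growth_law.g_rate * g
    c_per_g = stoich.c_per_g_dm[organ.kind]
    c_growth = dm_pot * c_per_g / resp.growth_yield  # substrate + growth respiration
    n_growth = dm_pot * c_per_g / stoich.tissue_cn[organ.kind]
    return OrganDemand(
        c_maintenance=maint.total,
        c_defense=c_def,
        n_defense=n_def,
        c_growth=c_growth,
        n_growth=n_growth,
        sink_strength_g=g,
        compound_potential=compound,
        growth_potential_mass=dm_pot,
        maintenance=maint,
    )


def _share_element(
    pool: float, demands: dict[OrganKind, float], weights: dict[OrganKind, float]
) -> tuple[dict[OrganKind, float], float]:
    """Single-pass capped-proportional sharing of one element.

    Full demand when the pool covers it; otherwise organ i receives
    min(demand_i, pool w_i demand_i / sum_j w_j demand_j).  The remainder
    stays in the pool (no recursive redistribution).
    """
    for kind, d in demands.items():
        if d < 0:
            raise ValueError(f"negative demand for organ {kind.value}")
    total = sum(demands.values())
    if total <= pool:
        return dict(demands), pool - total
    weighted = {k: weights.get(k, 0.0) * d for k, d in demands.items()}
    wsum = sum(weighted.values())
    if wsum <= 0:
        return {k: 0.0 for k in demands}, pool
    deliveries = {
        k: min(demands[k], pool * weighted[k] / wsum) for k in demands
    }
    delivered = sum(deliveries.values())
    if delivered > pool > 0.0:  # guard against rounding overshoot
        scale = pool / delivered
        deliveries = {k: v * scale for k, v in deliveries.items()}
        delivered = sum(deliveries.values())
    return deliveries, max(pool - delivered, 0.0)


@dataclass
class Delivery:
    c: float = 0.0
    n: float = 0.0


def allocate_pool(
    pool: CommonPool,
    demands: dict[OrganKind, OrganDemand],
    directives: AllocationDirectives,
) -> tuple[dict[OrganKind, Delivery], CommonPool]:
    """Share the common pool among organs, C and N independently.

    Organs with zero effective priority are excluded from allocation
    entirely (a grain before anthesis receives nothing even in surplus).
    """
    w = {k: directives.priority.get(k, 0.0) for k in demands}
    c_dem = {k: (d.c_total if w[k] > 0 else 0.0) for k, d in demands.items()}
    n_dem = {k: (d.n_total if w[k] > 0 else 0.0) for k, d in demands.items()}
    c_del, c_left = _share_element(pool.carbon, c_dem, w)
    n_del, n_left = _share_element(pool.nitrogen, n_dem, w)
    deliveries = {k: Delivery(c=c_del[k], n=n_del[k]) for k in demands}
    return deliveries, CommonPool(carbon=c_left, nitrogen=n_left)


def structural_growth(
    c_for_growth: float,
    n_for_growth: float,
    c_per_g_dm: float,
    growth_yield: float,
    tissue_cn: float,
    max_delta_mass: float = float("inf"),
) -> tuple[float, float, float, float, float, float]:
    """Build new structure from a C and an N offer at fixed stoichiometry.

    One g of new dry matter costs c_per_g_dm / Yg g C (substrate plus
    growth respiration) and c_per_g_dm / tissue_cn g N; realized growth is
    the minimum of the C-limited and N-limited masses (and the potential
    cap).  Returns (delta_mass, c_used, n_used, c_respired, c_returned,
    n_returned)."""
    if c_for_growth < 0 or n_for_growth < 0:
        raise ValueError("growth offers must be >= 0")
    c_per_dm = c_per_g_dm / growth_yield
    n_per_dm = c_per_g_dm / tissue_cn
    c_limited = c_for_growth / c_per_dm if c_per_dm > 0 else 0.0
    n_limited = n_for_growth / n_per_dm if n_per_dm > 0 else float("inf")
    delta = min(c_limited, n_limited, max_delta_mass)
    if delta <= _EPS:
        return 0.0, 0.0, 0.0, 0.0, c_for_growth, n_for_growth
    # clamp to the offers: delta * cost may exceed the offer by one ulp
    c_used = min(delta * c_per_dm, c_for_growth)
    n_used = min(delta * n_per_dm, n_for_growth)
    c_respired = max(c_used - delta * c_per_g_dm, 0.0)
    return delta, c_used, n_used, c_respired, c_for_growth - c_used, n_for_growth - n_used


@dataclass
class PartitionResult:
    """Within-organ split of a delivery.  Exact conservation holds per
    element: maintenance_from_delivery + defense_c + growth_c + returned_c
    = delivered C, and defense_n + growth_n + returned_n = delivered N."""

    maintenance_from_delivery_c: float = 0.0
    store_draw_c: float = 0.0
    unpaid_maintenance_c: float = 0.0
    defense_c: float = 0.0
    defense_n: float = 0.0
    compound_synthesized: float = 0.0
    growth_delta_mass: float = 0.0
    growth_c_used: float = 0.0
    growth_c_respired: float = 0.0
    growth_n_used: float = 0.0
    returned_c: float = 0.0
    returned_n: float = 0.0
    deficit: bool = False

    @property
    def maintenance_paid_c(self) -> float:
        return self.maintenance_from_delivery_c + self.store_draw_c


def partition_within_organ(
    delivery: Delivery,
    organ: OrganState,
    demand: OrganDemand,
    stoich: StoichiometryParams,
    growth_yield: float,
) -> PartitionResult:
    """Hierarchical maintenance -> defense -> growth partition.

    Maintenance is funded first, from the delivery and then from the
    organ's internal labile store; if both fall short the deficit flag is
    set and neither defense nor growth receives anything that day.  Of the
    post-maintenance carbon a fraction phi = D goes to defense synthesis
    (capped by the defense demand and by delivered N for the protein
    fraction); the rest is offered to growth, realized at the fixed tissue
    C:N ratio.  Whatever is not consumed is returned.
    """
    res = PartitionResult()
    need = demand.c_maintenance
    res.maintenance_from_delivery_c = min(delivery.c, need)
    shortfall = need - res.maintenance_from_delivery_c
    if shortfall > _EPS:
        res.store_draw_c = min(organ.c_store, shortfall)
        res.unpaid_maintenance_c = shortfall - res.store_draw_c
        if res.unpaid_maintenance_c > _EPS:
            res.deficit = True
        # delivery fully consumed by maintenance; delivered N returned
        res.returned_c = delivery.c - res.maintenance_from_delivery_c
        res.returned_n = delivery.n
        return res

    post_c = delivery.c - res.maintenance_from_delivery_c
    # defense split: phi = D of post-maintenance C, capped by demand and N
    c_cost = stoich.defense_c_per_g
    n_cost = stoich.defense_n_per_g
    c_offer_def = min(organ.d_coef * post_c, demand.c_defense)
    if c_cost > 0 and demand.compound_potential > 0:
        compound_by_c = c_offer_def / c_cost
        compound_by_n = delivery.n / n_cost if n_cost > 0 else float("inf")
        compound = min(compound_by_c, compound_by_n, demand.compound_potential)
    else:
        compound = 0.0
    res.compound_synthesized = compound
    # clamped so the sequential remainders below stay non-negative
    res.defense_c = min(compound * c_cost, post_c)
    res.defense_n = min(compound * n_cost, delivery.n)

    c_offer_growth = post_c - res.defense_c
    n_offer_growth = delivery.n - res.defense_n
    (
        res.growth_delta_mass,
        res.growth_c_used,
        res.growth_n_used,
        res.growth_c_respired,
        res.returned_c,
        res.returned_n,
    ) = structural_growth(
        c_offer_growth,
        n_offer_growth,
        stoich.c_per_g_dm[organ.kind],
        growth_yield,
        stoich.tissue_cn[organ.kind],
        max_delta_mass=demand.growth_potential_mass,
    )
    return res
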