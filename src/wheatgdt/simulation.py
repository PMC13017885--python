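"""Discrete-time simulation core: the three-phase daily update cycle,
trajectory recording, senescent-leaf remobilization and whole-run
mass-balance auditing.

Each simulated day executes three phases in order, all within one call:

* Phase A (time t): leaf gas exchange and root nitrate uptake at the
  source capacities set by the previous day's directives, then the
  per-organ stress-signal (S0) and defense-coefficient (D) update.
* Phase B (t + delta): newly assimilated C, absorbed N and remobilized
  senescent-leaf resources enter the common pool; organ signals are
  integrated into a plant status and fresh allocation directives.
* Phase C (t + 1): the pool is shared among organs by demand x priority,
  each organ partitions its delivery maintenance-first between defense
  and growth, respiration is debited, structure grows, and unused
  resources return to the pool.

The inter-phase instant has no real duration: transport of information
and assimilates is taken as fast relative to the daily step, so the
phases simply order the computation (the allocation delay is one day).
"""

from __future__ import annotations

import math

import pandas as pd

from .allocation import (
    AllocationDirectives,
    Delivery,
    PlantStatus,
    allocate_pool,
    compute_directives,
    integrate_plant_status,
    organ_demand,
    partition_within_organ,
)
from .config import RemobilizationParams, SimulationConfig
from .environment import EnvironmentDay, build_environment, stressor_classes
from .gas_exchange import daily_carbon_flux, solve_gas_exchange
from .nitrogen_uptake import organ_nitrogen_uptake
from .state import (
    LEAF_KINDS,
    NITROGEN_ABSORBING_KINDS,
    PHOTOSYNTHETIC_KINDS,
    REPRODUCTIVE,
    VEGETATIVE,
    CommonPool,
    DayRecord,
    OrganDayRecord,
    OrganKind,
    OrganState,
    PlantState,
    Trajectory,
)

_EPS = 1e-12


class SimulationError(RuntimeError):
    """Non-finite intermediate value, annotated with phase and organ."""


def _check_finite(value: float, phase: str, organ: str, what: str) -> None:
    if not math.isfinite(value):
        raise SimulationError(
            f"non-finite {what} in phase {phase} for organ {organ}"
        )


def initialize_plant(config: SimulationConfig) -> PlantState:
    """Build the day-0 plant from configured initial organ states.

    All stress signals and defense coefficients start at zero (an
    unstressed plant); the grain may legitimately start at zero mass
    before anthesis."""
    organs: dict[OrganKind, OrganState] = {}
    for kind in OrganKind:
        if kind not in config.organs:
            raise ValueError(f"configuration missing initial state for organ '{kind.value}'")
        init = config.organs[kind]
        organ = OrganState(
            kind=kind,
            structural_mass=init.structural_mass,
            c_store=init.c_store,
            n_store=init.n_store,
            defense_pool=init.defense_pool,
        )
        if kind in LEAF_KINDS:
            organ.area = organ.structural_mass * config.sla[kind]
        organs[kind] = organ
    stage = REPRODUCTIVE if 0 >= config.anthesis_day else VEGETATIVE
    plant = PlantState(
        day=0,
        organs=organs,
        pool=CommonPool(carbon=config.pool_c, nitrogen=config.pool_n),
        stage=stage,
        directives=AllocationDirectives.neutral(),
    )
    plant.validate()
    return plant


def remobilize_senescent(
    organ: OrganState, status: PlantStatus, params: RemobilizationParams
) -> tuple[float, float, OrganState]:
    """Daily export from senescent-leaf stores back to the pool.

    Fractions r_C and r_N of the labile stores leave per day, accelerated
    by whole-plant stress: flux = r x (1 + a_sen x S_plant) x store, with
    the effective fraction clamped to [0, 1].  Structural mass never
    changes (organ mortality is out of scope)."""
    if organ.kind is not OrganKind.SENESCENT_LEAF:
        raise ValueError("remobilization applies to the senescent leaf only")
    accel = 1.0 + params.a_sen * status.s_plant_mean
    frac_c = min(params.r_c * accel, 1.0)
    frac_n = min(params.r_n * accel, 1.0)
    flux_c = frac_c * organ.c_store
    flux_n = frac_n * organ.n_store
    new = organ.clone()
    new.c_store -= flux_c
    new.n_store -= flux_n
    return flux_c, flux_n, new


def _total_stocks(
    organs: dict[OrganKind, OrganState], pool: CommonPool, config: SimulationConfig
) -> tuple[float, float]:
    """Whole-plant C and N inventories (g), including structural tissue
    and accumulated defense compounds."""
    stoich = config.stoichiometry
    c = pool.carbon
    n = pool.nitrogen
    for kind, o in organs.items():
        c_per_g = stoich.c_per_g_dm[kind]
        c += o.c_store + o.structural_mass * c_per_g
        c += o.defense_pool * stoich.defense_c_per_g
        n += o.n_store + o.structural_mass * c_per_g / stoich.tissue_cn[kind]
        n += o.defense_pool * stoich.defense_n_per_g
    return c, n


def _organ_age(kind: OrganKind, day: int, config: SimulationConfig) -> float:
    """Organ age driving the sink-strength shape.  Vegetative organs age
    from day 0; the grain's clock starts at anthesis."""
    if kind is OrganKind.GRAIN:
        return float(day - config.anthesis_day) if day >= config.anthesis_day else -1.0
    return float(day)


def step(
    plant: PlantState, env: EnvironmentDay, config: SimulationConfig
) -> tuple[PlantState, DayRecord]:
    """Advance the plant by one day; returns the new state and the full
    flux record for the mass-balance audit."""
    p = plant.clone()
    day = p.day
    p.stage = REPRODUCTIVE if day >= config.anthesis_day else VEGETATIVE
    directives: AllocationDirectives = p.directives or AllocationDirectives.neutral()
    rec = DayRecord(day=day, stage=p.stage)
    for kind in OrganKind:
        rec.organs[kind] = OrganDayRecord()

    classes = stressor_classes(config.stress.events)

    # ---- Phase A (time t): sources and signals -------------------------
    net_c_by_leaf: dict[OrganKind, float] = {}
    for kind in PHOTOSYNTHETIC_KINDS:
        organ = p.organ(kind)
        orec = rec.organs[kind]
        if organ.area <= 0.0:
            continue
        result = solve_gas_exchange(
            par=env.par,
            t_leaf=env.t_leaf,
            rel_humidity=env.rel_humidity,
            ca=env.ca,
            params=config.gas_exchange,
            downregulation=directives.downregulation(kind),
        )
        net_c = daily_carbon_flux(result.a_net, organ.area, config.daylight_hours)
        _check_finite(net_c, "A", kind.value, "daily carbon flux")
        net_c_by_leaf[kind] = net_c
        orec.a_net = result.a_net
        orec.ci = result.ci
        orec.gs = result.gs
        orec.limitation = result.limitation

    root = p.organ(OrganKind.ROOTS)
    n_uptake = organ_nitrogen_uptake(
        root,
        env.soil_no3,
        config.nitrogen_uptake,
        downregulation=directives.downregulation(OrganKind.ROOTS),
    )
    _check_finite(n_uptake, "A", "roots", "nitrogen uptake")
    rec.organs[OrganKind.ROOTS].n_uptake = n_uptake

    if not config.disable_defense:
        from .stress_defense import (
            combine_stress_signals,
            defense_dose_response,
            update_defense_coefficient,
        )

        for kind in OrganKind:
            organ = p.organ(kind)
            inputs = env.organ_stress(kind)
            s_biotic = 0.0
            s_abiotic = 0.0
            for name, intensity in inputs.items():
                if classes.get(name, "abiotic") == "biotic":
                    s_biotic = max(s_biotic, intensity)
                else:
                    s_abiotic = max(s_abiotic, intensity)
            organ.s0 = combine_stress_signals(
                s_abiotic,
                s_biotic,
                mode=config.stress.combination_mode,
                gamma=config.stress.gamma,
            )
            d_target = defense_dose_response(organ.s0, config.defense)
            organ.d_coef = update_defense_coefficient(
                organ.d_coef, d_target, config.defense
            )
            override = config.defense_override
            if override is not None and override.applies(kind, day):
                organ.d_coef = override.value

    # ---- Phase B (t + delta): transfers and integration ----------------
    assimilation_total = 0.0
    dark_resp_total = 0.0
    for kind, net_c in net_c_by_leaf.items():
        organ = p.organ(kind)
        orec = rec.organs[kind]
        if net_c >= 0.0:
            p.pool.carbon += net_c
            orec.photosynthesis_c = net_c
            assimilation_total += net_c
        else:
            # dark day: day respiration drains the pool, then the leaf store
            cost = -net_c
            from_pool = min(p.pool.carbon, cost)
            p.pool.carbon -= from_pool
            from_store = min(organ.c_store, cost - from_pool)
            organ.c_store -= from_store
            orec.dark_respiration_c = from_pool + from_store
            orec.store_draw_c += from_store
            dark_resp_total += from_pool + from_store
    p.pool.nitrogen += n_uptake

    status = integrate_plant_status(p.organs, p.pool, p.stage)
    rec.s_plant_mean = status.s_plant_mean
    rec.s_plant_max = status.s_plant_max

    sen = p.organ(OrganKind.SENESCENT_LEAF)
    flux_c, flux_n, sen_new = remobilize_senescent(sen, status, config.remobilization)
    p.organs[OrganKind.SENESCENT_LEAF] = sen_new
    p.pool.carbon += flux_c
    p.pool.nitrogen += flux_n
    rec.organs[OrganKind.SENESCENT_LEAF].remobilized_c = flux_c
    rec.organs[OrganKind.SENESCENT_LEAF].remobilized_n = flux_n

    new_directives = compute_directives(
        p.organs, status, config.allocation, PHOTOSYNTHETIC_KINDS, NITROGEN_ABSORBING_KINDS
    )

    # ---- Phase C (t + 1): allocation, partition, growth ----------------
    t_for = {
        kind: (env.t_leaf if kind in LEAF_KINDS else env.t_air) for kind in OrganKind
    }
    demands = {}
    for kind in OrganKind:
        organ = p.organ(kind)
        demands[kind] = organ_demand(
            organ,
            age=_organ_age(kind, day, config),
            t_organ=t_for[kind],
            resp=config.respiration,
            stoich=config.stoichiometry,
            defense=config.defense,
            growth_law=config.allocation.growth[kind],
        )
    deliveries, pool_after = allocate_pool(p.pool, demands, new_directives)
    p.pool = pool_after

    maintenance_resp_total = 0.0
    growth_resp_total = 0.0
    for kind in OrganKind:
        organ = p.organ(kind)
        orec = rec.organs[kind]
        demand = demands[kind]
        delivery = deliveries[kind]
        part = partition_within_organ(
            delivery, organ, demand, config.stoichiometry, config.respiration.growth_yield
        )
        organ.c_store -= part.store_draw_c
        organ.structural_mass += part.growth_delta_mass
        organ.defense_pool += part.compound_synthesized
        if kind in LEAF_KINDS:
            organ.area = organ.structural_mass * config.sla[kind]
        if part.deficit:
            organ.maintenance_deficit_days += 1
            organ.maintenance_deficit_c += part.unpaid_maintenance_c

        # returned resources top the organ's labile store up toward its
        # target concentration before flowing back to the pool
        refill_c = refill_n = 0.0
        if config.allocation.store_refill:
            target_c = config.allocation.store_target_c[kind] * organ.structural_mass
            target_n = config.allocation.store_target_n[kind] * organ.structural_mass
            refill_c = min(part.returned_c, max(target_c - organ.c_store, 0.0))
            refill_n = min(part.returned_n, max(target_n - organ.n_store, 0.0))
            organ.c_store += refill_c
            organ.n_store += refill_n
        p.pool.carbon += part.returned_c - refill_c
        p.pool.nitrogen += part.returned_n - refill_n

        paid = part.maintenance_paid_c
        need = demand.c_maintenance
        defense_share = demand.maintenance.defense / need if need > 0 else 0.0
        maintenance_resp_total += paid
        growth_resp_total += part.growth_c_respired

        orec.delivered_c = delivery.c
        orec.delivered_n = delivery.n
        orec.maintenance_need_c = need
        orec.maintenance_basal_c = demand.maintenance.basal
        orec.maintenance_defense_c = demand.maintenance.defense
        orec.maintenance_paid_c = paid
        orec.maintenance_defense_paid_c = paid * defense_share
        orec.store_draw_c += part.store_draw_c
        orec.defense_synthesis_c = part.defense_c
        orec.defense_synthesis_n = part.defense_n
        orec.compound_synthesized = part.compound_synthesized
        orec.growth_mass = part.growth_delta_mass
        orec.growth_c_used = part.growth_c_used
        orec.growth_respiration_c = part.growth_c_respired
        orec.growth_n_used = part.growth_n_used
        orec.returned_c = part.returned_c
        orec.returned_n = part.returned_n
        orec.store_refill_c = refill_c
        orec.store_refill_n = refill_n
        orec.maintenance_deficit = part.deficit
        orec.unpaid_maintenance_c = part.unpaid_maintenance_c
        for value, what in ((organ.structural_mass, "mass"), (organ.c_store, "c_store")):
            _check_finite(value, "C", kind.value, what)

    # ---- bookkeeping ----------------------------------------------------
    p.day = day + 1
    p.directives = new_directives
    p.validate()

    for kind in OrganKind:
        organ = p.organ(kind)
        orec = rec.organs[kind]
        orec.mass = organ.structural_mass
        orec.c_store = organ.c_store
        orec.n_store = organ.n_store
        orec.defense_pool = organ.defense_pool
        orec.area = organ.area
        orec.s0 = organ.s0
        orec.d_coef = organ.d_coef
    rec.pool_c = p.pool.carbon
    rec.pool_n = p.pool.nitrogen
    rec.assimilation_c = assimilation_total
    rec.respiration_c = dark_resp_total + maintenance_resp_total + growth_resp_total
    rec.n_uptake_total = n_uptake
    rec.total_c, rec.total_n = _total_stocks(p.organs, p.pool, config)
    return p, rec


def _snapshot(plant: PlantState, config: SimulationConfig) -> DayRecord:
    rec = DayRecord(day=plant.day, is_initial=True, stage=plant.stage)
    for kind, organ in plant.organs.items():
        rec.organs[kind] = OrganDayRecord(
            mass=organ.structural_mass,
            c_store=organ.c_store,
            n_store=organ.n_store,
            defense_pool=organ.defense_pool,
            area=organ.area,
            s0=organ.s0,
            d_coef=organ.d_coef,
        )
    rec.pool_c = plant.pool.carbon
    rec.pool_n = plant.pool.nitrogen
    rec.total_c, rec.total_n = _total_stocks(plant.organs, plant.pool, config)
    return rec


def run_simulation(
    config: SimulationConfig, env_series: list[EnvironmentDay] | None = None
) -> Trajectory:
    """Run a full scenario.  The environment is generated from the config
    (weather seed + stress schedule) unless an explicit series is given;
    the run is deterministic for a given (config, seed)."""
    if env_series is None:
        if config.horizon_days > 0:
            env_series = build_environment(
                config.horizon_days,
                config.seed,
                config.weather,
                config.stress.events,
            )
        else:
            env_series = []
    if len(env_series) < config.horizon_days:
        raise ValueError(
            f"environment series has {len(env_series)} days; "
            f"horizon needs {config.horizon_days}"
        )
    plant = initialize_plant(config)
    traj = Trajectory(initial=_snapshot(plant, config))
    for t in range(config.horizon_days):
        plant, rec = step(plant, env_series[t], config)
        traj.records.append(rec)
    traj.final_state = plant
    return traj


def audit_mass_balance(trajectory: Trajectory, tol: float = 1e-9) -> pd.DataFrame:
    """Check the daily conservation identities over a whole run.

    For every simulated day the change of the total C inventory must equal
    assimilation minus total respiration, and the change of total N must
    equal root uptake (no gaseous N losses are modeled).  Residuals are
    reported relative to the daily throughput; any residual above ``tol``
    is flagged.  An empty trajectory yields an empty report."""
    rows = []
    prev = trajectory.initial
    for rec in trajectory.records:
        for field in ("total_c", "total_n", "assimilation_c", "respiration_c", "n_uptake_total"):
            if not math.isfinite(getattr(rec, field)):
                raise ValueError(f"audit: non-finite flux field '{field}' on day {rec.day}")
        dc = rec.total_c - prev.total_c
        dn = rec.total_n - prev.total_n
        expected_dc = rec.assimilation_c - rec.respiration_c
        c_den = max(abs(rec.assimilation_c) + abs(rec.respiration_c) + abs(dc), 1e-6)
        n_den = max(abs(rec.n_uptake_total) + abs(dn), 1e-6)
        c_resid = abs(dc - expected_dc) / c_den
        n_resid = abs(dn - rec.n_uptake_total) / n_den
        rows.append(
            {
                "day": rec.day,
                "c_residual": c_resid,
                "n_residual": n_resid,
                "flagged": bool(c_resid > tol or n_resid > tol),
            }
        )
        prev = rec
    return pd.DataFrame(rows, columns=["day", "c_residual", "n_residual", "flagged"])
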