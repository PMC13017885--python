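"""Integration unit: status aggregation, directives, demands, pool
sharing and the maintenance-first within-organ partition."""

import pytest

from wheatgdt.allocation import (
    AllocationDirectives,
    Delivery,
    OrganDemand,
    allocate_pool,
    compute_directives,
    defense_demand,
    integrate_plant_status,
    organ_demand,
    partition_within_organ,
    sink_strength,
    structural_growth,
)
from wheatgdt.config import (
    AllocationParams,
    DefenseParams,
    GrowthLaw,
    RespirationParams,
    StoichiometryParams,
)
from wheatgdt.respiration import MaintenanceDemand
from wheatgdt.state import (
    NITROGEN_ABSORBING_KINDS,
    PHOTOSYNTHETIC_KINDS,
    REPRODUCTIVE,
    VEGETATIVE,
    CommonPool,
    OrganKind,
    OrganState,
)


def _organs(s0_map=None, mass_map=None):
    s0_map = s0_map or {}
    mass_map = mass_map or {}
    organs = {}
    for kind in OrganKind:
        organs[kind] = OrganState(
            kind=kind,
            structural_mass=mass_map.get(kind, 1.0),
            s0=s0_map.get(kind, 0.0),
        )
    return organs


class TestStatus:
    def test_unstressed_plant(self):
        st = integrate_plant_status(_organs(), CommonPool(1, 1), VEGETATIVE)
        assert st.s_plant_mean == 0.0
        assert st.s_plant_max == 0.0

    def test_max_picks_single_stressed_organ(self):
        organs = _organs(s0_map={OrganKind.MATURE_LEAF: 0.8})
        st = integrate_plant_status(organs, CommonPool(0, 0), VEGETATIVE)
        assert st.s_plant_max == pytest.approx(0.8)

    def test_mass_weighted_mean_hand_value(self):
        # masses {1,1,2}, s0 {0, 0.4, 0.5} -> (0 + 0.4 + 1.0)/4 = 0.35
        organs = {
            k: OrganState(kind=k, structural_mass=0.0) for k in OrganKind
        }
        organs[OrganKind.ROOTS] = OrganState(kind=OrganKind.ROOTS, structural_mass=1.0, s0=0.0)
        organs[OrganKind.MATURE_LEAF] = OrganState(
            kind=OrganKind.MATURE_LEAF, structural_mass=1.0, s0=0.4
        )
        organs[OrganKind.GROWING_LEAF] = OrganState(
            kind=OrganKind.GROWING_LEAF, structural_mass=2.0, s0=0.5
        )
        st = integrate_plant_status(organs, CommonPool(0, 0), VEGETATIVE)
        assert st.s_plant_mean == pytest.approx(0.35)
        assert st.s_plant_mean <= st.s_plant_max

    def test_zero_total_mass_rejected(self):
        organs = {k: OrganState(kind=k, structural_mass=0.0) for k in OrganKind}
        with pytest.raises(ValueError):
            integrate_plant_status(organs, CommonPool(0, 0), VEGETATIVE)


class TestDirectives:
    params = AllocationParams()

    def _directives(self, organs, stage):
        st = integrate_plant_status(organs, CommonPool(0, 0), stage)
        return compute_directives(
            organs, st, self.params, PHOTOSYNTHETIC_KINDS, NITROGEN_ABSORBING_KINDS
        )

    def test_grain_priority_zero_in_vegetative(self):
        d = self._directives(_organs(), VEGETATIVE)
        assert d.priority[OrganKind.GRAIN] == 0.0

    def test_grain_dominates_reproductive(self):
        d = self._directives(_organs(), REPRODUCTIVE)
        assert d.priority[OrganKind.GRAIN] == max(d.priority.values())

    def test_beta_zero_leaves_base_priorities(self):
        params = AllocationParams(stress_boost_beta=0.0)
        organs = _organs(s0_map={OrganKind.MATURE_LEAF: 0.9})
        st = integrate_plant_status(organs, CommonPool(0, 0), VEGETATIVE)
        d = compute_directives(
            organs, st, params, PHOTOSYNTHETIC_KINDS, NITROGEN_ABSORBING_KINDS
        )
        assert d.priority == params.priorities_vegetative

    def test_stress_boost_hand_value(self):
        # base 1, beta 0.5, s0 0.6 -> effective 1.3
        params = AllocationParams(stress_boost_beta=0.5)
        params.priorities_vegetative[OrganKind.MATURE_LEAF] = 1.0
        organs = _organs(s0_map={OrganKind.MATURE_LEAF: 0.6})
        st = integrate_plant_status(organs, CommonPool(0, 0), VEGETATIVE)
        d = compute_directives(
            organs, st, params, PHOTOSYNTHETIC_KINDS, NITROGEN_ABSORBING_KINDS
        )
        assert d.priority[OrganKind.MATURE_LEAF] == pytest.approx(1.3)

    def test_source_downregulation_proportional_to_stress(self):
        d = self._directives(_organs(s0_map={OrganKind.MATURE_LEAF: 0.5}), VEGETATIVE)
        assert d.downregulation(OrganKind.MATURE_LEAF) == pytest.approx(
            self.params.sigma_max * 0.5
        )
        assert d.downregulation(OrganKind.SENESCENT_LEAF) == 0.0


class TestSinkStrength:
    def test_flat_when_exponents_one(self):
        law = GrowthLaw(g_rate=1.0, beta_a=1.0, beta_b=1.0, duration=100.0)
        assert sink_strength(0.0, law) == 1.0
        assert sink_strength(50.0, law) == 1.0

    def test_outside_window_is_zero(self):
        law = GrowthLaw(g_rate=1.0, beta_a=2.0, beta_b=2.0, duration=50.0)
        assert sink_strength(-1.0, law) == 0.0
        assert sink_strength(51.0, law) == 0.0

    def test_peaks_at_one_mid_window(self):
        law = GrowthLaw(g_rate=1.0, beta_a=2.0, beta_b=2.0, duration=50.0)
        assert sink_strength(25.0, law) == pytest.approx(1.0)
        assert sink_strength(10.0, law) < 1.0


class TestDemand:
    def test_defense_demand_hand_value_phenolic_only(self):
        # 0.5 x 2 x 0.01 x 2.5 x 0.4 = 0.01 g C
        stoich = StoichiometryParams(defense_protein_fraction=0.0, phenolic_glucose_cost=2.5)
        organ = OrganState(kind=OrganKind.MATURE_LEAF, structural_mass=2.0, d_coef=0.5)
        _, c_dem, n_dem = defense_demand(organ, 0.01, stoich)
        assert c_dem == pytest.approx(0.01, rel=1e-12)
        assert n_dem == 0.0

    def test_defense_demand_proportional_to_d_times_mass(self):
        stoich = StoichiometryParams()
        ref = defense_demand(
            OrganState(kind=OrganKind.MATURE_LEAF, structural_mass=1.0, d_coef=0.5), 0.01, stoich
        )[1]
        double_mass = defense_demand(
            OrganState(kind=OrganKind.MATURE_LEAF, structural_mass=2.0, d_coef=0.5), 0.01, stoich
        )[1]
        double_d = defense_demand(
            OrganState(kind=OrganKind.MATURE_LEAF, structural_mass=1.0, d_coef=1.0), 0.01, stoich
        )[1]
        assert double_mass == pytest.approx(2 * ref, rel=1e-12)
        assert double_d == pytest.approx(2 * ref, rel=1e-12)

    def test_zero_defense_coefficient_zero_defense_demand(self):
        organ = OrganState(kind=OrganKind.GROWING_LEAF, structural_mass=2.0, d_coef=0.0)
        dem = organ_demand(
            organ,
            age=10.0,
            t_organ=20.0,
            resp=RespirationParams(),
            stoich=StoichiometryParams(),
            defense=DefenseParams(),
            growth_law=GrowthLaw(g_rate=0.1, beta_a=2.0, beta_b=2.0, duration=50.0),
        )
        assert dem.c_defense == 0.0
        assert dem.n_defense == 0.0
        assert dem.c_growth > 0.0


class TestPoolSharing:
    def _demand(self, c, n=0.0):
        return OrganDemand(c_growth=c, n_growth=n)

    def _directives(self, weights):
        return AllocationDirectives(priority=weights, source_downregulation={})

    def test_surplus_delivers_full_demand(self):
        demands = {
            OrganKind.ROOTS: self._demand(0.3, 0.01),
            OrganKind.GROWING_LEAF: self._demand(0.5, 0.02),
        }
        w = {OrganKind.ROOTS: 1.0, OrganKind.GROWING_LEAF: 1.0}
        deliveries, pool = allocate_pool(CommonPool(2.0, 1.0), demands, self._directives(w))
        assert deliveries[OrganKind.ROOTS].c == pytest.approx(0.3)
        assert deliveries[OrganKind.GROWING_LEAF].c == pytest.approx(0.5)
        assert pool.carbon == pytest.approx(1.2)
        assert pool.nitrogen == pytest.approx(1.0 - 0.03)

    def test_empty_pool_delivers_nothing(self):
        demands = {OrganKind.ROOTS: self._demand(0.3)}
        deliveries, pool = allocate_pool(
            CommonPool(0.0, 0.0), demands, self._directives({OrganKind.ROOTS: 1.0})
        )
        assert deliveries[OrganKind.ROOTS].c == 0.0
        assert pool.carbon == 0.0

    def test_capped_proportional_sharing_hand_value(self):
        # pool 1.0, demands {0.8, 0.8}, equal weights -> each min(0.8, 0.5)
        demands = {
            OrganKind.ROOTS: self._demand(0.8),
            OrganKind.GROWING_LEAF: self._demand(0.8),
        }
        w = {OrganKind.ROOTS: 1.0, OrganKind.GROWING_LEAF: 1.0}
        deliveries, pool = allocate_pool(CommonPool(1.0, 0.0), demands, self._directives(w))
        assert deliveries[OrganKind.ROOTS].c == pytest.approx(0.5)
        assert deliveries[OrganKind.GROWING_LEAF].c == pytest.approx(0.5)
        assert pool.carbon == pytest.approx(0.0, abs=1e-15)

    def test_zero_priority_organ_excluded_even_in_surplus(self):
        demands = {OrganKind.GRAIN: self._demand(0.4)}
        deliveries, pool = allocate_pool(
            CommonPool(5.0, 0.0), demands, self._directives({OrganKind.GRAIN: 0.0})
        )
        assert deliveries[OrganKind.GRAIN].c == 0.0
        assert pool.carbon == pytest.approx(5.0)

    def test_negative_demand_rejected(self):
        demands = {OrganKind.ROOTS: self._demand(-0.1)}
        with pytest.raises(ValueError):
            allocate_pool(CommonPool(1.0, 0.0), demands, self._directives({OrganKind.ROOTS: 1.0}))


class TestStructuralGrowth:
    def test_no_nitrogen_no_growth(self):
        delta, c_used, n_used, resp, c_ret, n_ret = structural_growth(0.5, 0.0, 0.45, 0.75, 12.5)
        assert delta == 0.0
        assert c_ret == pytest.approx(0.5)

    def test_exact_stoichiometric_balance_consumes_both(self):
        # offers exactly matched to 1 g of new DM
        c_per_dm = 0.45 / 0.75
        n_per_dm = 0.45 / 12.5
        delta, c_used, n_used, _, c_ret, n_ret = structural_growth(
            c_per_dm, n_per_dm, 0.45, 0.75, 12.5
        )
        assert delta == pytest.approx(1.0)
        assert c_ret == pytest.approx(0.0, abs=1e-15)
        assert n_ret == pytest.approx(0.0, abs=1e-15)

    def test_two_limit_hand_value(self):
        # c=0.9, n=0.03, c_per_g 0.45, Yg 0.75, cn 15:
        # C-limited 1.5 g, N-limited 1.0 g -> 1.0 g; C used 0.6, returned 0.3
        delta, c_used, n_used, resp, c_ret, n_ret = structural_growth(0.9, 0.03, 0.45, 0.75, 15.0)
        assert delta == pytest.approx(1.0, rel=1e-12)
        assert c_used == pytest.approx(0.6, rel=1e-12)
        assert c_ret == pytest.approx(0.3, rel=1e-12)
        assert resp == pytest.approx(0.6 - 0.45, rel=1e-12)

    def test_realized_cn_ratio_equals_tissue_cn(self):
        delta, c_used, n_used, resp, _, _ = structural_growth(0.9, 0.03, 0.45, 0.75, 15.0)
        structural_c = c_used - resp
        assert structural_c / n_used == pytest.approx(15.0, rel=1e-12)


class TestPartition:
    stoich = StoichiometryParams()

    def _organ(self, d=0.0, c_store=0.0):
        return OrganState(
            kind=OrganKind.MATURE_LEAF, structural_mass=1.0, d_coef=d, c_store=c_store
        )

    def _demand(self, maintenance=0.2, defense_c=1.0, growth=10.0):
        return OrganDemand(
            c_maintenance=maintenance,
            c_defense=defense_c,
            n_defense=defense_c * self.stoich.defense_n_per_g / self.stoich.defense_c_per_g,
            c_growth=growth,
            n_growth=growth,
            compound_potential=defense_c / self.stoich.defense_c_per_g,
            growth_potential_mass=growth,
            maintenance=MaintenanceDemand(basal=maintenance, defense=0.0),
        )

    def test_maintenance_shortfall_blocks_defense_and_growth(self):
        res = partition_within_organ(
            Delivery(c=0.1, n=0.05), self._organ(d=0.5), self._demand(maintenance=0.2),
            self.stoich, 0.75,
        )
        assert res.deficit
        assert res.defense_c == 0.0
        assert res.growth_delta_mass == 0.0
        assert res.returned_n == pytest.approx(0.05)

    def test_store_covers_shortfall_without_deficit(self):
        res = partition_within_organ(
            Delivery(c=0.1, n=0.0), self._organ(c_store=0.5), self._demand(maintenance=0.2),
            self.stoich, 0.75,
        )
        assert not res.deficit
        assert res.store_draw_c == pytest.approx(0.1)
        assert res.maintenance_paid_c == pytest.approx(0.2)

    def test_zero_defense_coefficient_routes_all_to_growth(self):
        res = partition_within_organ(
            Delivery(c=1.0, n=0.5), self._organ(d=0.0), self._demand(maintenance=0.2),
            self.stoich, 0.75,
        )
        assert res.defense_c == 0.0
        assert res.growth_c_used > 0.0

    def test_spec_split_hand_values_and_conservation(self):
        # delivered 1.0, maintenance 0.2, D = 0.25 -> defense gets
        # 0.25 x 0.8 = 0.2, growth offer 0.6; everything sums back exactly
        res = partition_within_organ(
            Delivery(c=1.0, n=0.5), self._organ(d=0.25), self._demand(maintenance=0.2),
            self.stoich, 0.75,
        )
        assert res.maintenance_from_delivery_c == pytest.approx(0.2)
        assert res.defense_c == pytest.approx(0.2, rel=1e-12)
        total = (
            res.maintenance_from_delivery_c
            + res.defense_c
            + res.growth_c_used
            + res.returned_c
        )
        assert total == pytest.approx(1.0, abs=1e-15)
        n_total = res.defense_n + res.growth_n_used + res.returned_n
        assert n_total == pytest.approx(0.5, abs=1e-15)
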