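"""Simulation core: initialization, the daily cycle, remobilization,
determinism and mass-balance auditing."""

import copy

import pytest

from wheatgdt import (
    OrganKind,
    audit_mass_balance,
    default_config,
    initialize_plant,
    remobilize_senescent,
    run_simulation,
    step,
)
from wheatgdt.allocation import PlantStatus
from wheatgdt.config import RemobilizationParams
from wheatgdt.environment import EnvironmentDay, build_environment
from wheatgdt.state import VEGETATIVE, OrganState


class TestInitialization:
    def test_default_plant_is_unstressed(self, config):
        plant = initialize_plant(config)
        assert set(plant.organs) == set(OrganKind)
        for organ in plant.organs.values():
            assert organ.s0 == 0.0
            assert organ.d_coef == 0.0

    def test_massless_grain_valid_before_anthesis(self, config):
        config.organs[OrganKind.GRAIN].structural_mass = 0.0
        plant = initialize_plant(config)
        assert plant.organ(OrganKind.GRAIN).structural_mass == 0.0

    def test_negative_root_mass_rejected(self, config):
        with pytest.raises(Exception):
            config.organs[OrganKind.ROOTS].structural_mass = -1.0
            initialize_plant(config)

    def test_missing_organ_entry_names_the_organ(self, config):
        del config.organs[OrganKind.ROOTS]
        with pytest.raises(ValueError, match="roots"):
            initialize_plant(config)

    def test_leaf_area_follows_sla(self, config):
        plant = initialize_plant(config)
        leaf = plant.organ(OrganKind.MATURE_LEAF)
        assert leaf.area == pytest.approx(
            leaf.structural_mass * config.sla[OrganKind.MATURE_LEAF]
        )
        assert plant.organ(OrganKind.ROOTS).area == 0.0


class TestStep:
    def test_dark_day_assimilates_nothing_and_drains_the_pool(self, config):
        plant = initialize_plant(config)
        env = EnvironmentDay(
            day=0, par=0.0, t_air=15.0, t_leaf=15.0, rel_humidity=0.7, ca=420.0, soil_no3=2.0
        )
        pool_before = plant.pool.carbon
        new, rec = step(plant, env, config)
        assert rec.assimilation_c == 0.0
        assert rec.respiration_c > 0.0
        for kind in (OrganKind.MATURE_LEAF, OrganKind.GROWING_LEAF):
            assert rec.organs[kind].dark_respiration_c > 0.0
        assert new.pool.carbon < pool_before

    def test_step_does_not_mutate_input_state(self, config):
        plant = initialize_plant(config)
        snapshot = copy.deepcopy(plant.organs[OrganKind.ROOTS].structural_mass)
        env = build_environment(1, config.seed, config.weather)[0]
        step(plant, env, config)
        assert plant.organs[OrganKind.ROOTS].structural_mass == snapshot
        assert plant.day == 0


class TestRunSimulation:
    def test_same_seed_bit_identical(self, config):
        a = run_simulation(config)
        b = run_simulation(config)
        for ra, rb in zip(a.all_records(), b.all_records()):
            assert ra == rb

    def test_default_run_grows(self, full_config):
        traj = run_simulation(full_config)
        initial = sum(o.mass for o in traj.initial.organs.values())
        assert traj.final_total_mass() > initial

    def test_zero_horizon_keeps_only_initial_record(self):
        traj = run_simulation(default_config(horizon_days=0))
        assert len(traj.records) == 0
        assert traj.initial.is_initial

    def test_one_record_per_day(self, config):
        traj = run_simulation(config)
        assert len(traj.records) == config.horizon_days
        assert [r.day for r in traj.records] == list(range(config.horizon_days))

    def test_short_env_series_rejected(self, config):
        env = build_environment(10, config.seed, config.weather)
        with pytest.raises(ValueError):
            run_simulation(config, env_series=env)

    def test_no_negative_stocks_at_any_day(self, config):
        for rec in run_simulation(config).records:
            assert rec.pool_c >= 0.0
            assert rec.pool_n >= 0.0
            for orec in rec.organs.values():
                assert orec.mass >= 0.0
                assert orec.c_store >= 0.0
                assert orec.n_store >= 0.0

    def test_stage_switches_at_anthesis(self, full_config):
        traj = run_simulation(full_config)
        day_before = traj.records[full_config.anthesis_day - 1]
        day_at = traj.records[full_config.anthesis_day]
        assert day_before.stage == "vegetative"
        assert day_at.stage == "reproductive"


class TestRemobilization:
    def _status(self, s=0.0):
        return PlantStatus(s_plant_mean=s, s_plant_max=s, pool_c=0, pool_n=0, stage=VEGETATIVE)

    def _sen(self, c=0.5, n=1.0):
        return OrganState(kind=OrganKind.SENESCENT_LEAF, structural_mass=0.2, c_store=c, n_store=n)

    def test_switch_off(self):
        params = RemobilizationParams(r_c=0.0, r_n=0.0)
        fc, fn, organ = remobilize_senescent(self._sen(), self._status(), params)
        assert fc == 0.0 and fn == 0.0
        assert organ.n_store == pytest.approx(1.0)

    def test_fractional_rule_hand_value(self):
        # r_N = 0.05, store 1.0 g, no stress -> flux 0.05, store 0.95
        params = RemobilizationParams(r_c=0.03, r_n=0.05, a_sen=1.0)
        _, fn, organ = remobilize_senescent(self._sen(), self._status(0.0), params)
        assert fn == pytest.approx(0.05, rel=1e-12)
        assert organ.n_store == pytest.approx(0.95, rel=1e-12)

    def test_stress_doubles_fluxes_with_unit_acceleration(self):
        params = RemobilizationParams(r_c=0.03, r_n=0.05, a_sen=1.0)
        fc0, fn0, _ = remobilize_senescent(self._sen(), self._status(0.0), params)
        fc1, fn1, _ = remobilize_senescent(self._sen(), self._status(1.0), params)
        assert fc1 == pytest.approx(2 * fc0, rel=1e-12)
        assert fn1 == pytest.approx(2 * fn0, rel=1e-12)

    def test_structural_mass_never_changes(self):
        params = RemobilizationParams()
        _, _, organ = remobilize_senescent(self._sen(), self._status(1.0), params)
        assert organ.structural_mass == pytest.approx(0.2)

    def test_non_senescent_organ_rejected(self):
        leaf = OrganState(kind=OrganKind.MATURE_LEAF, structural_mass=1.0)
        with pytest.raises(ValueError):
            remobilize_senescent(leaf, self._status(), RemobilizationParams())


class TestAudit:
    def test_clean_run_has_no_flags(self, config):
        report = audit_mass_balance(run_simulation(config))
        assert len(report) == config.horizon_days
        assert not report["flagged"].any()
        assert report["c_residual"].max() <= 1e-9
        assert report["n_residual"].max() <= 1e-9

    def test_injected_fault_is_flagged(self, config):
        traj = run_simulation(config)
        traj.records[5].assimilation_c += 0.001
        report = audit_mass_balance(traj)
        assert bool(report.loc[report["day"] == 5, "flagged"].iloc[0])
        assert report["flagged"].sum() == 1

    def test_empty_trajectory_gives_empty_report(self):
        traj = run_simulation(default_config(horizon_days=0))
        assert len(audit_mass_balance(traj)) == 0
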