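"""Flow-cell simulator: conservation, analytic limits, saturation behavior,
geometry effects, determinism and fixtures."""

import dataclasses
import math

import numpy as np
import pytest

import dissolkin as dk
from dissolkin.datamodel import Geometry, LodPolicy, NM220
from dissolkin.io import write_eluate_csv
from dissolkin.morphology import summarize_sizes
from dissolkin.simulate import (
    FIXTURE_NAMES,
    SimConfig,
    default_schedule,
    make_fixture,
    simulate,
)

B_EXPECTED = 10.3 * 4.1e-4 * 24.0  # intrinsic_rate x BET, 1/d


def total_mass(state, cfg):
    flow_by = cfg.geometry == Geometry.FLOW_BY
    v_cell = cfg.channel_volume if flow_by else cfg.cell_volume
    v_chamber = cfg.cell_volume if flow_by else 0.0
    return state.total_mass_ng(cfg.material.stoich_factor, v_cell, v_chamber)


class TestConservation:
    @pytest.mark.parametrize("name", ["subsat_flowthrough", "flowby", "cuo_like"])
    def test_mass_conserved_at_every_checkpoint(self, name):
        cfg = make_fixture(name)
        _, traj = simulate(cfg)
        m0 = cfg.material.initial_mass_ng
        for state in traj:
            assert total_mass(state, cfg) == pytest.approx(m0, rel=1e-6)

    def test_mass_conserved_ripening(self, ripening_outcome):
        cfg, run, traj, _, _ = ripening_outcome
        m0 = cfg.material.initial_mass_ng
        for state in traj:
            assert total_mass(state, cfg) == pytest.approx(m0, rel=1e-6)

    def test_mass_conserved_saturated(self, saturated_default):
        cfg, run, traj, _ = saturated_default
        m0 = cfg.material.initial_mass_ng
        for state in traj:
            assert total_mass(state, cfg) == pytest.approx(m0, rel=1e-6)


class TestAnalyticLimit:
    def test_first_order_decay_without_saturation(self):
        """With no ceiling and no curvature, retained mass follows
        exp(-k0·BET·t) over three half-lives."""
        cfg = SimConfig(
            material=dataclasses.replace(NM220, initial_mass=1.0),
            intrinsic_rate=100.0,
            c_sat=math.inf,
            capillary_length=0.0,
            noise_cv=0.0,
            t_end=72.0,  # ~3 half-lives at 0.984/d
        )
        _, traj = simulate(cfg)
        rate_h = 100.0 * 4.1e-4
        for state in traj[1:]:
            expected = cfg.material.initial_mass_ng * math.exp(-rate_h * state.t)
            assert state.solid_mass == pytest.approx(expected, rel=0.01)


class TestParameterRecovery:
    def test_noiseless_recovery_within_2pct(self, subsat_noiseless):
        _, _, _, result = subsat_noiseless
        assert result.b_diss == pytest.approx(B_EXPECTED, rel=0.02)

    def test_noisy_recovery_within_10pct(self, subsat_noisy_seeds):
        for _, _, result in subsat_noisy_seeds:
            assert result.b_diss == pytest.approx(B_EXPECTED, rel=0.10)


class TestSaturation:
    def test_regimes(self, subsat_noiseless, saturated_default):
        assert subsat_noiseless[3].regime == dk.Regime.FIRST_ORDER
        _, _, _, result = saturated_default
        assert result.regime == dk.Regime.SATURATED_LINEAR
        assert result.ceiling_conc == pytest.approx(1.0, rel=0.10)

    def test_steady_release_at_ceiling(self, saturated_noiseless):
        """Zero-order regime: daily analyte release ~ flow x c_sat
        (2 mL/h x 1 mg/L = 48 µg/d), measured after the first day."""
        _, run, _, _ = saturated_noiseless
        late = [f for f in run.fractions if f.t_start >= 24.0]
        days = (late[-1].t_end - late[0].t_start) / 24.0
        daily_analyte = sum(f.analyte_mass_ug for f in late) / days
        assert daily_analyte == pytest.approx(48.0, rel=0.05)

    def test_flow_doubling_doubles_release(self, flow_doubling_run):
        _, run, _ = flow_doubling_run
        pre = [f for f in run.fractions if 24.0 <= f.t_start and f.t_end <= 84.0]
        post = [f for f in run.fractions if f.t_start >= 96.0]
        rate_pre = sum(f.analyte_mass_ug for f in pre) / (
            (pre[-1].t_end - pre[0].t_start) / 24.0
        )
        rate_post = sum(f.analyte_mass_ug for f in post) / (
            (post[-1].t_end - post[0].t_start) / 24.0
        )
        assert rate_post / rate_pre == pytest.approx(2.0, rel=0.10)


class TestRateCollapse:
    def test_saturating_material_decreasing_in_sa_over_v(self, sa_v_samples):
        from scipy import stats

        pts = np.array(sa_v_samples["baso4"])
        rho = stats.spearmanr(pts[:, 0], pts[:, 1]).statistic
        assert rho < -0.9

    def test_non_saturating_material_flat(self, sa_v_samples):
        pts = np.array(sa_v_samples["cuo"])
        k = pts[:, 1]
        assert k.std() / k.mean() < 0.05


class TestFlowByGeometry:
    def test_membrane_slows_apparent_dissolution(self, flowby_pair):
        result_fb, result_ft = flowby_pair
        assert result_fb.b_diss < result_ft.b_diss

    def test_flowby_ceiling_below_flowthrough(self, flowby_pair):
        result_fb, result_ft = flowby_pair
        assert result_fb.ceiling_conc < 0.5  # ~0.3 mg/L observable ceiling


class TestDeterminism:
    def test_identical_seed_identical_csv(self, tmp_path):
        cfg = make_fixture("subsat_flowthrough", seed=99)
        run1, _ = simulate(cfg)
        run2, _ = simulate(cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_eluate_csv(run1, p1)
        write_eluate_csv(run2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_different_noise(self):
        run1, _ = simulate(make_fixture("subsat_flowthrough", seed=1))
        run2, _ = simulate(make_fixture("subsat_flowthrough", seed=2))
        assert any(
            a.conc != b.conc for a, b in zip(run1.fractions, run2.fractions)
        )


class TestSizeTrajectory:
    def test_pure_dissolution_median_non_increasing(self, lam0_outcome):
        _, _, traj, sizes, _ = lam0_outcome
        medians = [summarize_sizes(s).median for s in sizes]
        assert all(b <= a + 1e-9 for a, b in zip(medians, medians[1:]))

    def test_ripening_median_grows_while_mass_shrinks(self, ripening_outcome):
        _, _, traj, sizes, _ = ripening_outcome
        assert summarize_sizes(sizes[-1]).median > summarize_sizes(sizes[0]).median * 0.99
        assert traj[-1].solid_mass < traj[0].solid_mass

    def test_counts_conserved_except_removal(self, ripening_outcome):
        _, _, traj, _, _ = ripening_outcome
        n0 = traj[0].bin_counts.sum()
        for state in traj:
            assert state.bin_counts.sum() <= n0 * (1 + 1e-9)

    def test_fixed_sample_size(self, lam0_outcome):
        _, _, _, sizes, _ = lam0_outcome
        assert all(s.n == 500 for s in sizes)


class TestLodCensoring:
    def test_low_concentrations_flagged(self):
        cfg = SimConfig(
            material=dataclasses.replace(NM220, initial_mass=0.001),
            intrinsic_rate=0.1,
            c_sat=1.0,
            noise_cv=0.0,
            lod=0.01,
            lod_policy=LodPolicy.HALF_LOD,
            t_end=48.0,
        )
        run, _ = simulate(cfg)
        flagged = [f for f in run.fractions if f.below_lod]
        assert flagged
        assert all(f.conc == pytest.approx(0.005) for f in flagged)


class TestFixtures:
    def test_spec_scenarios(self):
        subsat = make_fixture("subsat_flowthrough")
        assert subsat.material.initial_mass == 0.17
        assert subsat.flow == 2.0 and subsat.c_sat == 1.0
        saturated = make_fixture("saturated_flowthrough")
        assert saturated.material.initial_mass == 50.0
        cuo = make_fixture("cuo_like")
        assert math.isinf(cuo.c_sat) and cuo.capillary_length == 0.0
        flowby = make_fixture("flowby")
        assert flowby.geometry == Geometry.FLOW_BY

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("nope")

    def test_all_names_buildable(self):
        for name in FIXTURE_NAMES:
            assert make_fixture(name).material.initial_mass > 0


class TestSchedule:
    def test_default_plan_shape(self):
        plan = default_schedule(168.0)
        assert plan[0] == (0.0, 2.0)
        assert plan[11] == (22.0, 24.0)
        assert plan[12] == (24.0, 48.0)
        assert plan[-1][1] == 168.0
        assert len(plan) == 18

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(intrinsic_rate=-1.0)
        with pytest.raises(ValueError):
            SimConfig(area_model="cubist")
        with pytest.raises(ValueError):
            SimConfig(flow=((1.0, 2.0),))  # schedule must start at t=0
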