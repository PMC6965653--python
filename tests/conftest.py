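"""Shared fixtures: simulator runs are expensive enough to cache per session."""

from __future__ import annotations

import dataclasses

import pytest

import dissolkin as dk
from dissolkin.simulate import make_fixture, simulate, size_trajectory
from dissolkin.datamodel import NM220


@pytest.fixture(scope="session")
def subsat_noiseless():
    cfg = dataclasses.replace(make_fixture("subsat_flowthrough"), noise_cv=0.0)
    run, traj = simulate(cfg)
    return cfg, run, traj, dk.analyze(run)


@pytest.fixture(scope="session")
def subsat_noisy_seeds():
    out = []
    for seed in range(5):
        cfg = dataclasses.replace(
            make_fixture("subsat_flowthrough"), seed=seed, noise_cv=0.05
        )
        run, _ = simulate(cfg)
        out.append((cfg, run, dk.analyze(run)))
    return out


@pytest.fixture(scope="session")
def saturated_default():
    cfg = make_fixture("saturated_flowthrough")
    run, traj = simulate(cfg)
    return cfg, run, traj, dk.analyze(run)


@pytest.fixture(scope="session")
def saturated_noiseless():
    cfg = dataclasses.replace(make_fixture("saturated_flowthrough"), noise_cv=0.0)
    run, traj = simulate(cfg)
    return cfg, run, traj, dk.analyze(run)


@pytest.fixture(scope="session")
def flow_doubling_run():
    """10 mg saturated cell; flow stepped 2 → 4 mL/h at 84 h."""
    cfg = dataclasses.replace(
        make_fixture("saturated_flowthrough"),
        material=dataclasses.replace(NM220, initial_mass=10.0),
        flow=((0.0, 2.0), (84.0, 4.0)),
        noise_cv=0.0,
    )
    run, traj = simulate(cfg)
    return cfg, run, traj


@pytest.fixture(scope="session")
def flowby_pair():
    """Flow-by vs flow-through at identical intrinsic parameters."""
    cfg_fb = dataclasses.replace(make_fixture("flowby"), noise_cv=0.0)
    run_fb, _ = simulate(cfg_fb)
    cfg_ft = dataclasses.replace(cfg_fb, geometry=dk.Geometry.FLOW_THROUGH)
    run_ft, _ = simulate(cfg_ft)
    return dk.analyze(run_fb), dk.analyze(run_ft)


@pytest.fixture(scope="session")
def ripening_outcome():
    cfg = make_fixture("ripening")
    run, traj = simulate(cfg)
    sizes = size_trajectory(traj)
    f = dk.cumulative_dissolved(run).final_fraction
    return cfg, run, traj, sizes, f


@pytest.fixture(scope="session")
def lam0_outcome():
    cfg = dataclasses.replace(
        make_fixture("subsat_flowthrough"), capillary_length=0.0, noise_cv=0.0
    )
    run, traj = simulate(cfg)
    sizes = size_trajectory(traj)
    f = dk.cumulative_dissolved(run).final_fraction
    return cfg, run, traj, sizes, f


@pytest.fixture(scope="session")
def sa_v_samples():
    """Instantaneous rate samples for a saturating and a non-saturating
    material over varied loadings and flows."""

    def collect(configs):
        pts = []
        for cfg in configs:
            run, _ = simulate(cfg)
            for rs in dk.instantaneous_rates(run):
                if rs.t_mid > 4:  # skip the cell fill transient
                    pts.append((rs.sa_over_v_paper, rs.k_inst))
        return pts

    cu = make_fixture("cuo_like")
    cu_cfgs = [
        dataclasses.replace(
            cu,
            material=dataclasses.replace(cu.material, initial_mass=m),
            flow=fl,
            noise_cv=0.0,
        )
        for m, fl in [(0.1, 2.0), (1.0, 2.0), (1.0, 4.0)]
    ]
    ba = make_fixture("saturated_flowthrough")
    ba_cfgs = [
        dataclasses.replace(
            ba,
            material=dataclasses.replace(ba.material, initial_mass=m),
            flow=fl,
            noise_cv=0.0,
        )
        for m, fl in [(0.17, 2.0), (1.0, 2.0), (10.0, 2.0), (50.0, 2.0), (10.0, 4.0)]
    ]
    return {"cuo": collect(cu_cfgs), "baso4": collect(ba_cfgs)}
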