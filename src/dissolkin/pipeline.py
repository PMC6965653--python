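"""End-to-end orchestration: simulate/load → analyze → biokinetics →
morphology → report.

The report bundle mirrors the conventional cumulative-evaluation table of
flow-cell studies (daily release M_ion/T, conversion half-time t½,
cumulative rate k, fitted half-time t′½, fitted rate b_diss) plus the
in vivo prediction chain and an optional morphology verdict.  Everything is
deterministic under a fixed seed, and the provenance block records the
configuration hash, seed and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .biokinetics import B_MECH_PSLT, grouping_band, predict_invivo_halftime
from .datamodel import LodPolicy
from .io import read_eluate_csv, write_eluate_csv, write_report
from .kinetics import KineticsResult, analyze
from .morphology import MorphologyVerdict, classify_transformation
from .simulate import SimConfig, make_fixture, simulate, size_trajectory
from .units import round_sig

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "kinetics_report_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    """What to run and where to put it.

    Exactly one input source: a simulator fixture name, a full
    :class:`SimConfig`, or an eluate CSV (with material metadata inline or
    in a sidecar YAML).
    """

    fixture: Optional[str] = None
    sim_config: Optional[SimConfig] = None
    eluate_csv: Optional[Union[str, Path]] = None
    material_yaml: Optional[Union[str, Path]] = None
    lod_policy: LodPolicy = LodPolicy.HALF_LOD
    seed: int = 0
    b_mech: float = B_MECH_PSLT
    with_biokinetics: bool = True
    with_morphology: bool = True
    out_dir: Optional[Union[str, Path]] = None

    def __post_init__(self) -> None:
        sources = [self.fixture, self.sim_config, self.eluate_csv]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one of fixture, sim_config or eluate_csv must be given"
            )


@dataclass(frozen=True)
class ReportBundle:
    """Serializable result of one pipeline run."""

    run_meta: dict
    kinetics: KineticsResult
    biokinetics: Optional[dict] = None
    morphology: Optional[MorphologyVerdict] = None
    provenance: dict = field(default_factory=dict)

    def summary_rows(self) -> list[dict]:
        """The five conventional cumulative-evaluation columns."""
        k = self.kinetics
        return [
            {
                "M0_mg": self.run_meta.get("initial_mass_mg"),
                "M_ion_per_T_ug_d": round_sig(k.daily_release),
                "t_half_d": round_sig(k.t_half_from_k),
                "k_ng_cm2_h": round_sig(k.k_cum),
                "t_half_fit_d": round_sig(k.t_half_fit),
                "b_diss_pct_d": round_sig(k.b_diss * 100.0),
            }
        ]


def kinetics_report_dict(result: KineticsResult) -> dict:
    """Flat report fields for one kinetic evaluation (JSON-friendly)."""
    return {
        "k_cum_ng_cm2_h": result.k_cum,
        "b_diss_pct_d": result.b_diss * 100.0,
        "t_half_fit_d": result.t_half_fit,
        "t_half_from_k_d": result.t_half_from_k,
        "fit_r2": result.fit_r2,
        "regime": result.regime.value,
        "ceiling_mg_L": result.ceiling_conc,
        "daily_release_ug_d": result.daily_release,
        "dissolved_fraction": result.dissolved_fraction_final,
        "grouping_band": grouping_band(result.k_cum).value,
        "instantaneous": [
            {
                "t_mid_h": rs.t_mid,
                "k_inst_ng_cm2_h": rs.k_inst,
                "sa_cm2": rs.sa,
                "sa_over_v_paper_h_cm": rs.sa_over_v_paper,
                "sa_over_v_cm2_h_cm3": rs.sa_over_v,
                "flow_mL_h": rs.flow,
            }
            for rs in result.instantaneous
        ],
    }


def _config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        payload = json.dumps(
            dataclasses.asdict(obj), default=str, sort_keys=True
        ).encode()
    else:
        payload = repr(obj).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the enabled stages in order and write every artifact.

    Stages: (1) obtain a run — simulate a fixture/config or read an eluate
    CSV; (2) kinetic analysis; (3) biokinetic prediction of the in vivo
    retention half-time from the abiotic b_diss; (4) morphology verdict
    (simulated runs only — compares the end-state size distribution with
    the shrinking-sphere prediction).  Artifacts (eluate CSV for simulated
    runs, report JSON) are written to ``out_dir`` when given.
    """
    from . import __version__

    trajectory = None
    sim_cfg: Optional[SimConfig] = None
    stage = "input"
    try:
        if config.eluate_csv is not None:
            run = read_eluate_csv(
                config.eluate_csv,
                lod_policy=config.lod_policy,
                material_path=config.material_yaml,
            )
        else:
            sim_cfg = (
                config.sim_config
                if config.sim_config is not None
                else make_fixture(config.fixture, seed=config.seed)
            )
            run, trajectory = simulate(sim_cfg)

        stage = "kinetics"
        result = analyze(run)

        stage = "biokinetics"
        biokin = None
        if config.with_biokinetics:
            b = result.b_diss
            biokin = {
                "b_diss_abiotic_per_d": b,
                "b_mech_per_d": config.b_mech,
                "predicted_total_t_half_d": predict_invivo_halftime(b, config.b_mech),
                "grouping_band": grouping_band(result.k_cum).value,
            }

        stage = "morphology"
        morph = None
        if config.with_morphology and trajectory is not None:
            sizes = size_trajectory(trajectory)
            morph = classify_transformation(
                sim_cfg.material.d0_median,
                result.dissolved_fraction_final,
                sizes[-1],
            )

        stage = "report"
        meta = {
            "material": run.material.name,
            "initial_mass_mg": run.material.initial_mass,
            "bet_m2_g": run.material.bet_area,
            "geometry": run.geometry.value,
            "medium": run.medium,
            "duration_h": run.duration,
            "n_fractions": len(run.fractions),
        }
        bundle = ReportBundle(
            run_meta=meta,
            kinetics=result,
            biokinetics=biokin,
            morphology=morph,
            provenance={
                "seed": config.seed,
                "config_hash": _config_hash(sim_cfg if sim_cfg is not None else config),
                "package_version": __version__,
            },
        )
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            if sim_cfg is not None:
                write_eluate_csv(run, out / "eluate.csv")
            report = {
                "run": meta,
                **kinetics_report_dict(result),
                "biokinetics": biokin,
                "morphology": dataclasses.asdict(morph) if morph else None,
                "provenance": bundle.provenance,
            }
            write_report(report, out / "report.json")
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
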