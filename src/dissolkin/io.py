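"""Readers and writers for eluate tables, material configs, TEM size lists
and analysis reports.

Eluate CSV dialect
------------------
Header columns ``t_start_h, t_end_h, conc_mg_L`` and exactly one of
``volume_mL`` or ``flow_mL_h`` (volume is then flow × interval length).
Material and run metadata come either from a sidecar YAML file or from an
inline ``# key: value`` comment block preceding the header, e.g.::

    # name: BaSO4 NM-220
    # initial_mass_mg: 1.0
    # bet_m2_g: 41
    # stoich_factor: 1.6995
    # geometry: flow_through
    # lod_mg_L: 0.01
    t_start_h,t_end_h,conc_mg_L,flow_mL_h
    0,2,0.9,2
    ...

TEM diameter lists are one-column CSVs with header ``diameter_nm``.
Reports are schema-versioned JSON; floats survive a write/read round trip
exactly (shortest-round-trip decimal representation).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .datamodel import (
    EluateFraction,
    FlowCellRun,
    Geometry,
    LodPolicy,
    Material,
    SizeSample,
    censor_concentrations,
)

__all__ = [
    "read_material_yaml",
    "read_eluate_csv",
    "write_eluate_csv",
    "read_sizes_csv",
    "write_sizes_csv",
    "write_report",
    "read_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

_MATERIAL_KEYS = {
    "name": ("name", str),
    "initial_mass_mg": ("initial_mass", float),
    "bet_m2_g": ("bet_area", float),
    "stoich_factor": ("stoich_factor", float),
    "density_g_cm3": ("density", float),
    "d0_median_nm": ("d0_median", float),
    "d0_gsd": ("d0_gsd", float),
}
_RUN_KEYS = {"geometry", "medium", "temperature_C", "lod_mg_L", "residual_solid_mg", "membrane_mg"}


def _material_from_mapping(meta: dict) -> Material:
    missing = [k for k in ("initial_mass_mg", "bet_m2_g", "stoich_factor") if k not in meta]
    if missing:
        raise ValueError(f"missing material metadata: {', '.join(missing)}")
    kwargs = {}
    for key, (field_name, cast) in _MATERIAL_KEYS.items():
        if key in meta and meta[key] is not None:
            kwargs[field_name] = cast(meta[key])
    kwargs.setdefault("name", "unnamed material")
    return Material(**kwargs)


def read_material_yaml(path: Union[str, Path]) -> Material:
    """Load a material descriptor from a YAML key/value file."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ValueError(f"{path}: expected a mapping of material fields")
    return _material_from_mapping(meta)


def _parse_comment_block(path: Path) -> tuple[dict, int]:
    meta: dict = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = yaml.safe_load(value.strip())
    return meta, n_comment


def read_eluate_csv(
    path: Union[str, Path],
    lod_policy: Union[LodPolicy, str] = LodPolicy.HALF_LOD,
    material: Optional[Material] = None,
    material_path: Optional[Union[str, Path]] = None,
) -> FlowCellRun:
    """Parse an eluate-fraction CSV into a validated :class:`FlowCellRun`.

    Concentrations below the run's LOD are replaced according to
    ``lod_policy`` and flagged.  Overlapping or gapped intervals, negative
    concentrations and missing material metadata are rejected.
    """
    path = Path(path)
    meta, n_comment = _parse_comment_block(path)
    if material is None and material_path is not None:
        material = read_material_yaml(material_path)
    if material is None:
        material = _material_from_mapping(meta)

    df = pd.read_csv(path, skiprows=n_comment)
    required = {"t_start_h", "t_end_h", "conc_mg_L"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    has_vol = "volume_mL" in df.columns
    has_flow = "flow_mL_h" in df.columns
    if has_vol == has_flow:
        raise ValueError(f"{path}: need exactly one of volume_mL or flow_mL_h")

    df = df.sort_values("t_start_h", kind="stable").reset_index(drop=True)
    for i in range(1, len(df)):
        if df.loc[i, "t_start_h"] < df.loc[i - 1, "t_end_h"] - 1e-9:
            raise ValueError(f"overlapping intervals at row {i}")
    if (df["conc_mg_L"] < 0).any():
        bad = int(df.index[df["conc_mg_L"] < 0][0])
        raise ValueError(f"negative concentration at row {bad}")

    fractions = []
    for _, row in df.iterrows():
        dt = float(row["t_end_h"]) - float(row["t_start_h"])
        vol = float(row["volume_mL"]) if has_vol else float(row["flow_mL_h"]) * dt
        fractions.append(
            EluateFraction(
                t_start=float(row["t_start_h"]),
                t_end=float(row["t_end_h"]),
                conc=float(row["conc_mg_L"]),
                volume=vol,
            )
        )

    lod = float(meta.get("lod_mg_L", 0.01))
    fractions = censor_concentrations(fractions, lod, LodPolicy(lod_policy))
    return FlowCellRun(
        material=material,
        geometry=Geometry(meta.get("geometry", "flow_through")),
        fractions=tuple(fractions),
        medium=str(meta.get("medium", "")),
        temperature=float(meta.get("temperature_C", 37.0)),
        residual_solid_mass=(
            float(meta["residual_solid_mg"]) if meta.get("residual_solid_mg") is not None else None
        ),
        membrane_mass=(
            float(meta["membrane_mg"]) if meta.get("membrane_mg") is not None else None
        ),
        lod=lod,
    )


def write_eluate_csv(run: FlowCellRun, path: Union[str, Path]) -> None:
    """Write a run back to the eluate CSV dialect (inline metadata block,
    volumes rather than flows; full float precision)."""
    mat = run.material
    lines = [
        f"# name: {mat.name}",
        f"# initial_mass_mg: {mat.initial_mass!r}",
        f"# bet_m2_g: {mat.bet_area!r}",
        f"# stoich_factor: {mat.stoich_factor!r}",
    ]
    if mat.density is not None:
        lines.append(f"# density_g_cm3: {mat.density!r}")
    if mat.d0_median is not None:
        lines.append(f"# d0_median_nm: {mat.d0_median!r}")
    if mat.d0_gsd is not None:
        lines.append(f"# d0_gsd: {mat.d0_gsd!r}")
    lines += [
        f"# geometry: {run.geometry.value}",
        f"# medium: {run.medium}",
        f"# temperature_C: {run.temperature!r}",
        f"# lod_mg_L: {run.lod!r}",
    ]
    if run.residual_solid_mass is not None:
        lines.append(f"# residual_solid_mg: {run.residual_solid_mass!r}")
    if run.membrane_mass is not None:
        lines.append(f"# membrane_mg: {run.membrane_mass!r}")
    lines.append("t_start_h,t_end_h,conc_mg_L,volume_mL")
    for f in run.fractions:
        lines.append(f"{f.t_start!r},{f.t_end!r},{f.conc!r},{f.volume!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sizes_csv(path: Union[str, Path], label: str = "") -> SizeSample:
    """Read a one-diameter-per-row TEM size list (header ``diameter_nm``)."""
    df = pd.read_csv(path)
    if "diameter_nm" not in df.columns:
        raise ValueError(f"{path}: expected a 'diameter_nm' column")
    if df.empty:
        raise ValueError(f"{path}: empty size list")
    if (df["diameter_nm"] <= 0).any():
        bad = int(df.index[df["diameter_nm"] <= 0][0])
        raise ValueError(f"non-positive diameter at row {bad}")
    return SizeSample(diameters=tuple(float(v) for v in df["diameter_nm"]), label=label or str(path))


def write_sizes_csv(sample: SizeSample, path: Union[str, Path]) -> None:
    lines = ["diameter_nm"] + [repr(d) for d in sample.diameters]
    Path(path).write_text("\n".join(lines) + "\n")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "value") and not isinstance(obj, (int, float)):  # enums
        return obj.value
    if isinstance(obj, float) and math.isinf(obj):
        return "Infinity" if obj > 0 else "-Infinity"
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_report(bundle, path: Union[str, Path]) -> None:
    """Serialize a report bundle (any dataclass/dict tree) to versioned JSON."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, "report": _to_jsonable(bundle)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
        fh.write("\n")


def read_report(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema version {payload.get('schema_version')!r}")
    return payload["report"]
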