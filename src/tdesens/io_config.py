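"""Configuration files, curve/table I/O and field export."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import CoolingCurve, DeviationResult
from .phantom import Phantom
from .study import StudyConfig
from .thermal import TemperatureField

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "write_curves",
    "read_curves",
    "write_deviation_result",
    "export_field_hdf5",
    "export_phantom_hdf5",
    "write_vtk_image",
    "write_tissue_table",
]

CURVE_COLUMNS = ["time_h", "temp_C", "probe_id", "model_variant", "T_A", "R"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def load_config(path) -> StudyConfig:
    """Read a YAML study configuration; unknown keys are rejected.

    Missing keys fall back to the documented defaults (ambient list
    5/15/25 deg C, radii 0.5/1/2 cm, a = 1 h, b = 45 h, K = 1000).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    fields = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(
            f"{path}: unknown configuration keys: {sorted(unknown)}"
        )
    for key in ("variants", "T_A_list", "R_list"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return StudyConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(cfg: StudyConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    for key, val in data.items():
        if isinstance(val, tuple):
            data[key] = list(val)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_curves(curves, path, model_variant: str = "", R: float = np.nan) -> None:
    """Cooling curves as tidy CSV (one row per time sample)."""
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "time_h": c.times, "temp_C": c.temps, "probe_id": c.probe_id,
            "model_variant": model_variant, "T_A": c.T_A, "R": R,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=CURVE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def read_curves(path) -> list[CoolingCurve]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ConfigError(f"{path}: malformed CSV ({exc})") from exc
    missing = set(CURVE_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for pid, grp in df.groupby("probe_id", sort=False):
        grp = grp.sort_values("time_h")
        T_A = float(grp["T_A"].iloc[0]) if "T_A" in grp else float("nan")
        curves.append(CoolingCurve(times=grp.time_h.to_numpy(),
                                   temps=grp.temp_C.to_numpy(),
                                   probe_id=str(pid), T_A=T_A))
    return curves


def write_deviation_result(res: DeviationResult, frame, path) -> None:
    """DeviationResult (plus frame bounds) as a small JSON document."""
    doc = {
        "d_max_global_h": res.d_max_global,
        **{f"d_max_Q{i}_h": res.d_max_local.get(i) for i in range(1, 5)},
        "K": frame.K,
        **{f"K_{i}": res.K_i.get(i, 0) for i in range(1, 5)},
        "t_min_h": frame.t_MIN,
        "t_max_h": frame.t_MAX,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def export_field_hdf5(f: TemperatureField, path, name: str = "temperature") -> None:
    import h5py

    with h5py.File(path, "a") as h5:
        if name in h5:
            del h5[name]
        ds = h5.create_dataset(name, data=f.values, compression="gzip")
        ds.attrs["time_h"] = f.time
        ds.attrs["spacing_m"] = f.spacing
        ds.attrs["origin_m"] = f.origin


def export_phantom_hdf5(p: Phantom, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("labels", data=p.labels, compression="gzip")
        ds.attrs["spacing_m"] = p.spacing
        ds.attrs["origin_m"] = p.origin
        ds.attrs["length_m"] = p.length
        ds.attrs["mass_kg"] = p.declared_mass
        ds.attrs["rectal_probe_m"] = p.rectal_probe
        tis = h5.create_group("tissues")
        for lab, props in p.tissues.items():
            g = tis.create_group(str(lab))
            for fld in ("name", "kappa", "rho", "c", "w", "emissivity"):
                g.attrs[fld] = getattr(props, fld)


def write_vtk_image(array: np.ndarray, spacing, origin, path,
                    name: str = "scalars") -> None:
    """Legacy-VTK ASCII STRUCTURED_POINTS image for quick inspection."""
    nx, ny, nz = array.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}\n")
        fh.write(f"POINT_DATA {array.size}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, array.ravel(order="F")[None], fmt="%.6g",
                   delimiter=" ")


def write_tissue_table(tissues: dict, path) -> None:
    rows = [{
        "label": lab, "name": t.name, "kappa": t.kappa, "rho": t.rho,
        "c": t.c, "w": t.w, "emissivity": t.emissivity,
    } for lab, t in sorted(tissues.items())]
    pd.DataFrame(rows).to_csv(path, index=False)
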