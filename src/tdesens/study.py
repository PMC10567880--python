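"""Probe-placement sensitivity study: variants x ambients x radii x probes.

Runs the full pipeline on each phantom variant — ``free`` (symmetric body
floating in air), ``on_substrate`` (same body on a wet-soil slab) and
``asymmetric`` (perturbed organ layout, steady bioheat initial field) —
for every ambient temperature and octahedron radius, and tabulates the
death-time deviations D_MAX / D_MAX,Qi between the central rectal probe C
and each displaced probe SP_k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics, thermal
from .phantom import (PhantomSpec, ProbeSet, add_substrate, build_phantom,
                      make_octahedron_probes)

__all__ = ["StudyConfig", "VARIANTS", "run_study", "max_direction",
           "compare_variants", "summarize_maxima"]

log = logging.getLogger("tdesens.study")

VARIANTS = ("free", "on_substrate", "asymmetric")


@dataclass(frozen=True)
class StudyConfig:
    """Study grid and physics defaults.

    Ambient temperatures 5/15/25 deg C, octahedron radii 0.5/1/2 cm and
    the evaluation window a = 1 h to b = 45 h are the study conditions;
    grid spacing, K and the probe-output cadence are numerical choices.
    """

    variants: tuple[str, ...] = VARIANTS
    T_A_list: tuple[float, ...] = (5.0, 15.0, 25.0)
    R_list: tuple[float, ...] = (0.005, 0.01, 0.02)
    K: int = 1000
    a: float = 1.0
    b: float = 45.0
    seed: int = 0
    spacing: float = 0.01            # phantom voxel size, m
    h: float = 3.3                   # convective coefficient, W/(m^2 K)
    emissivity: float = 0.95
    T_core: float = 37.2             # deg C
    T_skin: float = 28.0             # deg C, gradient initial field
    core_depth: float = 0.05         # m, graded-shell thickness of the
                                     # initial field (deeper tissue = core)
    rho_b_c_b: float = 3.8e6         # blood volumetric heat capacity, J/(m^3 K)
    quantize_levels: int = 10        # bioheat initial-field quantisation
    substrate_thickness: float = 0.05  # m
    output_dt: float = 0.05          # probe sampling cadence, h

    def __post_init__(self) -> None:
        if not self.variants or not self.T_A_list or not self.R_list:
            raise ValueError("variants, T_A_list and R_list must be non-empty")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        if not 0 < self.a < self.b:
            raise ValueError("need 0 < a < b")


def _build_variant(variant: str, cfg: StudyConfig):
    spec = PhantomSpec(spacing=cfg.spacing,
                       symmetric=(variant != "asymmetric"),
                       r_max=max(cfg.R_list), seed=cfg.seed)
    p = build_phantom(spec)
    if variant == "on_substrate":
        p = add_substrate(p, thickness=cfg.substrate_thickness)
    return p


def _initial_field(variant: str, p, cfg: StudyConfig, bc):
    if variant == "asymmetric":
        T0 = thermal.solve_initial_field_bhte(
            p, T_core=cfg.T_core, bc=bc, rho_b_c_b=cfg.rho_b_c_b)
        return thermal.quantize_field(T0, cfg.quantize_levels, p)
    return thermal.gradient_initial_field(p, T_core=cfg.T_core,
                                          T_skin=cfg.T_skin,
                                          core_depth=cfg.core_depth)


def simulate_variant(variant: str, T_A: float, cfg: StudyConfig):
    """One cooling simulation; probe curves for C and all SP_k, all radii.

    All octahedron radii share a single simulation: every probe point is
    sampled from the same transient field.  Returns ``{probe_key: curve}``
    with keys ``"C"`` and ``"SP_k@R"``.
    """
    p = _build_variant(variant, cfg)
    bc = thermal.BoundaryCondition(T_A=T_A, h=cfg.h, emissivity=cfg.emissivity)
    T0 = _initial_field(variant, p, cfg, bc)
    points: dict[str, np.ndarray] = {"C": p.rectal_probe}
    for R in cfg.R_list:
        ps = make_octahedron_probes(p.rectal_probe, R)
        for pid, pt in ps.points().items():
            if pid != "C":
                points[f"{pid}@{R}"] = pt
    curves = thermal.simulate_cooling(p, T0, bc, points, t_end=cfg.b,
                                      output_dt=cfg.output_dt)
    return {c.probe_id: c for c in curves}


def run_study(cfg: StudyConfig | None = None) -> pd.DataFrame:
    """Full deviation table over the configured study cross product.

    One row per (variant, T_A, R, SP_k) with the global and Q-local
    maximum time deviations in hours.  Deterministic for a fixed config
    and seed.  A failed condition is recorded as a row of NaNs with the
    diagnostic logged.
    """
    cfg = cfg or StudyConfig()
    rows = []
    for variant in cfg.variants:
        for T_A in cfg.T_A_list:
            try:
                curves = simulate_variant(variant, T_A, cfg)
            except Exception:
                log.exception("simulation failed: %s T_A=%s", variant, T_A)
                for R in cfg.R_list:
                    for k in range(1, 7):
                        rows.append(_row(variant, T_A, R, k, None))
                continue
            for R in cfg.R_list:
                for k in range(1, 7):
                    pid = f"SP_{k}"
                    try:
                        res = metrics.d_max(curves["C"], curves[f"{pid}@{R}"],
                                            K=cfg.K, a=cfg.a, b=cfg.b)
                    except Exception:
                        log.exception("metric failed: %s T_A=%s R=%s %s",
                                      variant, T_A, R, pid)
                        res = None
                    rows.append(_row(variant, T_A, R, k, res))
    return pd.DataFrame(rows)


def _row(variant, T_A, R, k, res):
    pid = f"SP_{k}"
    row = {
        "variant": variant, "T_A": T_A, "R": R, "probe": pid,
        "axis": ProbeSet.AXIS_OF[pid],
        "d_max_global": np.nan,
    }
    for i in range(1, 5):
        row[f"d_max_Q{i}"] = np.nan
        row[f"K_{i}"] = 0
    if res is not None:
        row["d_max_global"] = res.d_max_global
        for i, v in res.d_max_local.items():
            row[f"d_max_Q{i}"] = v
            row[f"K_{i}"] = res.K_i[i]
    return row


def max_direction(table: pd.DataFrame, variant: str, T_A: float, R: float,
                  rtol: float = 1e-9) -> list[str]:
    """Axis (X/Y/Z) whose probe carries the largest D_MAX; ties -> both."""
    sel = table[(table.variant == variant) & (table.T_A == T_A)
                & (table.R == R)]
    if sel.empty:
        raise KeyError(f"no rows for ({variant}, {T_A}, {R})")
    best = sel.d_max_global.max()
    axes = sorted(set(sel.axis[sel.d_max_global >= best * (1 - rtol)]))
    return axes


def compare_variants(tableA: pd.DataFrame, tableB: pd.DataFrame) -> pd.DataFrame:
    """Per-condition signed differences D_MAX^A - D_MAX^B."""
    keys = ["T_A", "R", "probe"]
    a = tableA.set_index(keys).sort_index()
    b = tableB.set_index(keys).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("tables cover different (T_A, R, probe) conditions")
    cols = ["d_max_global"] + [f"d_max_Q{i}" for i in range(1, 5)]
    out = (a[cols] - b[cols]).reset_index()
    out.insert(0, "variants", f"{tableA.variant.iloc[0]}-{tableB.variant.iloc[0]}")
    return out


def summarize_maxima(table: pd.DataFrame) -> pd.DataFrame:
    """Max of D_MAX per (variant, T_A, R) plus an overall per-variant row."""
    per = (table.groupby(["variant", "T_A", "R"], as_index=False)
           .d_max_global.max())
    overall = (table.groupby("variant", as_index=False)
               .d_max_global.max())
    overall["T_A"] = np.nan
    overall["R"] = np.nan
    return pd.concat([per, overall[per.columns]], ignore_index=True)
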