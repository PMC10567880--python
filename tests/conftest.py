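"""Shared fixtures: analytic oracles and expensive simulation products."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import tdesens as td
from tdesens import study, thermal
from tdesens.phantom import Phantom, TissueProperties, default_tissues


# ---------------------------------------------------------------------------
# analytic / synthetic phantoms
# ---------------------------------------------------------------------------

def sphere_phantom(a: float, h: float, kappa=0.5, rho=1050.0, c=3600.0,
                   w=0.0) -> Phantom:
    """Homogeneous sphere of radius ``a`` voxelised at spacing ``h``."""
    n = int(round(2 * a / h)) + 6
    xs = (np.arange(n) + 0.5) * h
    ctr = n * h / 2
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    lab = (((X - ctr) ** 2 + (Y - ctr) ** 2 + (Z - ctr) ** 2) <= a * a)
    lab = lab.astype(np.int16)
    tis = {1: TissueProperties("homogeneous", kappa, rho, c, w, 0.95)}
    return Phantom(labels=lab, spacing=np.array([h] * 3), origin=np.zeros(3),
                   tissues=tis, rectal_probe=np.array([ctr] * 3), length=2 * a,
                   declared_mass=rho * lab.sum() * h ** 3)


def box_phantom(h: float, kappa=0.5, rho=1050.0, c=3600.0, w=0.0,
                emissivity=0.95, side=0.1, pad=2) -> Phantom:
    """Homogeneous axis-aligned cube (its staircase surface is exact)."""
    n = int(round(side / h))
    N = n + 2 * pad
    lab = np.zeros((N, N, N), dtype=np.int16)
    lab[pad:-pad, pad:-pad, pad:-pad] = 1
    tis = {1: TissueProperties("homogeneous", kappa, rho, c, w, emissivity)}
    return Phantom(labels=lab, spacing=np.array([h] * 3), origin=np.zeros(3),
                   tissues=tis, rectal_probe=np.array([N * h / 2] * 3),
                   length=side, declared_mass=rho * lab.sum() * h ** 3)


def compartment_box_phantom(h: float) -> Phantom:
    """Multi-tissue phantom whose compartments voxelise exactly at
    h in {0.02, 0.01, 0.005}: isolates solver discretisation error from
    geometry re-realisation when comparing grids."""
    nx, ny, nz = round(0.32 / h), round(0.24 / h), round(0.64 / h)
    lab = np.zeros((nx, ny, nz), dtype=np.int16)

    def box(x0, x1, y0, y1, z0, z1, v):
        lab[round(x0 / h):round(x1 / h), round(y0 / h):round(y1 / h),
            round(z0 / h):round(z1 / h)] = v

    box(0.04, 0.28, 0.04, 0.20, 0.04, 0.60, 1)   # muscle body
    box(0.06, 0.26, 0.06, 0.18, 0.06, 0.58, 4)   # visceral core
    box(0.12, 0.20, 0.06, 0.10, 0.04, 0.60, 3)   # dorsal bone slab
    tis = default_tissues()
    m = sum(tis[l].rho * np.count_nonzero(lab == l) for l in (1, 3, 4)) * h ** 3
    return Phantom(labels=lab, spacing=np.array([h] * 3), origin=np.zeros(3),
                   tissues=tis, rectal_probe=np.array([0.16, 0.12, 0.20]),
                   length=0.64, declared_mass=m)


# ---------------------------------------------------------------------------
# analytic oracles
# ---------------------------------------------------------------------------

def robin_sphere_center_series(t_s, a, alpha, Bi, n_terms=60):
    """Normalised centre temperature of a sphere cooling under a Robin
    boundary: eigenfunction series with roots of 1 - lam*cot(lam) = Bi
    found by bracketed root-finding in each (n*pi, (n+1)*pi)."""
    def f(lam):
        return 1.0 - lam / np.tan(lam) - Bi

    lam = np.array([brentq(f, n * np.pi + 1e-9, (n + 1) * np.pi - 1e-9)
                    for n in range(n_terms)])
    Cn = 4 * (np.sin(lam) - lam * np.cos(lam)) / (2 * lam - np.sin(2 * lam))
    Fo = alpha * np.atleast_1d(t_s)[:, None] / a ** 2
    return (Cn * np.exp(-lam ** 2 * Fo)).sum(axis=1)


def exponential_curve(times, T_A, T0, k, shift=0.0, probe_id="exp"):
    temps = T_A + (T0 - T_A) * np.exp(-k * np.maximum(times - shift, 0.0))
    return td.CoolingCurve(times=np.asarray(times, float), temps=temps,
                           probe_id=probe_id, T_A=T_A)


def brute_force_d_max(T1, T2, n_grid, a=1.0, b=45.0):
    """Independent exhaustive evaluation of the maximum time distance.

    Clips both curves to their decreasing windows inside [a, b], builds the
    pointwise-mean reference with plain numpy, and scans an ``n_grid``-point
    time grid, inverting each curve by direct interpolation on reversed
    arrays.  Shares no code with the library implementation.
    """
    def window(c):
        m = (c.times >= a) & (c.times <= b)
        ts, Ts = c.times[m], c.temps[m]
        i0 = int(np.argmax(Ts))
        return ts[i0:], Ts[i0:]

    t1, y1 = window(T1)
    t2, y2 = window(T2)
    lo = max(t1[0], t2[0])
    hi = min(t1[-1], t2[-1])
    ts = np.union1d(t1, t2)
    ts = ts[(ts >= lo) & (ts <= hi)]
    yR = 0.5 * (np.interp(ts, t1, y1) + np.interp(ts, t2, y2))
    T_MAX = min(y1[0], y2[0])
    T_MIN = max(y1[-1], y2[-1])
    tmin = float(np.interp(T_MAX, yR[::-1], ts[::-1]))
    tmax = float(np.interp(T_MIN, yR[::-1], ts[::-1]))
    grid = np.linspace(tmin, tmax, n_grid)
    Tk = np.interp(grid, ts, yR)
    inv1 = np.interp(Tk, y1[::-1], t1[::-1])
    inv2 = np.interp(Tk, y2[::-1], t2[::-1])
    return float(np.max(np.abs(inv1 - inv2)))


def slab_oracle_error(N=100, h=0.002, kappa=0.5, w=5e-4, rho_b_c_b=3.8e6,
                      Tc=37.2, TA=10.0):
    """Max abs difference between the sparse bioheat solve on a pseudo-1-D
    slab and an independently assembled dense finite-volume system."""
    lab = np.zeros((1, 1, N + 2), dtype=np.int16)
    lab[0, 0, 1:-1] = 1
    tis = {1: TissueProperties("t", kappa, 1050.0, 3600.0, w, 0.9)}
    p = Phantom(labels=lab, spacing=np.array([h] * 3), origin=np.zeros(3),
                tissues=tis, rectal_probe=np.array([h / 2, h / 2, N // 2 * h]),
                length=N * h, declared_mass=1050.0 * N * h ** 3)
    bc = thermal.BoundaryCondition(T_A=TA, h=3.3, emissivity=0.9)
    F = thermal.solve_initial_field_bhte(
        p, T_core=Tc, bc=bc, rho_b_c_b=rho_b_c_b,
        surface_correction=False, robin_axes=(False, False, True))
    T = F.values[0, 0, 1:-1]

    area = h * h
    g = kappa * area / h
    beta = rho_b_c_b * w * h ** 3
    gb = area / (h / (2 * kappa) + 1.0 / bc.gamma)
    A = np.zeros((N, N))
    b = np.full(N, beta * Tc)
    A[np.diag_indices(N)] += beta
    for i in range(N - 1):
        A[i, i] += g
        A[i + 1, i + 1] += g
        A[i, i + 1] -= g
        A[i + 1, i] -= g
    A[0, 0] += gb
    A[-1, -1] += gb
    b[0] += gb * TA
    b[-1] += gb * TA
    return float(np.max(np.abs(T - np.linalg.solve(A, b))))


# ---------------------------------------------------------------------------
# expensive session-scoped products
# ---------------------------------------------------------------------------

SPHERE = dict(a=0.1, h=1.0 / 300.0, kappa=0.5, rho=1050.0, c=3600.0,
              T0=37.0, T_A=15.0, output_dt=0.0125)


@pytest.fixture(scope="session")
def sphere_validation():
    """Simulated vs analytic Robin-sphere centre history (refined grid)."""
    P = SPHERE
    p = sphere_phantom(P["a"], P["h"], P["kappa"], P["rho"], P["c"])
    bc = thermal.BoundaryCondition(T_A=P["T_A"], h=3.3, emissivity=0.95)
    field = thermal.TemperatureField(
        values=np.where(p.labels > 0, P["T0"], P["T_A"]).astype(float),
        time=0.0, spacing=p.spacing, origin=p.origin)
    (curve,) = thermal.simulate_cooling(p, field, bc, {"C": p.rectal_probe},
                                        t_end=45.0, output_dt=P["output_dt"])
    mask = curve.times >= 1.0
    t_s = curve.times[mask] * 3600.0
    alpha = P["kappa"] / (P["rho"] * P["c"])
    Bi = bc.gamma * P["a"] / P["kappa"]
    theta = robin_sphere_center_series(t_s, P["a"], alpha, Bi)
    exact = P["T_A"] + (P["T0"] - P["T_A"]) * theta
    err_pct = np.abs(curve.temps[mask] - exact) / (P["T0"] - P["T_A"]) * 100
    return {"err_pct": err_pct, "n_cells": int((p.labels > 0).sum())}


@pytest.fixture(scope="session")
def study_table():
    """Full default study (1 cm grid, all variants, K = 1000, seed 0)."""
    return study.run_study(study.StudyConfig(seed=0))
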