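"""Heat solver: boundary coefficient, initial fields, transient cooling."""

import numpy as np
import pytest

import tdesens as td
from tdesens import thermal
from tdesens.phantom import Phantom, PhantomSpec, TissueProperties

from .conftest import box_phantom, compartment_box_phantom


class TestEffectiveGamma:
    @pytest.mark.parametrize("T_A, expected", [(5.0, 7.93), (15.0, 8.45),
                                               (25.0, 9.00)])
    def test_reference_values(self, T_A, expected):
        assert td.effective_gamma(3.3, 0.95, T_A) == pytest.approx(
            expected, abs=0.005)

    def test_zero_case(self):
        assert td.effective_gamma(0.0, 0.0, 20.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            td.effective_gamma(-1.0, 0.95, 15.0)
        with pytest.raises(ValueError):
            td.effective_gamma(3.3, -0.1, 15.0)

    def test_boundary_condition_consistency(self):
        bc = thermal.BoundaryCondition(T_A=15.0, h=3.3, emissivity=0.95)
        assert bc.gamma == td.effective_gamma(3.3, 0.95, 15.0)


def slab_phantom(N=100, h=0.002, kappa=0.5, w=5e-4):
    lab = np.zeros((1, 1, N + 2), dtype=np.int16)
    lab[0, 0, 1:-1] = 1
    tis = {1: TissueProperties("t", kappa, 1050.0, 3600.0, w, 0.9)}
    return Phantom(labels=lab, spacing=np.array([h] * 3), origin=np.zeros(3),
                   tissues=tis, rectal_probe=np.array([h / 2, h / 2, N // 2 * h]),
                   length=N * h, declared_mass=1050.0 * N * h ** 3)


class TestBioheatInitialField:
    def test_slab_matches_dense_oracle(self):
        """Pseudo-1-D slab: sparse solve equals an independently assembled
        dense finite-volume system."""
        N, h, kappa, w = 100, 0.002, 0.5, 5e-4
        rho_b_c_b, Tc, TA = 3.8e6, 37.2, 10.0
        p = slab_phantom(N, h, kappa, w)
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
        np.testing.assert_allclose(T, np.linalg.solve(A, b), atol=1e-8)

    def test_slab_matches_cosh_profile(self):
        """Fine slab approaches the continuous cosh solution family."""
        N, h, kappa, w = 200, 0.001, 0.5, 5e-4
        rho_b_c_b, Tc, TA = 3.8e6, 37.2, 10.0
        p = slab_phantom(N, h, kappa, w)
        bc = thermal.BoundaryCondition(T_A=TA, h=3.3, emissivity=0.9)
        F = thermal.solve_initial_field_bhte(
            p, T_core=Tc, bc=bc, rho_b_c_b=rho_b_c_b,
            surface_correction=False, robin_axes=(False, False, True))
        T = F.values[0, 0, 1:-1]
        ell = np.sqrt(kappa / (rho_b_c_b * w))
        Lh = N * h / 2
        x = (np.arange(N) + 0.5) * h - Lh
        B = (Tc - TA) / (np.cosh(Lh / ell)
                         + kappa / (bc.gamma * ell) * np.sinh(Lh / ell))
        np.testing.assert_allclose(T, Tc - B * np.cosh(x / ell), atol=5e-3)

    def test_large_perfusion_pins_core_temperature(self):
        p = box_phantom(0.01, w=1.0)
        F = thermal.solve_initial_field_bhte(
            p, T_core=37.2, bc=thermal.BoundaryCondition(T_A=15.0))
        assert F.values[p.body_mask].min() > 37.0

    def test_zero_perfusion_equilibrates_to_ambient(self):
        p = box_phantom(0.01, w=0.0)
        F = thermal.solve_initial_field_bhte(
            p, T_core=37.2, bc=thermal.BoundaryCondition(T_A=15.0))
        np.testing.assert_allclose(F.values[p.body_mask], 15.0, atol=1e-9)

    def test_singular_system_rejected(self):
        p = box_phantom(0.01, w=0.0, emissivity=0.0)
        bc = thermal.BoundaryCondition(T_A=15.0, h=0.0, emissivity=0.0)
        with pytest.raises(thermal.NumericalError):
            thermal.solve_initial_field_bhte(p, T_core=37.2, bc=bc)

    def test_bounded_between_ambient_and_core(self):
        p = compartment_box_phantom(0.02)
        F = thermal.solve_initial_field_bhte(
            p, T_core=37.2, bc=thermal.BoundaryCondition(T_A=5.0))
        vals = F.values[p.body_mask]
        assert vals.min() > 5.0 and vals.max() <= 37.2 + 1e-9


class TestGradientInitialField:
    def test_layered_ramp_on_cube(self):
        # 9^3 body: layer depths 1..5 voxels; full-depth normalisation
        p = box_phantom(0.01, side=0.09, pad=1)
        F = thermal.gradient_initial_field(p, T_core=37.0, T_skin=29.0,
                                           core_depth=None)
        c = p.labels.shape[0] // 2
        assert F.values[c, c, c] == pytest.approx(37.0)          # deepest
        assert F.values[1, c, c] == pytest.approx(29.0)          # skin voxel
        assert F.values[3, c, c] == pytest.approx(33.0)          # mid-depth

    def test_core_plateau(self):
        p = box_phantom(0.01, side=0.2, pad=2)
        F = thermal.gradient_initial_field(p, T_core=37.2, T_skin=28.0,
                                           core_depth=0.05)
        c = p.labels.shape[0] // 2
        assert F.values[c, c, c] == pytest.approx(37.2)
        assert F.values[2, c, c] == pytest.approx(28.0)

    def test_inverted_temperatures_rejected(self):
        p = box_phantom(0.01)
        with pytest.raises(ValueError):
            thermal.gradient_initial_field(p, T_core=30.0, T_skin=30.0)


class TestQuantize:
    def test_level_count_bound(self):
        p = compartment_box_phantom(0.02)
        F = thermal.gradient_initial_field(p, core_depth=None)
        Q = thermal.quantize_field(F, 10, p)
        assert len(np.unique(Q.values[p.body_mask])) <= 10

    def test_constant_field_unchanged(self):
        p = box_phantom(0.01)
        F = thermal.TemperatureField(np.full(p.labels.shape, 30.0), 0.0,
                                     p.spacing, p.origin)
        Q = thermal.quantize_field(F, 10, p)
        np.testing.assert_array_equal(Q.values, F.values)

    def test_two_valued_field_preserved_as_bin_centroids(self):
        p = box_phantom(0.01)
        vals = np.full(p.labels.shape, 30.0)
        body = p.body_mask
        idx = np.argwhere(body)
        half = idx[: len(idx) // 2]
        vals[tuple(half.T)] = 37.0
        F = thermal.TemperatureField(vals, 0.0, p.spacing, p.origin)
        Q = thermal.quantize_field(F, 2, p)
        assert set(np.unique(Q.values[body])) == {30.0, 37.0}


class TestSampleField:
    def grid_field(self):
        vals = np.zeros((4, 4, 4))
        return thermal.TemperatureField(vals, 0.0, np.array([0.01] * 3),
                                        np.zeros(3))

    def test_voxel_center_exact(self):
        f = self.grid_field()
        f.values[1, 2, 3] = 5.0
        assert thermal.sample_field(f, [0.015, 0.025, 0.035]) == 5.0

    def test_linear_field_reproduced(self):
        f = self.grid_field()
        xs = (np.arange(4) + 0.5) * 0.01
        f.values[:] = 2.0 + 300.0 * xs[:, None, None]
        pt = [0.0173, 0.02, 0.02]
        assert thermal.sample_field(f, pt) == pytest.approx(2.0 + 300.0 * 0.0173)

    def test_midpoint_mean(self):
        f = self.grid_field()
        f.values[1, 1, 1] = 10.0
        f.values[2, 1, 1] = 20.0
        assert thermal.sample_field(f, [0.02, 0.015, 0.015]) == pytest.approx(15.0)

    def test_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            thermal.sample_field(self.grid_field(), [1.0, 0.0, 0.0])


@pytest.fixture(scope="module")
def cooling_run():
    p = compartment_box_phantom(0.02)
    bc = thermal.BoundaryCondition(T_A=15.0)
    T0 = thermal.gradient_initial_field(p)
    probes = td.make_octahedron_probes(p.rectal_probe, 0.02)
    curves, diag = thermal.simulate_cooling(
        p, T0, bc, probes, t_end=45.0, output_dt=0.05,
        return_diagnostics=True)
    return p, bc, T0, curves, diag


class TestTransientCooling:
    def test_equilibrium_fixed_point(self):
        p = box_phantom(0.01)
        bc = thermal.BoundaryCondition(T_A=15.0)
        F = thermal.TemperatureField(np.full(p.labels.shape, 15.0), 0.0,
                                     p.spacing, p.origin)
        curves = thermal.simulate_cooling(p, F, bc, {"C": p.rectal_probe},
                                          t_end=2.0, output_dt=0.1)
        np.testing.assert_allclose(curves[0].temps, 15.0, atol=1e-9)

    def test_probe_outside_body_rejected(self):
        p = box_phantom(0.01)
        bc = thermal.BoundaryCondition(T_A=15.0)
        F = thermal.TemperatureField(np.full(p.labels.shape, 37.0), 0.0,
                                     p.spacing, p.origin)
        with pytest.raises(ValueError):
            thermal.simulate_cooling(p, F, bc, {"bad": [0.0, 0.0, 0.0]},
                                     t_end=1.0)

    def test_maximum_principle(self, cooling_run):
        p, bc, T0, curves, _ = cooling_run
        hi = T0.values[p.body_mask].max()
        for c in curves:
            assert c.temps.max() <= hi + 1e-6
            assert c.temps.min() >= bc.T_A - 1e-6

    def test_monotone_cooling_after_plateau(self, cooling_run):
        _, _, _, curves, _ = cooling_run
        for c in curves:
            tail = c.temps[c.times >= 1.0]
            assert np.all(np.diff(tail) <= 1e-3), c.probe_id

    def test_energy_balance_per_step(self, cooling_run):
        _, _, _, _, diag = cooling_run
        dE = np.array(diag.energy_change_J)
        Qb = np.array(diag.boundary_heat_J)
        rel = np.abs(dE - Qb) / np.maximum(np.abs(Qb), 1e-9)
        assert rel.max() < 1e-6

    def test_adaptive_step_change_bound(self, cooling_run):
        _, _, _, _, diag = cooling_run
        assert max(diag.max_change_K) <= 1.0 + 1e-9
        assert diag.dt_s[0] == pytest.approx(0.1)

    def test_ambient_ordering(self):
        """Comparison principle: lower ambient gives pointwise lower curves."""
        p = box_phantom(0.01)
        T0 = thermal.TemperatureField(np.full(p.labels.shape, 37.0), 0.0,
                                      p.spacing, p.origin)
        temps = {}
        for TA in (5.0, 15.0, 25.0):
            bc = thermal.BoundaryCondition(T_A=TA)
            (c,) = thermal.simulate_cooling(p, T0, bc, {"C": p.rectal_probe},
                                            t_end=20.0, output_dt=0.1)
            temps[TA] = c.temps
        assert np.all(temps[5.0] <= temps[15.0] + 1e-9)
        assert np.all(temps[15.0] <= temps[25.0] + 1e-9)

    def test_substrate_accelerates_dorsal_cooling(self):
        """Wet soil under the back drains heat: the dorsal probe cools
        faster on the substrate than floating free in air."""
        base = td.build_phantom(PhantomSpec(spacing=0.02))
        bc = thermal.BoundaryCondition(T_A=5.0)
        dorsal = base.rectal_probe - np.array([0.0, 0.02, 0.0])
        temps = {}
        for name, p in (("free", base), ("soil", td.add_substrate(base))):
            T0 = thermal.gradient_initial_field(p)
            (c,) = thermal.simulate_cooling(p, T0, bc, {"d": dorsal},
                                            t_end=10.0, output_dt=0.25)
            temps[name] = c.temps
        assert temps["soil"][-1] < temps["free"][-1] - 0.1


class TestSolverAccuracy:
    def test_sphere_matches_analytic_series(self, sphere_validation):
        """Robin-sphere centre history vs the eigenfunction series:
        error below 0.5% of the initial excess for t in [1, 45] h."""
        assert sphere_validation["err_pct"].max() < 0.5

    def test_small_biot_matches_lumped_exponential(self):
        """High-conductivity cube: centre curve within 2% of the
        lumped-capacitance closed form (exact staircase area, so the
        normal-weighting correction is disabled)."""
        side, h, kappa, rho, c = 0.1, 0.01, 10.0, 1050.0, 3600.0
        p = box_phantom(h, kappa=kappa, rho=rho, c=c, emissivity=0.0,
                        side=side)
        bc = thermal.BoundaryCondition(T_A=15.0, h=1.0, emissivity=0.0)
        T0v = 37.0
        F = thermal.TemperatureField(
            np.where(p.labels > 0, T0v, 15.0).astype(float), 0.0,
            p.spacing, p.origin)
        (curve,) = thermal.simulate_cooling(
            p, F, bc, {"C": p.rectal_probe}, t_end=45.0, output_dt=0.05,
            surface_correction=False)
        A, V = 6 * side ** 2, side ** 3
        k = bc.gamma * A / (rho * c * V)
        exact = 15.0 + (T0v - 15.0) * np.exp(-k * curve.times * 3600.0)
        err = np.abs(curve.temps - exact) / (T0v - 15.0)
        assert err.max() < 0.02

    def test_grid_refinement_stability_of_d_max(self):
        """Halving the default 1 cm voxel changes downstream D_MAX by <5%
        (compartments voxelise exactly at both spacings, so this isolates
        discretisation error)."""
        results = {}
        for h in (0.01, 0.005):
            p = compartment_box_phantom(h)
            bc = thermal.BoundaryCondition(T_A=15.0)
            T0 = thermal.gradient_initial_field(p)
            probes = td.make_octahedron_probes(p.rectal_probe, 0.02)
            curves = {c.probe_id: c for c in thermal.simulate_cooling(
                p, T0, bc, probes, t_end=45.0, output_dt=0.05)}
            results[h] = {
                pid: td.d_max(curves["C"], curves[pid], K=1000).d_max_global
                for pid in ("SP_1", "SP_3", "SP_4", "SP_5", "SP_6")}
        for pid, coarse in results[0.01].items():
            fine = results[0.005][pid]
            assert abs(coarse - fine) / max(coarse, fine) < 0.05, pid
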