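"""Haemodynamic metric operators against analytic and brute-force oracles."""

import numpy as np
import pytest

from aneuwall import CohortConfig, generate_wss_series
from aneuwall.fields import WSSFieldSeries, waveform
from aneuwall.mesh import generate_aneurysm_mesh
from aneuwall.metrics import (MetricField, osi, pressure_summary, rrt,
                              systolic_index, systolic_wss, tawss,
                              time_averaged_vector, vector_field_divergence,
                              wssd)


def constant_series(mesh, vec, n_times=33, T=1.0):
    times = np.linspace(0, T, n_times)
    wss = np.tile(np.asarray(vec, float), (n_times, mesh.n_nodes, 1))
    return WSSFieldSeries(times, T, wss, np.zeros((n_times, mesh.n_nodes)))


def sinusoid_series(mesh, A=3.0, n_times=65, T=1.0):
    times = np.linspace(0, T, n_times)
    wss = np.zeros((n_times, mesh.n_nodes, 3))
    wss[:, :, 0] = (A * np.sin(2 * np.pi * times / T))[:, None]
    return WSSFieldSeries(times, T, wss, np.zeros((n_times, mesh.n_nodes)))


class TestTawss:
    def test_constant_field(self, coarse_mesh):
        f = tawss(constant_series(coarse_mesh, [3.0, 0.0, 4.0]))
        np.testing.assert_allclose(f.values, 5.0, rtol=1e-12)
        assert f.units == "Pa"

    def test_zero_field(self, coarse_mesh):
        f = tawss(constant_series(coarse_mesh, [0.0, 0.0, 0.0]))
        np.testing.assert_allclose(f.values, 0.0)

    def test_rectified_sine_against_fine_quadrature(self, coarse_mesh):
        A, n = 3.0, 513
        f = tawss(sinusoid_series(coarse_mesh, A=A, n_times=n))
        # independent oracle: 1e5-point quadrature of |A sin|
        tq = np.linspace(0, 1, 100_001)
        oracle = np.trapezoid(np.abs(A * np.sin(2 * np.pi * tq)), tq)
        assert oracle == pytest.approx(2 * A / np.pi, rel=1e-8)
        np.testing.assert_allclose(f.values, oracle, rtol=1e-3)

    def test_bounds(self, coarse_mesh):
        rng = np.random.default_rng(0)
        times = np.linspace(0, 1, 33)
        wss = rng.normal(size=(33, coarse_mesh.n_nodes, 3))
        s = WSSFieldSeries(times, 1.0, wss, np.zeros((33, coarse_mesh.n_nodes)))
        ta = tawss(s).values
        assert (ta <= np.linalg.norm(wss, axis=2).max(axis=0) + 1e-12).all()
        assert (ta >= np.linalg.norm(time_averaged_vector(s), axis=1) - 1e-12).all()


class TestOsi:
    def test_unidirectional_zero(self, coarse_mesh):
        times = np.linspace(0, 1, 65)
        mag = 2.0 + np.sin(2 * np.pi * times)  # positive, no reversal
        wss = np.zeros((65, coarse_mesh.n_nodes, 3))
        wss[:, :, 1] = mag[:, None]
        s = WSSFieldSeries(times, 1.0, wss, np.zeros((65, coarse_mesh.n_nodes)))
        np.testing.assert_allclose(osi(s).values, 0.0, atol=1e-12)

    def test_zero_mean_sinusoid_half(self, coarse_mesh):
        s = sinusoid_series(coarse_mesh)
        np.testing.assert_allclose(osi(s).values, 0.5, atol=1e-12)

    def test_brute_force_equivalence(self, coarse_mesh):
        rng = np.random.default_rng(42)
        times = np.sort(rng.uniform(0, 1, 30))
        times[0], times[-1] = 0.0, 1.0
        wss = rng.normal(size=(30, coarse_mesh.n_nodes, 3))
        s = WSSFieldSeries(times, 1.0, wss, np.zeros((30, coarse_mesh.n_nodes)))
        got = osi(s).values
        # direct per-node evaluation of the definition
        for node in rng.choice(coarse_mesh.n_nodes, 25, replace=False):
            vec = np.array([np.trapezoid(wss[:, node, c], times) for c in range(3)])
            mag = np.trapezoid(np.linalg.norm(wss[:, node], axis=1), times)
            expect = 0.5 * (1 - np.linalg.norm(vec) / mag)
            assert got[node] == pytest.approx(expect, abs=1e-12)

    def test_bounded_on_random_fields(self, coarse_mesh):
        rng = np.random.default_rng(7)
        for _ in range(20):
            wss = rng.normal(size=(17, coarse_mesh.n_nodes, 3)) * rng.uniform(0.1, 10)
            s = WSSFieldSeries(np.linspace(0, 1, 17), 1.0, wss,
                              np.zeros((17, coarse_mesh.n_nodes)))
            v = osi(s).values
            assert (v >= 0).all() and (v <= 0.5).all()


class TestRrt:
    def test_direct_substitution(self):
        ta = MetricField("tawss", np.array([4.0, 10.0]), "Pa")
        os_ = MetricField("osi", np.array([0.0, 0.25]), "-")
        vals = rrt(ta, os_).values
        np.testing.assert_allclose(vals, [0.25, 0.2], rtol=1e-12)

    def test_undefined_at_full_oscillation(self):
        ta = MetricField("tawss", np.array([4.0, 4.0]), "Pa")
        os_ = MetricField("osi", np.array([0.5, 0.1]), "-")
        vals = rrt(ta, os_).values
        assert np.isnan(vals[0])
        assert np.isfinite(vals[1])

    def test_mismatched_nodes_rejected(self):
        ta = MetricField("tawss", np.ones(5), "Pa")
        os_ = MetricField("osi", np.zeros(4), "-")
        with pytest.raises(ValueError, match="mismatch"):
            rrt(ta, os_)

    def test_round_trip_identity(self, coarse_mesh):
        rng = np.random.default_rng(3)
        wss = rng.normal(size=(21, coarse_mesh.n_nodes, 3))
        s = WSSFieldSeries(np.linspace(0, 1, 21), 1.0, wss,
                          np.zeros((21, coarse_mesh.n_nodes)))
        ta, os_ = tawss(s), osi(s)
        r = rrt(ta, os_).values
        ok = np.isfinite(r)
        prod = r[ok] * ta.values[ok] * (1 - 2 * os_.values[ok])
        np.testing.assert_allclose(prod, 1.0, rtol=1e-10)


class TestWssd:
    def test_constant_field_zero(self, coarse_mesh):
        f = np.tile([1.0, -2.0, 0.5], (coarse_mesh.n_nodes, 1))
        d = vector_field_divergence(f, coarse_mesh)
        np.testing.assert_allclose(d[np.isfinite(d)], 0.0, atol=1e-10)

    def test_linear_field_exact(self, medium_mesh):
        a, b, c = 1.3, -0.7, 2.1
        p = medium_mesh.points
        f = np.stack([a * p[:, 0], b * p[:, 1], c * p[:, 2]], axis=1)
        d = vector_field_divergence(f, medium_mesh)
        ok = np.isfinite(d)
        assert ok.all()
        np.testing.assert_allclose(d[ok], a + b + c, rtol=1e-6)

    def test_brute_force_normal_equations(self, coarse_mesh):
        rng = np.random.default_rng(9)
        f = rng.normal(size=(coarse_mesh.n_nodes, 3))
        d = vector_field_divergence(f, coarse_mesh)
        pts = coarse_mesh.points
        for i in rng.choice(coarse_mesh.n_nodes, 30, replace=False):
            neigh = coarse_mesh.adjacency[i]
            dx = pts[neigh] - pts[i]
            w = 1.0 / np.linalg.norm(dx, axis=1)
            # explicit weighted normal equations, solved per component
            A = np.einsum("k,ka,kb->ab", w, dx, dx)
            trace = 0.0
            for comp in range(3):
                rhs = np.einsum("k,ka,k->a", w, dx, f[neigh, comp] - f[i, comp])
                grad = np.linalg.solve(A, rhs)
                trace += grad[comp]
            assert d[i] == pytest.approx(trace, abs=1e-10 * max(1, abs(trace)))

    def test_rotation_invariance(self, coarse_mesh):
        from scipy.spatial.transform import Rotation

        from aneuwall.mesh import SurfaceMesh

        p = coarse_mesh.points
        f = np.stack([np.sin(p[:, 0]), 0.3 * p[:, 1] ** 2,
                      0.2 * p[:, 0] * p[:, 2]], axis=1)
        d0 = vector_field_divergence(f, coarse_mesh)
        R = Rotation.from_euler("xyz", [0.4, -0.8, 1.1]).as_matrix()
        rotated = SurfaceMesh(p @ R.T, coarse_mesh.triangles,
                              coarse_mesh.node_region)
        d1 = vector_field_divergence(f @ R.T, rotated)
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_refinement_stays_bounded(self):
        """Quadratic-field error is dominated by a curvature bias that does
        not grow under refinement (the 1-ring ambient fit is exact only for
        linear fields; see the methods note)."""
        errs = []
        for res in ["coarse", "medium", "fine"]:
            m = generate_aneurysm_mesh(2.5, 1.2, res, seed=1, jitter=0.0)
            p = m.points
            f = np.stack([np.sin(p[:, 0]), 0.3 * p[:, 1] ** 2,
                          0.2 * p[:, 0] * p[:, 2]], axis=1)
            d = vector_field_divergence(f, m)
            true = np.cos(p[:, 0]) + 0.6 * p[:, 1] + 0.2 * p[:, 0]
            ok = np.isfinite(d)
            errs.append(np.sqrt(np.mean((d[ok] - true[ok]) ** 2)))
        assert errs[2] <= errs[0] * 1.25

    def test_mode_selection(self, coarse_mesh):
        cfg = CohortConfig(n_patients=1, mesh_resolution="coarse", seed=4)
        series, _ = generate_wss_series(coarse_mesh, cfg, 0)
        d_avg = wssd(series, coarse_mesh, mode="time_averaged_field")
        d_sys = wssd(series, coarse_mesh, mode="systolic_instant")
        assert d_avg.units == "Pa/mm"
        assert not np.allclose(np.nan_to_num(d_avg.values),
                               np.nan_to_num(d_sys.values))
        with pytest.raises(ValueError, match="mode"):
            wssd(series, coarse_mesh, mode="bogus")


class TestSystolicAndPressure:
    def test_constant_magnitude(self, coarse_mesh):
        f = systolic_wss(constant_series(coarse_mesh, [0.0, 5.0, 0.0]))
        np.testing.assert_allclose(f.values, 5.0)

    def test_systolic_instant_matches_waveform_peak(self, coarse_mesh, quiet_config):
        series, truth = generate_wss_series(coarse_mesh, quiet_config, 0)
        assert systolic_index(series) == truth.systolic_index
        w = waveform(quiet_config, series.times)
        assert truth.systolic_index == int(np.argmax(w))

    def test_systolic_index_shared_across_patients(self, coarse_mesh):
        cfg = CohortConfig(n_patients=2, mesh_resolution="coarse", seed=6,
                           oscillatory_sd=0.0)
        s0, _ = generate_wss_series(coarse_mesh, cfg, 0)
        s1, _ = generate_wss_series(coarse_mesh, cfg, 1)
        assert systolic_index(s0) == systolic_index(s1)

    def test_pressure_time_average_recovers_baseline(self, coarse_mesh):
        cfg = CohortConfig(n_patients=1, mesh_resolution="coarse", seed=0,
                           patient_sd=0.0, region_sd=0.0, noise_sd=0.0,
                           pressure_spatial_fraction=0.0,
                           thin_effect_multipliers={"wss": 1.0, "wssd": 1.0,
                                                    "pressure": 1.0})
        series, _ = generate_wss_series(coarse_mesh, cfg, 0)
        avg = pressure_summary(series, mode="time_averaged")
        np.testing.assert_allclose(avg.values, 10665.76, rtol=1e-6)

    def test_pressure_systolic_closed_form(self, coarse_mesh):
        cfg = CohortConfig(n_patients=1, mesh_resolution="coarse", seed=0,
                           patient_sd=0.0, region_sd=0.0, noise_sd=0.0,
                           oscillatory_sd=0.0,
                           waveform_amplitudes_pa=(4.0, 0.0),
                           pressure_spatial_fraction=0.0,
                           thin_effect_multipliers={"wss": 1.0, "wssd": 1.0,
                                                    "pressure": 1.0})
        series, _ = generate_wss_series(coarse_mesh, cfg, 0)
        sys_p = pressure_summary(series, mode="systolic")
        w = waveform(cfg, series.times)
        expected = 10665.76 * (1 + cfg.pressure_pulse_fraction
                               * (w.max() - 8.0) / 8.0)
        np.testing.assert_allclose(sys_p.values, expected, rtol=1e-9)
        with pytest.raises(ValueError, match="mode"):
            pressure_summary(series, mode="bogus")
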