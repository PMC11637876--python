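import numpy as np
import pytest

from osteoadapt import (
    DensityField,
    LoadCase,
    RemodelParams,
    build_grid,
    build_kernel,
    convergence_metric,
    density_rate,
    run_simulation,
    update_density,
)

from conftest import make_line_mesh


class TestKernel:
    def test_self_weight_unity(self, mesh5):
        k = build_kernel(mesh5, D=0.2)
        np.testing.assert_allclose(k.weights.diagonal(), 1.0)

    def test_decay_at_characteristic_distance(self):
        # two elements exactly D apart: relative influence drops to 36.8%
        D = 1.0
        mesh = make_line_mesh(2, h=D)
        k = build_kernel(mesh, D=D, cutoff_multiple=5.0)
        w = k.weights.toarray()
        assert w[0, 1] / w[0, 0] == pytest.approx(0.36787944117144233, rel=1e-12)

    def test_decay_at_two_characteristic_distances(self):
        mesh = make_line_mesh(3, h=1.0)
        k = build_kernel(mesh, D=0.5, cutoff_multiple=5.0)
        assert k.weights[0, 1] == pytest.approx(0.13533528323661270, rel=1e-12)

    def test_symmetric_and_bounded(self, mesh5):
        k = build_kernel(mesh5, D=0.7)
        W = k.weights
        assert (W != W.T).nnz == 0
        assert W.data.min() > 0 and W.data.max() <= 1.0

    def test_weights_decrease_with_distance(self, mesh5):
        k = build_kernel(mesh5, D=1.0, cutoff_multiple=5.0)
        c = mesh5.element_centroids
        coo = k.weights.tocoo()
        d = np.linalg.norm(c[coo.row] - c[coo.col], axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(coo.data[order]) <= 1e-12)

    def test_exhaustive_matches_truncated_inside_cutoff(self, mesh5):
        kt = build_kernel(mesh5, D=0.5, cutoff_multiple=5.0)
        ke = build_kernel(mesh5, D=0.5, cutoff_multiple=None)
        c = mesh5.element_centroids
        coo = kt.weights.tocoo()
        np.testing.assert_allclose(
            coo.data, np.asarray(ke.weights[coo.row, coo.col]).ravel(), rtol=1e-14
        )

    def test_invalid_D(self, mesh5):
        with pytest.raises(ValueError):
            build_kernel(mesh5, D=0.0)


class TestRateLaw:
    def test_homeostasis_zero_rate(self, mesh5):
        kernel = build_kernel(mesh5, D=0.2)
        rho = np.full(mesh5.n_elements, 0.87)
        sed = 0.025 * rho  # stimulus U/rho == k everywhere
        rate = density_rate(kernel, sed, rho, k=0.025, tau=1.0)
        np.testing.assert_allclose(rate, 0.0, atol=1e-15)

    def test_single_element_value(self):
        mesh = build_grid(1.0, 1.0)
        kernel = build_kernel(mesh, D=0.2)
        rate = density_rate(
            kernel, np.array([0.0330]), np.array([0.87]), k=0.025, tau=1.0
        )
        assert rate[0] == pytest.approx(0.012931034482758621, rel=1e-12)

    def test_two_elements_at_distance_D(self):
        # both elements carry the same stimulus excess s:
        # rate = tau * s * (1 + e^-1) at each
        D = 1.0
        mesh = make_line_mesh(2, h=D)
        kernel = build_kernel(mesh, D=D)
        rho = np.array([1.0, 1.0])
        s = 0.01
        sed = (s + 0.025) * rho
        rate = density_rate(kernel, sed, rho, k=0.025, tau=2.0)
        np.testing.assert_allclose(rate, 2.0 * s * (1 + np.exp(-1)), rtol=1e-12)


class TestUpdate:
    def test_zero_rate_unchanged(self, baseline_params):
        rho = DensityField(np.full(5, 0.87), iteration=3)
        new = update_density(rho, np.zeros(5), baseline_params)
        np.testing.assert_array_equal(new.values, rho.values)
        assert new.iteration == 4

    def test_upper_clamp(self, baseline_params):
        rho = DensityField(np.array([0.87]))
        new = update_density(rho, np.array([1e3]), baseline_params)
        assert new.values[0] == 1.74

    def test_lower_clamp(self, baseline_params):
        rho = DensityField(np.array([0.87]))
        new = update_density(rho, np.array([-1e3]), baseline_params)
        assert new.values[0] == 0.0174

    def test_plain_euler_step(self, baseline_params):
        rho = DensityField(np.array([0.87]))
        new = update_density(rho, np.array([0.02]), baseline_params)
        assert new.values[0] == pytest.approx(0.89, rel=1e-14)


class TestConvergenceMetric:
    def test_identical_fields(self):
        a = np.full(10, 0.87)
        assert convergence_metric(a, a.copy()) == 0.0

    def test_uniform_change(self):
        a = np.full(10, 0.87)
        assert convergence_metric(a + 0.02, a) == pytest.approx(0.02)

    def test_half_changed(self):
        a = np.full(10, 0.87)
        b = a.copy()
        b[:5] += 0.02
        assert convergence_metric(b, a) == pytest.approx(0.01)

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            convergence_metric(np.zeros(3), np.zeros(4))


class TestRunSimulation:
    def test_homeostatic_pressure_is_fixed_point(self, mesh4, laws):
        """Uniform pressure chosen so U/rho0 == k: density never moves."""
        E0 = laws["E1"](0.87)
        p = np.sqrt(2 * E0 * 0.025 * 0.87)
        params = RemodelParams(max_iter=10)
        trace = run_simulation(
            mesh4, laws["E1"], params, LoadCase(p, "uniform"), compute_metrics=False
        )
        assert trace.status == "CONVERGED"
        np.testing.assert_allclose(trace.final_density, 0.87, atol=1e-10)

    def test_zero_load_monotone_resorption(self, mesh4, laws):
        params = RemodelParams(max_iter=8)
        trace = run_simulation(
            mesh4, laws["E1"], params, LoadCase(0.0), compute_metrics=False
        )
        means = [r.mean_density for r in trace.records]
        assert all(b < a for a, b in zip(means, means[1:]))
        assert np.all(trace.final_density >= params.rho_min)

    def test_deterministic_runs(self, mesh4, laws, graded_load):
        params = RemodelParams(max_iter=3)
        t1 = run_simulation(mesh4, laws["E1"], params, graded_load)
        t2 = run_simulation(mesh4, laws["E1"], params, graded_load)
        np.testing.assert_array_equal(t1.final_density, t2.final_density)
        assert [r.mean_abs_delta for r in t1.records] == [
            r.mean_abs_delta for r in t2.records
        ]

    def test_densities_always_within_clamps(self, mesh4, laws, graded_load):
        params = RemodelParams(max_iter=12, tau=2.0)
        trace = run_simulation(
            mesh4, laws["E1"], params, graded_load, snapshot_every=1,
            compute_metrics=False,
        )
        for rho in trace.snapshots.values():
            assert rho.min() >= params.rho_min - 1e-15
            assert rho.max() <= params.rho_max + 1e-15

    def test_k_monotonicity_single_step(self, mesh4, laws, graded_load):
        """One update from the homogeneous state: larger k -> smaller density."""
        lo = run_simulation(
            mesh4, laws["E1"], RemodelParams(max_iter=1, k=0.025), graded_load,
            compute_metrics=False,
        ).final_density
        hi = run_simulation(
            mesh4, laws["E1"], RemodelParams(max_iter=1, k=0.045), graded_load,
            compute_metrics=False,
        ).final_density
        assert np.all(hi <= lo + 1e-15)
        unclamped = (lo > 0.0174 + 1e-12) & (lo < 1.74 - 1e-12)
        assert np.all(hi[unclamped] < lo[unclamped])

    def test_unsolvable_terminates_gracefully(self, mesh4, laws, graded_load, monkeypatch):
        def boom(*a, **k):
            raise RuntimeError("singular factor")

        monkeypatch.setattr("osteoadapt.fem.splu", boom)
        trace = run_simulation(
            mesh4, laws["E1"], RemodelParams(max_iter=5), graded_load,
            compute_metrics=False,
        )
        assert trace.status == "UNSOLVABLE"
        assert "iteration 1" in trace.message
        assert trace.n_iterations == 0
        np.testing.assert_allclose(trace.final_density, 0.87)


def test_param_validation():
    with pytest.raises(ValueError):
        RemodelParams(D=-0.1)
    with pytest.raises(ValueError):
        RemodelParams(rho0=2.0)
    with pytest.raises(ValueError):
        RemodelParams(cutoff_multiple=1.0)
    with pytest.raises(ValueError):
        RemodelParams(tau=0.0)
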