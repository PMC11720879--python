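"""Acoustic simulator physics: geometry, linearity, energy, reciprocity, noise."""

import numpy as np
import pytest
from scipy import stats

from sparsepat.acoustics import (
    Grid2D,
    KSpaceSolver,
    SensorData,
    add_gaussian_noise,
    build_sensor_array,
    simulate_forward,
)


def point_source(row=64, col=64):
    p0 = np.zeros((128, 128))
    p0[row, col] = 1.0
    return p0


class TestGridAndSensors:
    def test_default_time_stepping(self, default_grid, medium):
        c = medium.sound_speed
        assert default_grid.dt == pytest.approx(0.3 * default_grid.dx / c)
        # window covers at least 1.2 ring diameters of travel
        assert default_grid.nt * default_grid.dt * c >= 1.2 * 8e-3 - 1e-12
        assert default_grid.n_comp == (168, 168)

    def test_cfl_violation_rejected(self, medium):
        bad = Grid2D(dt=1e-6)
        with pytest.raises(ValueError, match="CFL"):
            KSpaceSolver(bad, medium)

    @pytest.mark.parametrize("n", [4, 600])
    def test_sensor_count_bounds(self, n):
        with pytest.raises(ValueError, match="n_sensors"):
            build_sensor_array(n)

    def test_eight_sensors_uniform_spacing(self, default_grid):
        arr = build_sensor_array(8, default_grid)
        spacing = np.diff(arr.angles)
        np.testing.assert_allclose(spacing, np.pi / 4)

    def test_dense_ring_radial_accuracy(self, default_grid):
        """All 512 snapped sensor nodes sit within half a pixel of the
        nominal 4 mm radius."""
        arr = build_sensor_array(512, default_grid)
        cr = default_grid.pml_width + default_grid.nx // 2
        dist = np.hypot(arr.rows - cr, arr.cols - cr)
        target = 4e-3 / default_grid.dx
        assert np.abs(dist - target).max() <= 0.5

    def test_sensors_inside_physical_region(self, default_grid):
        arr = build_sensor_array(512, default_grid)
        w = default_grid.pml_width
        assert arr.rows.min() >= w and arr.rows.max() < w + default_grid.nx
        assert arr.cols.min() >= w and arr.cols.max() < w + default_grid.ny


class TestForwardModel:
    def test_zero_source_records_zero(self, default_grid, medium):
        sensors = build_sensor_array(8, default_grid)
        data = simulate_forward(np.zeros((128, 128)), default_grid, medium, sensors)
        assert not data.series.any()

    def test_linearity_of_the_discrete_scheme(self, default_grid, medium, disc_phantom):
        sensors = build_sensor_array(8, default_grid)
        solver = KSpaceSolver(default_grid, medium)
        base, _ = solver.run_forward(disc_phantom, sensors)
        scaled, _ = solver.run_forward(3.7 * disc_phantom, sensors)
        np.testing.assert_allclose(scaled, 3.7 * base, rtol=1e-6, atol=1e-9 * np.abs(base).max())

    def test_superposition(self, default_grid, medium):
        sensors = build_sensor_array(8, default_grid)
        solver = KSpaceSolver(default_grid, medium)
        a = point_source(60, 60)
        b = point_source(70, 75)
        sa, _ = solver.run_forward(a, sensors)
        sb, _ = solver.run_forward(b, sensors)
        sab, _ = solver.run_forward(a + b, sensors)
        np.testing.assert_allclose(sab, sa + sb, atol=1e-12 + 1e-6 * np.abs(sab).max())

    def test_point_source_arrival_time(self, default_grid, medium):
        """The wavefront peak from a central single-pixel source reaches the
        4 mm ring at t = 4 mm / 1500 m/s = 2.67 us within two time steps."""
        sensors = build_sensor_array(8, default_grid)
        data = simulate_forward(
            point_source(), default_grid, medium, sensors, smooth_p0=False
        )
        expected = 4e-3 / medium.sound_speed / default_grid.dt  # 170.7 steps
        peaks = np.argmax(np.abs(data.series), axis=1)
        assert np.all(np.abs(peaks - expected) <= 2)

    def test_threshold_arrival_is_causal_up_to_the_smoothing_width(
        self, default_grid, medium
    ):
        """The 5%-of-peak crossing leads the geometric front by no more than
        the Gibbs-suppression kernel width, and never trails it."""
        sensors = build_sensor_array(8, default_grid)
        data = simulate_forward(point_source(), default_grid, medium, sensors)
        expected = 4e-3 / medium.sound_speed / default_grid.dt
        kernel_halfwidth_steps = 3.0 / (default_grid.cfl)  # ~3 px foot
        for trace in data.series:
            first = np.argmax(np.abs(trace) > 0.05 * np.abs(trace).max())
            assert expected - kernel_halfwidth_steps <= first <= expected + 2

    def test_energy_conserved_without_pml(self, default_grid, medium, disc_phantom):
        solver = KSpaceSolver(default_grid, medium, use_pml=False)
        sensors = build_sensor_array(8, default_grid)
        _, energy = solver.run_forward(disc_phantom, sensors, record_energy=True)
        e = energy[0, 1:]  # the step-0 entry predates the leapfrog invariant
        assert (e.max() - e.min()) / e.mean() < 0.005

    def test_energy_absorbed_monotonically_with_pml(self, default_grid, medium, disc_phantom):
        solver = KSpaceSolver(default_grid, medium, use_pml=True)
        sensors = build_sensor_array(8, default_grid)
        _, energy = solver.run_forward(disc_phantom, sensors, record_energy=True)
        e = energy[0, 1:]
        assert np.all(np.diff(e) <= 1e-12 * e[0])
        assert e[-1] < 0.01 * e[0]  # nearly everything leaves the domain

    def test_reciprocity_point_source_and_sensor_swap(self, default_grid, medium):
        """Swapping a point source and a point sensor reproduces the trace."""
        from sparsepat.acoustics import SensorArray

        a, b = (52, 64), (84, 70)
        solver = KSpaceSolver(default_grid, medium, smooth_p0=False)
        w = default_grid.pml_width

        def run(src, det):
            p0 = np.zeros((128, 128))
            p0[src] = 1.0
            det_arr = SensorArray(
                n_sensors=8,  # minimum accepted count; only channel 0 is read
                ring_radius=4e-3,
                angles=np.zeros(8),
                rows=np.full(8, det[0] + w),
                cols=np.full(8, det[1] + w),
            )
            series, _ = solver.run_forward(p0, det_arr)
            return series[0, 0]

        t_ab = run(a, b)
        t_ba = run(b, a)
        rel = np.linalg.norm(t_ab - t_ba) / np.linalg.norm(t_ab)
        assert rel < 0.01


class TestSensorNoise:
    def make_data(self, default_grid, medium, n=8):
        sensors = build_sensor_array(n, default_grid)
        r, c = np.mgrid[0:128, 0:128]
        p0 = np.exp(-((r - 64) ** 2 + (c - 64) ** 2) / 50.0)
        return simulate_forward(p0, default_grid, medium, sensors)

    def test_fixed_target_snr_is_realized(self, default_grid, medium):
        data = self.make_data(default_grid, medium)
        rng = np.random.default_rng(0)
        noisy = add_gaussian_noise(data, rng, (50.0, 50.0))
        noise = noisy.series - data.series
        measured = 10 * np.log10(np.mean(data.series**2) / np.mean(noise**2))
        assert measured == pytest.approx(50.0, abs=0.5)
        assert noisy.snr_db == pytest.approx(measured, abs=1e-9)

    def test_realized_snr_uniform_over_40_60_db(self, default_grid, medium):
        data = self.make_data(default_grid, medium)
        rng = np.random.default_rng(1)
        draws = [
            add_gaussian_noise(data, rng, (40.0, 60.0)).snr_db for _ in range(1000)
        ]
        assert min(draws) > 39.0 and max(draws) < 61.0
        p = stats.kstest(draws, stats.uniform(loc=40, scale=20).cdf).pvalue
        assert p > 0.01

    def test_infinite_snr_limit_keeps_data(self, default_grid, medium):
        data = self.make_data(default_grid, medium)
        noisy = add_gaussian_noise(data, np.random.default_rng(0), (np.inf, np.inf))
        np.testing.assert_array_equal(noisy.series, data.series)

    def test_zero_signal_rejected(self):
        data = SensorData(np.zeros((4, 100)), 1e-8)
        with pytest.raises(ValueError, match="SNR"):
            add_gaussian_noise(data, np.random.default_rng(0))
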