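"""Forward solver: complex permittivity, field solutions, capacitance frames."""

import numpy as np
import pytest

from cceit.geometry import Grid
from cceit.solver import (EPS0, MeasurementFrame, PermittivityField, SensorModel,
                          add_measurement_noise, complex_permittivity,
                          gauss_capacitance, homogeneous_head_field, measure_frame,
                          measurement_pairs, solve_dirichlet, solve_field)


class TestComplexPermittivity:
    def test_zero_conductivity_is_purely_real(self):
        assert complex_permittivity(46.46, 0.0, 64e6) == 46.46 + 0j

    def test_white_matter_against_direct_formula(self):
        # eps_r 67.8, sigma 292 mS/m at 64 MHz
        val = complex_permittivity(67.8, 292.0, 64e6)
        expected_im = -0.292 / (2.0 * np.pi * 64e6 * EPS0)
        assert val.real == pytest.approx(67.8)
        assert val.imag == pytest.approx(expected_im, rel=1e-12)

    def test_imaginary_part_linear_in_sigma(self):
        a = complex_permittivity(10.0, 100.0, 64e6)
        b = complex_permittivity(10.0, 200.0, 64e6)
        assert b.imag == pytest.approx(2.0 * a.imag, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            complex_permittivity(10.0, -1.0, 64e6)
        with pytest.raises(ValueError):
            complex_permittivity(10.0, 1.0, 0.0)


class TestFieldSolutions:
    def test_all_electrodes_at_same_potential_gives_constant_field(self, sensor):
        grid = sensor.default_grid(64)
        field = homogeneous_head_field(sensor, grid)
        from cceit.solver import _layout

        lay = _layout(sensor, grid)
        values = np.where(lay.dirichlet, 1.0, 0.0).astype(complex)
        v, _ = solve_dirichlet(field, lay.dirichlet, values)
        assert np.allclose(v, 1.0, atol=1e-9)

    def test_maximum_principle_for_real_permittivity(self, sensor):
        grid = sensor.default_grid(64)
        X, Y = grid.xy
        inside = (X / 77.0) ** 2 + (Y / 105.0) ** 2 <= 1.0
        eps = np.where(inside, 40.0 + 0j, 1.0 + 0j)
        field = PermittivityField(grid, eps, sensor.omega)
        sol = solve_field(field, sensor, excited=3)
        assert np.max(np.abs(sol.potential)) <= 1.0 + 1e-9
        assert sol.residual <= 1e-10

    def test_excited_electrode_holds_the_excitation_value(self, sensor, solver_field):
        from cceit.solver import _layout

        sol = solve_field(solver_field, sensor, excited=5)
        lay = _layout(sensor, solver_field.grid)
        assert np.allclose(sol.potential[lay.electrode_id == 5], 1.0)
        assert np.allclose(sol.potential[lay.electrode_id == 2], 0.0)
        assert np.allclose(sol.potential[lay.screen], 0.0)

    def test_resolution_and_index_guards(self, sensor, solver_field):
        with pytest.raises(ValueError):
            solve_field(solver_field, sensor, excited=16)
        small = PermittivityField(Grid(260.0, 32), np.ones((32, 32), complex),
                                  sensor.omega)
        with pytest.raises(ValueError):
            solve_field(small, sensor, excited=0)


class TestGaussCapacitance:
    def test_reciprocity(self, sensor, solver_field):
        frame = measure_frame(solver_field, sensor)
        d = dict(zip(frame.pairs, frame.values))
        worst = max(abs(d[(i, j)] - d[(j, i)]) / abs(d[(i, j)])
                    for i, j in frame.pairs if i < j)
        assert worst <= 1e-6

    def test_adjacent_pair_exceeds_opposite_pair_in_air(self, sensor):
        grid = sensor.default_grid(64)
        field = PermittivityField(grid, np.ones((grid.n, grid.n), complex),
                                  sensor.omega)
        frame = measure_frame(field, sensor)
        d = dict(zip(frame.pairs, frame.values))
        assert abs(d[(0, 1)]) > abs(d[(0, 8)])

    def test_uniform_scaling_scales_capacitance_exactly(self, sensor, solver_field):
        sol = solve_field(solver_field, sensor, excited=0)
        c1 = gauss_capacitance(sol, solver_field, sensor, measuring=5)
        k = 3.7
        scaled = PermittivityField(solver_field.grid, k * solver_field.eps,
                                   solver_field.omega)
        sol2 = solve_field(scaled, sensor, excited=0)
        c2 = gauss_capacitance(sol2, scaled, sensor, measuring=5)
        assert c2 == pytest.approx(k * c1, rel=1e-9)

    def test_measuring_must_differ_from_excited(self, sensor, solver_field):
        sol = solve_field(solver_field, sensor, excited=4)
        with pytest.raises(ValueError):
            gauss_capacitance(sol, solver_field, sensor, measuring=4)


class TestMeasureFrame:
    def test_sixteen_electrodes_give_240_ordered_pairs(self, sensor, solver_field):
        frame = measure_frame(solver_field, sensor)
        assert len(frame.values) == 240
        assert frame.as_real_input().shape == (2, 240)

    def test_two_electrode_frame_is_reciprocal(self):
        sensor = SensorModel(n_electrodes=2)
        field = homogeneous_head_field(sensor, sensor.default_grid(64))
        frame = measure_frame(field, sensor)
        assert len(frame.values) == 2
        assert frame.values[0] == pytest.approx(frame.values[1], rel=1e-9)

    def test_pair_enumeration_lengths(self):
        assert len(measurement_pairs(16)) == 240
        assert len(measurement_pairs(32)) == 992

    def test_insulation_thickness_strictly_lowers_all_magnitudes(self):
        frames = []
        for t in (0.5, 2.0, 6.0):
            s = SensorModel(insulation_thickness=t)
            f = homogeneous_head_field(s, s.default_grid(64))
            frames.append(np.abs(measure_frame(f, s).values))
        assert np.all(frames[1] < frames[0])
        assert np.all(frames[2] < frames[1])

    def test_grid_convergence_of_smooth_field(self, sensor):
        """Staircase electrodes limit pointwise convergence; the error must
        still shrink with resolution and stay below 6 % (median) at
        128 vs 256."""
        vals = {}
        for n in (64, 128, 256):
            f = homogeneous_head_field(sensor, sensor.default_grid(n))
            vals[n] = measure_frame(f, sensor).values
        err_128 = np.median(np.abs(vals[128] - vals[256]) / np.abs(vals[256]))
        err_64 = np.median(np.abs(vals[64] - vals[256]) / np.abs(vals[256]))
        assert err_128 < 0.06
        assert err_128 < err_64

    def test_csv_export(self, sensor, solver_field, tmp_path):
        frame = measure_frame(solver_field, sensor)
        path = tmp_path / "frame.csv"
        frame.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "excite,measure,re_c,im_c"
        assert len(lines) == 241


class TestMeasurementNoise:
    @pytest.fixture(scope="class")
    def frame(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=240) * 1e-11 + 1j * rng.normal(size=240) * 1e-11
        return MeasurementFrame(vals, 16)

    def test_infinite_snr_is_identity(self, frame):
        assert add_measurement_noise(frame, np.inf, 0) is frame

    def test_fixed_seed_is_bit_identical(self, frame):
        a = add_measurement_noise(frame, 30.0, rng_seed=5)
        b = add_measurement_noise(frame, 30.0, rng_seed=5)
        assert np.array_equal(a.values, b.values)
        assert a.snr_db == 30.0

    def test_empirical_peak_snr_within_half_db(self, frame):
        """Monte-Carlo oracle: the realised noise sd over 1000 frames maps
        back to 30 dB within 0.5 dB of the peak-referenced definition."""
        rng = np.random.default_rng(7)
        noises = []
        for _ in range(1000):
            noisy = add_measurement_noise(frame, 30.0, rng)
            d = noisy.values - frame.values
            noises.append(np.concatenate([d.real, d.imag]))
        sd_hat = np.std(np.concatenate(noises))
        snr_hat = 20.0 * np.log10(np.max(np.abs(frame.values)) / sd_hat)
        assert snr_hat == pytest.approx(30.0, abs=0.5)

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            MeasurementFrame(np.ones(10, complex), 16)
        with pytest.raises(ValueError):
            MeasurementFrame(np.full(240, np.nan + 0j), 16)
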