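import math

import numpy as np
import pytest

from thzmargin import (ComplexIndex, FieldCube, SearchGrid, SpectralTrace,
                       candidate_transfer, characterize_substrate, discrepancy,
                       extract_map, grid_search_pixel, hz_to_omega, objective,
                       transfer_from_fields)
from thzmargin.errors import EmptyBandError, ValidationError
from thzmargin.inversion import IndexMap, TransferSpectrum
from thzmargin.optics import AIR, SubstrateSpec, default_substrate
from thzmargin.phantom import reference_pulse

from conftest import random_on_grid_index


def synth_transfer(tissue, substrate, frequencies):
    """Forward-model a sample/reference pair and form its transfer spectrum."""
    reference = reference_pulse(frequencies)
    values = np.array([candidate_transfer(tissue, substrate, float(w))
                       for w in frequencies])
    sample = SpectralTrace(frequencies, values * reference.field)
    return transfer_from_fields(sample, reference)


class TestTransferFromFields:
    def test_sample_equals_reference(self, freq_axis):
        ref = reference_pulse(freq_axis)
        ts = transfer_from_fields(ref, ref)
        np.testing.assert_allclose(ts.values, 1.0)

    def test_half_amplitude(self, freq_axis):
        ref = reference_pulse(freq_axis)
        sample = SpectralTrace(freq_axis, 0.5 * ref.field)
        ts = transfer_from_fields(sample, ref)
        np.testing.assert_allclose(ts.values, 0.5)

    def test_forward_model_round_trip(self, substrate, freq_axis):
        tissue = ComplexIndex(2.3, 0.2)
        ts = synth_transfer(tissue, substrate, freq_axis)
        expected = np.array([candidate_transfer(tissue, substrate, float(w))
                             for w in ts.frequencies])
        np.testing.assert_allclose(ts.values, expected, rtol=1e-14)

    def test_floor_restricts_band(self, freq_axis):
        ref = reference_pulse(freq_axis)
        field = ref.field.copy()
        field[:3] = 1e-12  # kill the low end
        weak_ref = SpectralTrace(freq_axis, field)
        ts = transfer_from_fields(weak_ref, weak_ref, floor_rel=1e-6)
        assert ts.frequencies.size == freq_axis.size - 3

    def test_empty_band_error(self, freq_axis):
        dead = SpectralTrace(freq_axis, np.zeros_like(freq_axis, dtype=complex))
        with pytest.raises(EmptyBandError):
            transfer_from_fields(dead, dead)

    def test_mismatched_axes_rejected(self, freq_axis):
        a = reference_pulse(freq_axis)
        b = reference_pulse(freq_axis * 1.01)
        with pytest.raises(ValidationError):
            transfer_from_fields(a, b)


class TestDiscrepancyObjective:
    def test_matched_magnitudes(self):
        assert discrepancy(1 + 1j, 1 - 1j) == 0.0
        assert objective(0.3 + 0.1j, 0.1 + 0.3j) == 0.0

    def test_e_ratio(self):
        assert discrepancy(math.e, 1.0) == pytest.approx(1.0)
        assert objective(math.e ** 2, 1.0) == pytest.approx(4.0)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            a = complex(*rng.normal(size=2))
            b = complex(*rng.normal(size=2))
            if abs(a) == 0 or abs(b) == 0:
                continue
            assert discrepancy(a, b) == pytest.approx(-discrepancy(b, a))

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValidationError):
            discrepancy(0.0, 1.0)

    def test_phase_invariance(self):
        base = objective(0.4, 0.2)
        for phi in np.linspace(0, 2 * np.pi, 17):
            for psi in np.linspace(0, 2 * np.pi, 5):
                got = objective(0.4 * np.exp(1j * phi), 0.2 * np.exp(1j * psi))
                assert got == pytest.approx(base)

    def test_nonnegative(self, rng):
        for _ in range(50):
            a = complex(*rng.normal(size=2)) or 1.0
            b = complex(*rng.normal(size=2)) or 1.0
            assert objective(a, b) >= 0.0


class TestSearchGrid:
    def test_printed_counts(self, grid):
        assert grid.n_values.size == 151
        assert grid.kappa_values.size == 1001

    def test_inclusive_endpoints(self, grid):
        assert grid.n_values[0] == 1.5 and grid.n_values[-1] == 3.0
        assert grid.kappa_values[0] == 0.0 and grid.kappa_values[-1] == 1.0

    def test_snap_is_idempotent(self, grid, rng):
        for _ in range(10):
            ci = grid.snap(rng.uniform(1.4, 3.1), rng.uniform(-0.1, 1.1))
            again = grid.snap(ci.n, ci.kappa)
            assert (again.n, again.kappa) == (ci.n, ci.kappa)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValidationError):
            SearchGrid(n_step=0.0)
        with pytest.raises(ValidationError):
            SearchGrid(n_min=3.0, n_max=1.5)


class TestGridSearchPixel:
    def test_exact_on_grid_recovery(self, substrate, grid, freq_axis, omega550):
        truth = ComplexIndex(2.30, 0.200)
        ts = synth_transfer(truth, substrate, freq_axis)
        got = grid_search_pixel(ts, grid, substrate, omega550, mode="complex")
        assert (got.n, got.kappa) == (2.30, 0.200)

    def test_grid_corner_recovery(self, substrate, grid, freq_axis, omega550):
        truth = ComplexIndex(1.50, 0.0)
        ts = synth_transfer(truth, substrate, freq_axis)
        got = grid_search_pixel(ts, grid, substrate, omega550, mode="complex")
        assert (got.n, got.kappa) == (1.50, 0.000)

    def test_magnitude_mode_degeneracy_tolerated(self, substrate, grid,
                                                 freq_axis, omega550):
        truth = ComplexIndex(2.30, 0.200)
        ts = synth_transfer(truth, substrate, freq_axis)
        got = grid_search_pixel(ts, grid, substrate, omega550, mode="magnitude")
        ts_mag = abs(ts.values[ts.nearest_index(omega550)])
        got_mag = abs(candidate_transfer(got, substrate, omega550))
        # best achievable magnitude gap over the whole grid
        nhat = grid.n_values[None, :] - 1j * grid.kappa_values[:, None]
        table = np.abs(candidate_transfer(nhat, substrate, omega550))
        best_gap = np.abs(np.log(ts_mag / table)).min()
        assert abs(math.log(ts_mag / got_mag)) <= best_gap + 1e-12

    def test_brute_force_equivalence_small(self, substrate, freq_axis,
                                           omega550, rng):
        # full-scale 20-pixel scan lives in the acceptance suite
        grid = SearchGrid(n_step=0.05, kappa_step=0.02)
        for mode in ("complex", "magnitude"):
            for _ in range(3):
                truth = random_on_grid_index(rng, grid)
                ts = synth_transfer(truth, substrate, freq_axis)
                got = grid_search_pixel(ts, grid, substrate, omega550, mode=mode)
                ts_val = complex(ts.values[ts.nearest_index(omega550)])
                best = None
                for kappa in grid.kappa_values:
                    for n in grid.n_values:
                        tc = candidate_transfer(ComplexIndex(n, kappa),
                                                substrate, omega550)
                        chi = math.log(abs(ts_val) / abs(tc)) ** 2
                        if mode == "complex":
                            d = math.remainder(np.angle(ts_val) - np.angle(tc),
                                               2 * math.pi)
                            chi += d * d
                        if best is None or chi < best[0]:
                            best = (chi, n, kappa)
                assert (got.n, got.kappa) == (best[1], best[2])

    def test_out_of_band_rejected(self, substrate, grid, freq_axis):
        ts = synth_transfer(ComplexIndex(2.0, 0.1), substrate, freq_axis)
        with pytest.raises(ValidationError):
            grid_search_pixel(ts, grid, substrate, freq_axis[-1] * 10)


def make_cube(values, substrate, frequencies, kappa=0.1):
    """Build a noise-free cube whose pixels carry the given n values."""
    reference = reference_pulse(frequencies)
    values = np.asarray(values, dtype=float)
    nhat = values - 1j * kappa
    field = np.empty(values.shape + (frequencies.size,), dtype=complex)
    for fi, w in enumerate(frequencies):
        field[:, :, fi] = candidate_transfer(nhat, substrate, float(w)) * \
            reference.field[fi]
    return FieldCube(frequencies, field), reference


class TestExtractMap:
    def test_constant_cube(self, substrate, freq_axis):
        cube, ref = make_cube(np.full((8, 8), 2.6), substrate, freq_axis, kappa=0.3)
        out = extract_map(cube, ref, substrate)
        assert out.support.all()
        np.testing.assert_array_equal(out.values, np.full((8, 8), 2.6))

    def test_two_block_recovery(self, substrate, freq_axis):
        values = np.full((8, 8), 2.0)
        values[:, 4:] = 2.6
        cube, ref = make_cube(values, substrate, freq_axis, kappa=0.2)
        out = extract_map(cube, ref, substrate, mode="complex")
        np.testing.assert_array_equal(out.values, values)

    def test_noisy_recovery_tolerance(self, substrate, freq_axis):
        from thzmargin.phantom import simulate_cube
        from thzmargin.inversion import IndexMap as IM
        values = np.full((16, 16), 2.0)
        values[:, 8:] = 2.6
        truth = IM(values=values, frequency=hz_to_omega(550e9),
                   support=np.ones((16, 16), bool),
                   kappa=np.full((16, 16), 0.2))
        cube, ref = simulate_cube(truth, substrate, freq_axis,
                                  snr_db=30.0, seed=5)
        out = extract_map(cube, ref, substrate, mode="complex")
        err = np.abs(out.values - values)
        assert np.percentile(err, 95) <= 0.05

    def test_pixel_permutation_equivariance(self, substrate, freq_axis, rng, grid):
        values = rng.choice(grid.n_values, size=(4, 4))
        cube, ref = make_cube(values, substrate, freq_axis)
        out = extract_map(cube, ref, substrate)
        perm = rng.permutation(16)
        permuted_field = cube.field.reshape(16, -1)[perm].reshape(4, 4, -1)
        cube2 = FieldCube(freq_axis, permuted_field)
        out2 = extract_map(cube2, ref, substrate)
        np.testing.assert_array_equal(out2.values.ravel(),
                                      out.values.ravel()[perm])

    def test_bad_pixels_masked(self, substrate, freq_axis):
        cube, ref = make_cube(np.full((4, 4), 2.2), substrate, freq_axis)
        cube.field[1, 2, :] = 0.0
        out = extract_map(cube, ref, substrate)
        assert not out.support[1, 2]
        assert np.isnan(out.values[1, 2])
        assert out.support.sum() == 15

    def test_support_mask_respected(self, substrate, freq_axis):
        cube, ref = make_cube(np.full((4, 4), 2.2), substrate, freq_axis)
        support = np.zeros((4, 4), bool)
        support[:2] = True
        out = extract_map(cube, ref, substrate, support=support)
        np.testing.assert_array_equal(out.support, support)
        assert np.isnan(out.values[~support]).all()

    def test_frequency_outside_band_rejected(self, substrate, freq_axis):
        cube, ref = make_cube(np.full((2, 2), 2.2), substrate, freq_axis)
        with pytest.raises(ValidationError):
            extract_map(cube, ref, substrate, frequency=5e13)


class TestCharacterizeSubstrate:
    def bare_trace(self, true_substrate, nominal, frequencies):
        reference = reference_pulse(frequencies)
        values = np.empty(frequencies.size, dtype=complex)
        for fi, w in enumerate(frequencies):
            ns = true_substrate.index_at(float(w))
            from thzmargin.optics import (fresnel_reflection,
                                          fresnel_transmission, propagation)
            p = propagation(ns, true_substrate.thickness, float(w))
            values[fi] = fresnel_transmission(AIR, ns) * \
                fresnel_reflection(ns, AIR) * \
                fresnel_transmission(ns, AIR) * p * p / -1.0
        return SpectralTrace(frequencies, values * reference.field)

    def test_recovers_on_grid_substrate(self, freq_axis):
        frequencies = freq_axis[::12]
        wide = SearchGrid(n_min=2.5, n_max=3.5, kappa_max=0.1)
        truth = wide.snap(3.07, 0.01)  # nearest wide-grid candidate
        true_sub = SubstrateSpec(thickness=2e-3, n=truth.n, kappa=truth.kappa)
        nominal = SubstrateSpec(thickness=2e-3)
        bare = self.bare_trace(true_sub, nominal, frequencies)
        fitted = characterize_substrate(bare, reference_pulse(frequencies),
                                        nominal, grid=wide)
        np.testing.assert_array_equal(fitted.n, np.full(frequencies.size, truth.n))
        np.testing.assert_array_equal(fitted.kappa,
                                      np.full(frequencies.size, truth.kappa))

    def test_grid_floor_round_trip(self, freq_axis):
        frequencies = freq_axis[::24]
        grid = SearchGrid()
        true_sub = SubstrateSpec(thickness=2e-3, n=1.5, kappa=0.0)
        bare = self.bare_trace(true_sub, true_sub, frequencies)
        fitted = characterize_substrate(bare, reference_pulse(frequencies),
                                        SubstrateSpec(thickness=2e-3), grid=grid)
        np.testing.assert_array_equal(fitted.n, np.full(frequencies.size, 1.5))

    def test_idempotence(self, freq_axis):
        frequencies = freq_axis[::24]
        wide = SearchGrid(n_min=2.5, n_max=3.5, kappa_max=0.1)
        true_sub = SubstrateSpec(thickness=2e-3, n=3.07, kappa=0.01)
        bare = self.bare_trace(true_sub, true_sub, frequencies)
        once = characterize_substrate(bare, reference_pulse(frequencies),
                                      SubstrateSpec(thickness=2e-3), grid=wide)
        twice = characterize_substrate(bare, reference_pulse(frequencies),
                                       once, grid=wide)
        np.testing.assert_array_equal(once.n, twice.n)
        np.testing.assert_array_equal(once.kappa, twice.kappa)
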