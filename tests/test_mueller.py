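import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thzpol as tp
from thzpol import mueller as mu


def mueller_reference(S):
    """Independent complex-arithmetic oracle for one 2x2 matrix."""
    Svv, Svh = S[0, 0], S[0, 1]
    Shv, Shh = S[1, 0], S[1, 1]
    return np.array([
        [abs(Svv) ** 2, abs(Svh) ** 2,
         (np.conj(Svh) * Svv).real, -(np.conj(Svh) * Svv).imag],
        [abs(Shv) ** 2, abs(Shh) ** 2,
         (Shv * np.conj(Shh)).real, -(Shv * np.conj(Shh)).imag],
        [2 * (Svv * np.conj(Shv)).real, 2 * (Svh * np.conj(Shh)).real,
         (Svv * np.conj(Shh) + Svh * np.conj(Shv)).real,
         -(Svv * np.conj(Shh) - Svh * np.conj(Shv)).imag],
        [2 * (Svv * np.conj(Shv)).imag, 2 * (Svh * np.conj(Shh)).imag,
         (Svv * np.conj(Shh) + Svh * np.conj(Shv)).imag,
         (Svv * np.conj(Shh) - Svh * np.conj(Shv)).real],
    ])


class TestMuellerFromS:
    def test_identity_scattering_gives_identity_matrix(self):
        M = mu.mueller_from_S(np.eye(2, dtype=complex))
        assert np.array_equal(M, np.eye(4))

    def test_quarter_wave_copol_phase(self):
        S = np.diag([1.0, 1.0j]).astype(complex)
        M = mu.mueller_from_S(S)
        assert M[0, 0] == 1.0 and M[1, 1] == 1.0
        assert M[2, 2] == pytest.approx(0.0, abs=1e-15)
        assert M[2, 3] == pytest.approx(1.0)
        assert M[3, 2] == pytest.approx(-1.0)
        assert M[3, 3] == pytest.approx(0.0, abs=1e-15)

    def test_mixed_matrix_against_frozen_oracle(self):
        S = np.array([[1.0, 0.2j], [0.2j, 0.8]], dtype=complex)
        M = mu.mueller_from_S(S)
        expected = np.array([
            [1.0, 0.04, 0.0, 0.2],
            [0.04, 0.64, 0.0, -0.16],
            [0.0, 0.0, 0.84, 0.0],
            [-0.4, 0.32, 0.0, 0.76],
        ])
        assert np.allclose(M, expected, atol=1e-15)
        assert np.allclose(M, mueller_reference(S), atol=1e-15)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_elementwise_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
        assert np.allclose(mu.mueller_from_S(S), mueller_reference(S), atol=1e-12)

    def test_rank_one_identities_hold_exactly(self, random_scattering_matrices):
        res = mu.rank_one_residuals(mu.mueller_from_S(random_scattering_matrices))
        assert res.max() < 1e-12

    def test_reciprocity_corollary_for_symmetric_S(self, random_scattering_matrices):
        S = random_scattering_matrices.copy()
        S[..., 1, 0] = S[..., 0, 1]
        M = mu.mueller_from_S(S)
        assert np.allclose(M[..., 0, 1], M[..., 1, 0])
        # M41 = -2*M14 for reciprocal scatterers in this element ordering
        assert np.allclose(M[..., 3, 0], -2.0 * M[..., 0, 3])


class TestScatteringFromScan:
    def test_identity_cube_recovers_identity(self, clean_grid41):
        n_freq = clean_grid41.n_samples // 2 + 1
        S = np.zeros((2, 2, n_freq, 2, 2), dtype=complex)
        S[..., 0, 0] = 1.0
        S[..., 1, 1] = 1.0
        cube = tp.cube_from_scattering(S, clean_grid41)
        field = mu.scattering_from_scan(cube, band=tp.BAND_41)
        assert np.allclose(field.S[..., 0, 0], 1.0, atol=1e-9)
        assert np.allclose(field.S[..., 1, 1], 1.0, atol=1e-9)
        assert np.allclose(field.S[..., 0, 1], 0.0, atol=1e-9)

    def test_collagen_forward_inverse_round_trip(self, geometry, clean_grid41):
        props = tp.default_optics("collagen", "block")
        freqs = clean_grid41.freqs_thz()
        S_true = tp.pixel_scattering(props, 30.0, geometry, freqs)
        S = np.broadcast_to(S_true, (3, 3) + S_true.shape).copy()
        cube = tp.cube_from_scattering(S, clean_grid41)
        field = mu.scattering_from_scan(cube, band=tp.BAND_41)
        idx = tp.select_band(freqs, tp.BAND_41)
        expected = S[:, :, idx]
        err = np.abs(field.S - expected) / np.maximum(np.abs(expected), 1e-30)
        nz = np.abs(expected) > 1e-12
        assert err[nz].max() < 1e-6

    def test_missing_reference_error_names_channel(self, clean_grid41):
        n_freq = clean_grid41.n_samples // 2 + 1
        S = np.zeros((1, 1, n_freq, 2, 2), dtype=complex)
        S[..., 0, 0] = 1.0
        S[..., 1, 1] = 1.0
        cube = tp.cube_from_scattering(S, clean_grid41)
        del cube.references["VV"]
        with pytest.raises(ValueError, match="VV"):
            mu.scattering_from_scan(cube, band=tp.BAND_41)

    def test_unknown_scheme_rejected(self, clean_block_cube):
        with pytest.raises(ValueError, match="scheme"):
            mu.scattering_from_scan(clean_block_cube, scheme="sideways")


class TestBandAverage:
    def test_frequency_constant_stack_unchanged(self):
        rng = np.random.default_rng(0)
        S1 = rng.normal(size=(2, 2, 1, 2, 2)) + 1j * rng.normal(size=(2, 2, 1, 2, 2))
        S = np.repeat(S1, 5, axis=2)
        freqs = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        stack = mu.MuellerStack(M=mu.mueller_from_S(S), freqs_thz=freqs,
                                band=None, scheme="emitter")
        avg = mu.band_average_mueller(stack, tp.BandConfig(0.5, 2.5))
        assert np.allclose(avg.M, stack.M[..., 0, :, :])

    def test_two_bin_arithmetic_mean(self):
        M = np.zeros((1, 1, 2, 4, 4))
        M[..., 0, 0, 0] = 1.0
        M[..., 1, 0, 0] = 3.0
        stack = mu.MuellerStack(M=M, freqs_thz=np.array([1.0, 2.0]),
                                band=None, scheme="emitter")
        avg = mu.band_average_mueller(stack, tp.BandConfig(0.5, 2.5))
        assert avg.M[0, 0, 0, 0] == 2.0

    def test_isotropic_phantom_averaged_m12_zero(self, block_optics, geometry,
                                                 clean_grid41):
        labels = tp.make_label_map(tp.uniform_phantom(tp.TissueClass.FAT, 4, 4))
        cube = tp.simulate_scan(labels, block_optics, geometry, clean_grid41)
        field = mu.scattering_from_scan(cube, band=tp.BAND_41)
        avg = mu.band_average_mueller(mu.mueller_stack(field), tp.BAND_41)
        assert np.allclose(avg.M[..., 0, 1], 0.0, atol=1e-20)

    def test_band_averaging_relaxes_identities_to_inequalities(self, geometry,
                                                               clean_grid41):
        props = tp.default_optics("collagen", "block")
        freqs = clean_grid41.freqs_thz()
        S_true = tp.pixel_scattering(props, 25.0, geometry, freqs)
        S = np.broadcast_to(S_true, (2, 2) + S_true.shape).copy()
        cube = tp.cube_from_scattering(S, clean_grid41)
        field = mu.scattering_from_scan(cube, band=tp.BAND_41)
        avg = mu.band_average_mueller(mu.mueller_stack(field), tp.BAND_41)
        M = avg.M
        tol = 1e-10
        assert np.all(M[..., 0, 2] ** 2 + M[..., 0, 3] ** 2
                      <= M[..., 0, 0] * M[..., 0, 1] * (1 + tol) + tol)
        assert np.all(M[..., 2, 0] ** 2 + M[..., 3, 0] ** 2
                      <= 4 * M[..., 0, 0] * M[..., 1, 0] * (1 + tol) + tol)

    def test_double_band_average_rejected(self, clean_block_cube):
        field = mu.scattering_from_scan(clean_block_cube, band=tp.BAND_41)
        avg = mu.band_average_mueller(mu.mueller_stack(field), tp.BAND_41)
        with pytest.raises(ValueError, match="already"):
            mu.band_average_mueller(avg, tp.BAND_41)


class TestStokes:
    @pytest.mark.parametrize("Ev,Eh,expected", [
        (1.0, 0.0, (1, 1, 0, 0)),
        (1 / np.sqrt(2), 1 / np.sqrt(2), (1, 0, 1, 0)),
    ])
    def test_cardinal_states(self, Ev, Eh, expected):
        assert np.allclose(mu.stokes_from_field(Ev, Eh), expected)

    def test_circular_state_has_unit_s3(self):
        s = mu.stokes_from_field(1 / np.sqrt(2), 1j / np.sqrt(2))
        assert abs(s[3]) == pytest.approx(1.0)
        assert s[3] == pytest.approx(1.0)  # documented sign convention

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fully_polarized_fields_saturate_the_stokes_cone(self, seed):
        rng = np.random.default_rng(seed)
        Ev = complex(rng.normal(), rng.normal())
        Eh = complex(rng.normal(), rng.normal())
        s = mu.stokes_from_field(Ev, Eh)
        assert s[0] ** 2 == pytest.approx(s[1] ** 2 + s[2] ** 2 + s[3] ** 2,
                                          rel=1e-12)


def test_power_and_mueller_routes_agree_bitwise(clean_block_cube):
    """M11/M22/M12/M21 equal the per-frequency normalized power images."""
    field = mu.scattering_from_scan(clean_block_cube, band=tp.BAND_41)
    stack = mu.mueller_stack(field)
    power = tp.power_images_from_field(field.S)
    assert np.array_equal(stack.M[..., 0, 0], power["VV"])
    assert np.array_equal(stack.M[..., 1, 1], power["HH"])
    assert np.array_equal(stack.M[..., 0, 1], power["VH"])
    assert np.array_equal(stack.M[..., 1, 0], power["HV"])
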