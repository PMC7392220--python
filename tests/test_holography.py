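import numpy as np
import pytest

from holomri._util import fft_c
from holomri.holography import (
    LayerSpec,
    OpticsConfig,
    PhaseHologram,
    build_comparative_hologram,
    build_tumor_stack_hologram,
    chirp_phase,
    default_layer_stack,
    ifta,
    modulate_layer,
    ramp_phase,
    superpose_layers,
    tile_hologram,
    zero_pad_center,
)
from holomri.reconstruction import fourier_reconstruct

SMALL = OpticsConfig(slm_shape=(64, 64))


def random_target(shape=(64, 64), pad=4, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    img[shape[0] // 4 : -shape[0] // 4, shape[1] // 4 : -shape[1] // 4] = rng.random(
        (shape[0] // 2, shape[1] // 2)
    )
    return zero_pad_center(img, (shape[0] * pad, shape[1] * pad))


class TestZeroPad:
    def test_paper_geometry(self):
        out = zero_pad_center(np.ones((320, 260)), (4320, 7680))
        assert out.shape == (4320, 7680)
        assert out.sum() == 320 * 260

    def test_values_in_central_block(self):
        img = np.arange(6.0).reshape(2, 3)
        out = zero_pad_center(img, (4, 5))
        assert np.array_equal(out[1:3, 1:4], img)

    def test_identity_at_factor_one(self):
        img = np.random.default_rng(0).random((8, 8))
        assert np.array_equal(zero_pad_center(img, (8, 8)), img)

    def test_oversized_input_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            zero_pad_center(np.ones((10, 10)), (8, 12))


class TestIfta:
    def test_impulse_converges_immediately_with_flat_phase(self):
        target = np.zeros((32, 32))
        target[16, 16] = 1.0
        phase, trace = ifta(target)
        assert trace.n_iterations == 1 and trace.converged
        assert trace.rmse[0] == pytest.approx(0.0, abs=1e-12)
        # flat phase up to a global piston
        field = np.exp(1j * phase)
        assert np.abs(field - field[0, 0]).max() < 1e-9

    def test_emitted_hologram_is_pure_phase(self):
        phase, _ = ifta(random_target(seed=1), max_iter=5)
        assert np.abs(np.abs(np.exp(1j * phase)) - 1.0).max() < 1e-12
        assert phase.min() >= 0.0 and phase.max() < 2 * np.pi

    def test_error_drops_below_tolerance_with_monotone_endpoints(self):
        phase, trace = ifta(random_target(seed=2), max_iter=200)
        assert trace.rmse[-1] <= 0.05
        assert trace.rmse[-1] <= trace.rmse[0]

    def test_trace_invariant_at_stop(self):
        _, trace = ifta(random_target(seed=3), max_iter=200, epsilon=0.05)
        assert len(trace.rmse) == len(trace.phase_change) == trace.n_iterations
        assert trace.phase_change[-1] < trace.epsilon or trace.n_iterations == 200

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ifta(np.zeros((8, 8)))

    def test_deterministic_for_fixed_seed(self):
        a, _ = ifta(random_target(seed=4), max_iter=10)
        b, _ = ifta(random_target(seed=4), max_iter=10)
        assert np.array_equal(a, b)


class TestChirp:
    def test_zero_distance_is_identity(self):
        assert np.allclose(chirp_phase((16, 16), 0.0, SMALL), 1.0)

    def test_opposite_distances_cancel(self):
        chi = chirp_phase((16, 16), 0.004, SMALL)
        assert np.allclose(chi * chirp_phase((16, 16), -0.004, SMALL), 1.0)

    def test_closed_form_at_one_frequency_sample(self):
        # pixel (i, j) of an N-grid maps to v = (idx - N//2) / (N * pitch);
        # the chirp there is exp(i * pi * lambda * z * |v|^2)
        optics = OpticsConfig(slm_shape=(16, 16))
        z = 0.01
        chi = chirp_phase((16, 16), z, optics)
        i, j = 3, 12
        vr = (i - 8) / (16 * optics.slm_pixel_pitch)
        vc = (j - 8) / (16 * optics.slm_pixel_pitch)
        expected = np.exp(1j * np.pi * optics.wavelength * z * (vr**2 + vc**2))
        assert chi[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unit_modulus(self):
        chi = chirp_phase((32, 32), 0.0065, SMALL)
        assert np.abs(np.abs(chi) - 1.0).max() < 1e-12


class TestRamp:
    def test_zero_shift_is_identity(self):
        assert np.allclose(ramp_phase((16, 16), (0.0, 0.0)), 1.0)

    def test_ramps_compose_additively(self):
        r1 = ramp_phase((16, 16), (2.0, 1.0))
        r2 = ramp_phase((16, 16), (-5.0, 3.0))
        assert np.allclose(r1 * r2, ramp_phase((16, 16), (-3.0, 4.0)))

    def test_single_bin_ramp_shifts_reconstruction_by_one_pixel(self):
        rng = np.random.default_rng(0)
        field = np.exp(1j * rng.uniform(0, 2 * np.pi, (32, 32)))
        base = np.abs(fft_c(field)) ** 2
        shifted = np.abs(fft_c(field * ramp_phase((32, 32), (0.0, 1.0)))) ** 2
        assert np.abs(np.roll(base, 1, axis=1) - shifted).max() < 1e-9

    def test_tilt_angles_require_nonzero_distance(self):
        layer = LayerSpec(z=0.0, shift_px=(0.0, 5.0))
        with pytest.raises(ValueError, match="z = 0"):
            layer.tilt_angles(SMALL, (64, 64))

    def test_physical_shift_reporting(self):
        optics = OpticsConfig()
        layer = LayerSpec(z=0.0065, shift_px=(0.0, 100.0))
        du = layer.delta_u(optics, (1080, 1920))
        expected = 100.0 * optics.wavelength * optics.focal_length / (1920 * optics.slm_pixel_pitch)
        assert du[1] == pytest.approx(expected)


class TestModulateAndSuperpose:
    def test_identity_layer_leaves_field_unchanged(self):
        field = np.exp(1j * np.random.default_rng(1).uniform(0, 2 * np.pi, (16, 16)))
        out = modulate_layer(field, LayerSpec(z=0.0, shift_px=(0.0, 0.0)), SMALL)
        assert np.array_equal(out, field)

    def test_modulation_preserves_modulus(self):
        field = np.exp(1j * np.random.default_rng(2).uniform(0, 2 * np.pi, (16, 16)))
        out = modulate_layer(field, LayerSpec(z=0.003, shift_px=(2.0, -1.0)), SMALL)
        assert np.allclose(np.abs(out), 1.0)

    def test_single_field_superposition_returns_its_phase(self):
        phase = np.random.default_rng(3).uniform(0, 2 * np.pi, (16, 16))
        holo = superpose_layers([np.exp(1j * phase)], SMALL)
        assert np.allclose(np.exp(1j * holo.phase), np.exp(1j * phase))

    def test_exactly_cancelling_fields_get_zero_phase(self):
        f = np.ones((4, 4), dtype=complex)
        holo = superpose_layers([f, -f], SMALL)
        assert np.all(holo.phase == 0.0)

    def test_empty_superposition_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            superpose_layers([], SMALL)

    def test_four_disjoint_impulses_reconstruct_at_configured_shifts(self):
        n = 64
        target = np.zeros((n, n))
        target[n // 2, n // 2] = 1.0
        phase, _ = ifta(target)
        base = np.exp(1j * phase)
        shifts = [(0.0, -16.0), (0.0, -5.0), (0.0, 7.0), (0.0, 19.0)]
        fields = [
            modulate_layer(base, LayerSpec(z=0.0, shift_px=s), SMALL) for s in shifts
        ]
        holo = superpose_layers(fields, SMALL)
        recon = fourier_reconstruct(holo).intensity
        peaks = []
        work = recon.copy()
        for _ in range(4):
            idx = np.unravel_index(np.argmax(work), work.shape)
            peaks.append(idx)
            work[idx[0] - 2 : idx[0] + 3, idx[1] - 2 : idx[1] + 3] = 0
        expected = {(n // 2, int(n // 2 + s[1])) for s in shifts}
        assert set(peaks) == expected


class TestSchemes:
    def test_degenerate_stack_equals_plain_ifta(self):
        img = np.zeros((16, 16))
        img[4:12, 4:12] = 1.0
        holo, traces = build_tumor_stack_hologram(
            [img], [LayerSpec()], SMALL, pad_factor=1, max_iter=10
        )
        phase, _ = ifta(zero_pad_center(img, (64, 64)), max_iter=10)
        assert np.allclose(holo.phase, phase)
        assert len(traces) == 1

    def test_duplicate_shifts_warn(self):
        img = np.zeros((16, 16))
        img[6:10, 6:10] = 1.0
        layers = [LayerSpec(z=0.0, shift_px=(0.0, 3.0))] * 2
        with pytest.warns(UserWarning, match="overlap"):
            build_tumor_stack_hologram([img, img], layers, SMALL, pad_factor=1, max_iter=3)

    def test_default_layer_stack_uses_paper_spacing(self):
        layers = default_layer_stack(4, optics=SMALL, pad_factor=4)
        zs = [l.z for l in layers]
        assert np.allclose(np.diff(zs), 6.5e-3)
        assert len({l.shift_px for l in layers}) == 4

    def test_comparative_tumorless_exams_reduce_to_brain_terms(self):
        brain = np.zeros((16, 16))
        brain[4:12, 4:12] = 0.7
        empty = np.zeros((16, 16))
        holo, meta = build_comparative_hologram(
            brain, empty, brain, empty, gamma=2.0, shift_px=(0.0, 8.0),
            optics=SMALL, pad_factor=1, max_iter=5,
        )
        assert meta["traces"]["tumor_first"] is None
        phase_b, _ = ifta(zero_pad_center(brain, (64, 64)), max_iter=5)
        ramp = ramp_phase((64, 64), (0.0, 8.0))
        expected = superpose_layers(
            [np.exp(1j * phase_b), np.exp(1j * phase_b) * ramp], SMALL
        )
        assert np.allclose(holo.phase, expected.phase)

    def test_comparative_rejects_nonpositive_gamma(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError, match="gamma"):
            build_comparative_hologram(img, img, img, img, gamma=0.0, optics=SMALL, pad_factor=1)


class TestTiling:
    def test_sixteen_tiles_partition_the_extended_hologram(self):
        optics = OpticsConfig(slm_shape=(32, 48))
        phase = np.random.default_rng(0).uniform(0, 2 * np.pi, (128, 192))
        holo = PhaseHologram(phase=phase, optics=optics)
        tiles = tile_hologram(holo)
        assert len(tiles) == 16
        rebuilt = np.block([[tiles[4 * i + j].phase for j in range(4)] for i in range(4)])
        assert np.array_equal(rebuilt, holo.phase)

    def test_factor_one_returns_single_identical_tile(self):
        phase = np.random.default_rng(1).uniform(0, 2 * np.pi, (32, 48))
        holo = PhaseHologram(phase=phase, optics=OpticsConfig(slm_shape=(32, 48)))
        tiles = tile_hologram(holo)
        assert len(tiles) == 1
        assert np.array_equal(tiles[0].phase, phase)

    def test_non_integer_tiling_rejected(self):
        holo = PhaseHologram(
            phase=np.zeros((100, 192)), optics=OpticsConfig(slm_shape=(32, 48))
        )
        with pytest.raises(ValueError, match="integer multiple"):
            tile_hologram(holo)


class TestEnergySuperposition:
    def test_disjoint_layer_energies_add_with_small_cross_terms(self):
        # the complex sum of holograms of disjointly placed targets carries
        # each target's reconstruction energy at its own window: cross terms
        # between the quasi-independent unit fields are statistically small
        n = 32
        img = np.zeros((n, n))
        img[12:20, 12:20] = 1.0
        phase, _ = ifta(zero_pad_center(img, (128, 128)), max_iter=20)
        base = np.exp(1j * phase)
        shifts = [(0.0, -32.0), (0.0, 32.0)]
        fields = [modulate_layer(base, LayerSpec(z=0.0, shift_px=s), SMALL) for s in shifts]
        summed = np.sum(fields, axis=0)
        combined = np.abs(fft_c(summed)) ** 2
        single = np.abs(fft_c(fields[0])) ** 2
        w = 20
        c0, c1 = 64, 64 - 32
        window = np.s_[c0 - w : c0 + w, c1 - w : c1 + w]
        # the combined field carries 2 layers' energy; layer 0's share at its
        # window must match the single-layer reconstruction within 10%
        ratio = (2.0 * combined[window].sum() / combined.sum()) / (
            single[window].sum() / single.sum()
        )
        assert ratio == pytest.approx(1.0, abs=0.10)

    def test_phase_only_projection_retains_most_window_energy(self):
        # taking arg() of the two-field sum (the emitted SLM hologram)
        # scatters some energy into intermodulation products; the in-window
        # share must still dominate (documented efficiency loss ~20%)
        n = 32
        img = np.zeros((n, n))
        img[12:20, 12:20] = 1.0
        phase, _ = ifta(zero_pad_center(img, (128, 128)), max_iter=20)
        base = np.exp(1j * phase)
        shifts = [(0.0, -32.0), (0.0, 32.0)]
        fields = [modulate_layer(base, LayerSpec(z=0.0, shift_px=s), SMALL) for s in shifts]
        combined = fourier_reconstruct(superpose_layers(fields, SMALL)).intensity
        single = fourier_reconstruct(superpose_layers([fields[0]], SMALL)).intensity
        w = 20
        window = np.s_[64 - w : 64 + w, 64 - 32 - w : 64 - 32 + w]
        ratio = (2.0 * combined[window].sum() / combined.sum()) / (
            single[window].sum() / single.sum()
        )
        assert ratio >= 0.70
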