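"""Dixon reconstruction: phase maps, unwrapping, separation, fat fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hynp

from musclefat.dixon import (
    EchoSeries,
    FatWaterPair,
    PhaseMap,
    fat_fraction,
    reconstruct,
    separate_fat_water,
    unwrap_phase,
    wrapped_double_phase,
)
from musclefat.phantom import (
    FieldSpec,
    build_forearm_phantom,
    noise_sd_for_snr,
    simulate_echoes,
)

from conftest import uniform_ff_spec


def _uniform_echoes(w, f, phi0, phi, shape=(4, 4)):
    W = np.full(shape, w, dtype=float)
    F = np.full(shape, f, dtype=float)
    field = FieldSpec(
        phase0_coeffs=np.array([[phi0]]),
        phase_per_echo_coeffs=np.array([[phi]]),
        allow_wrap_violation=True,
    )
    return simulate_echoes(W, F, field)


class TestWrappedDoublePhase:
    def test_recovers_twice_the_field_phase(self):
        pm = wrapped_double_phase(_uniform_echoes(0.7, 0.3, 0.3, 0.8))
        np.testing.assert_allclose(pm.values, 1.6, atol=1e-12)
        assert pm.wrapped

    def test_zero_field_gives_zero_map(self):
        pm = wrapped_double_phase(_uniform_echoes(0.7, 0.3, 0.5, 0.0))
        np.testing.assert_allclose(pm.values, 0.0, atol=1e-12)

    def test_wraps_into_principal_interval(self):
        # 2*phi = 4.0 wraps to 4 - 2*pi
        pm = wrapped_double_phase(_uniform_echoes(0.7, 0.3, 0.0, 2.0))
        np.testing.assert_allclose(pm.values, 4.0 - 2 * np.pi, atol=1e-12)

    def test_zero_magnitude_pixels_flagged(self):
        ech = _uniform_echoes(1.0, 0.0, 0.0, 0.5)
        ech.S1[0, 0] = 0.0
        pm = wrapped_double_phase(ech)
        assert pm.values[0, 0] == 0.0
        assert pm.quality[0, 0] == 0.0
        assert np.all(pm.quality[1:, :] > 0)


class TestUnwrapPhase:
    def test_smooth_ramp_recovered_up_to_global_offset(self):
        y = np.linspace(0.0, 6.0 * np.pi, 64)
        truth = np.tile(y, (8, 1))
        wrapped = np.angle(np.exp(1j * truth))
        wrapped[wrapped == -np.pi] = np.pi
        out = unwrap_phase(
            PhaseMap(values=wrapped, wrapped=True), quality=np.ones_like(wrapped)
        )
        offset = out.values - truth
        np.testing.assert_allclose(offset, offset.flat[0], atol=1e-9)
        assert offset.flat[0] / (2 * np.pi) == pytest.approx(
            round(offset.flat[0] / (2 * np.pi)), abs=1e-9
        )

    def test_constant_map_unchanged(self):
        w = np.full((16, 16), 1.2)
        out = unwrap_phase(PhaseMap(values=w, wrapped=True), quality=np.ones_like(w))
        np.testing.assert_allclose(out.values, 1.2, atol=1e-12)
        assert not out.wrapped

    def test_rejects_already_unwrapped_input(self):
        with pytest.raises(ValueError, match="already unwrapped"):
            unwrap_phase(PhaseMap(values=np.zeros((4, 4)), wrapped=False))

    @settings(max_examples=20, deadline=None)
    @given(
        hynp.arrays(
            float,
            (12, 12),
            elements=st.floats(-3.14, 3.14, allow_nan=False),
        )
    )
    def test_congruence_modulo_two_pi_for_any_input(self, wrapped):
        """Unwrapping may only add integer multiples of 2*pi per pixel."""
        out = unwrap_phase(
            PhaseMap(values=wrapped, wrapped=True), quality=np.ones_like(wrapped)
        )
        k = (out.values - wrapped) / (2 * np.pi)
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)


class TestSeparation:
    def test_noiseless_pixelwise_inversion(self, small_spec):
        water, fat, mask = build_forearm_phantom(small_spec)
        ech = simulate_echoes(water, fat)  # default smooth field, no noise
        pair, ffmap, _ = reconstruct(ech)
        m = mask.labels > 0
        np.testing.assert_allclose(pair.water[m], water[m], atol=1e-6)
        np.testing.assert_allclose(pair.fat[m], fat[m], atol=1e-6)
        truth_ff = 100.0 * fat[m] / (water[m] + fat[m])
        assert np.abs(ffmap.ff[m] - truth_ff).max() < 1e-6

    def test_inversion_without_inphase_averaging(self, small_spec):
        water, fat, mask = build_forearm_phantom(small_spec)
        ech = simulate_echoes(water, fat)
        pair, ffmap, _ = reconstruct(ech, inphase_average=False)
        m = mask.labels > 0
        np.testing.assert_allclose(pair.water[m], water[m], atol=1e-6)
        np.testing.assert_allclose(pair.fat[m], fat[m], atol=1e-6)

    def test_branch_flip_exchanges_water_and_fat_exactly(self, small_spec):
        water, fat, _ = build_forearm_phantom(small_spec)
        ech = simulate_echoes(water, fat, noise_sd=0.02, seed=5)
        w2 = unwrap_phase(wrapped_double_phase(ech))
        a = separate_fat_water(ech, w2, resolve_swap=False)
        b = separate_fat_water(ech, w2, resolve_swap=False, flip_branch=True)
        np.testing.assert_array_equal(a.water, b.fat)
        np.testing.assert_array_equal(a.fat, b.water)

    def test_pure_water_limit_no_fat(self):
        ech = _uniform_echoes(1.0, 0.0, 0.0, 0.0)  # S2 == S1
        w2 = unwrap_phase(wrapped_double_phase(ech))
        pair = separate_fat_water(ech, w2, signal_threshold=0.0)
        np.testing.assert_allclose(pair.fat, 0.0, atol=1e-12)
        np.testing.assert_allclose(pair.water, 1.0, atol=1e-12)

    def test_fat_only_pixel_inside_water_dominant_compartment(self, small_spec):
        water, fat, mask = build_forearm_phantom(small_spec)
        sel = mask.labels == 2
        water[sel] = 0.0
        fat[sel] = small_spec.total_signal
        ech = simulate_echoes(water, fat)
        pair, ffmap, _ = reconstruct(ech)
        assert np.all(np.abs(pair.fat[sel] - small_spec.total_signal) < 1e-6)
        assert np.all(np.abs(pair.water[sel]) < 1e-6)
        assert np.all(ffmap.ff[sel] > 99.9)

    def test_wrapped_input_rejected(self, small_spec):
        water, fat, _ = build_forearm_phantom(small_spec)
        ech = simulate_echoes(water, fat)
        with pytest.raises(ValueError, match="unwrapped"):
            separate_fat_water(ech, wrapped_double_phase(ech))


class TestFatFraction:
    def test_arithmetic_and_boundaries(self):
        pair = FatWaterPair(
            water=np.array([[0.7, 1.0, 0.0]]),
            fat=np.array([[0.3, 0.0, 0.8]]),
            signal_mask=np.ones((1, 3), dtype=bool),
        )
        ffmap = fat_fraction(pair)
        np.testing.assert_allclose(ffmap.ff[0], [30.0, 0.0, 100.0], atol=1e-12)

    def test_zero_total_flagged_not_nan(self):
        pair = FatWaterPair(
            water=np.array([[0.0, 1.0]]),
            fat=np.array([[0.0, 0.0]]),
            signal_mask=np.ones((1, 2), dtype=bool),
        )
        ffmap = fat_fraction(pair)
        assert not ffmap.mask[0, 0]
        assert ffmap.mask[0, 1]
        assert np.all(np.isfinite(ffmap.ff))

    def test_range_invariant_under_noise(self, small_spec):
        water, fat, _ = build_forearm_phantom(small_spec)
        ech = simulate_echoes(
            water, fat, noise_sd=noise_sd_for_snr(small_spec.total_signal, 10.0),
            seed=3,
        )
        _, ffmap, _ = reconstruct(ech)
        assert ffmap.ff.min() >= 0.0
        assert ffmap.ff.max() <= 100.0


class TestNoiseRobustness:
    @pytest.mark.parametrize("ff_true", [5.0, 30.0, 60.0])
    def test_roi_mean_bias_below_half_point_at_snr_50(self, small_spec, ff_true):
        """Monte-Carlo bias of the ROI-mean f.f. at clinical SNR.

        Two muscles carry the probed fat fraction inside an otherwise
        disease-typical compartment (so the compartment stays majority
        water, the regime the swap vote assumes).
        """
        from musclefat.phantom import PhantomSpec

        profile = {**small_spec.muscle_ff_true, 3: ff_true, 8: ff_true}
        spec = PhantomSpec(**{**small_spec.__dict__, "muscle_ff_true": profile})
        water, fat, mask = build_forearm_phantom(spec)
        sd = noise_sd_for_snr(spec.total_signal, 50.0)
        probe = (mask.labels == 3) | (mask.labels == 8)
        means = []
        for seed in range(20):
            ech = simulate_echoes(water, fat, noise_sd=sd, seed=seed)
            _, ffmap, _ = reconstruct(ech, vote_mask=mask.labels > 0)
            means.append(ffmap.ff_for_stats[probe].mean())
        assert abs(np.mean(means) - ff_true) <= 0.5
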