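"""Phantom construction, echo forward model and cohort simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from musclefat.dixon import fat_fraction, FatWaterPair
from musclefat.phantom import (
    CohortSpec,
    FieldSpec,
    PhantomSpec,
    build_forearm_phantom,
    noise_sd_for_snr,
    scale_ff_to_target,
    simulate_cohort,
    simulate_echoes,
)

from conftest import uniform_ff_spec


class TestBuildPhantom:
    def test_zero_fat_everywhere_inside_compartment(self, small_spec):
        spec = uniform_ff_spec(small_spec, 0.0)
        water, fat, mask = build_forearm_phantom(spec)
        assert np.all(fat[mask.labels > 0] == 0.0)
        assert np.all(water[mask.labels > 0] == spec.total_signal)

    def test_pixel_values_follow_construction(self, small_spec):
        spec = PhantomSpec(
            **{
                **small_spec.__dict__,
                "muscle_ff_true": {**small_spec.muscle_ff_true, 3: 30.0},
                "total_signal": 1000.0,
            }
        )
        water, fat, mask = build_forearm_phantom(spec)
        sel = mask.labels == 3
        assert sel.any()
        assert np.all(fat[sel] == 300.0)
        assert np.all(water[sel] == 700.0)

    def test_per_roi_mean_ff_equals_truth_bruteforce(self, small_spec):
        """Pixel-loop oracle: mean of fat/(water+fat)*100 per label == truth."""
        water, fat, mask = build_forearm_phantom(small_spec)
        w, f, lab = water[0], fat[0], mask.labels[0]
        for label, ff_true in small_spec.muscle_ff_true.items():
            vals = []
            for iy in range(lab.shape[0]):
                for ix in range(lab.shape[1]):
                    if lab[iy, ix] == label:
                        tot = w[iy, ix] + f[iy, ix]
                        vals.append(100.0 * f[iy, ix] / tot)
            assert vals, f"label {label} empty"
            assert np.mean(vals) == pytest.approx(ff_true, abs=1e-12)

    def test_all_ten_labels_present_and_disjoint(self, small_spec):
        _, _, mask = build_forearm_phantom(small_spec)
        assert mask.present_labels() == set(range(1, 11))

    def test_subcutaneous_ring_is_pure_fat(self, small_spec):
        water, fat, mask = build_forearm_phantom(small_spec)
        ring = (fat == small_spec.total_signal) & (mask.labels == 0)
        assert ring.any()
        assert np.all(water[ring] == 0.0)

    def test_invalid_specs_rejected(self, small_spec):
        with pytest.raises(ValueError, match="1..10"):
            PhantomSpec(**{**small_spec.__dict__, "muscle_ff_true": {1: 10.0}})
        bad = {**small_spec.muscle_ff_true, 5: 130.0}
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            PhantomSpec(**{**small_spec.__dict__, "muscle_ff_true": bad})
        with pytest.raises(ValueError, match="bone_radius"):
            PhantomSpec(**{**small_spec.__dict__, "bone_radius": 25.0})

    def test_scale_ff_to_target_hits_weighted_mean_exactly(self, small_spec):
        spec = scale_ff_to_target(small_spec, 0.9)
        _, _, mask = build_forearm_phantom(spec)
        lab = mask.labels[0]
        num = sum(
            spec.muscle_ff_true[l] * (lab == l).sum() for l in range(1, 11)
        )
        assert num / (lab > 0).sum() == pytest.approx(0.9, abs=1e-12)

    @settings(max_examples=10, deadline=None)
    @given(
        ffs=st.lists(
            st.floats(0.0, 100.0, allow_nan=False), min_size=10, max_size=10
        )
    )
    def test_construction_identity_property(self, ffs):
        """Fat fraction recomputed from truth maps returns the spec exactly."""
        spec = PhantomSpec(
            grid_shape=(64, 64),
            n_slices=1,
            compartment_radius=12.0,
            bone_radius=3.0,
            subcutaneous_ring=2.0,
            muscle_ff_true={i + 1: v for i, v in enumerate(ffs)},
        )
        water, fat, mask = build_forearm_phantom(spec)
        ff = fat_fraction(
            FatWaterPair(water=water, fat=fat, signal_mask=water + fat > 0)
        )
        for label, truth in spec.muscle_ff_true.items():
            sel = mask.labels == label
            assert ff.ff[sel].mean() == pytest.approx(truth, abs=1e-9)


class TestSimulateEchoes:
    def test_water_only_in_phase_signal(self, flat_field):
        ech = simulate_echoes(np.ones((4, 4)), np.zeros((4, 4)), flat_field)
        for s in (ech.S1, ech.S2, ech.S3):
            np.testing.assert_allclose(s, 1.0, atol=1e-15)

    def test_forward_model_direct_evaluation(self):
        field = FieldSpec(
            phase0_coeffs=np.array([[0.3]]),
            phase_per_echo_coeffs=np.array([[0.8]]),
        )
        w = np.full((3, 3), 0.7)
        f = np.full((3, 3), 0.3)
        ech = simulate_echoes(w, f, field)
        np.testing.assert_allclose(ech.S1, np.exp(0.3j), atol=1e-12)
        np.testing.assert_allclose(ech.S2, 0.4 * np.exp(1.1j), atol=1e-12)
        np.testing.assert_allclose(ech.S3, np.exp(1.9j), atol=1e-12)

    def test_opposed_phase_magnitude_is_water_minus_fat(self, small_spec):
        water, fat, _ = build_forearm_phantom(small_spec)
        ech = simulate_echoes(water, fat)
        np.testing.assert_allclose(np.abs(ech.S2), np.abs(water - fat), atol=1e-10)

    def test_seeded_determinism(self, small_spec):
        water, fat, _ = build_forearm_phantom(small_spec)
        sd = noise_sd_for_snr(small_spec.total_signal, 50.0)
        a = simulate_echoes(water, fat, noise_sd=sd, seed=11)
        b = simulate_echoes(water, fat, noise_sd=sd, seed=11)
        c = simulate_echoes(water, fat, noise_sd=sd, seed=12)
        np.testing.assert_array_equal(a.S1, b.S1)
        np.testing.assert_array_equal(a.S3, b.S3)
        assert not np.array_equal(a.S1, c.S1)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_echoes(np.ones((2, 2)), np.zeros((2, 2)), noise_sd=-1.0)

    def test_field_capture_bound_enforced(self):
        steep = FieldSpec(phase_per_echo_coeffs=np.array([[0.0, 0.0], [400.0, 0.0]]))
        with pytest.raises(ValueError, match="capture"):
            simulate_echoes(np.ones((64, 64)), np.zeros((64, 64)), steep)
        steep.allow_wrap_violation = True
        simulate_echoes(np.ones((64, 64)), np.zeros((64, 64)), steep)


class TestSimulateCohort:
    def test_row_count_matches_attrition(self):
        table = simulate_cohort(CohortSpec(seed=1))
        assert len(table) == 15 + 9 + 7 + 7
        counts = table.groupby("visit_months")["subject_id"].nunique()
        assert counts.tolist() == [15, 9, 7, 7]

    def test_dropout_is_monotone(self):
        table = simulate_cohort(CohortSpec(seed=2))
        for _, grp in table.groupby("subject_id"):
            visits = sorted(grp["visit_months"])
            expected = [v for v in (0, 3, 6, 12) if v <= max(visits)]
            assert visits == expected

    def test_noiseless_changes_exact(self):
        spec = CohortSpec(between_subject_sd=0.0, residual_sd=0.0, seed=3)
        table = simulate_cohort(spec)
        wide = table.pivot(index="subject_id", columns="visit_months", values="value")
        for visit, truth in spec.true_mean_change.items():
            change = (wide[visit] - wide[0]).dropna()
            np.testing.assert_allclose(change, truth, atol=1e-12)

    def test_seeded_determinism(self):
        a = simulate_cohort(CohortSpec(seed=9))
        b = simulate_cohort(CohortSpec(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_monte_carlo_mean_change_matches_truth(self):
        """Empirical 12-month change over 200 cohorts ~ generating truth."""
        means = []
        for s in range(200):
            t = simulate_cohort(CohortSpec(seed=40_000 + s))
            wide = t.pivot(index="subject_id", columns="visit_months", values="value")
            means.append((wide[12] - wide[0]).dropna().mean())
        means = np.asarray(means)
        mc_se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - 5.0) < 3 * mc_se

    def test_exactly_one_subject_off_steroids(self):
        table = simulate_cohort(CohortSpec(seed=4))
        per_subject = table.groupby("subject_id")["steroid"].first()
        assert (~per_subject).sum() == 1

    def test_invalid_cohort_specs(self):
        with pytest.raises(ValueError, match="non-increasing"):
            CohortSpec(n_per_visit=(15, 9, 10, 7))
        with pytest.raises(ValueError, match="baseline"):
            CohortSpec(n_per_visit=(14, 9, 7, 7))
        with pytest.raises(ValueError, match="nonnegative"):
            CohortSpec(residual_sd=-1.0)
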