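import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xyloscan import (GrayProfile, RingTruth, RingWidths, detect_cambium,
                      detect_transition, generate_profile, measure_widths,
                      microtomy_increment)

PITCH = 2.49


def constant_profile(value=25000.0, n=200):
    return GrayProfile(positions=np.arange(n) * PITCH,
                       values=np.full(n, value), kind="cell_wall",
                       voxel_pitch=PITCH)


class TestDetectCambium:
    def test_symmetric_valley_flat_bottom(self):
        # flat bottom centered on a grid point; sides mirror-symmetric
        x = np.arange(200) * PITCH
        center = x[60]
        d = np.abs(x - center)
        u = np.clip((d - 30.0) / 250.0, 0.0, 1.0)
        vals = 10000.0 + 18000.0 * u * u * (3.0 - 2.0 * u)
        prof = GrayProfile(positions=x, values=vals, kind="cell_wall",
                           voxel_pitch=PITCH)
        cam = detect_cambium(prof, (center - 120.0, center + 120.0))
        assert abs(cam - center) <= PITCH

    def test_generator_valley(self, valley_truth):
        prof = generate_profile(valley_truth, 500)
        cam = detect_cambium(prof, (20.0, 320.0))
        assert abs(cam - valley_truth.cambium_pos) <= PITCH

    def test_entirely_constant_window_returns_median(self, valley_truth):
        prof = generate_profile(valley_truth, 500)
        # plateau region: constant, so the run spans the whole window
        cam = detect_cambium(prof, (700.0, 1000.0))
        assert cam == pytest.approx(850.0, abs=PITCH)

    def test_strictly_monotone_window_errors(self, valley_truth):
        prof = generate_profile(valley_truth, 500)
        with pytest.raises(ValueError, match="widen the window"):
            detect_cambium(prof, (250.0, 500.0))

    def test_small_window_rejected(self, valley_truth):
        prof = generate_profile(valley_truth, 500)
        with pytest.raises(ValueError, match="at least 10"):
            detect_cambium(prof, (100.0, 110.0))

    def test_noisy_valley_accuracy(self):
        errs = []
        for seed in range(10):
            truth = RingTruth(cambium_pos=150.0, transition_pos=550.0,
                              prev_boundary_pos=1150.0, phloem_gray=30000.0,
                              cambium_flat_halfwidth=25.0, cambium_gray=8000.0,
                              noise_sd=300.0, ramp="smoothstep", seed=seed)
            prof = generate_profile(truth, 500)
            errs.append(detect_cambium(prof, (20.0, 280.0)) - 150.0)
        assert np.median(np.abs(errs)) < 3 * PITCH


class TestDetectTransition:
    def test_ramp_then_plateau(self):
        truth = RingTruth(cambium_pos=0.01, transition_pos=400.0,
                          prev_boundary_pos=1000.0)
        prof = generate_profile(truth, 402)
        trans, flag = detect_transition(prof, 0.01, 1000.0)
        assert not flag
        assert abs(trans - 400.0) <= 2 * PITCH

    def test_constant_ring_transition_at_zero(self):
        prof = constant_profile()
        trans, flag = detect_transition(prof, 10.0, 480.0)
        assert not flag
        assert trans == 10.0  # distance 0 from the cambium

    def test_monotone_ramp_no_plateau(self):
        truth = RingTruth(cambium_pos=100.0, transition_pos=1100.0,
                          prev_boundary_pos=1100.0, ramp="linear")
        prof = generate_profile(truth, 500)
        trans, flag = detect_transition(prof, 100.0, 1100.0)
        assert flag
        assert trans == 1100.0

    def test_degenerate_ring_errors(self):
        prof = constant_profile(n=50)
        with pytest.raises(ValueError, match="degenerate ring"):
            detect_transition(prof, 0.0, 15.0)

    def test_bad_ordering_errors(self):
        prof = constant_profile()
        with pytest.raises(ValueError, match="precede"):
            detect_transition(prof, 400.0, 100.0)


class TestMeasureWidths:
    def test_arithmetic(self):
        rw = RingWidths(cambium_pos=100.0, prev_boundary_pos=1100.0,
                        transition_pos=500.0, w_incr=1000.0, w_maturing=400.0,
                        w_mat=600.0)
        assert (rw.w_incr, rw.w_maturing, rw.w_mat) == (1000.0, 400.0, 600.0)

    def test_additivity_enforced(self):
        with pytest.raises(ValueError, match="w_maturing \\+ w_mat"):
            RingWidths(cambium_pos=0.0, prev_boundary_pos=100.0,
                       transition_pos=40.0, w_incr=100.0, w_maturing=40.0,
                       w_mat=70.0)

    def test_no_plateau_gives_zero_mature(self):
        truth = RingTruth(cambium_pos=100.0, transition_pos=1100.0,
                          prev_boundary_pos=1100.0, ramp="linear")
        prof = generate_profile(truth, 500)
        rw = measure_widths(prof, 100.0, 1100.0)
        assert rw.no_plateau
        assert rw.w_mat == 0.0
        assert rw.w_maturing == rw.w_incr

    def test_constant_ring_end_of_season(self):
        rw = measure_widths(constant_profile(), 10.0, 480.0)
        assert rw.end_of_season
        assert rw.w_maturing == 0.0
        assert rw.w_mat == rw.w_incr

    def test_recovery_at_2pct_noise(self):
        # 20 seeds; medians of the per-width relative errors within 5%
        rels = {"w_incr": [], "w_maturing": [], "w_mat": []}
        for seed in range(20):
            truth = RingTruth(cambium_pos=150.0, transition_pos=550.0,
                              prev_boundary_pos=1150.0, noise_sd=600.0,
                              seed=seed)
            prof = generate_profile(truth, 520)
            rw = measure_widths(prof, 150.0, 1150.0)
            for name in rels:
                rels[name].append(abs(getattr(rw, name) - getattr(truth, name))
                                  / truth.w_incr)
        for name, vals in rels.items():
            assert np.median(vals) < 0.05, name

    def test_bad_annotation_errors(self):
        with pytest.raises(ValueError, match="exceed"):
            measure_widths(constant_profile(), 480.0, 10.0)


class TestInvariants:
    def test_translation_equivariance(self, ring_truth):
        prof = generate_profile(ring_truth, 520)
        shift = 15 * PITCH  # grid-aligned shift
        shifted = GrayProfile(positions=prof.positions + shift,
                              values=prof.values, kind="cell_wall",
                              voxel_pitch=PITCH)
        rw = measure_widths(prof, 150.0, 1150.0)
        rw2 = measure_widths(shifted, 150.0 + shift, 1150.0 + shift)
        assert rw2.cambium_pos - rw.cambium_pos == pytest.approx(shift)
        assert rw2.transition_pos - rw.transition_pos == pytest.approx(shift, abs=1e-6)
        assert rw2.w_maturing == pytest.approx(rw.w_maturing, abs=1e-6)
        assert rw2.w_mat == pytest.approx(rw.w_mat, abs=1e-6)

    def test_gray_scale_invariance(self, ring_truth):
        prof = generate_profile(ring_truth, 520)
        scaled = GrayProfile(positions=prof.positions, values=prof.values * 1.5,
                             kind="cell_wall", voxel_pitch=PITCH)
        t1, _ = detect_transition(prof, 150.0, 1150.0)
        t2, _ = detect_transition(scaled, 150.0, 1150.0)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_additivity_all_flag_states(self):
        cases = [
            constant_profile(),                                      # end of season
            generate_profile(RingTruth(cambium_pos=100, transition_pos=1100,
                                       prev_boundary_pos=1100, ramp="linear"),
                             500),                                    # no plateau
            generate_profile(RingTruth(cambium_pos=150, transition_pos=550,
                                       prev_boundary_pos=1150, noise_sd=300,
                                       seed=2), 520),                 # mid season
        ]
        bounds = [(10.0, 480.0), (100.0, 1100.0), (150.0, 1150.0)]
        for prof, (c, b) in zip(cases, bounds):
            rw = measure_widths(prof, c, b)
            assert rw.w_maturing + rw.w_mat == pytest.approx(rw.w_incr, abs=1e-9)

    def test_full_chain_recovery_loose(self):
        # detected cambium + detected transition; looser bound than the
        # acceptance criterion because both detection errors accumulate
        errs = []
        for i in range(15):
            frac = (i + 0.5) / 15
            wm = max(frac * 1000.0, 60.0)
            truth = RingTruth(cambium_pos=150.0, transition_pos=150.0 + wm,
                              prev_boundary_pos=1150.0, phloem_gray=30000.0,
                              cambium_flat_halfwidth=min(20.0, wm / 3),
                              cambium_gray=8000.0, noise_sd=300.0,
                              ramp="smoothstep", seed=i)
            prof = generate_profile(truth, 520)
            cam = detect_cambium(prof, (20.0, 280.0))
            rw = measure_widths(prof, cam, 1150.0)
            errs.append(rw.w_maturing - wm)
        assert np.median(np.abs(errs)) < 6 * PITCH


class TestMicrotomyIncrement:
    def test_worked_example(self):
        assert microtomy_increment(600.0, 400.0, 40.0) == 1020.0

    def test_zero(self):
        assert microtomy_increment(0.0, 0.0, 0.0) == 0.0

    @given(w=st.floats(min_value=0, max_value=1e5, allow_nan=False))
    def test_identity_case(self, w):
        assert microtomy_increment(w, 0.0, 0.0) == w

    @given(w_mat=st.floats(0, 1e4), w_maturing=st.floats(0, 1e4),
           w_cambium=st.floats(0, 1e3))
    @settings(max_examples=50)
    def test_formula(self, w_mat, w_maturing, w_cambium):
        assert microtomy_increment(w_mat, w_maturing, w_cambium) == pytest.approx(
            w_mat + w_maturing + w_cambium / 2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            microtomy_increment(-1.0, 0.0, 0.0)
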