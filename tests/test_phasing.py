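"""Cycle detection, phase binning and window assembly."""

import numpy as np
import pytest

from respmotion.phasing import (
    PhaseLabel,
    assign_phases,
    build_windows,
    detect_cycles,
    samples_to_arrays,
    windows_to_frame,
)
from respmotion.simulate import MotionTrace, couple_tumor, WaveformConfig


def _cos4_trace(period=4.0, duration=40.0, fs=30.0, amplitude=8.0):
    t = np.arange(int(duration * fs) + 1) / fs
    ap = amplitude * np.cos(np.pi * t / period) ** 4
    marker = np.column_stack([np.zeros_like(t), ap, np.zeros_like(t)])
    return MotionTrace(subject_id="cos4", sample_rate=fs, time=t, marker=marker)


class TestDetectCycles:
    def test_pure_cos4_peaks_at_analytic_maxima(self):
        # maxima of cos^4(pi t / 4) on [0, 40] sit at t = 0, 4, ..., 40
        trace = _cos4_trace()
        peaks = detect_cycles(trace, nominal_bpm=15.0)
        expected = np.array([round(k * 4.0 * 30.0) for k in range(11)])
        assert len(peaks) == 11
        assert np.all(np.abs(peaks - expected) <= 1)

    def test_matches_generator_ground_truth(self, clean_trace):
        peaks = detect_cycles(clean_trace)
        truth = clean_trace.cycle_starts
        assert len(peaks) == len(truth)
        assert np.all(np.abs(peaks - truth) <= 1)

    def test_constant_trace_rejected(self):
        t = np.arange(100) / 30.0
        marker = np.ones((100, 3))
        trace = MotionTrace("flat", 30.0, t, marker)
        with pytest.raises(ValueError, match="constant"):
            detect_cycles(trace)

    def test_single_cycle_rejected(self):
        trace = _cos4_trace(period=4.0, duration=2.0)
        with pytest.raises(ValueError):
            detect_cycles(trace, nominal_bpm=15.0)


class TestAssignPhases:
    def test_peak_is_phase_zero_and_trough_phase_five(self):
        trace = _cos4_trace()
        starts = detect_cycles(trace, nominal_bpm=15.0)
        labels = assign_phases(trace, starts)
        assert labels[starts[0]] == 0  # end-inhale
        mid = (starts[0] + starts[1]) // 2
        assert labels[mid] == 5  # end-exhale at the symmetric trough

    def test_equal_phase_occupancy_within_cycle(self):
        trace = _cos4_trace()
        starts = detect_cycles(trace, nominal_bpm=15.0)
        labels = assign_phases(trace, starts)
        cycle = labels[starts[0]:starts[1]]
        counts = np.bincount(cycle, minlength=10)
        assert counts.max() - counts.min() <= 1

    def test_amplitude_scaling_invariance(self):
        a = _cos4_trace(amplitude=5.0)
        b = _cos4_trace(amplitude=20.0)
        la = assign_phases(a, detect_cycles(a, nominal_bpm=15.0))
        lb = assign_phases(b, detect_cycles(b, nominal_bpm=15.0))
        assert np.array_equal(la, lb)

    def test_agreement_with_generator_truth(self, clean_trace):
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        mask = (labels >= 0) & (clean_trace.phase_truth >= 0)
        agreement = np.mean(labels[mask] == clean_trace.phase_truth[mask])
        assert agreement >= 0.99

    def test_needs_two_cycle_starts(self, clean_trace):
        with pytest.raises(ValueError):
            assign_phases(clean_trace, [5])


class TestPhaseLabel:
    def test_percent_and_range(self):
        assert PhaseLabel(3).percent == 30
        with pytest.raises(ValueError):
            PhaseLabel(10)


class TestBuildWindows:
    def test_feature_length_and_count(self, clean_trace, regular_profile):
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        windows = build_windows(clean_trace, labels, regular_profile,
                                cycle_starts=starts)
        n_cycles = len(starts) - 1
        assert len(windows) <= 10 * n_cycles
        # interior cycles contribute all 10 phases
        assert len(windows) > 10 * (n_cycles - 1) - 1
        assert all(w.stacked().shape == (33,) for w in windows)

    def test_early_windows_without_history_dropped(self, clean_trace, regular_profile):
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        period = np.diff(clean_trace.time[starts]).mean()
        windows = build_windows(clean_trace, labels, regular_profile,
                                lag=0.3 * period, cycle_starts=starts)
        first_cycle = [w for w in windows if w.cycle_index == 0]
        assert len(first_cycle) < 10

    def test_subject_block_constant_across_steps(self, clean_trace, regular_profile):
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        w = build_windows(clean_trace, labels, regular_profile,
                          cycle_starts=starts)[0]
        assert np.array_equal(w.features_tm2[3:], w.features_t0[3:])
        assert np.array_equal(w.features_tm1[3:], w.features_t0[3:])

    def test_time_ordering_of_marker_steps(self, clean_trace, regular_profile):
        # on a cycle's descending (exhale) limb AP decreases, so
        # T-2 > T-1 > T0 on the AP channel for an exhale-side window
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        windows = build_windows(clean_trace, labels, regular_profile,
                                cycle_starts=starts, max_cycles=1)
        w = [x for x in windows if x.target_phase == 2][0]
        assert w.features_tm2[1] > w.features_tm1[1] > w.features_t0[1]

    def test_excessive_lag_rejected(self, clean_trace, regular_profile):
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        with pytest.raises(ValueError, match="lag"):
            build_windows(clean_trace, labels, regular_profile, lag=100.0,
                          cycle_starts=starts)

    def test_max_cycles_gives_exact_accounting(self, clean_trace, regular_profile):
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        windows = build_windows(clean_trace, labels, regular_profile,
                                cycle_starts=starts, max_cycles=2)
        assert len(windows) == 20

    def test_regression_target_from_coupling(self, clean_trace, regular_profile):
        cfg = WaveformConfig(tumor_gain=1.0, tumor_lag=0.0, tumor_noise_sd=0.0)
        coupled = couple_tumor(clean_trace, cfg, seed=0)
        starts = detect_cycles(coupled)
        labels = assign_phases(coupled, starts)
        windows = build_windows(coupled, labels, regular_profile,
                                cycle_starts=starts, max_cycles=1)
        assert all(w.target_disp is not None for w in windows)
        # identity coupling: end-exhale (phase 5) displacement ~ 0
        p5 = [w.target_disp for w in windows if w.target_phase == 5][0]
        p0 = [w.target_disp for w in windows if w.target_phase == 0][0]
        assert p0 > p5

    def test_serialization_round_trip(self, clean_trace, regular_profile):
        starts = detect_cycles(clean_trace)
        labels = assign_phases(clean_trace, starts)
        windows = build_windows(clean_trace, labels, regular_profile,
                                cycle_starts=starts, max_cycles=1)
        df = windows_to_frame(windows)
        X, phases, disps, subjects = samples_to_arrays(windows)
        feat_cols = [c for c in df.columns if c.startswith(("tm2_", "tm1_", "t0_"))]
        assert np.allclose(df[feat_cols].to_numpy(), X)
        assert np.array_equal(df["target_phase"].to_numpy(dtype=int), phases)
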