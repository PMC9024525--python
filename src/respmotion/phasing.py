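"""Breathing-cycle detection, 10-phase labelling and window assembly.

A breathing cycle runs from one end-inhale chest peak to the next and is cut
into 10 equal-duration respiratory phases (0% = end-inhale, 50% =
end-exhale).  Each phase bin yields one training record holding the marker
coordinates at three time-lagged instants (T-2, T-1, T0) concatenated with
the 8 subject specifics — 11 features per time step, 33 per record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .simulate import MotionTrace, SubjectProfile

__all__ = [
    "PhaseLabel",
    "WindowedSample",
    "detect_cycles",
    "assign_phases",
    "build_windows",
    "windows_to_frame",
    "samples_to_arrays",
]

N_PHASES = 10
N_FEATURES_PER_STEP = 11  # 3 marker coords + 8 subject specifics
#: default T-1/T-2 spacing as a fraction of the cycle period.  One phase bin
#: (0.10) is too narrow: the cos^4 waveform dwells flat around end-exhale, so
#: lagged features one bin apart differ by less than the marker noise there;
#: 1.5 bins spans the dwell and keeps the window inside one cycle.
DEFAULT_LAG_FRACTION = 0.15


@dataclass(frozen=True)
class PhaseLabel:
    """One of the 10 respiratory phases; phase percent = 10 * index."""

    index: int

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 9:
            raise ValueError("phase index must lie in 0..9")

    @property
    def percent(self) -> int:
        return self.index * 10


@dataclass
class WindowedSample:
    """One record: marker features at T-2/T-1/T0 plus subject specifics.

    Each ``features_*`` vector is (marker x, y, z) followed by the 8 subject
    features; the subject block is identical across the three time steps.
    """

    features_tm2: np.ndarray
    features_tm1: np.ndarray
    features_t0: np.ndarray
    subject_id: str
    cycle_index: int
    target_phase: Optional[int] = None
    target_disp: Optional[float] = None

    def stacked(self) -> np.ndarray:
        """Concatenated 33-vector in (T-2, T-1, T0) order."""
        return np.concatenate(
            [self.features_tm2, self.features_tm1, self.features_t0]
        )


def _estimate_period(ap: np.ndarray, fs: float) -> float:
    """Dominant breathing period via the FFT of the detrended AP channel."""
    x = ap - ap.mean()
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    k = int(np.argmax(spectrum[1:])) + 1  # skip DC
    if freqs[k] <= 0:
        raise ValueError("could not estimate a breathing period from the trace")
    return 1.0 / freqs[k]


def detect_cycles(trace: MotionTrace, nominal_bpm: Optional[float] = None) -> np.ndarray:
    """Find end-inhale peaks (cycle starts) on the AP marker channel.

    Peaks must exceed 20% of the signal's peak-to-peak prominence and be at
    least half the nominal period apart; the nominal period comes from
    ``nominal_bpm`` when given, otherwise from the dominant FFT component.
    Trace endpoints that are themselves cycle peaks are recovered explicitly
    (a boundary sample can never be a local maximum).
    """
    ap = trace.ap
    ptp = float(np.ptp(ap))
    if ptp < 1e-9:
        raise ValueError("AP channel is constant; no breathing cycles to detect")
    period = 60.0 / nominal_bpm if nominal_bpm else _estimate_period(ap, trace.sample_rate)
    min_dist = max(1, int(round(0.5 * period * trace.sample_rate)))
    prominence = 0.2 * ptp
    peaks, _ = find_peaks(ap, distance=min_dist, prominence=prominence)

    # boundary recovery: an endpoint dominating its first/last half-period
    w = max(2, min_dist)
    height_floor = ap.max() - 0.5 * ptp
    if (not len(peaks) or peaks[0] >= min_dist) and ap[0] >= ap[1:w].max() and ap[0] >= height_floor:
        peaks = np.concatenate([[0], peaks])
    n = len(ap)
    if (not len(peaks) or peaks[-1] <= n - 1 - min_dist) and ap[-1] >= ap[n - w:-1].max() and ap[-1] >= height_floor:
        peaks = np.concatenate([peaks, [n - 1]])

    if len(peaks) < 2:
        raise ValueError(
            f"found {len(peaks)} end-inhale peak(s); need >= 2 to delimit a cycle"
        )
    return peaks.astype(int)


def assign_phases(trace: MotionTrace, cycle_starts: Sequence[int]) -> np.ndarray:
    """Label every sample with its respiratory phase 0..9 (-1 outside cycles).

    Each cycle [peak_k, peak_{k+1}) is cut into 10 equal-duration bins; bin j
    is phase j (0 = end-inhale at the peak, 5 = end-exhale mid-cycle).
    """
    cycle_starts = np.asarray(cycle_starts, dtype=int)
    if len(cycle_starts) < 2:
        raise ValueError("need >= 2 cycle starts to assign phases")
    labels = np.full(len(trace.time), -1, dtype=int)
    for s, e in zip(cycle_starts[:-1], cycle_starts[1:]):
        idx = np.arange(s, e)
        labels[idx] = np.minimum((N_PHASES * (idx - s)) // (e - s), N_PHASES - 1)
    return labels


def build_windows(
    trace: MotionTrace,
    labels: np.ndarray,
    profile: SubjectProfile,
    lag: Optional[float] = None,
    cycle_starts: Optional[Sequence[int]] = None,
    max_cycles: Optional[int] = None,
) -> list[WindowedSample]:
    """Assemble one windowed record per (cycle, phase bin).

    Each record is anchored at the bin midpoint ``t0`` with marker features
    linearly interpolated at ``t0``, ``t0 - lag`` and ``t0 - 2*lag``.  The
    default lag is ``DEFAULT_LAG_FRACTION`` (0.15) of the mean cycle period
    — wide enough to resolve the flat end-exhale dwell.  Windows whose
    earliest instant precedes the trace start are dropped.  With
    ``max_cycles`` set, only the first ``max_cycles`` cycles that yield a
    complete set of 10 windows are kept — the per-repeat accounting used for
    cohort generation.
    """
    labels = np.asarray(labels, dtype=int)
    if cycle_starts is None:
        if trace.cycle_starts is not None:
            cycle_starts = trace.cycle_starts
        else:
            # recover boundaries from label resets (9 -> 0 transitions)
            starts = [i for i in range(len(labels))
                      if labels[i] == 0 and (i == 0 or labels[i - 1] != 0)]
            cycle_starts = starts
    cycle_starts = np.asarray(cycle_starts, dtype=int)
    if len(cycle_starts) < 2:
        raise ValueError("trace must contain >= 2 cycle starts")

    periods = np.diff(trace.time[cycle_starts])
    mean_period = float(periods.mean())
    if lag is None:
        lag = DEFAULT_LAG_FRACTION * mean_period
    if lag <= 0:
        raise ValueError("lag must be positive")
    if lag >= mean_period:
        raise ValueError(
            f"lag {lag:.3f}s reaches beyond one breathing cycle "
            f"({mean_period:.3f}s); windows would be ambiguous"
        )

    subject_vec = profile.feature_vector()
    t = trace.time

    def features_at(when: float) -> np.ndarray:
        coords = [np.interp(when, t, trace.marker[:, c]) for c in range(3)]
        return np.concatenate([coords, subject_vec])

    per_cycle: list[list[WindowedSample]] = []
    for k, (s, e) in enumerate(zip(cycle_starts[:-1], cycle_starts[1:])):
        period = trace.time[e] - trace.time[s]
        bin_width = period / N_PHASES
        cycle_windows = []
        for j in range(N_PHASES):
            t0 = trace.time[s] + (j + 0.5) * bin_width
            if t0 - 2 * lag < t[0]:
                continue  # insufficient history for the lagged steps
            disp = (
                float(np.interp(t0, t, trace.tumor_disp))
                if trace.tumor_disp is not None
                else None
            )
            cycle_windows.append(
                WindowedSample(
                    features_tm2=features_at(t0 - 2 * lag),
                    features_tm1=features_at(t0 - lag),
                    features_t0=features_at(t0),
                    subject_id=profile.subject_id,
                    cycle_index=k,
                    target_phase=j,
                    target_disp=disp,
                )
            )
        per_cycle.append(cycle_windows)

    if max_cycles is None:
        return [w for cyc in per_cycle for w in cyc]
    out: list[WindowedSample] = []
    kept = 0
    for cyc in per_cycle:
        if len(cyc) == N_PHASES:
            out.extend(cyc)
            kept += 1
            if kept == max_cycles:
                break
    return out


_STEP_NAMES = ("tm2", "tm1", "t0")
_FEATURE_NAMES = (
    "marker_x", "marker_y", "marker_z",
    "age", "weight", "height", "bpm", "heart_rate",
    "tumor_mid_x", "tumor_mid_y", "tumor_mid_z",
)


def windows_to_frame(samples: Sequence[WindowedSample]) -> pd.DataFrame:
    """Serialize windowed records as a flat table (33 feature columns)."""
    rows = []
    for s in samples:
        row = {"subject_id": s.subject_id, "cycle_index": s.cycle_index}
        for step, vec in zip(
            _STEP_NAMES, (s.features_tm2, s.features_tm1, s.features_t0)
        ):
            for name, value in zip(_FEATURE_NAMES, vec):
                row[f"{step}_{name}"] = value
        row["target_phase"] = s.target_phase if s.target_phase is not None else np.nan
        row["target_disp"] = s.target_disp if s.target_disp is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def samples_to_arrays(
    samples: Sequence[WindowedSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack records into (X, phase, displacement, subject) arrays.

    X has shape (n, 33) in (T-2, T-1, T0) block order; missing targets are
    -1 (phase) or NaN (displacement).
    """
    X = np.array([s.stacked() for s in samples])
    phases = np.array(
        [s.target_phase if s.target_phase is not None else -1 for s in samples]
    )
    disps = np.array(
        [s.target_disp if s.target_disp is not None else np.nan for s in samples]
    )
    subjects = np.array([s.subject_id for s in samples])
    return X, phases, disps, subjects
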