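"""Synthetic pseudopatient breathing cohorts.

Emulates the data a chest-wall surrogate tracker records during lung
radiotherapy: a marker block on the xiphoid process whose anterior-posterior
(AP) excursion follows the breathing waveform, plus the subject specifics
(age, weight, height, breathing rate, heart rate, tumor midpoint) that feed
the downstream networks.  The waveform is the standard Lujan-type
``cos^(2n)`` respiratory model; irregular breathers add per-cycle amplitude
and period jitter, baseline drift and occasional shallow cycles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "BreathingPattern",
    "BpmClass",
    "SubjectProfile",
    "WaveformConfig",
    "MotionTrace",
    "BPM_RANGES",
    "sample_profile",
    "generate_trace",
    "couple_tumor",
    "generate_cohort",
]


class BreathingPattern(str, Enum):
    REGULAR = "regular"
    IRREGULAR = "irregular"


class BpmClass(str, Enum):
    LOW = "low"  # < 12 bpm
    NORMAL = "normal"  # 12-20 bpm
    HIGH = "high"  # > 20 bpm


#: breaths-per-minute sampling interval per class (low <12, normal 12-20, high >20)
BPM_RANGES = {
    BpmClass.LOW: (8.0, 12.0),
    BpmClass.NORMAL: (12.0, 20.0),
    BpmClass.HIGH: (20.0, 30.0),
}


@dataclass
class SubjectProfile:
    """Subject specifics used as the 8 static input features."""

    subject_id: str
    age: int  # years
    weight: float  # kg
    height: float  # cm
    bpm: float  # breaths per minute
    heart_rate: float  # beats per minute
    tumor_midpoint: tuple[float, float, float]  # mm
    pattern: BreathingPattern = BreathingPattern.REGULAR
    bpm_class: BpmClass = BpmClass.NORMAL

    def feature_vector(self) -> np.ndarray:
        """The 8 subject-specific features, in canonical order."""
        return np.array(
            [
                float(self.age),
                self.weight,
                self.height,
                self.bpm,
                self.heart_rate,
                *self.tumor_midpoint,
            ],
            dtype=float,
        )


@dataclass
class WaveformConfig:
    """Breathing-waveform and coupling parameters.

    ``amplitude`` is the AP chest peak-to-peak excursion in mm.  The waveform
    is ``baseline + amplitude * cos^(2*shape_exponent)(pi * t / period)``, so
    end-inhale (chest peak) sits at cycle start.  Jitter/drift/shallow
    parameters only apply to irregular breathers.  ``tumor_gain`` maps the AP
    chest excursion to longitudinal (cranio-caudal) tumor displacement.
    """

    amplitude: float = 8.0  # mm
    shape_exponent: int = 2  # cos^(2n); n=2 gives the cos^4 dwell at exhale
    sample_rate: float = 30.0  # Hz (depth-camera frame rate)
    amplitude_jitter_sd: float = 0.30  # fraction, per cycle
    period_jitter_sd: float = 0.20  # fraction, per cycle
    baseline_drift_sd: float = 0.30  # mm per cycle, random walk
    shallow_cycle_prob: float = 0.20
    shallow_factor: float = 0.30  # shallow-cycle amplitude fraction
    marker_noise_sd: float = 0.10  # mm, AP channel measurement noise
    lateral_jitter_sd: float = 0.20  # mm, x/z marker channels
    tumor_gain: float = 1.4  # mm tumor per mm chest excursion
    tumor_lag: float = 0.15  # s, tumor lags the surrogate
    tumor_noise_sd: float = 0.20  # mm

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.shape_exponent < 1:
            raise ValueError("shape_exponent must be >= 1")
        if not 0.0 <= self.shallow_cycle_prob <= 1.0:
            raise ValueError("shallow_cycle_prob must lie in [0, 1]")
        for name in (
            "amplitude_jitter_sd",
            "period_jitter_sd",
            "baseline_drift_sd",
            "marker_noise_sd",
            "lateral_jitter_sd",
            "tumor_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MotionTrace:
    """A uniformly sampled marker-block trajectory with optional ground truth.

    ``marker`` columns are (x, y, z) = (lateral, anterior-posterior,
    longitudinal) in mm; the AP column carries the breathing waveform.
    ``phase_truth`` uses -1 for samples outside complete cycles.
    """

    subject_id: str
    sample_rate: float
    time: np.ndarray
    marker: np.ndarray  # (n, 3)
    tumor_disp: Optional[np.ndarray] = None
    phase_truth: Optional[np.ndarray] = None
    cycle_starts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.marker = np.asarray(self.marker, dtype=float)
        if self.marker.ndim != 2 or self.marker.shape[1] != 3:
            raise ValueError("marker must be an (n, 3) array")
        if self.marker.shape[0] != self.time.shape[0]:
            raise ValueError("marker and time must have equal length")
        steps = np.diff(self.time)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(
                steps, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9)):
            raise ValueError("time must increase uniformly at 1/sample_rate")
        for name in ("tumor_disp", "phase_truth"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.time):
                raise ValueError(f"{name} must match time length")

    @property
    def ap(self) -> np.ndarray:
        """Anterior-posterior marker channel (the breathing surrogate)."""
        return self.marker[:, 1]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self.time) else 0.0


def sample_profile(
    pattern: BreathingPattern | str,
    bpm_class: BpmClass | str,
    seed: int,
    subject_id: str = "S000",
) -> SubjectProfile:
    """Draw one subject uniformly from the study population ranges.

    Age 45-65 y, weight 50-80 kg, height 150-185 cm, heart rate 60-100 bpm;
    breathing rate uniform within the requested bpm class; tumor midpoint
    uniform in a lung-sized box.
    """
    pattern = BreathingPattern(pattern)
    bpm_class = BpmClass(bpm_class)
    rng = np.random.default_rng(seed)
    lo, hi = BPM_RANGES[bpm_class]
    return SubjectProfile(
        subject_id=subject_id,
        age=int(rng.integers(45, 66)),
        weight=float(rng.uniform(50.0, 80.0)),
        height=float(rng.uniform(150.0, 185.0)),
        bpm=float(rng.uniform(lo, hi)),
        heart_rate=float(rng.uniform(60.0, 100.0)),
        tumor_midpoint=(
            float(rng.uniform(-80.0, 80.0)),
            float(rng.uniform(-60.0, 60.0)),
            float(rng.uniform(-100.0, 100.0)),
        ),
        pattern=pattern,
        bpm_class=bpm_class,
    )


def _cycle_plan(
    profile: SubjectProfile,
    config: WaveformConfig,
    duration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle (start time, period, amplitude, baseline) covering duration."""
    nominal = 60.0 / profile.bpm
    starts, periods, amps, baselines = [], [], [], []
    t, baseline = 0.0, 0.0
    irregular = profile.pattern is BreathingPattern.IRREGULAR
    while t < duration:
        if irregular:
            period = nominal * max(0.4, 1.0 + rng.normal(0.0, config.period_jitter_sd))
            amp = config.amplitude * max(0.15, 1.0 + rng.normal(0.0, config.amplitude_jitter_sd))
            if rng.uniform() < config.shallow_cycle_prob:
                amp = config.amplitude * config.shallow_factor
            baseline += rng.normal(0.0, config.baseline_drift_sd)
        else:
            period, amp = nominal, config.amplitude
        starts.append(t)
        periods.append(period)
        amps.append(amp)
        baselines.append(baseline)
        t += period
    return (np.array(starts), np.array(periods), np.array(amps), np.array(baselines))


def generate_trace(
    profile: SubjectProfile,
    config: WaveformConfig,
    duration: float,
    seed: int,
) -> MotionTrace:
    """Simulate one marker-block trace for a subject.

    Regular breathers follow a strictly periodic ``cos^(2n)`` waveform with
    period 60/bpm; irregular breathers perturb each cycle per the config.
    Ground-truth phase labels and cycle-start indices come straight from the
    generator's cycle plan.
    """
    nominal = 60.0 / profile.bpm
    if duration < 3.0 * nominal:
        raise ValueError(
            f"duration {duration:.2f}s must cover >= 3 breathing cycles "
            f"({3 * nominal:.2f}s at {profile.bpm:.1f} bpm)"
        )
    rng = np.random.default_rng(seed)
    starts, periods, amps, baselines = _cycle_plan(profile, config, duration, rng)

    fs = config.sample_rate
    n = int(np.floor(duration * fs)) + 1
    time = np.arange(n) / fs
    # locate each sample's cycle and its fractional position u in [0, 1)
    idx = np.searchsorted(starts, time, side="right") - 1
    u = (time - starts[idx]) / periods[idx]
    ap = baselines[idx] + amps[idx] * np.cos(np.pi * u) ** (2 * config.shape_exponent)

    marker = np.column_stack(
        [
            rng.normal(0.0, config.lateral_jitter_sd, n),
            ap + rng.normal(0.0, config.marker_noise_sd, n),
            rng.normal(0.0, config.lateral_jitter_sd, n),
        ]
    )
    # ground truth on the sample grid, matching the downstream convention:
    # cycle starts snap to the nearest sample (the sampled-waveform argmax
    # for a symmetric peak) and phases are equal integer-index bins between
    # consecutive start samples; samples outside complete cycles get -1
    in_range = starts <= time[-1] + 0.5 / fs
    cycle_starts = np.unique(
        np.clip(np.round(starts[in_range] * fs).astype(int), 0, n - 1)
    )
    phase_truth = np.full(n, -1, dtype=int)
    for s, e in zip(cycle_starts[:-1], cycle_starts[1:]):
        idx = np.arange(s, e)
        phase_truth[idx] = np.minimum((10 * (idx - s)) // (e - s), 9)
    return MotionTrace(
        subject_id=profile.subject_id,
        sample_rate=fs,
        time=time,
        marker=marker,
        phase_truth=phase_truth,
        cycle_starts=cycle_starts,
    )


def surrogate_excursion(trace: MotionTrace) -> np.ndarray:
    """AP marker excursion above its per-cycle baseline (minimum)."""
    ap = trace.ap
    if trace.cycle_starts is None or len(trace.cycle_starts) < 2:
        return ap - ap.min()
    bounds = list(trace.cycle_starts) + [len(ap)]
    excursion = np.empty_like(ap)
    # samples before the first cycle start borrow the first cycle's baseline
    first_base = ap[bounds[0]:bounds[1]].min()
    excursion[: bounds[0]] = ap[: bounds[0]] - first_base
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < 2:
            excursion[s:e] = ap[s:e] - first_base
            continue
        excursion[s:e] = ap[s:e] - ap[s:e].min()
    return excursion


def couple_tumor(
    trace: MotionTrace,
    config: WaveformConfig,
    seed: int,
) -> MotionTrace:
    """Attach longitudinal tumor displacement to a trace.

    ``tumor(t) = gain * excursion(t - lag) + noise`` where ``excursion`` is
    the AP chest excursion above its per-cycle baseline; the edge before
    ``lag`` holds the first excursion value.
    """
    if config.tumor_lag >= trace.duration:
        raise ValueError("tumor_lag must be shorter than the trace duration")
    rng = np.random.default_rng(seed)
    excursion = surrogate_excursion(trace)
    shifted = np.interp(
        trace.time - config.tumor_lag, trace.time, excursion,
        left=excursion[0], right=excursion[-1],
    )
    tumor = config.tumor_gain * shifted
    if config.tumor_noise_sd > 0:
        tumor = tumor + rng.normal(0.0, config.tumor_noise_sd, len(tumor))
    return dataclasses.replace(trace, tumor_disp=tumor)


@dataclass
class CohortMember:
    profile: SubjectProfile
    config: WaveformConfig
    traces: list[MotionTrace] = field(default_factory=list)


@dataclass
class Cohort:
    members: list[CohortMember]
    manifest: dict

    def __iter__(self):
        return iter(self.members)


def _bpm_assignment(n_subjects: int, bpm_mix: Optional[dict]) -> list[BpmClass]:
    classes = [BpmClass.LOW, BpmClass.NORMAL, BpmClass.HIGH]
    if bpm_mix is None:
        return [classes[i % 3] for i in range(n_subjects)]
    mix = {BpmClass(k): int(v) for k, v in bpm_mix.items()}
    if sum(mix.values()) != n_subjects:
        raise ValueError(
            f"bpm_mix totals {sum(mix.values())} but the pattern group has "
            f"{n_subjects} subjects"
        )
    out: list[BpmClass] = []
    for cls in classes:
        out.extend([cls] * mix.get(cls, 0))
    return out


def generate_cohort(
    n_regular: int,
    n_irregular: int,
    repeats: int,
    config: WaveformConfig | None = None,
    seed: int = 0,
    bpm_mix: Optional[dict] = None,
    cycles_per_trace: int = 1,
    amplitude_range: tuple[float, float] = (4.0, 12.0),
    tumor_gain_range: tuple[float, float] = (0.8, 2.0),
    train_fraction: float = 2.0 / 3.0,
    with_tumor: bool = True,
) -> Cohort:
    """Generate a full pseudopatient cohort.

    One trace per subject x repeat, each long enough to contribute
    ``cycles_per_trace`` complete 10-phase cycles after windowing, so the
    cohort yields ``10 * cycles_per_trace * subjects * repeats`` phase-level
    samples downstream.  Per-subject AP amplitude and tumor gain are drawn
    from ``amplitude_range`` / ``tumor_gain_range``.  The manifest records a
    recording-level train/test split (each subject's repeats interleaved so
    the pattern-group fraction is exact) stratified by breathing pattern so
    regular and irregular contribute equally.
    """
    if n_regular < 0 or n_irregular < 0 or n_regular + n_irregular == 0:
        raise ValueError("subject counts must be non-negative and total > 0")
    if repeats < 1:
        raise ValueError("repeats must be positive")
    config = config or WaveformConfig()
    root = np.random.SeedSequence(seed)
    members: list[CohortMember] = []
    split: dict[str, str] = {}

    groups = [
        (BreathingPattern.REGULAR, n_regular),
        (BreathingPattern.IRREGULAR, n_irregular),
    ]
    sid = 0
    for pattern, count in groups:
        if count == 0:
            continue
        bpm_classes = _bpm_assignment(count, bpm_mix)
        group_ids: list[str] = []
        for j in range(count):
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            subject_id = f"{'P' if pattern is BreathingPattern.REGULAR else 'Q'}{sid:03d}"
            profile = sample_profile(
                pattern, bpm_classes[j],
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=subject_id,
            )
            subj_config = dataclasses.replace(
                config,
                amplitude=float(rng.uniform(*amplitude_range)),
                tumor_gain=float(rng.uniform(*tumor_gain_range)),
            )
            member = CohortMember(profile=profile, config=subj_config)
            # 2.5 extra cycles: warm-up history for the lagged windows plus slack
            duration = (cycles_per_trace + 2.5) * 60.0 / profile.bpm
            for r in range(repeats):
                trace_seed = int(rng.integers(0, 2**31 - 1))
                trace = generate_trace(profile, subj_config, duration, trace_seed)
                if with_tumor:
                    trace = couple_tumor(
                        trace, subj_config, seed=int(rng.integers(0, 2**31 - 1))
                    )
                member.traces.append(trace)
            members.append(member)
            group_ids.append(subject_id)
            sid += 1
        # recording-level split, exact at the group level: walk repeats-major
        # so every subject contributes to both partitions
        n_train_traces = int(round(train_fraction * count * repeats))
        k = 0
        for r in range(repeats):
            for subject_id in group_ids:
                split[f"{subject_id}:{r}"] = "train" if k < n_train_traces else "test"
                k += 1

    manifest = {
        "seed": seed,
        "repeats": repeats,
        "cycles_per_trace": cycles_per_trace,
        "n_regular": n_regular,
        "n_irregular": n_irregular,
        "train_fraction": train_fraction,
        "split": split,
        "subjects": {
            m.profile.subject_id: {
                "pattern": m.profile.pattern.value,
                "bpm_class": m.profile.bpm_class.value,
                "bpm": m.profile.bpm,
                "amplitude": m.config.amplitude,
                "tumor_gain": m.config.tumor_gain,
            }
            for m in members
        },
    }
    return Cohort(members=members, manifest=manifest)
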