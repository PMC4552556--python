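"""Synthetic tri-axial acceleration + pressure traces for the beaver ethogram.

Each labelled segment is composed, per axis, of

    posture_mean + segment-level posture offset + sway sinusoid + white noise

sampled at 8 Hz (acceleration, clipped to the sensor range of +/-4 g) and
2 Hz (pressure, mB). The segment offset is drawn from N(0, jitter_sd) where
jitter_sd comes from decomposing the published per-axis raw SDs
(:func:`castoract.calibrate.posture_jitter_sd`); the white-noise SD is solved
per segment so that the mean ODBA measured through the 2-s running-mean
pipeline lands on a per-segment draw from N(odba_target, odba_sd).

Dives add a piecewise-linear depth profile (pressure = surface + 98.1 mB/m),
a 0.91-g static heave during submersion and a 1-s v-shaped dip in heave and
surge at initiation. Sleep sessions are semi-Markov sequences over four lying
postures with exponential dwell times and brief high-dynamism turns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .calibrate import (
    calibrate_noise_sd,
    oscillation_odba_floor,
    posture_jitter_sd,
    solve_noise_sd,
)
from .profiles import (
    AXES,
    CLASSIFIED_BEHAVIOURS,
    BehaviourProfile,
    Oscillation,
    SleepPosture,
    default_behaviour_profiles,
)

__all__ = [
    "AccelTrace",
    "LabeledSegment",
    "simulate_segment",
    "simulate_dive",
    "simulate_sleep_session",
    "simulate_dataset",
    "concatenate_segments",
    "ACCEL_RANGE_G",
    "PRESSURE_RANGE_MB",
    "MB_PER_METRE",
    "SURFACE_PRESSURE_MB",
]

ACCEL_RANGE_G = (-4.0, 4.0)
PRESSURE_RANGE_MB = (950.0, 10_000.0)
#: hydrostatic gradient in fresh water
MB_PER_METRE = 98.1
SURFACE_PRESSURE_MB = 1013.0


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration with optional pressure channel."""

    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray
    pressure: Optional[np.ndarray] = None
    sample_rate_accel: float = 8.0
    sample_rate_pressure: float = 2.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.surge = np.asarray(self.surge, dtype=float)
        self.sway = np.asarray(self.sway, dtype=float)
        self.heave = np.asarray(self.heave, dtype=float)
        if not (len(self.surge) == len(self.sway) == len(self.heave)):
            raise ValueError("acceleration channels must have equal length")
        for name in ("surge", "sway", "heave"):
            ch = getattr(self, name)
            if len(ch) and (ch.min() < ACCEL_RANGE_G[0] or ch.max() > ACCEL_RANGE_G[1]):
                raise ValueError(f"{name} samples outside sensor range {ACCEL_RANGE_G} g")
        if self.pressure is not None:
            self.pressure = np.asarray(self.pressure, dtype=float)
            lo, hi = PRESSURE_RANGE_MB
            if len(self.pressure) and (
                self.pressure.min() < lo or self.pressure.max() > hi
            ):
                raise ValueError(f"pressure samples outside sensor range {PRESSURE_RANGE_MB} mB")
            expected = self.n_samples * self.sample_rate_pressure / self.sample_rate_accel
            if abs(len(self.pressure) - expected) > 1.0:
                raise ValueError(
                    "pressure channel length inconsistent with sample rates: "
                    f"{len(self.pressure)} vs expected ~{expected:.1f}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.surge)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_accel

    @property
    def times(self) -> np.ndarray:
        """Sample times (s) of the acceleration channels."""
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_accel

    @property
    def pressure_times(self) -> Optional[np.ndarray]:
        if self.pressure is None:
            return None
        return self.start_time_s + np.arange(len(self.pressure)) / self.sample_rate_pressure

    def axes(self) -> np.ndarray:
        """(3, n) array in (surge, sway, heave) order."""
        return np.vstack([self.surge, self.sway, self.heave])

    def slice(self, t0: float, t1: float) -> "AccelTrace":
        """Sub-trace covering [t0, t1) in absolute time."""
        if t1 <= t0:
            raise ValueError("t1 must be > t0")
        ia0 = int(round((t0 - self.start_time_s) * self.sample_rate_accel))
        ia1 = int(round((t1 - self.start_time_s) * self.sample_rate_accel))
        ia0, ia1 = max(ia0, 0), min(ia1, self.n_samples)
        pressure = None
        if self.pressure is not None:
            ip0 = int(round((t0 - self.start_time_s) * self.sample_rate_pressure))
            ip1 = int(round((t1 - self.start_time_s) * self.sample_rate_pressure))
            pressure = self.pressure[max(ip0, 0): min(ip1, len(self.pressure))]
        return AccelTrace(
            self.surge[ia0:ia1],
            self.sway[ia0:ia1],
            self.heave[ia0:ia1],
            pressure=pressure,
            sample_rate_accel=self.sample_rate_accel,
            sample_rate_pressure=self.sample_rate_pressure,
            start_time_s=self.start_time_s + ia0 / self.sample_rate_accel,
        )


@dataclass
class LabeledSegment:
    """A behaviour-labelled slice of a trace."""

    segment_id: str
    label: str
    start_s: float
    end_s: float
    trace: AccelTrace
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("end_s must be > start_s")
        if self.duration_s < 2.0:
            raise ValueError("segments must last at least 2 s (smoothing window)")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@lru_cache(maxsize=64)
def _profile_calibration(
    profile: BehaviourProfile, sample_rate: float, window_s: float
) -> tuple[float, tuple[float, ...]]:
    """Cached (nominal noise SD, per-axis jitter SD) for a profile."""
    sigma = calibrate_noise_sd(
        profile, window_s, sample_rate=sample_rate, floor_slack=math.inf
    )
    jitter = posture_jitter_sd(
        profile, sigma, sample_rate=sample_rate, window_s=window_s
    )
    return sigma, tuple(jitter)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _oscillation_signal(
    osc: Oscillation, n: int, sample_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, float, float]:
    """Sway sinusoid samples plus the realized (amplitude, frequency).

    Per-segment draws: half-amplitude A ~ |N(amp_mean, amp_sd)|, frequency
    f ~ N(freq_mean, freq_sd) (clipped below Nyquist), uniform phase. With
    ``amp_per_cycle`` the amplitude is redrawn at each full cycle boundary;
    the reported amplitude is then the mean of the per-cycle draws.
    """
    amp = abs(rng.normal(osc.amp_mean, osc.amp_sd))
    freq = float(np.clip(rng.normal(osc.freq_mean, osc.freq_sd), 0.02, 0.49 * sample_rate))
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / sample_rate
    theta = 2.0 * np.pi * freq * t + phase
    if not osc.amp_per_cycle:
        return amp * np.sin(theta), amp, freq
    cycle = np.floor(theta / (2.0 * np.pi)).astype(int)
    cycle -= cycle.min()
    n_cycles = cycle.max() + 1
    amps = np.abs(rng.normal(osc.amp_mean, osc.amp_sd, size=n_cycles))
    return amps[cycle] * np.sin(theta), float(amps.mean()), freq


def _draw_segment_odba(
    profile: BehaviourProfile,
    rng: np.random.Generator,
    floor: float,
) -> float:
    """Per-segment mean-ODBA level ~ N(odba_target, odba_sd), kept feasible."""
    lo = floor + 1e-4
    hi = profile.odba_target + 4.0 * profile.odba_sd
    draw = rng.normal(profile.odba_target, profile.odba_sd)
    return float(np.clip(draw, lo, max(hi, lo)))


def simulate_segment(
    profile: BehaviourProfile,
    duration_s: Optional[float] = None,
    seed=None,
    *,
    sample_rate: float = 8.0,
    pressure_rate: float = 2.0,
    window_s: float = 2.0,
    segment_id: str = "seg-0",
    start_s: float = 0.0,
    surface_pressure_mB: float = SURFACE_PRESSURE_MB,
) -> LabeledSegment:
    """Simulate one labelled segment of a (non-dive, non-sleep) behaviour.

    The white-noise SD is re-solved for each segment so that the segment's
    expected pipeline ODBA equals a draw from N(odba_target, odba_sd) given
    the realized oscillation amplitude/frequency; the between-segment posture
    offset uses the raw-SD decomposition of the profile. Identical seeds give
    bit-identical traces.
    """
    if profile.posture_mean is None:
        raise ValueError(
            f"profile {profile.label!r} has no single posture; use "
            "simulate_sleep_session for sleeping"
        )
    if duration_s is None:
        duration_s = profile.segment_duration_s
    if duration_s < 2.0:
        raise ValueError("duration_s must be >= 2 s")
    rng = _as_rng(seed)
    n = int(round(duration_s * sample_rate))

    # 1) oscillation draw (sway only)
    if profile.oscillation is not None:
        osc_signal, amp, freq = _oscillation_signal(
            profile.oscillation, n, sample_rate, rng
        )
        if profile.oscillation.amp_per_cycle:
            # expected ODBA integrates over the per-cycle amplitude law
            floor = oscillation_odba_floor(
                profile.oscillation, freq=freq,
                sample_rate=sample_rate, window_s=window_s, n_samples=n,
            )
        else:
            floor = oscillation_odba_floor(
                profile.oscillation, amp=amp, freq=freq,
                sample_rate=sample_rate, window_s=window_s, n_samples=n,
            )
    else:
        osc_signal, amp, freq = np.zeros(n), 0.0, float("nan")
        floor = 0.0

    # 2) per-segment ODBA level and the noise SD that realizes it
    odba_seg = _draw_segment_odba(profile, rng, floor)
    if profile.oscillation is not None and profile.oscillation.amp_per_cycle:
        sigma_seg = solve_noise_sd(
            odba_seg, profile.oscillation, freq=freq,
            sample_rate=sample_rate, window_s=window_s, n_samples=n,
        )
    else:
        sigma_seg = solve_noise_sd(
            odba_seg, profile.oscillation, amp=amp, freq=freq,
            sample_rate=sample_rate, window_s=window_s, n_samples=n,
        )

    # 3) segment-level posture offset from the raw-SD decomposition
    _, jitter = _profile_calibration(profile, sample_rate, window_s)
    offset = rng.normal(0.0, np.asarray(jitter))

    # 4) compose
    noise = rng.normal(0.0, sigma_seg, size=(3, n)) if sigma_seg > 0 else np.zeros((3, n))
    mean = np.asarray(profile.posture_mean)[:, None] + offset[:, None]
    signal = mean + noise
    signal[1] += osc_signal
    signal = np.clip(signal, *ACCEL_RANGE_G)

    n_p = int(round(duration_s * pressure_rate))
    pressure = np.full(n_p, surface_pressure_mB)

    trace = AccelTrace(
        signal[0], signal[1], signal[2],
        pressure=pressure,
        sample_rate_accel=sample_rate,
        sample_rate_pressure=pressure_rate,
        start_time_s=start_s,
    )
    meta = {"odba_draw": odba_seg, "noise_sd": sigma_seg}
    if profile.oscillation is not None:
        meta.update({"osc_amp": amp, "osc_freq": freq})
    return LabeledSegment(
        segment_id=segment_id,
        label=profile.label,
        start_s=start_s,
        end_s=start_s + duration_s,
        trace=trace,
        meta=meta,
    )


def _dive_depth(
    t: np.ndarray, max_depth_m: float, descent_s: float, bottom_s: float, ascent_s: float
) -> np.ndarray:
    """Piecewise-linear depth profile (m) of a v/u-shaped dive."""
    d = np.zeros_like(t)
    t1, t2 = descent_s, descent_s + bottom_s
    t3 = t2 + ascent_s
    desc = (t >= 0) & (t < t1)
    bot = (t >= t1) & (t < t2)
    asc = (t >= t2) & (t <= t3)
    d[desc] = max_depth_m * t[desc] / descent_s
    d[bot] = max_depth_m
    d[asc] = max_depth_m * (t3 - t[asc]) / ascent_s
    return np.clip(d, 0.0, max_depth_m)


def simulate_dive(
    max_depth_m: float,
    descent_s: float = 13.0,
    bottom_s: float = 4.0,
    ascent_s: float = 13.0,
    seed=None,
    *,
    profile: Optional[BehaviourProfile] = None,
    sample_rate: float = 8.0,
    pressure_rate: float = 2.0,
    window_s: float = 2.0,
    segment_id: str = "dive-0",
    start_s: float = 0.0,
    surface_pressure_mB: float = SURFACE_PRESSURE_MB,
    transient_amp_g: float = 0.4,
    transient_s: float = 1.0,
) -> LabeledSegment:
    """Simulate a dive: stretched-out posture, v-shaped initiation transient,
    and a hydrostatic pressure channel.

    Depth is piecewise linear (descent/bottom/ascent); pressure is
    ``surface + 98.1 mB per metre``. The static heave sits at the diving
    posture (0.91 g) throughout submersion and a ``transient_s``-long
    half-sine dip of ``-transient_amp_g`` in heave and surge marks the
    initiation. ODBA is calibrated exactly like any other segment
    (target 0.233 g for the default diving profile).
    """
    if min(descent_s, ascent_s) <= 0 or bottom_s < 0:
        raise ValueError("descent_s and ascent_s must be > 0, bottom_s >= 0")
    if max_depth_m <= 0:
        raise ValueError("max_depth_m must be > 0")
    peak = surface_pressure_mB + MB_PER_METRE * max_depth_m
    if peak > PRESSURE_RANGE_MB[1]:
        raise ValueError(
            f"dive to {max_depth_m} m implies pressure {peak:.0f} mB beyond the "
            f"sensor range {PRESSURE_RANGE_MB[1]:.0f} mB"
        )
    if profile is None:
        profile = default_behaviour_profiles()["diving"]
    duration_s = descent_s + bottom_s + ascent_s
    seg = simulate_segment(
        profile,
        duration_s,
        seed,
        sample_rate=sample_rate,
        pressure_rate=pressure_rate,
        window_s=window_s,
        segment_id=segment_id,
        start_s=start_s,
        surface_pressure_mB=surface_pressure_mB,
    )
    tr = seg.trace
    t = np.arange(tr.n_samples) / sample_rate
    dip = -transient_amp_g * np.sin(np.pi * np.clip(t / transient_s, 0.0, 1.0))
    dip[t > transient_s] = 0.0
    tr.heave = np.clip(tr.heave + dip, *ACCEL_RANGE_G)
    tr.surge = np.clip(tr.surge + dip, *ACCEL_RANGE_G)
    t_p = np.arange(len(tr.pressure)) / pressure_rate
    depth = _dive_depth(t_p, max_depth_m, descent_s, bottom_s, ascent_s)
    tr.pressure = surface_pressure_mB + MB_PER_METRE * depth
    seg.meta.update(
        max_depth_m=max_depth_m,
        descent_s=descent_s,
        bottom_s=bottom_s,
        ascent_s=ascent_s,
    )
    return seg


def simulate_sleep_session(
    duration_s: float,
    seed=None,
    *,
    mean_dwell_s: float = 600.0,
    min_dwell_s: float = 60.0,
    turn_s: float = 5.0,
    turn_noise_sd: float = 0.15,
    posture_jitter_g: float = 0.2,
    profile: Optional[BehaviourProfile] = None,
    sample_rate: float = 8.0,
    pressure_rate: float = 2.0,
    window_s: float = 2.0,
    segment_id: str = "sleep-0",
    start_s: float = 0.0,
    surface_pressure_mB: float = SURFACE_PRESSURE_MB,
) -> LabeledSegment:
    """Simulate a sleep session: a semi-Markov walk over four lying postures.

    Postures (back, belly-sitting, left side, right side) put gravity on a
    single axis (+/-1 g) with N(0, ``posture_jitter_g``) offsets on the other
    two, drawn per bout. Dwell times are exponential with mean
    ``mean_dwell_s`` (floored at ``min_dwell_s`` so bouts stay resolvable),
    separated by ``turn_s``-long high-dynamism turns that interpolate between
    postures. Within-posture ODBA is calibrated to the sleeping target
    (0.057 g). The bout schedule is stored in ``meta["postures"]`` as
    (start_s, end_s, posture_name) tuples.
    """
    if duration_s < 600.0:
        raise ValueError("sleep sessions must last at least 600 s")
    if profile is None:
        profile = default_behaviour_profiles()["sleeping"]
    postures: Sequence[SleepPosture] = profile.sleep_postures or ()
    if not postures:
        raise ValueError("profile carries no sleep posture repertoire")
    rng = _as_rng(seed)
    n = int(round(duration_s * sample_rate))
    signal = np.empty((3, n))

    # schedule bouts
    bouts: list[tuple[float, float, int]] = []  # (t0, t1, posture index)
    turns: list[tuple[float, float]] = []
    t = 0.0
    current = int(rng.integers(len(postures)))
    while t < duration_s:
        dwell = max(float(rng.exponential(mean_dwell_s)), min_dwell_s)
        t1 = min(t + dwell, duration_s)
        bouts.append((t, t1, current))
        t = t1
        if t >= duration_s:
            break
        turns.append((t, min(t + turn_s, duration_s)))
        t = min(t + turn_s, duration_s)
        nxt = int(rng.integers(len(postures) - 1))
        current = nxt if nxt < current else nxt + 1

    base_sigma = solve_noise_sd(
        profile.odba_target, None, sample_rate=sample_rate, window_s=window_s
    )
    vectors: list[np.ndarray] = []
    for (t0, t1, pi) in bouts:
        vec = np.array(postures[pi].unit_vector())
        jitter = rng.normal(0.0, posture_jitter_g, size=3)
        jitter[np.abs(vec) > 0] = 0.0
        vectors.append(vec + jitter)
    for k, (t0, t1, pi) in enumerate(bouts):
        i0, i1 = int(round(t0 * sample_rate)), int(round(t1 * sample_rate))
        odba_bout = max(float(rng.normal(profile.odba_target, profile.odba_sd)), 1e-3)
        sigma = base_sigma * odba_bout / profile.odba_target
        signal[:, i0:i1] = vectors[k][:, None] + rng.normal(0.0, sigma, size=(3, i1 - i0))
    for k, (t0, t1) in enumerate(turns):
        i0, i1 = int(round(t0 * sample_rate)), int(round(t1 * sample_rate))
        if i1 <= i0:
            continue
        frac = np.linspace(0.0, 1.0, i1 - i0)
        v0, v1 = vectors[k], vectors[min(k + 1, len(vectors) - 1)]
        ramp = v0[:, None] + (v1 - v0)[:, None] * frac[None, :]
        signal[:, i0:i1] = ramp + rng.normal(0.0, turn_noise_sd, size=(3, i1 - i0))

    signal = np.clip(signal, *ACCEL_RANGE_G)
    n_p = int(round(duration_s * pressure_rate))
    trace = AccelTrace(
        signal[0], signal[1], signal[2],
        pressure=np.full(n_p, surface_pressure_mB),
        sample_rate_accel=sample_rate,
        sample_rate_pressure=pressure_rate,
        start_time_s=start_s,
    )
    meta = {
        "postures": [
            (t0 + start_s, t1 + start_s, postures[pi].name) for (t0, t1, pi) in bouts
        ],
        "turns": [(t0 + start_s, t1 + start_s) for (t0, t1) in turns],
    }
    return LabeledSegment(
        segment_id=segment_id,
        label="sleeping",
        start_s=start_s,
        end_s=start_s + duration_s,
        trace=trace,
        meta=meta,
    )


def simulate_dataset(
    n_per_class: int,
    seed=None,
    *,
    profiles: Optional[dict[str, BehaviourProfile]] = None,
    sample_rate: float = 8.0,
    window_s: float = 2.0,
    dive_depth_range_m: tuple[float, float] = (1.0, 3.0),
) -> list[LabeledSegment]:
    """Labelled segments for the six classified behaviours, n per class.

    Durations follow the observation protocol the signatures came from: 10 s
    for the transient behaviours (standing, walking), 60 s for swimming,
    grooming and feeding, and 30-s dives (13 s descent / 4 s bottom / 13 s
    ascent) with maximum depths drawn uniformly from ``dive_depth_range_m``.
    Sleeping is generated by :func:`simulate_sleep_session` only and is not
    part of the classifier dataset. Deterministic given ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if profiles is None:
        profiles = default_behaviour_profiles()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(CLASSIFIED_BEHAVIOURS))
    segments: list[LabeledSegment] = []
    for child, label in zip(children, CLASSIFIED_BEHAVIOURS):
        prof = profiles[label]
        rng = np.random.default_rng(child)
        for i in range(n_per_class):
            seg_id = f"{label}-{i:04d}"
            if label == "diving":
                depth = float(rng.uniform(*dive_depth_range_m))
                seg = simulate_dive(
                    depth,
                    seed=rng,
                    profile=prof,
                    sample_rate=sample_rate,
                    window_s=window_s,
                    segment_id=seg_id,
                )
            else:
                seg = simulate_segment(
                    prof,
                    prof.segment_duration_s,
                    seed=rng,
                    sample_rate=sample_rate,
                    window_s=window_s,
                    segment_id=seg_id,
                )
            segments.append(seg)
    return segments


def concatenate_segments(segments: Sequence[LabeledSegment]) -> tuple[AccelTrace, list[LabeledSegment]]:
    """Stitch segments into one continuous trace with re-based time bounds.

    Returns the combined trace and new segments whose ``start_s``/``end_s``
    refer to positions within it (traces are shared slices, not copies).
    """
    if not segments:
        raise ValueError("no segments to concatenate")
    fs_a = segments[0].trace.sample_rate_accel
    fs_p = segments[0].trace.sample_rate_pressure
    surge = np.concatenate([s.trace.surge for s in segments])
    sway = np.concatenate([s.trace.sway for s in segments])
    heave = np.concatenate([s.trace.heave for s in segments])
    has_pressure = all(s.trace.pressure is not None for s in segments)
    pressure = (
        np.concatenate([s.trace.pressure for s in segments]) if has_pressure else None
    )
    trace = AccelTrace(
        surge, sway, heave, pressure=pressure,
        sample_rate_accel=fs_a, sample_rate_pressure=fs_p,
    )
    rebased = []
    t = 0.0
    for s in segments:
        d = s.trace.duration_s
        sub = s.trace
        sub = AccelTrace(
            sub.surge, sub.sway, sub.heave, pressure=sub.pressure,
            sample_rate_accel=fs_a, sample_rate_pressure=fs_p, start_time_s=t,
        )
        rebased.append(
            LabeledSegment(s.segment_id, s.label, t, t + d, sub, dict(s.meta))
        )
        t += d
    return trace, rebased
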