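"""Windowed feature extraction and sleep/posture coding.

Each labelled segment is summarised by the 8-dimensional vector used for
classification: means of the static surge/sway/heave channels (posture),
SDs of the raw channels (movement variability), and mean + SD of the
per-sample ODBA series (movement intensity). Sleep periods are found as
low-ODBA runs and coded into the four lying postures from the static axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .signal import DecomposedTrace, decompose
from .simulate import AccelTrace, LabeledSegment

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "extract_features",
    "features_table",
    "segment_trace",
    "classify_lying_posture",
    "SleepBout",
    "detect_sleep",
]

FEATURE_NAMES = (
    "mean_surge",
    "mean_sway",
    "mean_heave",
    "sd_surge",
    "sd_sway",
    "sd_heave",
    "mean_odba",
    "sd_odba",
)


@dataclass(frozen=True)
class FeatureVector:
    """Summary features of one segment (all in g); ``label`` optional."""

    mean_surge: float
    mean_sway: float
    mean_heave: float
    sd_surge: float
    sd_sway: float
    sd_heave: float
    mean_odba: float
    sd_odba: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("features must be finite")
        if min(self.sd_surge, self.sd_sway, self.sd_heave, self.sd_odba) < 0:
            raise ValueError("SD features must be >= 0")
        if self.mean_odba < 0:
            raise ValueError("mean ODBA must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def extract_features(
    segment: Union[AccelTrace, LabeledSegment],
    *,
    window_s: float = 2.0,
    means_from: str = "static",
    sds_from: str = "raw",
) -> FeatureVector:
    """The 8 summary features of a segment.

    Axis means are taken from the static (2-s running mean) channels and axis
    SDs from the raw channels by default; both choices are switchable
    (``means_from``/``sds_from`` in {"static", "raw"}) since the published
    magnitudes support static means but raw SDs.
    """
    label = segment.label if isinstance(segment, LabeledSegment) else None
    trace = segment.trace if isinstance(segment, LabeledSegment) else segment
    if trace.duration_s < 2.0:
        raise ValueError("segments must last at least 2 s")
    for arg, name in ((means_from, "means_from"), (sds_from, "sds_from")):
        if arg not in ("static", "raw"):
            raise ValueError(f"{name} must be 'static' or 'raw', got {arg!r}")
    dec = decompose(trace, window_s=window_s)
    raw = trace.axes()
    mean_src = dec.static if means_from == "static" else raw
    sd_src = raw if sds_from == "raw" else dec.static
    means = mean_src.mean(axis=1)
    sds = sd_src.std(axis=1, ddof=1)
    return FeatureVector(
        mean_surge=float(means[0]),
        mean_sway=float(means[1]),
        mean_heave=float(means[2]),
        sd_surge=float(sds[0]),
        sd_sway=float(sds[1]),
        sd_heave=float(sds[2]),
        mean_odba=float(dec.odba.mean()),
        sd_odba=float(dec.odba.std(ddof=1)),
        label=label,
    )


def features_table(
    segments: Sequence[LabeledSegment],
    *,
    window_s: float = 2.0,
    means_from: str = "static",
    sds_from: str = "raw",
) -> pd.DataFrame:
    """Feature table (segment_id, label, 8 feature columns) for many segments."""
    rows = []
    for seg in segments:
        fv = extract_features(
            seg, window_s=window_s, means_from=means_from, sds_from=sds_from
        )
        rows.append(
            {"segment_id": seg.segment_id, "label": seg.label}
            | {name: getattr(fv, name) for name in FEATURE_NAMES}
        )
    return pd.DataFrame(rows, columns=["segment_id", "label", *FEATURE_NAMES])


def segment_trace(
    trace: AccelTrace,
    window_s: float,
    step_s: Optional[float] = None,
    *,
    label: Optional[str] = None,
    id_prefix: str = "win",
) -> list[LabeledSegment]:
    """Cut a trace into fixed-length windows (non-overlapping by default).

    ``step_s`` defaults to ``window_s``; a partial tail window is dropped.
    """
    if window_s > trace.duration_s:
        raise ValueError("window_s exceeds the trace duration")
    if step_s is None:
        step_s = window_s
    if step_s <= 0 or window_s <= 0:
        raise ValueError("window_s and step_s must be > 0")
    out = []
    t0 = trace.start_time_s
    k = 0
    while t0 + window_s <= trace.start_time_s + trace.duration_s + 1e-9:
        sub = trace.slice(t0, t0 + window_s)
        out.append(
            LabeledSegment(
                segment_id=f"{id_prefix}-{k:05d}",
                label=label or "unlabelled",
                start_s=t0,
                end_s=t0 + window_s,
                trace=sub,
            )
        )
        k += 1
        t0 += step_s
    return out


def classify_lying_posture(
    static_vector: Sequence[float], threshold_g: float = 0.5
) -> str:
    """Code a static (surge, sway, heave) vector into a lying posture.

    Gravity dominantly on one axis identifies the posture: heave towards
    -1 g means lying on the back, sway towards -1/+1 g the left/right side,
    surge towards +1 g sitting on the belly. Checked in that precedence
    order at ``threshold_g``; anything else is indeterminate.
    """
    surge, sway, heave = (float(x) for x in static_vector)
    if heave <= -threshold_g:
        return "back"
    if sway <= -threshold_g:
        return "left_side"
    if sway >= threshold_g:
        return "right_side"
    if surge >= threshold_g:
        return "belly_sitting"
    return "indeterminate"


@dataclass
class SleepBout:
    """A detected low-ODBA (sleep) bout with its posture sequence.

    ``postures`` lists (window_start_s, posture) per analysis window;
    ``turns`` the times at which the coded posture changed to a new posture
    that persisted for at least one window.
    """

    start_s: float
    end_s: float
    postures: list[tuple[float, str]]
    turns: list[float]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_sleep(
    decomposed: DecomposedTrace,
    odba_thresh: float = 0.08,
    min_bout_s: float = 300.0,
    *,
    window_s: float = 30.0,
    bridge_windows: int = 1,
) -> list[SleepBout]:
    """Find sleep bouts as sustained low-ODBA runs and code their postures.

    The trace is scanned in ``window_s`` windows; windows with mean ODBA
    below ``odba_thresh`` are sleep candidates. Runs of candidates lasting at
    least ``min_bout_s`` become bouts; up to ``bridge_windows`` consecutive
    above-threshold windows inside a run are bridged (posture turns are brief
    high-dynamism events that should not split a night's sleep). Each
    window's posture comes from its mean static vector; a turn is recorded
    when the coded posture changes and the new posture persists for at least
    one full window.
    """
    fs = decomposed.sample_rate
    wlen = int(round(window_s * fs))
    n_win = decomposed.n_samples // wlen
    if n_win == 0:
        return []
    odba_w = np.array(
        [decomposed.odba[i * wlen: (i + 1) * wlen].mean() for i in range(n_win)]
    )
    is_sleep = odba_w < odba_thresh

    # bridge short above-threshold gaps between sleep windows
    bridged = is_sleep.copy()
    i = 0
    while i < n_win:
        if not is_sleep[i]:
            j = i
            while j < n_win and not is_sleep[j]:
                j += 1
            if 0 < i and j < n_win and (j - i) <= bridge_windows:
                bridged[i:j] = True
            i = j
        else:
            i += 1

    bouts: list[SleepBout] = []
    min_windows = int(np.ceil(min_bout_s / window_s))
    i = 0
    while i < n_win:
        if bridged[i]:
            j = i
            while j < n_win and bridged[j]:
                j += 1
            if j - i >= min_windows:
                postures = []
                for k in range(i, j):
                    static_vec = decomposed.static[:, k * wlen: (k + 1) * wlen].mean(axis=1)
                    postures.append((k * window_s, classify_lying_posture(static_vec)))
                turns = []
                prev = postures[0][1]
                for t, post in postures[1:]:
                    if post != prev and post != "indeterminate":
                        turns.append(t)
                        prev = post
                bouts.append(
                    SleepBout(
                        start_s=i * window_s,
                        end_s=j * window_s,
                        postures=postures,
                        turns=turns,
                    )
                )
            i = j
        else:
            i += 1
    return bouts
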