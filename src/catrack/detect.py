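"""Calcium-transient detection and per-neuron activity summaries.

A transient is a run of frames on the 5-frame boxcar-smoothed detrended
trace that stays above ``f0_offset + 3 x noise_sd`` for at least 10
consecutive frames (1.0 s at 10 Hz; "more than 9 frames"). Peaks closer
than 15 frames (1.5 s) are merged, keeping the higher peak. The minimum
peak height of 3 noise sd is guaranteed by the threshold and checked before
merging.

Per-session activity is summarized as transients per minute and as the area
under the positive part of the ΔF/F curve per minute, and categorized as
rarely (< 0.25), intermediately (0.25-4) or highly (> 4 transients/min)
active. A neuron is "active" if it shows at least one transient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from ._filters import boxcar_smooth
from .traces import ConditionedTrace

__all__ = [
    "TransientEvent",
    "ActivitySummary",
    "detect_transients",
    "transient_rate",
    "auc_per_min",
    "classify_activity",
    "summarize_activity",
    "CATEGORIES",
    "RATE_RARE_MAX",
    "RATE_HIGH_MIN",
]

CATEGORIES = ("rare", "intermediate", "high")
RATE_RARE_MAX = 0.25  # transients/min; below this a neuron is rarely active
RATE_HIGH_MIN = 4.0  # transients/min; above this a neuron is highly active


@dataclass
class TransientEvent:
    """One detected calcium transient (frame indices are 0-based)."""

    onset_frame: int
    offset_frame: int
    peak_frame: int
    peak_height: float  # in noise_sd units above f0_offset
    peak_dff: float

    def __post_init__(self) -> None:
        if not (self.onset_frame <= self.peak_frame <= self.offset_frame):
            raise ValueError("event must satisfy onset <= peak <= offset")


@dataclass
class ActivitySummary:
    """Per-neuron, per-session activity measures."""

    neuron_id: int
    session_id: int
    transients_per_min: float
    auc_per_min: float
    category: str
    is_active: bool
    n_events: int
    flags: tuple = ()


def _find_runs(above: np.ndarray):
    """Start and end (inclusive) indices of maximal True runs."""
    a = np.asarray(above, dtype=bool)
    if a.size == 0:
        return np.empty(0, int), np.empty(0, int)
    d = np.diff(a.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if a[0]:
        starts = np.concatenate(([0], starts))
    if a[-1]:
        ends = np.concatenate((ends, [a.size - 1]))
    return starts, ends


def detect_transients(
    cond: ConditionedTrace,
    smooth_frames: int = 5,
    k_sd: float = 3.0,
    duration_frames: int = 10,
    min_distance_frames: int = 15,
) -> List[TransientEvent]:
    """Detect transients on the smoothed detrended trace.

    Supra-threshold runs (strictly above ``f0_offset + k_sd * noise_sd``)
    lasting at least ``duration_frames`` frames carry the events; candidate
    peaks are the local maxima of the smoothed trace within those runs, all
    of which satisfy the minimum peak height of ``k_sd`` by construction
    (checked before merging); peaks closer than ``min_distance_frames`` are
    merged by iterative greedy suppression keeping the higher peak. A run
    holding several surviving peaks is split at the minima between them, so
    closely spaced transients that never dip below threshold are still
    resolved as separate events.

    Raises ``ValueError`` for ``noise_sd <= 0`` (degenerate trace — the
    caller should flag and exclude the neuron).
    """
    if cond.noise_sd <= 0:
        raise ValueError("detection refused: noise_sd must be positive")
    smoothed = boxcar_smooth(cond.detrended, smooth_frames)
    threshold = cond.f0_offset + k_sd * cond.noise_sd
    starts, ends = _find_runs(smoothed > threshold)
    # candidate peaks: local maxima of the smoothed trace above threshold;
    # the k_sd prominence floor keeps noise wiggles riding on a transient's
    # tail from splitting one event into several
    cand, _ = find_peaks(smoothed, height=threshold, prominence=k_sd * cond.noise_sd)
    cand = set(int(p) for p in cand)
    run_of = {}
    candidates = []  # (peak_frame, run_index)
    valid_runs = []
    for s, e in zip(starts, ends):
        if e - s + 1 < duration_frames:
            continue
        ri = len(valid_runs)
        valid_runs.append((int(s), int(e)))
        in_run = sorted(p for p in cand if s <= p <= e)
        if not in_run:
            # monotone run (e.g. truncated at a trace boundary): use argmax
            in_run = [int(s + np.argmax(smoothed[s : e + 1]))]
        for p in in_run:
            if (smoothed[p] - cond.f0_offset) / cond.noise_sd >= k_sd:
                candidates.append((p, ri))
            run_of[p] = ri
    # iterative greedy minimum-distance suppression: highest peak wins
    candidates.sort(key=lambda c: (-smoothed[c[0]], c[0]))
    kept: List[tuple] = []
    for p, ri in candidates:
        if all(abs(p - q) >= min_distance_frames for q, _ in kept):
            kept.append((p, ri))
    kept.sort()
    events = []
    has_dff = np.isfinite(cond.dff).all()
    by_run: dict = {}
    for p, ri in kept:
        by_run.setdefault(ri, []).append(p)
    for ri, peaks_in_run in sorted(by_run.items()):
        s, e = valid_runs[ri]
        # split the run between adjacent surviving peaks at the local minimum
        bounds = [s]
        for p0, p1 in zip(peaks_in_run[:-1], peaks_in_run[1:]):
            bounds.append(p0 + int(np.argmin(smoothed[p0 : p1 + 1])))
        bounds.append(e)
        for i, p in enumerate(peaks_in_run):
            o0 = bounds[i] if i == 0 else bounds[i] + 1
            o1 = bounds[i + 1]
            height = (smoothed[p] - cond.f0_offset) / cond.noise_sd
            peak_dff = float(cond.dff[p]) if has_dff else float("nan")
            events.append(
                TransientEvent(
                    onset_frame=int(o0),
                    offset_frame=int(o1),
                    peak_frame=int(p),
                    peak_height=float(height),
                    peak_dff=peak_dff,
                )
            )
    events.sort(key=lambda ev: ev.peak_frame)
    return events


def transient_rate(events: Sequence, duration_s: float) -> float:
    """Event frequency in transients per minute."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return 60.0 * len(events) / duration_s


def auc_per_min(dff: np.ndarray, duration_s: float) -> float:
    """Integral of the positive part of ΔF/F over time, per minute.

    The positive-part convention is deliberate: a signed integral of a
    zero-baseline trace cancels noise symmetrically and measures nothing.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    dff = np.asarray(dff, dtype=np.float64)
    dt = duration_s / dff.shape[0]
    area = float(np.trapezoid(np.clip(dff, 0.0, None), dx=dt))
    return area * 60.0 / duration_s


def classify_activity(rate: float) -> str:
    """Activity category from the transient rate (transients/min).

    Boundaries are inclusive to the intermediate class: rare < 0.25,
    intermediate 0.25-4, high > 4.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate < RATE_RARE_MAX:
        return "rare"
    if rate <= RATE_HIGH_MIN:
        return "intermediate"
    return "high"


def summarize_activity(
    cond: ConditionedTrace,
    events: Optional[Sequence[TransientEvent]] = None,
    **detect_kwargs,
) -> ActivitySummary:
    """Detect (if needed) and summarize one neuron-session."""
    flags = list(cond.flags)
    if events is None:
        if cond.noise_sd <= 0:
            events = []
            flags.append("detection_refused")
        else:
            events = detect_transients(cond, **detect_kwargs)
    duration = cond.duration_s
    rate = transient_rate(events, duration)
    if "nonpositive_f0_raw" in flags or not np.isfinite(cond.dff).all():
        auc = float("nan")
    else:
        auc = auc_per_min(cond.dff, duration)
    return ActivitySummary(
        neuron_id=cond.neuron_id if cond.neuron_id is not None else -1,
        session_id=cond.session_id if cond.session_id is not None else -1,
        transients_per_min=rate,
        auc_per_min=auc,
        category=classify_activity(rate),
        is_active=len(events) > 0,
        n_events=len(events),
        flags=tuple(flags),
    )
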