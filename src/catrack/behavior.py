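"""Behavioral epoch segmentation from a binary whisking track.

Head-fixed mice alternate long quiet-wakefulness phases with brief whisking
(or grooming) bouts. Whisking bouts shorter than 330 ms are too brief to be
aligned with the slow calcium indicator and are dropped. Because the
indicator decays over seconds, whisk-associated neuronal activity is read
out in a window of up to 2 s *after* whisking offset (kept only if at least
1 s survives truncation by the next bout); stationary activity excludes
whisk frames, whisk-associated windows, and the discarded short windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "Epoch",
    "EpochSet",
    "detect_whisk_epochs",
    "whisk_response_windows",
    "stationary_mask",
]


@dataclass(frozen=True)
class Epoch:
    onset_frame: int
    offset_frame: int  # inclusive
    epoch_class: str  # whisk | stationary | excluded

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1


@dataclass
class EpochSet:
    epochs: List[Epoch]
    frame_rate_hz: float
    n_frames: int

    def whisk_epochs(self) -> List[Epoch]:
        return [e for e in self.epochs if e.epoch_class == "whisk"]

    def mask(self, epoch_class: str) -> np.ndarray:
        m = np.zeros(self.n_frames, dtype=bool)
        for e in self.epochs:
            if e.epoch_class == epoch_class:
                m[e.onset_frame : e.offset_frame + 1] = True
        return m


def _runs_of_ones(track: np.ndarray) -> List[Tuple[int, int]]:
    t = np.asarray(track).astype(np.int8)
    d = np.diff(t)
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if t.size and t[0]:
        starts.insert(0, 0)
    if t.size and t[-1]:
        ends.append(t.size - 1)
    return list(zip(starts, ends))


def detect_whisk_epochs(
    track: np.ndarray, frame_rate_hz: float, min_duration_s: float = 0.33
) -> EpochSet:
    """Segment a binary whisking track into whisk and stationary epochs.

    Maximal runs of 1 lasting at least ``ceil(min_duration_s * frame_rate)``
    frames (4 frames at 10 Hz) become whisk epochs; shorter runs are
    reclassified as stationary.
    """
    track = np.asarray(track)
    if not np.isin(track, (0, 1)).all():
        raise ValueError("whisking track must be binary")
    min_frames = max(1, math.ceil(min_duration_s * frame_rate_hz - 1e-9))
    whisks = [
        Epoch(s, e, "whisk") for s, e in _runs_of_ones(track) if e - s + 1 >= min_frames
    ]
    # everything outside kept whisk runs is (so far) stationary
    epochs: List[Epoch] = []
    cursor = 0
    for w in whisks:
        if w.onset_frame > cursor:
            epochs.append(Epoch(cursor, w.onset_frame - 1, "stationary"))
        epochs.append(w)
        cursor = w.offset_frame + 1
    if cursor < track.size:
        epochs.append(Epoch(cursor, track.size - 1, "stationary"))
    return EpochSet(epochs=epochs, frame_rate_hz=frame_rate_hz, n_frames=track.size)


def whisk_response_windows(
    epochs: EpochSet,
    w_min_s: float = 1.0,
    w_max_s: float = 2.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Frames carrying whisk-associated activity.

    For each whisk epoch the window spans the ``w_max_s`` seconds after its
    offset, truncated at the next whisk onset or the track end; windows left
    shorter than ``w_min_s`` are discarded. Returns ``(mask, discarded)``:
    the whisk-associated frame mask and the frames of discarded windows
    (excluded from every epoch class).
    """
    fr = epochs.frame_rate_hz
    n = epochs.n_frames
    w_max_f = int(round(w_max_s * fr))
    w_min_f = int(round(w_min_s * fr))
    whisks = epochs.whisk_epochs()
    mask = np.zeros(n, dtype=bool)
    discarded = np.zeros(n, dtype=bool)
    for i, w in enumerate(whisks):
        start = w.offset_frame + 1
        stop = min(w.offset_frame + w_max_f, n - 1)  # inclusive
        if i + 1 < len(whisks):
            stop = min(stop, whisks[i + 1].onset_frame - 1)
        if stop < start:
            continue
        if stop - start + 1 >= w_min_f:
            mask[start : stop + 1] = True
        else:
            discarded[start : stop + 1] = True
    return mask, discarded


def stationary_mask(
    epochs: EpochSet,
    whisk_assoc_mask: np.ndarray,
    discarded_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Frames in neither a whisk epoch, a whisk-associated window, nor a
    discarded short window."""
    whisk_assoc_mask = np.asarray(whisk_assoc_mask, dtype=bool)
    if whisk_assoc_mask.shape[0] != epochs.n_frames:
        raise ValueError("mask length does not match the epoch set")
    out = ~epochs.mask("whisk") & ~whisk_assoc_mask
    if discarded_mask is not None:
        out &= ~np.asarray(discarded_mask, dtype=bool)
    return out
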