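"""Fluorescence trace conditioning.

Raw somatic fluorescence from an awake two-photon recording is contaminated
by neuropil signal, slow drift (bleaching, brain-state fluctuations) and
shot noise. The conditioning chain implemented here is:

1. neuropil compensation
       F_comp[t] = F_roi[t] + factor * (median(F_neuropil) - F_neuropil[t])
   with ``factor`` defaulting to 0.7;
2. low-pass filtering at 5 Hz (skipped, with a logged notice, when the
   cutoff reaches the Nyquist frequency — at the native 10 Hz frame rate the
   step is a no-op by construction);
3. slow-trend removal by subtracting the running 8th percentile in a
   centered ±50 s window;
4. baseline (F0) and noise estimation from the "noise band": the detrended
   trace minus its running 8th percentile in a ±0.5 s window, restricted to
   quiescent frames (residual below its 60th percentile);
5. ΔF/F = (detrended - f0_offset) / f0_raw, where f0_raw is the median of
   the compensated, low-passed but *not* trend-subtracted trace over the
   quiescent frames (detrending removes the absolute baseline that the
   denominator needs).

All detection thresholds downstream are expressed in units of the noise
standard deviation, so the chain is invariant to affine rescaling of the
raw fluorescence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

from ._filters import moving_percentile

logger = logging.getLogger(__name__)

__all__ = [
    "RawTracePair",
    "ConditionedTrace",
    "compensate_neuropil",
    "lowpass_and_detrend",
    "estimate_f0_and_noise",
    "compute_dff",
    "condition_trace",
]


@dataclass
class RawTracePair:
    """Raw somatic and surrounding-neuropil fluorescence of one neuron."""

    f_roi: np.ndarray
    f_neuropil: np.ndarray
    frame_rate_hz: float
    neuron_id: Optional[int] = None
    session_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.f_roi = np.asarray(self.f_roi, dtype=np.float64)
        self.f_neuropil = np.asarray(self.f_neuropil, dtype=np.float64)
        if self.f_roi.shape != self.f_neuropil.shape:
            raise ValueError("ROI and neuropil traces must have equal length")
        if self.f_roi.size == 0:
            raise ValueError("empty trace")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")


@dataclass
class ConditionedTrace:
    """Output of the conditioning chain for one neuron and session."""

    dff: np.ndarray
    detrended: np.ndarray
    f0_offset: float
    f0_raw: float
    noise_sd: float
    quiescent_mask: np.ndarray
    frame_rate_hz: float
    neuron_id: Optional[int] = None
    session_id: Optional[int] = None
    params_used: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.detrended.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


def compensate_neuropil(f_roi, f_neuropil=None, factor: float = 0.7) -> np.ndarray:
    """Subtract the fluctuating part of the neuropil signal from the ROI trace.

    ``out[t] = f_roi[t] + factor * (median(f_neuropil) - f_neuropil[t])``.
    Adding back the neuropil median keeps the trace on the raw-fluorescence
    scale, so a constant neuropil leaves the ROI trace unchanged.

    Accepts either a :class:`RawTracePair` or two equal-length arrays.
    """
    if isinstance(f_roi, RawTracePair):
        pair = f_roi
        f_roi, f_neuropil = pair.f_roi, pair.f_neuropil
    f_roi = np.asarray(f_roi, dtype=np.float64)
    f_neuropil = np.asarray(f_neuropil, dtype=np.float64)
    if f_roi.shape != f_neuropil.shape:
        raise ValueError("ROI and neuropil traces must have equal length")
    if f_roi.size == 0:
        raise ValueError("empty trace")
    return f_roi + factor * (np.median(f_neuropil) - f_neuropil)


def lowpass_and_detrend(
    trace: np.ndarray,
    frame_rate_hz: float,
    cutoff_hz: float = 5.0,
    window_s: float = 50.0,
    pct: float = 8.0,
    return_lowpassed: bool = False,
):
    """Low-pass filter, then remove slow trends with a running percentile.

    The trend is the ``pct``-th percentile of the (possibly filtered) trace
    in a centered window of ±``window_s`` seconds, truncated at the edges.
    When ``cutoff_hz`` is at or above 95% of Nyquist the filter is skipped
    (logged): the data are already band-limited by the acquisition.

    Returns the detrended trace, or ``(detrended, lowpassed)`` when
    ``return_lowpassed`` is set (the unsubtracted low-passed trace carries
    the absolute baseline needed for the ΔF/F denominator).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 3:
        raise ValueError("trace too short to detrend (need >= 3 frames)")
    nyquist = frame_rate_hz / 2.0
    if cutoff_hz >= 0.95 * nyquist:
        logger.info(
            "low-pass skipped: cutoff %.3g Hz >= 0.95 x Nyquist (%.3g Hz)",
            cutoff_hz,
            nyquist,
        )
        lowpassed = trace.copy()
    else:
        b, a = butter(4, cutoff_hz / nyquist)
        lowpassed = filtfilt(b, a, trace)
    half = int(round(window_s * frame_rate_hz))
    trend = moving_percentile(np.ascontiguousarray(lowpassed), half, float(pct))
    detrended = lowpassed - trend
    if return_lowpassed:
        return detrended, lowpassed
    return detrended


def estimate_f0_and_noise(
    detrended: np.ndarray,
    frame_rate_hz: float,
    short_window_s: float = 1.0,
    band_pct: float = 60.0,
    trend_pct: float = 8.0,
):
    """Estimate the baseline offset and noise sd from quiescent frames.

    Pinned procedure: (1) ``B[t]`` = ``trend_pct``-th percentile of the
    detrended trace in a ±``short_window_s``/2 window; (2) residual
    ``r = detrended - B``; (3) ``q`` = ``band_pct``-th percentile of ``r``;
    (4) quiescent frames are those with ``r < q``; (5) ``f0_offset`` is the
    median of the detrended trace over quiescent frames; (6) ``noise_sd`` is
    the standard deviation of ``r`` over quiescent frames. Selecting frames
    through the short-window residual makes the estimate robust to event
    density: transients occupy the upper tail of ``r`` for rarely and highly
    active cells alike.

    Returns ``(f0_offset, noise_sd, quiescent_mask)``. A degenerate
    (all-equal) trace yields ``noise_sd = 0`` with a logged warning.
    """
    detrended = np.asarray(detrended, dtype=np.float64)
    half = max(1, int(round(short_window_s * frame_rate_hz / 2.0)))
    if detrended.size <= 2 * half:
        raise ValueError("trace shorter than the short percentile window")
    b = moving_percentile(np.ascontiguousarray(detrended), half, float(trend_pct))
    r = detrended - b
    q = np.percentile(r, band_pct)
    quiescent = r < q
    if not quiescent.any():
        # all residuals equal (constant trace): keep every frame
        quiescent = np.ones_like(r, dtype=bool)
        logger.warning("degenerate trace: all residuals equal; noise_sd = 0")
    f0_offset = float(np.median(detrended[quiescent]))
    noise_sd = float(np.std(r[quiescent]))
    if noise_sd == 0.0:
        logger.warning("noise_sd = 0 (flat trace); downstream detection disabled")
    return f0_offset, noise_sd, quiescent


def compute_dff(detrended: np.ndarray, f0_offset: float, f0_raw: float) -> np.ndarray:
    """ΔF/F: ``(detrended - f0_offset) / f0_raw`` with ``f0_raw > 0``."""
    if f0_raw <= 0:
        raise ValueError(
            "f0_raw must be positive; neuron should be flagged and excluded "
            "from AUC analyses"
        )
    return (np.asarray(detrended, dtype=np.float64) - f0_offset) / f0_raw


def condition_trace(
    pair: RawTracePair,
    neuropil_factor: float = 0.7,
    cutoff_hz: float = 5.0,
    window_s: float = 50.0,
    pct: float = 8.0,
    short_window_s: float = 1.0,
    band_pct: float = 60.0,
) -> ConditionedTrace:
    """Run the full conditioning chain on one raw trace pair."""
    comp = compensate_neuropil(pair, factor=neuropil_factor)
    detrended, lowpassed = lowpass_and_detrend(
        comp,
        pair.frame_rate_hz,
        cutoff_hz=cutoff_hz,
        window_s=window_s,
        pct=pct,
        return_lowpassed=True,
    )
    f0_offset, noise_sd, quiescent = estimate_f0_and_noise(
        detrended,
        pair.frame_rate_hz,
        short_window_s=short_window_s,
        band_pct=band_pct,
        trend_pct=pct,
    )
    f0_raw = float(np.median(lowpassed[quiescent]))
    flags = []
    if f0_raw <= 0:
        flags.append("nonpositive_f0_raw")
        dff = np.full_like(detrended, np.nan)
    else:
        dff = compute_dff(detrended, f0_offset, f0_raw)
    if noise_sd == 0.0:
        flags.append("zero_noise_sd")
    return ConditionedTrace(
        dff=dff,
        detrended=detrended,
        f0_offset=f0_offset,
        f0_raw=f0_raw,
        noise_sd=noise_sd,
        quiescent_mask=quiescent,
        frame_rate_hz=pair.frame_rate_hz,
        neuron_id=pair.neuron_id,
        session_id=pair.session_id,
        params_used={
            "neuropil_factor": neuropil_factor,
            "cutoff_hz": cutoff_hz,
            "window_s": window_s,
            "pct": pct,
            "short_window_s": short_window_s,
            "band_pct": band_pct,
        },
        flags=flags,
    )
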