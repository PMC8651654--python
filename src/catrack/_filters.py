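"""Low-level sliding-window filters shared by the conditioning and detection code.

The moving percentile keeps a sorted window and slides it one frame at a
time; edge windows are truncated (never padded), so the first and last
``half_window`` frames use asymmetric windows. Percentiles interpolate
linearly between order statistics, matching ``numpy.percentile``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _insert_sorted(buf, m, value):
    lo, hi = 0, m
    while lo < hi:
        mid = (lo + hi) // 2
        if buf[mid] < value:
            lo = mid + 1
        else:
            hi = mid
    for i in range(m, lo, -1):
        buf[i] = buf[i - 1]
    buf[lo] = value
    return m + 1


@njit(cache=True)
def _remove_sorted(buf, m, value):
    lo, hi = 0, m
    while lo < hi:
        mid = (lo + hi) // 2
        if buf[mid] < value:
            lo = mid + 1
        else:
            hi = mid
    for i in range(lo, m - 1):
        buf[i] = buf[i + 1]
    return m - 1


@njit(cache=True)
def _percentile_sorted(buf, m, q):
    if m == 1:
        return buf[0]
    pos = q / 100.0 * (m - 1)
    i0 = int(np.floor(pos))
    if i0 >= m - 1:
        return buf[m - 1]
    frac = pos - i0
    return buf[i0] + (buf[i0 + 1] - buf[i0]) * frac


@njit(cache=True)
def moving_percentile(x, half_window, q):
    """Percentile of ``x`` in a centered window of ±``half_window`` frames.

    Windows are truncated at the trace edges. Runs in O(N·W) via an
    incrementally maintained sorted buffer.
    """
    n = x.shape[0]
    out = np.empty(n, dtype=np.float64)
    buf = np.empty(2 * half_window + 1, dtype=np.float64)
    m = 0
    # initial window for t = 0: x[0 : half_window + 1]
    hi = min(half_window + 1, n)
    for i in range(hi):
        m = _insert_sorted(buf, m, x[i])
    out[0] = _percentile_sorted(buf, m, q)
    for t in range(1, n):
        enter = t + half_window
        leave = t - half_window - 1
        if enter < n:
            m = _insert_sorted(buf, m, x[enter])
        if leave >= 0:
            m = _remove_sorted(buf, m, x[leave])
        out[t] = _percentile_sorted(buf, m, q)
    return out


def boxcar_smooth(x: np.ndarray, n_frames: int) -> np.ndarray:
    """Centered moving-average smoothing with edge truncation.

    Each output frame is the mean of the available samples in a window of
    ``n_frames`` centered on it (for even ``n_frames`` the window extends one
    frame further into the past, i.e. frames ``t-n//2 .. t+(n-1)//2``).
    """
    x = np.asarray(x, dtype=np.float64)
    if n_frames <= 1:
        return x.copy()
    n = x.shape[0]
    back = n_frames // 2
    fwd = n_frames - back - 1
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - back, 0, n)
    hi = np.clip(np.arange(n) + fwd + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
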