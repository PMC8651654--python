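"""Pairwise synchrony on binarized activity traces.

Each neuron's detrended trace is smoothed over 20 frames (2 s) and
binarized at f0_offset + 2 noise sd; synchrony is the Pearson correlation
R of these binary vectors per neuron pair (on binary data this equals the
phi coefficient of the 2x2 co-occurrence table). A circular time-shift
shuffle — preserving each neuron's event count and autocorrelation —
provides the chance level. Correlations can be restricted to behavioral
epoch classes, to pairs sharing an activity category, and summarized as a
function of the in-plane distance between ROI centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from ._filters import boxcar_smooth
from .traces import ConditionedTrace

__all__ = [
    "BinaryRaster",
    "PairwiseResult",
    "binarize_trace",
    "build_raster",
    "pairwise_correlation",
    "shuffle_control",
    "epoch_restricted_correlation",
    "correlation_vs_distance",
    "category_restricted_correlation",
]

MIN_RETAINED_FRAMES = 100


def binarize_trace(
    cond: ConditionedTrace, smooth_frames: int = 20, k_sd: float = 2.0
) -> np.ndarray:
    """Binary activity vector: smoothed detrended trace above f0 + k_sd·sd."""
    if cond.noise_sd <= 0:
        raise ValueError("binarization refused: noise_sd must be positive")
    smoothed = boxcar_smooth(cond.detrended, smooth_frames)
    return (smoothed > cond.f0_offset + k_sd * cond.noise_sd).astype(np.uint8)


@dataclass
class BinaryRaster:
    """frames x neurons binary activity with optional in-plane centroids."""

    data: np.ndarray
    frame_rate_hz: float
    centroids_um: Optional[np.ndarray] = None  # (n_neurons, 2)
    neuron_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster must be 2-D (frames x neurons)")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("raster entries must be binary")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.data.shape[1])

    @property
    def n_neurons(self) -> int:
        return self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def build_raster(
    conds: Sequence[ConditionedTrace],
    centroids_um: Optional[np.ndarray] = None,
    smooth_frames: int = 20,
    k_sd: float = 2.0,
) -> BinaryRaster:
    """Binarize a set of conditioned traces into one raster."""
    cols = [binarize_trace(c, smooth_frames, k_sd) for c in conds]
    ids = np.array([c.neuron_id if c.neuron_id is not None else i for i, c in enumerate(conds)])
    return BinaryRaster(
        data=np.column_stack(cols),
        frame_rate_hz=conds[0].frame_rate_hz,
        centroids_um=centroids_um,
        neuron_ids=ids,
    )


@dataclass
class PairwiseResult:
    """Condensed upper-triangle pairwise Pearson R values for one FOV."""

    r: np.ndarray  # NaN where undefined (constant vector)
    pairs: np.ndarray  # (n_pairs, 2) neuron indices, i < j
    distances_um: Optional[np.ndarray] = None
    valid: bool = True
    n_excluded: int = 0
    neuron_ids: Optional[np.ndarray] = None
    flags: list = field(default_factory=list)

    @property
    def mean_r(self) -> float:
        """Mean R over defined pairs (excluded pairs do not enter)."""
        vals = self.r[np.isfinite(self.r)]
        return float(vals.mean()) if vals.size else float("nan")


def pairwise_correlation(
    raster: BinaryRaster, frame_mask: Optional[np.ndarray] = None
) -> PairwiseResult:
    """Pearson R per neuron pair over the retained frames.

    Pairs where either vector is constant over the retained frames are
    flagged undefined (NaN) and excluded from means. With a frame mask
    retaining fewer than 100 frames the whole FOV is flagged invalid.
    """
    if raster.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    data = raster.data
    if frame_mask is not None:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        data = data[frame_mask]
    iu = np.triu_indices(raster.n_neurons, k=1)
    pairs = np.column_stack(iu)
    distances = None
    if raster.centroids_um is not None:
        c = np.asarray(raster.centroids_um, dtype=np.float64)[:, :2]
        distances = np.sqrt(((c[iu[0]] - c[iu[1]]) ** 2).sum(axis=1))
    if frame_mask is not None and data.shape[0] < MIN_RETAINED_FRAMES:
        return PairwiseResult(
            r=np.full(len(pairs), np.nan),
            pairs=pairs,
            distances_um=distances,
            valid=False,
            n_excluded=len(pairs),
            neuron_ids=raster.neuron_ids,
            flags=[f"only {data.shape[0]} retained frames (< {MIN_RETAINED_FRAMES})"],
        )
    x = data.astype(np.float64)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - x.mean(axis=0)) / sd
        corr = (z.T @ z) / x.shape[0]
    constant = sd == 0
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    r = corr[iu]
    # clip numerical overshoot
    r = np.clip(r, -1.0, 1.0, out=r)
    return PairwiseResult(
        r=r,
        pairs=pairs,
        distances_um=distances,
        valid=True,
        n_excluded=int(np.isnan(r).sum()),
        neuron_ids=raster.neuron_ids,
    )


def shuffle_control(
    raster: BinaryRaster,
    n_shuffles: int = 100,
    seed: int = 0,
    frame_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Null distribution of the per-FOV mean R under circular time-shifts.

    Every shuffle applies an independent uniform circular shift to each
    neuron's binary vector (preserving its event count and autocorrelation)
    and recomputes the mean pairwise R.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n_frames = raster.n_frames
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shifts = rng.integers(0, n_frames, size=raster.n_neurons)
        shifted = np.empty_like(raster.data)
        for j in range(raster.n_neurons):
            shifted[:, j] = np.roll(raster.data[:, j], shifts[j])
        shuffled = BinaryRaster(
            data=shifted,
            frame_rate_hz=raster.frame_rate_hz,
            centroids_um=raster.centroids_um,
            neuron_ids=raster.neuron_ids,
        )
        out[s] = pairwise_correlation(shuffled, frame_mask).mean_r
    return out


def epoch_restricted_correlation(
    raster: BinaryRaster, epoch_masks: Dict[str, np.ndarray]
) -> Dict[str, PairwiseResult]:
    """Pairwise correlation per behavioral epoch class (e.g. whisk/stationary)."""
    return {name: pairwise_correlation(raster, mask) for name, mask in epoch_masks.items()}


def correlation_vs_distance(
    result: PairwiseResult, bin_edges_um: np.ndarray
) -> pd.DataFrame:
    """Mean pair R per centroid-distance bin.

    Returns one row per bin with the pair count and mean R (NaN for empty
    bins). The result is flagged when some bin has no pairs — following the
    convention of excluding FOVs whose pairs do not cover the whole distance
    range.
    """
    if result.distances_um is None:
        raise ValueError("pair distances unavailable (no centroids)")
    edges = np.asarray(bin_edges_um, dtype=np.float64)
    ok = np.isfinite(result.r)
    idx = np.digitize(result.distances_um, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = ok & (idx == b)
        rows.append(
            {
                "bin_lo_um": edges[b],
                "bin_hi_um": edges[b + 1],
                "n_pairs": int(sel.sum()),
                "mean_r": float(result.r[sel].mean()) if sel.any() else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["covers_all_bins"] = bool((df["n_pairs"] > 0).all())
    return df


def category_restricted_correlation(
    result: PairwiseResult, categories: Dict[int, str], category: str
) -> np.ndarray:
    """R values of pairs in which *both* neurons share ``category``.

    ``categories`` maps neuron_id -> activity category for the same session.
    Returns the (possibly empty) array of defined R values.
    """
    ids = result.neuron_ids
    if ids is None:
        ids = np.arange(result.pairs.max() + 1)
    keep = np.array(
        [
            categories.get(int(ids[i])) == category and categories.get(int(ids[j])) == category
            for i, j in result.pairs
        ],
        dtype=bool,
    )
    vals = result.r[keep]
    return vals[np.isfinite(vals)]
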