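"""Cross-session statistics on longitudinally matched neurons.

All operations consume a tidy "longitudinal table": one row per neuron and
session with the detected transient rate, AUC and activity category, plus
field-of-view (FOV) and cohort labels. Neurons are matched across sessions
by ``neuron_id`` (within a FOV the same ID denotes the same cell at every
time point).

Statistics implemented: per-neuron activity change between sessions;
within-FOV similarity of activity (Pearson correlation of per-neuron rates
between two time points) with a neuron-identity shuffle null; 3x3 category
transition matrices; per-category reoccurrence rates; recruitment of "novel
highly active" neurons and their activity gain (percentile bootstrap CI);
and two-sample Kolmogorov-Smirnov / Mann-Whitney comparisons of change
distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .detect import CATEGORIES, ActivitySummary

__all__ = [
    "TransitionResult",
    "NovelHighResult",
    "build_longitudinal_table",
    "activity_change",
    "similarity_index",
    "shuffle_null_similarity",
    "transition_matrix",
    "reoccurrence_rate",
    "novel_high_analysis",
    "compare_change_distributions",
    "mann_whitney",
]


def build_longitudinal_table(
    summaries: Sequence[ActivitySummary],
    fov_ids: Optional[dict] = None,
    cohort: str = "",
) -> pd.DataFrame:
    """Assemble per-session activity summaries into a longitudinal table.

    ``fov_ids`` optionally maps neuron_id -> FOV label (default: one FOV).
    """
    rows = [
        {
            "neuron_id": s.neuron_id,
            "session_id": s.session_id,
            "rate": s.transients_per_min,
            "auc": s.auc_per_min,
            "category": s.category,
            "fov_id": (fov_ids or {}).get(s.neuron_id, 0),
            "cohort": cohort,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows).sort_values(["neuron_id", "session_id"]).reset_index(drop=True)


def _matched(table: pd.DataFrame, s0, s1) -> pd.DataFrame:
    """Wide frame of neurons present at both sessions, in neuron_id order."""
    t0 = table[table["session_id"] == s0].set_index("neuron_id")
    t1 = table[table["session_id"] == s1].set_index("neuron_id")
    ids = t0.index.intersection(t1.index).sort_values()
    if len(ids) == 0:
        raise ValueError(f"no neurons matched between sessions {s0} and {s1}")
    out = pd.DataFrame(
        {
            "rate0": t0.loc[ids, "rate"],
            "rate1": t1.loc[ids, "rate"],
            "cat0": t0.loc[ids, "category"],
            "cat1": t1.loc[ids, "category"],
            "fov_id": t0.loc[ids, "fov_id"],
        }
    )
    return out


def activity_change(table: pd.DataFrame, s0, s1) -> pd.Series:
    """Per-neuron rate change ``rate(s1) - rate(s0)`` (transients/min)."""
    m = _matched(table, s0, s1)
    return (m["rate1"] - m["rate0"]).rename("delta_rate")


def similarity_index(rates_s0: np.ndarray, rates_s1: np.ndarray) -> float:
    """Pearson correlation across neurons of rates between two sessions.

    Returns NaN (flagged-undefined) when either vector is constant; FOVs
    with undefined similarity are excluded from averages by the callers.
    """
    a = np.asarray(rates_s0, dtype=np.float64)
    b = np.asarray(rates_s1, dtype=np.float64)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 neurons")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def shuffle_null_similarity(
    table: pd.DataFrame,
    s0,
    s1,
    n_shuffles: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Null distribution of the similarity index under neuron-identity shuffles.

    Each draw permutes the neuron labels at session ``s1`` uniformly at
    random and recomputes the similarity index. With ``exhaustive`` the
    full permutation set is enumerated instead (only sensible for tiny n).
    """
    m = _matched(table, s0, s1)
    a = m["rate0"].to_numpy()
    b = m["rate1"].to_numpy()
    if exhaustive:
        perms = itertools.permutations(range(len(b)))
        return np.array([_pearson_or_nan(a, b[list(p)]) for p in perms])
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = _pearson_or_nan(a, rng.permutation(b))
    return out


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class TransitionResult:
    """Category transition counts/fractions between two sessions."""

    counts: pd.DataFrame  # 3x3, rows = category at s0, cols = category at s1
    fractions: pd.DataFrame  # row-normalized (NaN rows for empty categories)
    n_neurons: int

    @property
    def recruitment_rate(self) -> float:
        """Fraction of intermediately active neurons turning highly active."""
        return float(self.fractions.loc["intermediate", "high"])


def transition_matrix(table: pd.DataFrame, s0, s1) -> TransitionResult:
    m = _matched(table, s0, s1)
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    grouped = m.groupby(["cat0", "cat1"], observed=True).size()
    for (c0, c1), n in grouped.items():
        counts.loc[c0, c1] = int(n)
    row_sums = counts.sum(axis=1)
    fractions = counts.div(row_sums.replace(0, np.nan), axis=0)
    return TransitionResult(counts=counts, fractions=fractions, n_neurons=len(m))


def reoccurrence_rate(
    table: pd.DataFrame, category: str, s0, s1, by: str = "pooled"
):
    """Fraction of neurons in ``category`` at ``s0`` still there at ``s1``.

    ``by='pooled'`` returns one fraction over all neurons; ``by='fov'``
    returns a per-FOV Series (FOVs with an empty category at ``s0`` are
    excluded as undefined).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    m = _matched(table, s0, s1)
    sel = m[m["cat0"] == category]
    if by == "pooled":
        if len(sel) == 0:
            raise ValueError(f"no neurons in category {category!r} at session {s0}")
        return float((sel["cat1"] == category).mean())
    if by == "fov":
        out = {}
        for fov, grp in sel.groupby("fov_id"):
            if len(grp):
                out[fov] = float((grp["cat1"] == category).mean())
        return pd.Series(out, name="reoccurrence", dtype=float)
    raise ValueError("by must be 'pooled' or 'fov'")


@dataclass
class NovelHighResult:
    """Neurons newly highly active at a session: origin and activity gain."""

    n_new_high: int
    frac_from_intermediate: float  # NaN when no new high cells
    frac_from_rare: float
    mean_gain: float  # transients/min
    ci_low: float
    ci_high: float
    gains: np.ndarray


def novel_high_analysis(
    table: pd.DataFrame,
    s_prev,
    s_new,
    n_boot: int = 10_000,
    seed: int = 0,
) -> NovelHighResult:
    """Source categories and rate gain of neurons turning highly active.

    "Novel highly active" = high at ``s_new`` and not high at the
    immediately preceding session ``s_prev``. The mean gain CI is a seeded
    percentile bootstrap.
    """
    m = _matched(table, s_prev, s_new)
    new_high = m[(m["cat1"] == "high") & (m["cat0"] != "high")]
    n = len(new_high)
    if n == 0:
        nan = float("nan")
        return NovelHighResult(0, nan, nan, nan, nan, nan, np.empty(0))
    gains = (new_high["rate1"] - new_high["rate0"]).to_numpy()
    frac_int = float((new_high["cat0"] == "intermediate").mean())
    frac_rare = float((new_high["cat0"] == "rare").mean())
    rng = np.random.default_rng(seed)
    boots = rng.choice(gains, size=(n_boot, n), replace=True).mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return NovelHighResult(
        n_new_high=n,
        frac_from_intermediate=frac_int,
        frac_from_rare=frac_rare,
        mean_gain=float(gains.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        gains=gains,
    )


def compare_change_distributions(
    deltas_a: np.ndarray, deltas_b: np.ndarray
) -> Tuple[float, float]:
    """Two-sample KS test: ``D = sup |ECDF_a - ECDF_b|`` and its p-value.

    Exact p by enumeration for n*m <= 10 000, asymptotic otherwise.
    """
    a = np.asarray(deltas_a, dtype=np.float64)
    b = np.asarray(deltas_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if a.size * b.size <= 10_000 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    """Mann-Whitney U (two-sided), exact for n*m <= 10 000 without ties."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 10_000 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
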