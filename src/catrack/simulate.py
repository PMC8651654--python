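"""Synthetic multi-session calcium-imaging cohorts with known ground truth.

The generator emulates the statistical structure of longitudinal awake
two-photon recordings in amyloidosis-model (APPPS1-like) and wild-type-like
cohorts: three activity classes at the empirical category weights, GCaMP6s-
like transient kinetics (0.18 s rise, 1.8 s decay), correlated neuropil
contamination shared across a field of view, slow drift, session-to-session
rate persistence with small drift, shared network events controlling
pairwise synchrony, whisking bouts (~1 s mean duration) and growing amyloid
plaques rendered as anisotropic sphere unions.

Event trains are renewal processes with a refractory interval and
rate-corrected exponential gaps, so the intended rate is matched exactly in
expectation while consecutive transients stay separable at 10 Hz. The
ground-truth manifest records exactly what was generated, so every pipeline
stage can be scored against it.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .correlate import BinaryRaster
from .detect import classify_activity
from .plaques import DEFAULT_VOXEL_SIZE_UM, PlaqueDistanceRecord, PlaqueVolume
from .traces import RawTracePair

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "KineticsSpec",
    "SessionPlan",
    "PlaqueFieldSpec",
    "GroundTruthManifest",
    "SessionRecording",
    "SimulatedCohort",
    "wt_like_population",
    "appps1_like_population",
    "cohort_plan",
    "transient_kernel",
    "sample_event_times",
    "simulate_cohort",
    "simulate_plaque_volume",
    "render_structural_channels",
    "simulate_binary_raster",
    "simulate_rate_table",
    "random_distance_records",
    "simulate_detection_benchmark",
]

# Category weights observed across the two cohorts (counts of rarely,
# intermediately and highly active neurons at baseline).
WT_CATEGORY_COUNTS = (94, 309, 81)  # n = 484
APP_CATEGORY_COUNTS = (177, 951, 444)  # n = 1572

DEFAULT_RATE_RANGES = {
    "rare": (0.01, 0.24),
    "intermediate": (0.25, 4.0),
    "high": (4.1, 12.0),
}

REFRACTORY_S = 2.0  # minimum inter-transient interval in generated trains


@dataclass
class PopulationSpec:
    """Composition of a simulated neuron population."""

    n_neurons: int
    category_fractions: Tuple[float, float, float]  # rare, intermediate, high
    rate_ranges_per_min: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_RANGES)
    )
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        f = np.asarray(self.category_fractions, dtype=np.float64)
        if f.min() < 0 or f.max() > 1 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("category fractions must lie in [0,1] and sum to 1")
        lo_r, hi_r = self.rate_ranges_per_min["rare"]
        lo_i, hi_i = self.rate_ranges_per_min["intermediate"]
        lo_h, hi_h = self.rate_ranges_per_min["high"]
        if not (hi_r < 0.25 and 0.25 <= lo_i and hi_i <= 4.0 and lo_h > 4.0):
            raise ValueError("rate ranges inconsistent with category bounds")


def wt_like_population(n_neurons: int = sum(WT_CATEGORY_COUNTS)) -> PopulationSpec:
    """Wild-type-like composition (rare/intermediate/high = 94/309/81)."""
    total = sum(WT_CATEGORY_COUNTS)
    return PopulationSpec(
        n_neurons=n_neurons,
        category_fractions=tuple(c / total for c in WT_CATEGORY_COUNTS),
        cohort_label="WT-like",
    )


def appps1_like_population(n_neurons: int = sum(APP_CATEGORY_COUNTS)) -> PopulationSpec:
    """Amyloidosis-model-like composition (rare/intermediate/high = 177/951/444)."""
    total = sum(APP_CATEGORY_COUNTS)
    return PopulationSpec(
        n_neurons=n_neurons,
        category_fractions=tuple(c / total for c in APP_CATEGORY_COUNTS),
        cohort_label="APPPS1-like",
    )


@dataclass
class KineticsSpec:
    """Indicator kinetics and noise model of the rendered traces.

    The double-exponential kernel (0.18 s rise, 1.8 s decay) makes a single
    transient span well over 10 frames at 10 Hz, matching the detector's
    duration rule. Amplitudes are lognormal around ``amplitude_dff`` (in
    ΔF/F units of the baseline). ``neuropil_mix`` scales the shared neuropil
    fluctuation added to each soma and defaults to the 0.7 compensation
    factor.
    """

    rise_tau_s: float = 0.18
    decay_tau_s: float = 1.8
    amplitude_dff: float = 0.8
    amplitude_sigma: float = 0.35
    baseline_f0: float = 100.0
    noise_sd: float = 16.0
    neuropil_mix: float = 0.7
    drift_amplitude: float = 5.0
    drift_period_s: float = 120.0
    neuropil_baseline: float = 60.0
    neuropil_sd: float = 10.0
    neuropil_ar1: float = 0.97
    neuropil_sin_amplitude: float = 4.0
    neuropil_sin_period_s: float = 37.0
    neuropil_measure_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        if not 0.0 <= self.neuropil_mix <= 1.0:
            raise ValueError("neuropil_mix must lie in [0, 1]")


@dataclass
class SessionPlan:
    """Session layout and between-session dynamics.

    ``rate_drift_mean`` may be a scalar or a per-category mapping (the
    amyloidosis-like preset drifts only intermediately active neurons
    upward). Shared network events occur at ``shared_event_rate_per_min``
    and each neuron joins one with probability ``shared_participation_p``
    (optionally decaying with distance from the event's epicenter, and
    optionally confined to whisking-associated frames).
    """

    n_sessions: int = 3
    frames_per_session: int = 5000
    frame_rate_hz: float = 10.0
    rate_drift_mean: object = 0.0  # float or {category: float}
    rate_drift_sd: float = 1.0
    shared_event_rate_per_min: float = 2.0
    shared_participation_p: float = 0.15
    shared_event_spatial_scale_um: Optional[float] = None
    shared_events_whisk_only: bool = False
    whisk_mean_s: float = 1.0
    quiet_mean_s: float = 20.0
    fov_size_um: float = 220.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.n_sessions <= 0 or self.frames_per_session <= 0:
            raise ValueError("session counts must be positive")
        if not 0.0 <= self.shared_participation_p <= 1.0:
            raise ValueError("shared_participation_p must lie in [0, 1]")

    @property
    def duration_s(self) -> float:
        return self.frames_per_session / self.frame_rate_hz

    def drift_mean_for(self, category: str) -> float:
        if isinstance(self.rate_drift_mean, dict):
            return float(self.rate_drift_mean.get(category, 0.0))
        return float(self.rate_drift_mean)


def cohort_plan(cohort: str, **overrides) -> SessionPlan:
    """Preset session plans: 'wt' (no drift, weaker shared events) or 'app'
    (intermediate-class upward drift, stronger shared participation)."""
    key = cohort.lower()
    if key in ("wt", "wt-like"):
        base = dict(rate_drift_mean=0.0, shared_participation_p=0.10)
    elif key in ("app", "appps1", "appps1-like"):
        base = dict(
            rate_drift_mean={"intermediate": 0.3},
            shared_participation_p=0.20,
        )
    else:
        raise ValueError(f"unknown cohort preset {cohort!r}")
    base.update(overrides)
    return SessionPlan(**base)


@dataclass
class PlaqueFieldSpec:
    """Layout of the synthetic structural volume and its plaques.

    Defaults approximate the overview stacks around an imaged region: 350 x
    350 µm in plane (520 x 520 px), 120 µm of depth at 0.5 µm z increments,
    holding 18 growing plaques — enough to put the median nearest-
    plaque distance in the few-tens-of-µm range where the close/distant
    split is informative.
    """

    n_plaques: int = 18
    shape_voxels: Tuple[int, int, int] = (240, 520, 520)  # z, y, x
    voxel_size_um: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    radius_mean_um: float = 8.0
    radius_sigma: float = 0.25
    growth_um_per_session: float = 1.5


@dataclass
class GroundTruthManifest:
    """Exact record of what the generator produced."""

    neuron_ids: np.ndarray
    categories: List[List[str]]  # [session][neuron]
    true_rates: np.ndarray  # (n_sessions, n_neurons), realized rates
    intended_rates: np.ndarray  # (n_sessions, n_neurons)
    true_event_times: List[List[np.ndarray]]  # [session][neuron] -> seconds
    shared_event_times: List[np.ndarray]  # [session] -> seconds
    roi_centroids_um: np.ndarray  # (n_neurons, 3) x, y, z
    plaque_centers_um: np.ndarray  # (n_plaques, 3)
    plaque_radii_um: np.ndarray  # (n_sessions, n_plaques)
    whisk_epochs: List[List[Tuple[float, float]]]  # [session] -> (onset_s, offset_s)
    duration_s: float
    frame_rate_hz: float
    cohort_label: str = ""

    def event_counts(self, session: int) -> np.ndarray:
        return np.array([len(t) for t in self.true_event_times[session]])

    def to_json(self, path) -> None:
        payload = {
            "neuron_ids": self.neuron_ids.tolist(),
            "categories": self.categories,
            "true_rates": self.true_rates.tolist(),
            "intended_rates": self.intended_rates.tolist(),
            "true_event_times": [
                [t.tolist() for t in sess] for sess in self.true_event_times
            ],
            "shared_event_times": [t.tolist() for t in self.shared_event_times],
            "roi_centroids_um": self.roi_centroids_um.tolist(),
            "plaque_centers_um": self.plaque_centers_um.tolist(),
            "plaque_radii_um": self.plaque_radii_um.tolist(),
            "whisk_epochs": self.whisk_epochs,
            "duration_s": self.duration_s,
            "frame_rate_hz": self.frame_rate_hz,
            "cohort_label": self.cohort_label,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SessionRecording:
    """One simulated imaging session (traces are frames x neurons)."""

    session_id: int
    f_roi: np.ndarray
    f_neuropil: np.ndarray
    frame_rate_hz: float
    whisk_track: np.ndarray
    plaque_volume: Optional[PlaqueVolume] = None

    def trace_pair(self, j: int, neuron_id: Optional[int] = None) -> RawTracePair:
        return RawTracePair(
            f_roi=self.f_roi[:, j],
            f_neuropil=self.f_neuropil[:, j],
            frame_rate_hz=self.frame_rate_hz,
            neuron_id=int(neuron_id if neuron_id is not None else j),
            session_id=self.session_id,
        )


@dataclass
class SimulatedCohort:
    sessions: List[SessionRecording]
    manifest: GroundTruthManifest
    pop: PopulationSpec
    kin: KineticsSpec
    plan: SessionPlan


def transient_kernel(
    rise_tau_s: float, decay_tau_s: float
) -> Tuple[callable, float]:
    """Unit-peak difference-of-exponentials kernel and its peak delay (s)."""
    if decay_tau_s <= rise_tau_s:
        raise ValueError("decay tau must exceed rise tau")
    t_peak = math.log(decay_tau_s / rise_tau_s) / (1 / rise_tau_s - 1 / decay_tau_s)
    norm = math.exp(-t_peak / decay_tau_s) - math.exp(-t_peak / rise_tau_s)

    def kernel(t: np.ndarray) -> np.ndarray:
        t = np.maximum(np.asarray(t, dtype=np.float64), 0.0)
        return (np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)) / norm

    return kernel, t_peak


def sample_event_times(
    rate_per_min: float,
    duration_s: float,
    rng: np.random.Generator,
    refractory_s: float = REFRACTORY_S,
) -> np.ndarray:
    """Renewal event train with refractory gap and exact expected rate.

    Inter-event intervals are ``refractory_s + Exp(mean_gap)`` with
    ``mean_gap = 1/rate - refractory_s`` so the mean interval equals
    ``1/rate`` exactly; rates at or above the refractory limit fall back to
    near-periodic trains at the refractory interval.
    """
    lam = rate_per_min / 60.0
    if lam <= 0:
        return np.empty(0)
    mean_iei = 1.0 / lam
    mean_gap = max(mean_iei - refractory_s, 1e-3)
    times = []
    t = rng.uniform(0.0, refractory_s + mean_gap)  # random initial phase
    while t < duration_s:
        times.append(t)
        t += refractory_s + rng.exponential(mean_gap)
    return np.asarray(times)


def _sample_categories(pop: PopulationSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(
        np.array(["rare", "intermediate", "high"]),
        size=pop.n_neurons,
        p=np.asarray(pop.category_fractions, dtype=np.float64),
    )


def _loguniform(lo: float, hi: float, size, rng: np.random.Generator) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _whisk_track(
    plan: SessionPlan, rng: np.random.Generator
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Alternating renewal whisk/quiet track at frame resolution."""
    duration = plan.duration_s
    fr = plan.frame_rate_hz
    epochs: List[Tuple[float, float]] = []
    t = rng.exponential(plan.quiet_mean_s)  # start quiet
    while t < duration:
        d = rng.exponential(plan.whisk_mean_s)
        epochs.append((t, min(t + d, duration)))
        t += d + rng.exponential(plan.quiet_mean_s)
    track = np.zeros(plan.frames_per_session, dtype=np.uint8)
    frame_times = np.arange(plan.frames_per_session) / fr
    for on, off in epochs:
        track[(frame_times >= on) & (frame_times < off)] = 1
    return track, epochs


def _shared_event_times(
    plan: SessionPlan,
    rng: np.random.Generator,
    whisk_epochs: List[Tuple[float, float]],
) -> np.ndarray:
    duration = plan.duration_s
    n = rng.poisson(plan.shared_event_rate_per_min * duration / 60.0)
    if n == 0:
        return np.empty(0)
    if plan.shared_events_whisk_only and whisk_epochs:
        # place events inside whisk epochs (or their 2 s decay windows)
        spans = np.array([(on, min(off + 2.0, duration)) for on, off in whisk_epochs])
        weights = spans[:, 1] - spans[:, 0]
        weights = weights / weights.sum()
        idx = rng.choice(len(spans), size=n, p=weights)
        times = spans[idx, 0] + rng.uniform(size=n) * (spans[idx, 1] - spans[idx, 0])
    else:
        times = rng.uniform(0.0, duration, size=n)
    return np.sort(times)


def _merge_with_refractory(
    own: np.ndarray, extra: np.ndarray, refractory_s: float = REFRACTORY_S
) -> np.ndarray:
    """Add shared-event times to a train, skipping violations of the gap."""
    events = list(np.sort(own))
    for t in np.sort(extra):
        if all(abs(t - e) >= refractory_s for e in events):
            events.append(t)
            events.sort()
    return np.asarray(events)


def simulate_cohort(
    pop: PopulationSpec,
    kin: KineticsSpec,
    plan: SessionPlan,
    seed: int,
    plaque_field: Optional[PlaqueFieldSpec] = None,
    render_plaque_volumes: bool = False,
) -> SimulatedCohort:
    """Generate a multi-session cohort with traces, behavior, plaques and
    a ground-truth manifest.

    Per neuron, transients are drawn at its (category-dependent) rate and
    rendered as double-exponential kernels on a baseline with shared
    neuropil fluctuation, slow sinusoidal drift and white noise; the
    measured neuropil trace is the shared fluctuation plus small independent
    measurement noise. Neuron identities, centroids and plaque geometry are
    fixed across sessions; per-neuron rates evolve by truncated-normal
    drift. The realized event times/rates are recorded exactly in the
    manifest.
    """
    root = np.random.default_rng(seed)
    rng_pop, rng_geom, *rng_sessions = root.spawn(2 + plan.n_sessions)

    categories0 = _sample_categories(pop, rng_pop)
    rates0 = np.empty(pop.n_neurons)
    for cat in ("rare", "intermediate", "high"):
        sel = categories0 == cat
        lo, hi = pop.rate_ranges_per_min[cat]
        rates0[sel] = _loguniform(lo, hi, int(sel.sum()), rng_pop)

    # geometry: in-plane centroids inside the FOV, depth near stack middle
    if plaque_field is None:
        n_plq = 18 if "app" in pop.cohort_label.lower() else 0
        plaque_field = PlaqueFieldSpec(n_plaques=n_plq)
    nz, ny, nx = plaque_field.shape_voxels
    vx, vy, vz = plaque_field.voxel_size_um
    ext_x, ext_y, ext_z = nx * vx, ny * vy, nz * vz
    margin = 0.08
    cx = rng_geom.uniform(margin * ext_x, (1 - margin) * ext_x, pop.n_neurons)
    cy = rng_geom.uniform(margin * ext_y, (1 - margin) * ext_y, pop.n_neurons)
    cz = rng_geom.uniform(0.35 * ext_z, 0.65 * ext_z, pop.n_neurons)
    centroids = np.column_stack((cx, cy, cz))
    if plaque_field.n_plaques > 0:
        pc = np.column_stack(
            [
                rng_geom.uniform(0.05 * e, 0.95 * e, plaque_field.n_plaques)
                for e in (ext_x, ext_y, ext_z)
            ]
        )
        r0 = plaque_field.radius_mean_um * np.exp(
            rng_geom.normal(0.0, plaque_field.radius_sigma, plaque_field.n_plaques)
        )
    else:
        pc = np.empty((0, 3))
        r0 = np.empty(0)
    radii = np.array(
        [r0 + s * plaque_field.growth_um_per_session for s in range(plan.n_sessions)]
    ).reshape(plan.n_sessions, -1)

    kernel, _ = transient_kernel(kin.rise_tau_s, kin.decay_tau_s)
    n_frames = plan.frames_per_session
    fr = plan.frame_rate_hz
    duration = plan.duration_s
    frame_times = np.arange(n_frames) / fr
    support = int(math.ceil((kin.decay_tau_s * 8.0 + kin.rise_tau_s) * fr))

    sessions: List[SessionRecording] = []
    all_event_times: List[List[np.ndarray]] = []
    all_shared: List[np.ndarray] = []
    all_whisk: List[List[Tuple[float, float]]] = []
    true_rates = np.empty((plan.n_sessions, pop.n_neurons))
    intended = np.empty((plan.n_sessions, pop.n_neurons))
    cat_by_session: List[List[str]] = []

    rates = rates0.copy()
    for s in range(plan.n_sessions):
        rng = rng_sessions[s]
        if s > 0:
            means = np.array(
                [plan.drift_mean_for(classify_activity(r)) for r in rates]
            )
            # reflecting boundary at 0: a silent neuron drifts back into
            # activity rather than sticking at zero rate
            rates = np.abs(rates + rng.normal(means, plan.rate_drift_sd))
        intended[s] = rates
        whisk_track, whisk_epochs = _whisk_track(plan, rng)
        shared = _shared_event_times(plan, rng, whisk_epochs)
        if plan.shared_event_spatial_scale_um and shared.size:
            epicenters = rng.uniform(0.0, plan.fov_size_um, size=(shared.size, 2))
        else:
            epicenters = None

        # shared neuropil fluctuation for the whole FOV
        ar_noise = rng.normal(0.0, kin.neuropil_sd, n_frames)
        rho = kin.neuropil_ar1
        np_fluct = lfilter([math.sqrt(1 - rho**2)], [1, -rho], ar_noise)
        np_fluct += kin.neuropil_sin_amplitude * np.sin(
            2 * np.pi * frame_times / kin.neuropil_sin_period_s
            + rng.uniform(0, 2 * np.pi)
        )

        f_roi = np.empty((n_frames, pop.n_neurons))
        f_np = np.empty((n_frames, pop.n_neurons))
        session_events: List[np.ndarray] = []
        for j in range(pop.n_neurons):
            target_cat = classify_activity(rates[j])
            if shared.size:
                # participation scales with the neuron's own rate (capped at
                # 1 transient/min) so shared events do not lift rarely active
                # neurons out of their class ...
                p = plan.shared_participation_p * min(1.0, rates[j])
                if epicenters is not None:
                    d = np.sqrt(
                        ((epicenters - centroids[j, :2][None, :]) ** 2).sum(axis=1)
                    )
                    probs = p * np.exp(-d / plan.shared_event_spatial_scale_um)
                else:
                    probs = np.full(shared.size, p)
                # ... and the individual event rate is compensated by the
                # expected shared contribution so the realized total rate
                # matches the assigned rate
                own_rate = max(0.0, rates[j] - 60.0 * probs.sum() / duration)
            else:
                own_rate = rates[j]
                probs = None
            # the study's class weights are weights of *observed* classes at
            # this session duration; condition the realized train on the
            # assigned class so count quantization near the class boundaries
            # does not reshuffle the composition
            for _attempt in range(100):
                own = sample_event_times(own_rate, duration, rng)
                if probs is not None:
                    join = shared[rng.uniform(size=shared.size) < probs]
                    events = _merge_with_refractory(own, join)
                else:
                    events = own
                if classify_activity(60.0 * events.size / duration) == target_cat:
                    break
            else:
                logger.warning(
                    "neuron %d session %d: realized class differs from "
                    "assigned %s (rate %.3g/min)",
                    j, s, target_cat, rates[j],
                )
            session_events.append(events)
            true_rates[s, j] = 60.0 * events.size / duration

            trace = np.full(n_frames, kin.baseline_f0)
            amps = kin.amplitude_dff * kin.baseline_f0 * np.exp(
                rng.normal(0.0, kin.amplitude_sigma, events.size)
            )
            for te, a in zip(events, amps):
                i0 = int(math.ceil(te * fr))
                i1 = min(i0 + support, n_frames)
                if i0 >= n_frames:
                    continue
                trace[i0:i1] += a * kernel(frame_times[i0:i1] - te)
            phase = rng.uniform(0, 2 * np.pi)
            trace += kin.drift_amplitude * np.sin(
                2 * np.pi * frame_times / kin.drift_period_s + phase
            )
            trace += kin.neuropil_mix * np_fluct
            trace += rng.normal(0.0, kin.noise_sd, n_frames)
            f_roi[:, j] = trace
            f_np[:, j] = (
                kin.neuropil_baseline
                + np_fluct
                + rng.normal(0.0, kin.neuropil_measure_noise_sd, n_frames)
            )

        cat_by_session.append([classify_activity(r) for r in true_rates[s]])
        all_event_times.append(session_events)
        all_shared.append(shared)
        all_whisk.append([(float(a), float(b)) for a, b in whisk_epochs])

        volume = None
        if render_plaque_volumes and plaque_field.n_plaques > 0:
            volume = simulate_plaque_volume(
                pc, radii[s], plaque_field.voxel_size_um, plaque_field.shape_voxels
            )
        sessions.append(
            SessionRecording(
                session_id=s,
                f_roi=f_roi,
                f_neuropil=f_np,
                frame_rate_hz=fr,
                whisk_track=whisk_track,
                plaque_volume=volume,
            )
        )

    manifest = GroundTruthManifest(
        neuron_ids=np.arange(pop.n_neurons),
        categories=cat_by_session,
        true_rates=true_rates,
        intended_rates=intended,
        true_event_times=all_event_times,
        shared_event_times=all_shared,
        roi_centroids_um=centroids,
        plaque_centers_um=pc,
        plaque_radii_um=radii,
        whisk_epochs=all_whisk,
        duration_s=duration,
        frame_rate_hz=fr,
        cohort_label=pop.cohort_label,
    )
    return SimulatedCohort(sessions=sessions, manifest=manifest, pop=pop, kin=kin, plan=plan)


def simulate_plaque_volume(
    centers_um: np.ndarray,
    radii_um: np.ndarray,
    voxel_size_um: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM,
    shape_voxels: Tuple[int, int, int] = (240, 520, 520),
    seed: Optional[int] = None,
) -> PlaqueVolume:
    """Binary plaque mask as the union of anisotropy-corrected spheres.

    ``centers_um`` are (x, y, z) physical coordinates; the mask is indexed
    (z, y, x). A sphere entirely outside the volume logs a warning but the
    volume remains valid.
    """
    centers = np.asarray(centers_um, dtype=np.float64).reshape(-1, 3)
    radii = np.asarray(radii_um, dtype=np.float64).reshape(-1)
    if centers.shape[0] != radii.shape[0]:
        raise ValueError("centers and radii must have equal length")
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    vx, vy, vz = voxel_size_um
    nz, ny, nx = shape_voxels
    mask = np.zeros(shape_voxels, dtype=bool)
    for (x, y, z), r in zip(centers, radii):
        zi0 = max(0, int(math.floor((z - r) / vz)))
        zi1 = min(nz, int(math.ceil((z + r) / vz)) + 1)
        yi0 = max(0, int(math.floor((y - r) / vy)))
        yi1 = min(ny, int(math.ceil((y + r) / vy)) + 1)
        xi0 = max(0, int(math.floor((x - r) / vx)))
        xi1 = min(nx, int(math.ceil((x + r) / vx)) + 1)
        if zi0 >= zi1 or yi0 >= yi1 or xi0 >= xi1:
            logger.warning("sphere at %s entirely outside the volume", (x, y, z))
            continue
        zz = np.arange(zi0, zi1) * vz - z
        yy = np.arange(yi0, yi1) * vy - y
        xx = np.arange(xi0, xi1) * vx - x
        d2 = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        )
        mask[zi0:zi1, yi0:yi1, xi0:xi1] |= d2 <= r * r
    return PlaqueVolume(mask=mask, voxel_size_um=voxel_size_um)


def render_structural_channels(
    vol: PlaqueVolume,
    seed: int = 0,
    background: float = 20.0,
    signal: float = 120.0,
    noise_sd: float = 4.0,
    bleed_fraction: float = 0.3,
    n_gcamp_blobs: int = 30,
    blob_amplitude: float = 80.0,
) -> Dict[str, np.ndarray]:
    """Render noisy raw plaque-dye and indicator channels from a mask.

    The indicator channel contains bright cell-body blobs; a fraction of it
    bleeds into the plaque-dye channel, which the cleanup pipeline must
    remove.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = vol.mask.shape
    gcamp = np.full((nz, ny, nx), background)
    for _ in range(n_gcamp_blobs):
        z = rng.integers(0, nz)
        y, x = rng.integers(4, ny - 4), rng.integers(4, nx - 4)
        gcamp[z, y - 3 : y + 4, x - 3 : x + 4] += blob_amplitude
    gcamp = gcamp + rng.normal(0.0, noise_sd, gcamp.shape)
    methoxy = (
        background
        + signal * vol.mask
        + bleed_fraction * (gcamp - background)
        + rng.normal(0.0, noise_sd, gcamp.shape)
    )
    return {"methoxy": methoxy, "gcamp": gcamp}


def simulate_binary_raster(
    n_neurons: int,
    n_frames: int,
    rate_per_min: float = 2.0,
    shared_rate_per_min: float = 5.0,
    participation_p: float = 0.2,
    seed: int = 0,
    frame_rate_hz: float = 10.0,
    event_support_frames: int = 10,
    centroids_um: Optional[np.ndarray] = None,
    spatial_scale_um: Optional[float] = None,
    whisk_mask: Optional[np.ndarray] = None,
) -> BinaryRaster:
    """Directly generate a binary event raster with shared network events.

    Each neuron fires independent events at ``rate_per_min`` plus shared
    events it joins with probability ``participation_p`` (optionally
    decaying with distance from the event epicenter, optionally confined to
    ``whisk_mask`` frames). Events mark ``event_support_frames`` consecutive
    frames, emulating the support of a binarized transient.
    """
    rng = np.random.default_rng(seed)
    duration = n_frames / frame_rate_hz
    data = np.zeros((n_frames, n_neurons), dtype=np.uint8)
    n_shared = rng.poisson(shared_rate_per_min * duration / 60.0)
    if whisk_mask is not None:
        whisk_frames = np.flatnonzero(np.asarray(whisk_mask, dtype=bool))
        shared_frames = rng.choice(whisk_frames, size=n_shared)
    else:
        shared_frames = rng.integers(0, n_frames, size=n_shared)
    if spatial_scale_um is not None:
        if centroids_um is None:
            raise ValueError("spatial decay requires centroids")
        extent = centroids_um[:, :2].max(axis=0)
        epicenters = rng.uniform(0.0, 1.0, size=(n_shared, 2)) * extent
    for j in range(n_neurons):
        n_own = rng.poisson(rate_per_min * duration / 60.0)
        frames = list(rng.integers(0, n_frames, size=n_own))
        if n_shared:
            if spatial_scale_um is not None:
                d = np.sqrt(
                    ((epicenters - centroids_um[j, :2][None, :]) ** 2).sum(axis=1)
                )
                probs = participation_p * np.exp(-d / spatial_scale_um)
            else:
                probs = np.full(n_shared, participation_p)
            frames += list(shared_frames[rng.uniform(size=n_shared) < probs])
        for f in frames:
            data[f : f + event_support_frames, j] = 1
    return BinaryRaster(
        data=data,
        frame_rate_hz=frame_rate_hz,
        centroids_um=centroids_um,
    )


def simulate_rate_table(
    pop: PopulationSpec,
    n_sessions: int = 3,
    drift_mean: object = 0.0,
    drift_sd: float = 1.0,
    seed: int = 0,
    n_fovs: int = 1,
    cohort: Optional[str] = None,
) -> pd.DataFrame:
    """Longitudinal rate table sampled directly at the rate level.

    Skips trace rendering and detection: per-neuron rates are drawn from the
    category mixture and evolve by truncated-normal drift. Used for
    dynamics-level statistics where the imaging layer is irrelevant.
    """
    rng = np.random.default_rng(seed)
    cats = _sample_categories(pop, rng)
    rates = np.empty(pop.n_neurons)
    for cat in ("rare", "intermediate", "high"):
        sel = cats == cat
        lo, hi = pop.rate_ranges_per_min[cat]
        rates[sel] = _loguniform(lo, hi, int(sel.sum()), rng)
    fov_ids = rng.integers(0, n_fovs, size=pop.n_neurons)
    rows = []
    plan = SessionPlan(rate_drift_mean=drift_mean, rate_drift_sd=drift_sd)
    for s in range(n_sessions):
        if s > 0:
            means = np.array([plan.drift_mean_for(classify_activity(r)) for r in rates])
            rates = np.abs(rates + rng.normal(means, drift_sd))
        for j in range(pop.n_neurons):
            rows.append(
                {
                    "neuron_id": j,
                    "session_id": s,
                    "rate": rates[j],
                    "auc": float("nan"),
                    "category": classify_activity(rates[j]),
                    "fov_id": int(fov_ids[j]),
                    "cohort": cohort if cohort is not None else pop.cohort_label,
                }
            )
    return pd.DataFrame(rows)


def random_distance_records(
    neuron_ids: Sequence[int],
    session_ids: Sequence[int],
    seed: int = 0,
    lo_um: float = 5.0,
    hi_um: float = 100.0,
) -> List[PlaqueDistanceRecord]:
    """Distance records independent of activity (null for stratified tests).

    Each neuron gets one distance, constant across sessions.
    """
    rng = np.random.default_rng(seed)
    out = []
    for nid in neuron_ids:
        d = float(rng.uniform(lo_um, hi_um))
        for s in session_ids:
            out.append(PlaqueDistanceRecord(neuron_id=int(nid), session_id=int(s), distance_um=d))
    return out


def simulate_detection_benchmark(
    n_neurons: int = 100,
    rate_range_per_min: Tuple[float, float] = (0.25, 8.0),
    snr: float = 5.0,
    duration_s: float = 500.0,
    frame_rate_hz: float = 10.0,
    seed: int = 0,
) -> Tuple[List[RawTracePair], List[np.ndarray], float]:
    """Single-session benchmark with fixed-amplitude events at a given SNR.

    Rates are log-uniform over ``rate_range_per_min``; the raw event
    amplitude is ``snr`` times the white-noise sd and constant across
    events. Returns the raw trace pairs, per-neuron true event times, and
    the kernel peak delay (seconds) for matching detected peaks to truth.
    """
    kin = KineticsSpec(amplitude_sigma=0.0)
    kin.noise_sd = kin.amplitude_dff * kin.baseline_f0 / snr
    rng = np.random.default_rng(seed)
    rates = _loguniform(rate_range_per_min[0], rate_range_per_min[1], n_neurons, rng)
    kernel, t_peak = transient_kernel(kin.rise_tau_s, kin.decay_tau_s)
    n_frames = int(round(duration_s * frame_rate_hz))
    frame_times = np.arange(n_frames) / frame_rate_hz
    support = int(math.ceil((kin.decay_tau_s * 5.5 + kin.rise_tau_s) * frame_rate_hz))
    amp = kin.amplitude_dff * kin.baseline_f0

    # shared neuropil fluctuation, as in simulate_cohort
    rho = kin.neuropil_ar1
    np_fluct = lfilter(
        [math.sqrt(1 - rho**2)], [1, -rho], rng.normal(0.0, kin.neuropil_sd, n_frames)
    )
    np_fluct += kin.neuropil_sin_amplitude * np.sin(
        2 * np.pi * frame_times / kin.neuropil_sin_period_s + rng.uniform(0, 2 * np.pi)
    )

    pairs: List[RawTracePair] = []
    truths: List[np.ndarray] = []
    for j in range(n_neurons):
        events = sample_event_times(rates[j], duration_s, rng)
        trace = np.full(n_frames, kin.baseline_f0)
        for te in events:
            i0 = int(math.ceil(te * frame_rate_hz))
            i1 = min(i0 + support, n_frames)
            if i0 >= n_frames:
                continue
            trace[i0:i1] += amp * kernel(frame_times[i0:i1] - te)
        trace += kin.drift_amplitude * np.sin(
            2 * np.pi * frame_times / kin.drift_period_s + rng.uniform(0, 2 * np.pi)
        )
        trace += kin.neuropil_mix * np_fluct
        trace += rng.normal(0.0, kin.noise_sd, n_frames)
        f_np = (
            kin.neuropil_baseline
            + np_fluct
            + rng.normal(0.0, kin.neuropil_measure_noise_sd, n_frames)
        )
        pairs.append(
            RawTracePair(
                f_roi=trace,
                f_neuropil=f_np,
                frame_rate_hz=frame_rate_hz,
                neuron_id=j,
                session_id=0,
            )
        )
        truths.append(events)
    return pairs, truths, t_peak
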