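# catrack

Longitudinal awake two-photon calcium-imaging analysis for cortical
amyloidosis studies: from raw ROI fluorescence to calcium transients,
activity categories, four-week single-cell dynamics, pairwise network
synchrony, and 3D amyloid-plaque proximity — together with a ground-truth
synthetic-data generator that emulates the recording conditions, so every
stage of the chain is testable against known truth.

**Who it is for.** Labs doing chronic GCaMP imaging in head-fixed mice
(e.g. APPPS1-type amyloidosis models vs wild-type littermates) who track
the *same* identified layer-2/3 neurons across sessions and ask: how stable
are single-neuron activity levels, where do hyperactive neurons come from,
how synchronized is the network, and does proximity to amyloid plaques
change any of this.

## The analysis in brief

Per neuron and session, raw fluorescence is neuropil-compensated

    F_comp(t) = F_ROI(t) + 0.7 · (median(F_neuropil) − F_neuropil(t)),

low-pass filtered at 5 Hz, detrended by a running 8th-percentile filter
(±50 s), and referenced to an F0/noise band estimated from quiescent
frames. Calcium transients are supra-threshold excursions of the 5-frame-
smoothed trace above F0 + 3σ lasting >9 frames, with a 15-frame minimum
peak distance; neurons are classed rarely (<0.25), intermediately (0.25–4)
or highly (>4 transients/min) active. Matched neurons yield activity-change
distributions, a within-field-of-view similarity index (Pearson R of rates
across sessions, with a neuron-identity shuffle null), category transition
matrices, reoccurrence rates and "novel highly active" recruitment.
Synchrony is the pairwise Pearson R of binarized traces (20-frame
smoothing, 2σ threshold) against a circular-shift shuffle, restricted by
behavioral epoch (whisking vs quiet wakefulness), activity category, or
centroid distance. Plaque proximity is the anisotropic 3D Euclidean
distance from each ROI centroid to the nearest plaque-positive voxel of a
cleaned, binarized structural stack; neurons ≤40 µm from a plaque are
"close". Full details and all pinned constants: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small amyloidosis-like cohort, detect transients, and summarize
one neuron:

```python
from catrack import simulate, detect
from catrack.traces import condition_trace

pop = simulate.appps1_like_population(50)
plan = simulate.cohort_plan("app")          # 3 sessions, 5000 frames, 10 Hz
cohort = simulate.simulate_cohort(pop, simulate.KineticsSpec(), plan, seed=1)

cond = condition_trace(cohort.sessions[0].trace_pair(7))
events = detect.detect_transients(cond)
summary = detect.summarize_activity(cond, events)
print(f"neuron 7: {summary.transients_per_min:.2f} transients/min, "
      f"AUC {summary.auc_per_min:.1f} dF/F*s per min, class {summary.category}")
print(f"ground truth: {cohort.manifest.true_rates[0, 7]:.2f} transients/min, "
      f"class {cohort.manifest.categories[0][7]}")
```

prints

```
neuron 7: 5.76 transients/min, AUC 13.4 dF/F*s per min, class high
ground truth: 5.76 transients/min, class high
```

— the detector recovered this highly active neuron's 48 transients
exactly. At cohort
scale (the `analysis/` drivers below), detected activity classes agree with
the generator's ground truth for ~99% of neuron-sessions.

## The analysis drivers

Numbered scripts under `analysis/` run the study-scale analyses over the
two synthetic cohorts (wild-type-like, 484 neurons; amyloidosis-like,
1572 neurons) and write tidy tables under `results/`:

1. `01_simulate_cohorts.py` — generate both cohorts, record ground truth.
2. `02_condition_and_detect.py` — condition all traces, detect transients,
   write per-neuron summaries.
3. `03_longitudinal_dynamics.py` — activity change, similarity vs shuffle,
   transitions, reoccurrence, novel-high recruitment.
4. `04_synchrony.py` — pairwise correlations vs shuffle, whisking vs
   stationary epochs, correlation vs distance.
5. `05_plaque_proximity.py` — 3D plaque distances, close/distant and
   distance-bin stratified dynamics.

Each step prints what it found; e.g. step 5 reports median nearest-plaque
distances of 37.1 / 35.6 / 34.1 µm across the three sessions (plaques grow,
distances shrink) and a higher persistence of highly active neurons close
to plaques. A `catrack` command-line interface wraps the same library
(`catrack simulate|extract|detect|dynamics|correlate|plaques|run`), and
`catrack run --config cfg.yaml` executes the whole pipeline from one strict
config file.

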