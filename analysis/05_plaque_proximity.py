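"""3D plaque proximity and its effect on activity dynamics.

Re-creates the amyloidosis-like cohort, renders the plaque volumes for each
session from the manifest geometry, measures every neuron's nearest-plaque
distance (anisotropic 3D), and stratifies the longitudinal statistics into
close (<= 40 µm) and distant neurons and into distance bins. Writes
results/plaque_distances.csv and results/proximity_dynamics.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from catrack import io, plaques, simulate
from catrack.dynamics import build_longitudinal_table
from catrack.detect import summarize_activity
from catrack.traces import condition_trace

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260925  # the amyloidosis-like cohort of 01_simulate_cohorts.py


def main() -> None:
    OUT.mkdir(exist_ok=True)
    pop = simulate.appps1_like_population()
    plan = simulate.cohort_plan("app")
    cohort = simulate.simulate_cohort(pop, simulate.KineticsSpec(), plan, seed=SEED)
    m = cohort.manifest

    summaries_path = OUT / "summaries_app.csv"
    if summaries_path.exists():
        table = pd.read_csv(summaries_path).rename(
            columns={
                "session": "session_id",
                "neuron": "neuron_id",
                "transients_per_min": "rate",
                "auc_per_min": "auc",
            }
        )
        table["fov_id"] = 0
    else:
        summaries = [
            summarize_activity(condition_trace(s.trace_pair(j)))
            for s in cohort.sessions
            for j in range(pop.n_neurons)
        ]
        table = build_longitudinal_table(summaries, cohort="app")

    rois = [
        plaques.RoiGeometry(int(nid), tuple(m.roi_centroids_um[j]))
        for j, nid in enumerate(m.neuron_ids)
    ]
    records, rows = [], []
    for s in range(plan.n_sessions):
        vol = simulate.simulate_plaque_volume(m.plaque_centers_um, m.plaque_radii_um[s])
        dists = plaques.nearest_plaque_distances(rois, vol)
        for roi, d in zip(rois, dists):
            rec = plaques.PlaqueDistanceRecord(roi.neuron_id, s, float(d))
            records.append(rec)
            rows.append(
                {
                    "session": s,
                    "neuron": rec.neuron_id,
                    "distance_um": rec.distance_um,
                    "class": rec.proximity_class,
                }
            )
    dist_df = pd.DataFrame(rows)
    io.write_csv(dist_df, OUT / "plaque_distances.csv")
    for s in range(plan.n_sessions):
        med = dist_df[dist_df.session == s]["distance_um"].median()
        print(f"session {s}: median nearest-plaque distance {med:.1f} µm")

    strat = plaques.proximity_stratified_dynamics(table, records, cutoff_um=40.0)
    bins = plaques.proximity_stratified_dynamics(
        table, records, bin_edges_um=np.array([0.0, 20.0, 40.0, 60.0, 200.0])
    )
    for name, v in strat["strata"].items():
        print(
            f"{name}: n={v['n_neurons']}, high reoccurrence "
            f"{v['reoccurrence']['high']:.2f}"
        )

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    (OUT / "proximity_dynamics.json").write_text(
        json.dumps({"cutoff_40um": clean(strat), "bins": clean(bins)}, indent=2, sort_keys=True)
    )
    print(f"wrote plaque tables to {OUT}")


if __name__ == "__main__":
    main()
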