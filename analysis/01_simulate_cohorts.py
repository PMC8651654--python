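"""Generate the two study-like cohorts and record their ground truth.

Simulates a wild-type-like cohort (484 neurons) and an amyloidosis-model-
like cohort (1572 neurons), each imaged over three sessions of 5000 frames
at 10 Hz, and writes a composition summary to results/ (the full per-event
ground-truth manifests are megabytes of regenerable JSON and go to
scratch/). Downstream drivers re-create the same cohorts deterministically
from the seeds recorded here instead of shipping bulky trace tables.
"""

import json
from pathlib import Path

import numpy as np

from catrack import simulate

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEEDS = {"wt": 20260924, "app": 20260925}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    summary = {}
    for label, pop in (
        ("wt", simulate.wt_like_population()),
        ("app", simulate.appps1_like_population()),
    ):
        plan = simulate.cohort_plan(label)
        cohort = simulate.simulate_cohort(
            pop, simulate.KineticsSpec(), plan, seed=SEEDS[label]
        )
        m = cohort.manifest
        m.to_json(SCRATCH / f"ground_truth_{label}.json")
        cats = np.array(m.categories[0])
        summary[label] = {
            "seed": SEEDS[label],
            "n_neurons": pop.n_neurons,
            "sessions": plan.n_sessions,
            "frames_per_session": plan.frames_per_session,
            "category_fractions_session0": {
                c: round(float((cats == c).mean()), 4)
                for c in ("rare", "intermediate", "high")
            },
            "mean_true_rate_per_min": round(float(m.true_rates[0].mean()), 3),
            "n_plaques": int(m.plaque_centers_um.shape[0]),
        }
        print(
            f"{label}: {pop.n_neurons} neurons, composition "
            f"{summary[label]['category_fractions_session0']}, "
            f"mean rate {summary[label]['mean_true_rate_per_min']}/min"
        )
    (OUT / "cohorts.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    print(f"wrote manifests and cohorts.json to {OUT}")


if __name__ == "__main__":
    main()
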