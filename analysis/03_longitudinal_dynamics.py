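"""Four-week dynamics of matched neurons: stability, transitions,
recruitment of novel highly active cells.

Consumes the summaries written by 02_condition_and_detect.py and writes a
tidy statistics table (results/dynamics.csv). Prints the headline
contrasts: activity-change spread, similarity vs its shuffle null,
intermediate-to-high recruitment, per-category reoccurrence, and the origin
and gain of novel highly active neurons.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from catrack import dynamics as dyn, io

OUT = Path(__file__).resolve().parent.parent / "results"


def load_table(label: str) -> pd.DataFrame:
    df = pd.read_csv(OUT / f"summaries_{label}.csv").rename(
        columns={
            "session": "session_id",
            "neuron": "neuron_id",
            "transients_per_min": "rate",
            "auc_per_min": "auc",
        }
    )
    df["fov_id"] = 0
    df["cohort"] = label
    return df


def main() -> None:
    rows = []
    for label in ("wt", "app"):
        t = load_table(label)
        for s0, s1 in ((0, 1), (0, 2)):
            pair = f"week0-{2 * s1}"
            delta = dyn.activity_change(t, s0, s1)
            m0 = t[t.session_id == s0].set_index("neuron_id")["rate"]
            m1 = t[t.session_id == s1].set_index("neuron_id")["rate"]
            sim = dyn.similarity_index(m0.to_numpy(), m1.to_numpy())
            null = dyn.shuffle_null_similarity(t, s0, s1, n_shuffles=100, seed=1)
            tr = dyn.transition_matrix(t, s0, s1)
            novel = dyn.novel_high_analysis(t, s0, s1, seed=1)
            rec = {
                c: dyn.reoccurrence_rate(t, c, s0, s1)
                for c in ("rare", "intermediate", "high")
            }
            rows.append(
                {
                    "cohort": label,
                    "pair": pair,
                    "frac_abs_delta_le_2": float((delta.abs() <= 2).mean()),
                    "similarity": sim,
                    "similarity_shuffled": float(np.nanmean(null)),
                    "recruitment_int_to_high": tr.recruitment_rate,
                    "reocc_rare": rec["rare"],
                    "reocc_intermediate": rec["intermediate"],
                    "reocc_high": rec["high"],
                    "novel_high_n": novel.n_new_high,
                    "novel_from_intermediate": novel.frac_from_intermediate,
                    "novel_gain_per_min": novel.mean_gain,
                    "novel_gain_ci_lo": novel.ci_low,
                    "novel_gain_ci_hi": novel.ci_high,
                }
            )
            if (s0, s1) == (0, 1):
                print(
                    f"{label} week0-2: similarity {sim:.2f} "
                    f"(shuffled {np.nanmean(null):+.3f}), "
                    f"int->high {100 * tr.recruitment_rate:.1f}%, "
                    f"novel-high gain {novel.mean_gain:.2f} "
                    f"[{novel.ci_low:.2f}, {novel.ci_high:.2f}]/min "
                    f"({100 * novel.frac_from_intermediate:.0f}% from intermediate)"
                )
        # distributions of activity change differ between cohorts?
    wt_delta = dyn.activity_change(load_table("wt"), 0, 2)
    app_delta = dyn.activity_change(load_table("app"), 0, 2)
    d, p = dyn.compare_change_distributions(wt_delta, app_delta)
    print(f"KS(wt vs app, week0-4 change): D={d:.3f}, p={p:.2g}")
    io.write_csv(pd.DataFrame(rows), OUT / "dynamics.csv")
    print(f"wrote dynamics.csv to {OUT}")


if __name__ == "__main__":
    main()
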