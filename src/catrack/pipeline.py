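"""End-to-end pipeline driver: simulate or load, condition, detect,
longitudinal dynamics, synchrony, plaque proximity; all results to disk.

Per-neuron quality problems (flat traces, non-positive baselines) are
logged and flagged but never abort the run; missing inputs fail fast.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import __version__
from . import behavior, correlate, detect, dynamics, io, plaques, simulate
from .config import RunConfig
from .traces import condition_trace

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _condition_all(pairs_by_session, cfg: RunConfig):
    conds = {}
    for sid, pairs in pairs_by_session.items():
        conds[sid] = [
            condition_trace(
                p,
                neuropil_factor=cfg.neuropil_factor,
                cutoff_hz=cfg.lowpass_cutoff_hz,
                window_s=cfg.detrend_window_s,
                pct=cfg.detrend_pct,
                short_window_s=cfg.f0_short_window_s,
                band_pct=cfg.noise_band_pct,
            )
            for p in pairs
        ]
    return conds


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full chain and write the report bundle to config.out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    logging.getLogger("catrack").addHandler(handler)
    report: Dict = {"config": config.to_dict(), "version": __version__}
    try:
        # ---- inputs -----------------------------------------------------
        manifest = None
        whisk_by_session: Dict[int, np.ndarray] = {}
        centroids = None
        if config.traces_path is not None:
            path = Path(config.traces_path)
            if not path.exists():
                raise FileNotFoundError(f"traces input not found: {path}")
            if path.suffix in (".h5", ".hdf5"):
                pairs_by_session = io.read_trace_tables_hdf5(path)
            else:
                pairs_by_session = io.read_trace_tables_csv(path, config.frame_rate_hz)
            if config.whisk_path:
                wdf = pd.read_csv(config.whisk_path)
                for sid, grp in wdf.groupby("session"):
                    whisk_by_session[int(sid)] = (
                        grp.sort_values("frame")["state"].to_numpy().astype(np.uint8)
                    )
        else:
            pop = (
                simulate.appps1_like_population(config.n_neurons)
                if config.cohort == "app"
                else simulate.wt_like_population(config.n_neurons)
            )
            plan = simulate.cohort_plan(
                config.cohort,
                n_sessions=config.n_sessions,
                frames_per_session=config.frames_per_session,
                frame_rate_hz=config.frame_rate_hz,
            )
            field = simulate.PlaqueFieldSpec(
                n_plaques=4 if config.cohort == "app" else 0,
                shape_voxels=(48, 160, 160),
            )
            cohort = simulate.simulate_cohort(
                pop,
                simulate.KineticsSpec(),
                plan,
                seed=config.seed,
                plaque_field=field,
                render_plaque_volumes=True,
            )
            manifest = cohort.manifest
            centroids = manifest.roi_centroids_um
            pairs_by_session = {
                s.session_id: [s.trace_pair(j) for j in range(s.f_roi.shape[1])]
                for s in cohort.sessions
            }
            whisk_by_session = {s.session_id: s.whisk_track for s in cohort.sessions}
            volumes = {s.session_id: s.plaque_volume for s in cohort.sessions}

        session_ids = sorted(pairs_by_session)
        # ---- condition + detect ----------------------------------------
        conds = _condition_all(pairs_by_session, config)
        events_by_key, summaries = {}, []
        for sid in session_ids:
            for cond in conds[sid]:
                if cond.noise_sd <= 0:
                    logger.warning(
                        "neuron %s session %s: flat trace, excluded", cond.neuron_id, sid
                    )
                    events = []
                else:
                    events = detect.detect_transients(
                        cond,
                        smooth_frames=config.detect_smooth_frames,
                        k_sd=config.detect_k_sd,
                        duration_frames=config.detect_duration_frames,
                        min_distance_frames=config.detect_min_distance_frames,
                    )
                events_by_key[(sid, cond.neuron_id)] = events
                summaries.append(detect.summarize_activity(cond, events))
        frame_rate = pairs_by_session[session_ids[0]][0].frame_rate_hz
        events_df = io.events_to_frame(events_by_key, frame_rate)
        summaries_df = io.summaries_to_frame(summaries)
        table = dynamics.build_longitudinal_table(summaries, cohort="")
        table["session_id"] = table["session_id"].astype(int)

        # ---- longitudinal dynamics -------------------------------------
        dyn: Dict = {}
        s0 = session_ids[0]
        for s1 in session_ids[1:]:
            key = f"{s0}-{s1}"
            delta = dynamics.activity_change(table, s0, s1)
            tr = dynamics.transition_matrix(table, s0, s1)
            m0 = table[table["session_id"] == s0].set_index("neuron_id")
            m1 = table[table["session_id"] == s1].set_index("neuron_id")
            ids = m0.index.intersection(m1.index)
            si = dynamics.similarity_index(
                m0.loc[ids, "rate"].to_numpy(), m1.loc[ids, "rate"].to_numpy()
            )
            null = dynamics.shuffle_null_similarity(
                table, s0, s1, n_shuffles=config.n_shuffles, seed=config.seed
            )
            novel = dynamics.novel_high_analysis(table, s0, s1, seed=config.seed)
            reocc = {}
            for cat in detect.CATEGORIES:
                try:
                    reocc[cat] = dynamics.reoccurrence_rate(table, cat, s0, s1)
                except ValueError:
                    reocc[cat] = float("nan")
            dyn[key] = {
                "mean_delta_rate": float(delta.mean()),
                "frac_abs_delta_le_2": float((delta.abs() <= 2).mean()),
                "similarity_index": si,
                "similarity_null_mean": float(np.nanmean(null)),
                "transition_counts": tr.counts.to_numpy().tolist(),
                "recruitment_int_to_high": tr.recruitment_rate,
                "reoccurrence": reocc,
                "novel_high": {
                    "n": novel.n_new_high,
                    "frac_from_intermediate": novel.frac_from_intermediate,
                    "mean_gain": novel.mean_gain,
                    "ci": [novel.ci_low, novel.ci_high],
                },
            }

        # ---- synchrony --------------------------------------------------
        corr_rows = []
        for sid in session_ids:
            usable = [c for c in conds[sid] if c.noise_sd > 0]
            cent = centroids[:, :2] if centroids is not None else None
            raster = correlate.build_raster(
                usable,
                centroids_um=cent,
                smooth_frames=config.binarize_smooth_frames,
                k_sd=config.binarize_k_sd,
            )
            res = correlate.pairwise_correlation(raster)
            null = correlate.shuffle_control(
                raster, n_shuffles=config.n_shuffles, seed=config.seed
            )
            row = {
                "session": sid,
                "mean_r": res.mean_r,
                "null_mean_r": float(np.nanmean(null)),
                "n_pairs": len(res.r),
                "n_excluded_pairs": res.n_excluded,
            }
            if sid in whisk_by_session:
                epochs = behavior.detect_whisk_epochs(
                    whisk_by_session[sid], frame_rate, config.whisk_min_duration_s
                )
                assoc, discarded = behavior.whisk_response_windows(
                    epochs, config.whisk_window_min_s, config.whisk_window_max_s
                )
                stat = behavior.stationary_mask(epochs, assoc, discarded)
                whisk_frames = epochs.mask("whisk") | assoc
                by_epoch = correlate.epoch_restricted_correlation(
                    raster, {"whisk": whisk_frames, "stationary": stat}
                )
                row["mean_r_whisk"] = by_epoch["whisk"].mean_r
                row["mean_r_stationary"] = by_epoch["stationary"].mean_r
            corr_rows.append(row)
        corr_df = pd.DataFrame(corr_rows)

        # ---- plaque proximity ------------------------------------------
        dist_df = pd.DataFrame()
        strat = None
        if manifest is not None and manifest.plaque_centers_um.shape[0] > 0:
            rois = [
                plaques.RoiGeometry(int(nid), tuple(manifest.roi_centroids_um[j]))
                for j, nid in enumerate(manifest.neuron_ids)
            ]
            records = []
            for sid in session_ids:
                dists = plaques.nearest_plaque_distances(rois, volumes[sid])
                records.extend(
                    plaques.PlaqueDistanceRecord(roi.neuron_id, sid, float(d))
                    for roi, d in zip(rois, dists)
                )
            dist_df = pd.DataFrame(
                [
                    {
                        "session": r.session_id,
                        "neuron": r.neuron_id,
                        "distance_um": r.distance_um,
                        "class": r.proximity_class,
                    }
                    for r in records
                ]
            )
            strat = plaques.proximity_stratified_dynamics(
                table, records, cutoff_um=config.proximity_cutoff_um
            )

        # ---- write bundle ----------------------------------------------
        io.write_csv(summaries_df, out_dir / "summaries.csv")
        io.write_csv(events_df, out_dir / "events.csv")
        io.write_longitudinal(table, out_dir / "longitudinal.csv")
        io.write_csv(corr_df, out_dir / "correlation.csv")
        (out_dir / "dynamics.json").write_text(
            json.dumps(dyn, indent=2, sort_keys=True)
        )
        if not dist_df.empty:
            io.write_csv(dist_df, out_dir / "plaque_distances.csv")
        if strat is not None:
            serializable = {
                "ks_between_strata": strat["ks_between_strata"],
                "strata": {
                    k: {
                        kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                        for kk, vv in v.items()
                    }
                    for k, v in strat["strata"].items()
                },
            }
            (out_dir / "proximity_stratified.json").write_text(
                json.dumps(serializable, indent=2, sort_keys=True)
            )
        run_manifest = {
            "config": config.to_dict(),
            "version": __version__,
            "n_sessions": len(session_ids),
            "n_neurons": int(table["neuron_id"].nunique()),
            "n_events_total": int(sum(len(v) for v in events_by_key.values())),
            "seed": config.seed,
        }
        (out_dir / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=2, sort_keys=True)
        )
        report.update(
            {
                "summaries": summaries_df,
                "events": events_df,
                "longitudinal": table,
                "dynamics": dyn,
                "correlation": corr_df,
                "plaque_distances": dist_df,
                "stratified": strat,
                "run_manifest": run_manifest,
                "out_dir": str(out_dir),
            }
        )
        return report
    finally:
        logging.getLogger("catrack").removeHandler(handler)
        handler.close()
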