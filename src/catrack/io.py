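"""Reading and writing the pipeline's table and image formats.

Trace tables travel as long-format CSV (session, neuron, frame, f_roi,
f_neuropil) or HDF5 (datasets per session); events, summaries and the
longitudinal table as tidy CSV; plaque volumes as multi-page TIFF with a
JSON voxel-size sidecar. All CSV output uses a fixed float format so that
identical runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import tifffile

from .detect import ActivitySummary, TransientEvent
from .plaques import PlaqueVolume
from .traces import RawTracePair

__all__ = [
    "FLOAT_FORMAT",
    "write_csv",
    "extract_traces",
    "write_trace_tables_csv",
    "read_trace_tables_csv",
    "write_trace_tables_hdf5",
    "read_trace_tables_hdf5",
    "events_to_frame",
    "summaries_to_frame",
    "write_longitudinal",
    "read_longitudinal",
    "write_plaque_volume",
    "read_plaque_volume",
]

FLOAT_FORMAT = "%.9g"


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV output (fixed float format, no index)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def extract_traces(
    movie: np.ndarray, roi_labels: np.ndarray, neuropil_labels: np.ndarray
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame mean fluorescence over each ROI and its neuropil region.

    ``movie`` is (frames, y, x); the label images assign positive integer
    IDs to ROI and neuropil pixels. Returns two frames x neuron DataFrames
    (columns = ROI IDs). Missing or empty labels raise with the offending ID.
    """
    movie = np.asarray(movie, dtype=np.float64)
    roi_labels = np.asarray(roi_labels)
    neuropil_labels = np.asarray(neuropil_labels)
    if movie.ndim != 3 or movie.shape[1:] != roi_labels.shape:
        raise ValueError("movie and label images must share the in-plane shape")
    ids = sorted(int(i) for i in np.unique(roi_labels) if i > 0)
    if not ids:
        raise ValueError("no ROI labels found")
    flat = movie.reshape(movie.shape[0], -1)
    roi_out, np_out = {}, {}
    for i in ids:
        roi_idx = np.flatnonzero(roi_labels.ravel() == i)
        np_idx = np.flatnonzero(neuropil_labels.ravel() == i)
        if roi_idx.size == 0:
            raise ValueError(f"ROI label {i} is empty")
        if np_idx.size == 0:
            raise ValueError(f"label {i} absent from the neuropil mask")
        roi_out[i] = flat[:, roi_idx].mean(axis=1)
        np_out[i] = flat[:, np_idx].mean(axis=1)
    return pd.DataFrame(roi_out), pd.DataFrame(np_out)


# ---- trace tables -------------------------------------------------------

def _pairs_to_long(pairs_by_session: Dict[int, List[RawTracePair]]) -> pd.DataFrame:
    rows = []
    for sid in sorted(pairs_by_session):
        for p in pairs_by_session[sid]:
            rows.append(
                pd.DataFrame(
                    {
                        "session": sid,
                        "neuron": p.neuron_id,
                        "frame": np.arange(p.f_roi.size),
                        "f_roi": p.f_roi,
                        "f_neuropil": p.f_neuropil,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_trace_tables_csv(
    pairs_by_session: Dict[int, List[RawTracePair]], path
) -> None:
    write_csv(_pairs_to_long(pairs_by_session), path)


def read_trace_tables_csv(path, frame_rate_hz: float) -> Dict[int, List[RawTracePair]]:
    df = pd.read_csv(path)
    out: Dict[int, List[RawTracePair]] = {}
    for (sid, nid), grp in df.groupby(["session", "neuron"], sort=True):
        grp = grp.sort_values("frame")
        out.setdefault(int(sid), []).append(
            RawTracePair(
                f_roi=grp["f_roi"].to_numpy(),
                f_neuropil=grp["f_neuropil"].to_numpy(),
                frame_rate_hz=frame_rate_hz,
                neuron_id=int(nid),
                session_id=int(sid),
            )
        )
    return out


def write_trace_tables_hdf5(
    pairs_by_session: Dict[int, List[RawTracePair]], path, frame_rate_hz: float
) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["frame_rate_hz"] = frame_rate_hz
        for sid, pairs in pairs_by_session.items():
            grp = fh.create_group(f"session_{sid}")
            grp.create_dataset("f_roi", data=np.column_stack([p.f_roi for p in pairs]))
            grp.create_dataset(
                "f_neuropil", data=np.column_stack([p.f_neuropil for p in pairs])
            )
            grp.create_dataset(
                "neuron_ids", data=np.array([p.neuron_id for p in pairs])
            )


def read_trace_tables_hdf5(path) -> Dict[int, List[RawTracePair]]:
    out: Dict[int, List[RawTracePair]] = {}
    with h5py.File(path, "r") as fh:
        fr = float(fh.attrs["frame_rate_hz"])
        for name in sorted(fh):
            sid = int(name.split("_")[1])
            grp = fh[name]
            roi = grp["f_roi"][()]
            npil = grp["f_neuropil"][()]
            ids = grp["neuron_ids"][()]
            out[sid] = [
                RawTracePair(roi[:, j], npil[:, j], fr, int(ids[j]), sid)
                for j in range(roi.shape[1])
            ]
    return out


# ---- events and summaries ----------------------------------------------

def events_to_frame(
    events_by_neuron: Dict[Tuple[int, int], Sequence[TransientEvent]],
    frame_rate_hz: float,
) -> pd.DataFrame:
    """Events table in seconds, keyed by (session, neuron)."""
    rows = []
    for (sid, nid), events in sorted(events_by_neuron.items()):
        for e in events:
            rows.append(
                {
                    "session": sid,
                    "neuron": nid,
                    "onset_s": e.onset_frame / frame_rate_hz,
                    "offset_s": e.offset_frame / frame_rate_hz,
                    "peak_s": e.peak_frame / frame_rate_hz,
                    "peak_height_sd": e.peak_height,
                    "peak_dff": e.peak_dff,
                }
            )
    columns = ["session", "neuron", "onset_s", "offset_s", "peak_s", "peak_height_sd", "peak_dff"]
    return pd.DataFrame(rows, columns=columns)


def summaries_to_frame(summaries: Sequence[ActivitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "session": s.session_id,
                "neuron": s.neuron_id,
                "transients_per_min": s.transients_per_min,
                "auc_per_min": s.auc_per_min,
                "category": s.category,
                "is_active": s.is_active,
                "n_events": s.n_events,
                "flags": ";".join(s.flags),
            }
            for s in sorted(summaries, key=lambda s: (s.session_id, s.neuron_id))
        ]
    )


def write_longitudinal(table: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            for col in table.columns:
                data = table[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                fh.create_dataset(col, data=data)
    else:
        write_csv(table, path)


def read_longitudinal(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            cols = {}
            for name in fh:
                data = fh[name][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[name] = data
        df = pd.DataFrame(cols)
    else:
        df = pd.read_csv(path)
    order = [c for c in ("neuron_id", "session_id", "rate", "auc", "category", "fov_id", "cohort") if c in df.columns]
    return df[order + [c for c in df.columns if c not in order]]


# ---- volumes ------------------------------------------------------------

def write_plaque_volume(vol: PlaqueVolume, tif_path) -> None:
    """Multi-page TIFF (one page per z-slice) + JSON voxel-size sidecar."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, vol.mask.astype(np.uint8))
    sidecar = tif_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "voxel_size_um": list(vol.voxel_size_um),
                "origin_um": list(vol.origin_um),
                "axis_order": "zyx",
            },
            indent=2,
        )
    )


def read_plaque_volume(tif_path) -> PlaqueVolume:
    tif_path = Path(tif_path)
    mask = tifffile.imread(tif_path).astype(bool)
    meta = json.loads(tif_path.with_suffix(".json").read_text())
    return PlaqueVolume(
        mask=mask,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
    )
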