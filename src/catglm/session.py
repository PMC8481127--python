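"""Session containers and their HDF5 / CSV persistence.

A :class:`SessionRecording` bundles everything one imaging session
contributes to the analysis: the inferred-spike activity matrix
(neurons x frames), the frame rate, the trial table and the continuous
behavioral covariates (running speed, per-spout lick rates). Synthetic
sessions additionally carry their planted ground truth under
``meta["ground_truth"]``.

On disk the container is an HDF5 file with groups ``/activity``,
``/covariates``, ``/trials`` (columnar) and ``/meta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["SessionRecording", "save_session", "load_session"]


@dataclass
class SessionRecording:
    """One imaging session: activity, covariates and the trial table."""

    activity: np.ndarray = field(repr=False)       # neurons x frames
    frame_rate_hz: float
    trials: pd.DataFrame = field(repr=False)
    covariates: dict[str, np.ndarray] = field(repr=False)
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def _write_dataframe(group: h5py.Group, df: pd.DataFrame) -> None:
    for name in df.columns:
        col = df[name]
        if col.dtype == object or pd.api.types.is_string_dtype(col):
            data = col.astype(str).to_numpy()
            group.create_dataset(name, data=data.astype(h5py.string_dtype("utf-8")))
        else:
            group.create_dataset(name, data=col.to_numpy())
    group.attrs["column_order"] = json.dumps(list(df.columns))


def _read_dataframe(group: h5py.Group) -> pd.DataFrame:
    order = json.loads(group.attrs["column_order"])
    data = {}
    for name in order:
        arr = group[name][()]
        if arr.dtype.kind in ("O", "S"):
            arr = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in arr])
        data[name] = arr
    return pd.DataFrame(data)


def save_session(session: SessionRecording, path) -> None:
    """Write a session container to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=session.activity)
        cov = f.create_group("covariates")
        for name, trace in session.covariates.items():
            cov.create_dataset(name, data=np.asarray(trace))
        _write_dataframe(f.create_group("trials"), session.trials)
        meta = f.create_group("meta")
        meta.attrs["frame_rate_hz"] = session.frame_rate_hz
        gt = session.meta.get("ground_truth")
        if gt is not None:
            gt_group = meta.create_group("ground_truth")
            gt_group.create_dataset("weights", data=np.asarray(gt["weights"]))
            _write_dataframe(gt_group.create_group("columns"), gt["columns"])
        rest = {k: v for k, v in session.meta.items() if k != "ground_truth"}
        meta.attrs["json"] = json.dumps(rest, default=str)


def load_session(path) -> SessionRecording:
    """Read a session container written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        activity = f["activity"][()]
        covariates = {name: f["covariates"][name][()] for name in f["covariates"]}
        trials = _read_dataframe(f["trials"])
        meta = json.loads(f["meta"].attrs["json"])
        frame_rate = float(f["meta"].attrs["frame_rate_hz"])
        if "ground_truth" in f["meta"]:
            gt_group = f["meta"]["ground_truth"]
            meta["ground_truth"] = {
                "weights": gt_group["weights"][()],
                "columns": _read_dataframe(gt_group["columns"]),
            }
    # restore boolean dtype lost through HDF5 round trip
    for col in ("response_made", "correct"):
        if col in trials:
            trials[col] = trials[col].astype(bool)
    return SessionRecording(
        activity=activity, frame_rate_hz=frame_rate,
        trials=trials, covariates=covariates, meta=meta,
    )
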