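"""On-disk formats.

* EEG: raw little-endian float32, channel-major, with a JSON sidecar
  carrying the sampling rate, channel names and 3-D electrode positions
  (mm).
* Gaze and events: TSV with fixed column names.
* ROI atlas: JSON (see :class:`frproi.projection.ROIAtlas`).
* Epoch sets: HDF5 with datasets ``epochs``, ``times``, ``labels``,
  ``conditions`` and attributes ``fs``, ``series_kind``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .gaze import GazeTrace
from .preprocess import EpochSet, Recording

GAZE_COLUMNS = ("t_s", "x_deg", "y_deg", "pupil", "valid")
EVENT_COLUMNS = ("onset_s", "stim_x_deg", "stim_y_deg", "is_target",
                 "condition")


def write_recording(rec: Recording, stem: Path) -> None:
    """``<stem>.f32`` (channel-major float32) plus ``<stem>.json``."""
    stem = Path(stem)
    rec.data.astype("<f4").tofile(stem.with_suffix(".f32"))
    sidecar = dict(fs=rec.fs, channel_names=list(rec.channel_names),
                   electrode_positions_mm=np.asarray(
                       rec.electrode_positions).tolist(),
                   n_channels=rec.data.shape[0],
                   n_samples=rec.data.shape[1],
                   reference=rec.reference, dtype="<f4", order="channel-major")
    stem.with_suffix(".json").write_text(json.dumps(sidecar))


def read_recording(stem: Path) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".f32"), dtype="<f4").reshape(
        meta["n_channels"], meta["n_samples"]).astype(float)
    return Recording(data=data, fs=meta["fs"],
                     channel_names=tuple(meta["channel_names"]),
                     electrode_positions=np.asarray(
                         meta["electrode_positions_mm"]),
                     reference=meta.get("reference", "recording"))


def write_gaze(trace: GazeTrace, path: Path) -> None:
    pd.DataFrame({"t_s": trace.t, "x_deg": trace.x, "y_deg": trace.y,
                  "pupil": trace.pupil,
                  "valid": trace.valid.astype(int)}).to_csv(
        path, sep="\t", index=False)


def read_gaze(path: Path, fs: float | None = None) -> GazeTrace:
    df = pd.read_csv(path, sep="\t")
    t = df["t_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return GazeTrace(t=t, x=df["x_deg"].to_numpy(), y=df["y_deg"].to_numpy(),
                     pupil=df["pupil"].to_numpy(),
                     valid=df["valid"].to_numpy().astype(bool), fs=fs)


def write_events(events: pd.DataFrame, path: Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_epochs(epochs: EpochSet, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("epochs", data=epochs.epochs)
        fh.create_dataset("times", data=epochs.times)
        fh.create_dataset("labels", data=epochs.labels)
        fh.create_dataset("conditions",
                          data=np.asarray(epochs.conditions, dtype="S"))
        fh.attrs["fs"] = epochs.fs
        fh.attrs["series_kind"] = epochs.series_kind


def read_epochs(path: Path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        return EpochSet(
            epochs=fh["epochs"][()], times=fh["times"][()],
            labels=fh["labels"][()],
            conditions=np.array([c.decode() for c in fh["conditions"][()]],
                                dtype=object),
            fs=float(fh.attrs["fs"]),
            series_kind=str(fh.attrs["series_kind"]))


def write_dipoles(dipoles, path: Path) -> None:
    rows = [dict(ic=i, x_mm=d.location[0], y_mm=d.location[1],
                 z_mm=d.location[2], rv=d.residual_variance)
            for i, d in enumerate(dipoles)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_weights(weights, path: Path) -> None:
    rows = []
    for i in range(weights.w.shape[0]):
        for j, roi in enumerate(weights.roi_names):
            rows.append(dict(ic=i, roi=roi, weight=weights.w[i, j]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
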