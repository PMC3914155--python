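"""File formats: recordings (HDF5), spike trains (CSV), masks (text rasters).

Recording schema (HDF5): dataset ``samples`` (channels x time, volts) with
attributes ``sampling_rate`` (Hz) and ``band``; optional dataset
``event_times`` (seconds).  Spike trains are CSV with columns
``channel, time_s, label``.  Barrel masks are plain-text 0/1 rasters with a
JSON sidecar describing the plane they live on.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .barrels import BarrelMask
from .preprocessing import Recording

__all__ = [
    "save_recording",
    "load_recording",
    "save_spike_trains",
    "load_spike_times",
    "save_mask",
    "load_mask",
    "write_manifest",
    "export_plane_csv",
]


def save_recording(recording: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=recording.samples)
        ds.attrs["units"] = "V"
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["band"] = recording.band
        f.attrs["channel_labels"] = json.dumps(list(recording.channel_labels))
        if len(recording.event_times):
            f.create_dataset("event_times", data=recording.event_times)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        events = f["event_times"][()] if "event_times" in f else np.empty(0)
        labels = tuple(json.loads(f.attrs.get("channel_labels", "[]")))
        return Recording(
            samples=f["samples"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            event_times=events,
            channel_labels=labels,
            band=str(f.attrs.get("band", "raw")),
        )


def save_spike_trains(trains, path) -> None:
    rows = []
    for tr in trains:
        labels = tr.labels if tr.labels is not None else [""] * tr.n_spikes
        for t, lab in zip(tr.times, labels):
            rows.append({"channel": tr.channel, "time_s": t, "label": lab})
    pd.DataFrame(rows, columns=["channel", "time_s", "label"]).to_csv(
        path, index=False)


def load_spike_times(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_mask(mask: BarrelMask, path) -> None:
    path = Path(path)
    np.savetxt(path, mask.values, fmt="%d")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "plane_index": mask.plane_index,
        "provenance": mask.provenance,
        "shape": list(mask.values.shape),
    }, indent=1))


def load_mask(path) -> BarrelMask:
    path = Path(path)
    values = np.loadtxt(path, dtype=int)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return BarrelMask(values=np.atleast_2d(values),
                      plane_index=int(meta.get("plane_index", 0)),
                      provenance=meta.get("provenance", "anatomical"))


def write_manifest(path, **entries) -> None:
    """Record run provenance (inputs, parameters, seeds) as JSON."""
    from . import __version__

    payload = {"package_version": __version__}
    payload.update(entries)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


def export_plane_csv(volume, z_index, path):
    """Write one interior xy-plane of a CSD volume as tidy CSV.

    Columns: x_um, y_um, z_um, csd (per-um^3 units); guard nodes excluded.
    """
    from .barrels import extract_layer4_plane

    plane = extract_layer4_plane(volume, z_index)
    grid = volume.grid
    gx, gy, _ = grid.guard_widths
    xs = grid.origin[0] + (gx + np.arange(plane.shape[0])) * grid.d
    ys = grid.origin[1] + (gy + np.arange(plane.shape[1])) * grid.d
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    z = grid.origin[2] + z_index * grid.d
    pd.DataFrame({
        "x_um": X.ravel(), "y_um": Y.ravel(),
        "z_um": np.full(plane.size, z), "csd": plane.ravel(),
    }).to_csv(path, index=False)
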