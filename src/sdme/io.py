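"""File formats: HDF5/CSV rasters and stimuli, JSON models and manifests.

Raster container (HDF5): datasets ``/spikes`` (uint8, repeat x time x
neuron), ``/dt`` (scalar seconds), optional ``/positions`` (neuron x 2,
micrometres).  CSV alternative: columns (neuron_id, repeat, spike_time_s)
binarized on load.  Stimulus: HDF5 ``/luminance`` + ``/update_rate_hz``
(+ optional ``/taps``), or a one-column CSV with the rate supplied by the
caller.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import numpy as np
import pandas as pd

from .popdata import SpikeRaster, StimulusTrace, binarize


def save_raster(raster: SpikeRaster, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=raster.spikes, dtype="uint8",
                         compression="gzip")
        f.create_dataset("dt", data=float(raster.dt))
        if raster.positions is not None:
            f.create_dataset("positions", data=raster.positions)


def load_raster(path) -> SpikeRaster:
    path = str(path)
    if path.endswith(".csv"):
        return _load_raster_csv(path)
    with h5py.File(path, "r") as f:
        if "spikes" not in f or "dt" not in f:
            raise ValueError(f"malformed raster file {path!r}: needs "
                             "/spikes and /dt")
        spikes = f["spikes"][...]
        dt = float(f["dt"][()])
        pos = f["positions"][...] if "positions" in f else None
    return SpikeRaster(spikes, dt=dt, positions=pos)


def _load_raster_csv(path, dt: float = 0.02) -> SpikeRaster:
    df = pd.read_csv(path)
    need = {"neuron_id", "repeat", "spike_time_s"}
    if not need.issubset(df.columns):
        raise ValueError(f"raster CSV must have columns {sorted(need)}")
    n_neu = int(df.neuron_id.max()) + 1
    n_rep = int(df["repeat"].max()) + 1
    duration = float(df.spike_time_s.max()) + dt
    trains = [[df.loc[(df["repeat"] == r) & (df.neuron_id == i),
                      "spike_time_s"].to_numpy()
               for i in range(n_neu)] for r in range(n_rep)]
    return binarize(trains, dt, duration=duration)


def save_stimulus(stim: StimulusTrace, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("luminance", data=stim.luminance)
        f.create_dataset("update_rate_hz", data=float(stim.update_rate))
        f.create_dataset("taps", data=int(stim.D))


def load_stimulus(path, update_rate_hz: float | None = None,
                  D: int = 40) -> StimulusTrace:
    path = str(path)
    if path.endswith(".csv"):
        lum = pd.read_csv(path).iloc[:, 0].to_numpy(dtype=float)
        if update_rate_hz is None:
            raise ValueError("update_rate_hz required for CSV stimulus")
        return StimulusTrace(lum, update_rate_hz, D=D)
    with h5py.File(path, "r") as f:
        lum = f["luminance"][...]
        rate = float(f["update_rate_hz"][()])
        taps = int(f["taps"][()]) if "taps" in f else D
    return StimulusTrace(lum, rate, D=taps)


def save_samples(samples: np.ndarray, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=samples.astype(np.uint8),
                         compression="gzip")


def checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
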