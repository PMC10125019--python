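"""Session readers/writers.

Sessions are stored in a documented flat HDF5 layout:

::

    /lfp/data            (n_channels, n_samples) float64, volts
    /lfp/timestamps      (n_samples,) float64, seconds
    /lfp/artifact_mask   (n_samples,) bool
    /channels/{channel_id, probe_id, area, ap, dv, ml}
    /units/table/{cluster_id, probe_id, area, ap, dv, ml,
                  waveform_duration_ms, peak_trough_ratio, isi_violations,
                  amplitude_cutoff, presence_ratio, firing_rate}
    /units/spike_times   ragged: concatenated times + /units/spike_index
    /behavior/{times, speed}

Analysis tables are written as CSV (fixed float format, so identical inputs
produce byte-identical files) or Parquet; summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    ChannelInfo,
    DataIntegrityError,
    LfpRecording,
    SpeedTrace,
    SpikeClusterSet,
)

_STR = h5py.string_dtype(encoding="utf-8")

UNIT_COLUMNS = [
    "cluster_id",
    "probe_id",
    "area",
    "ap",
    "dv",
    "ml",
    "waveform_duration_ms",
    "peak_trough_ratio",
    "isi_violations",
    "amplitude_cutoff",
    "presence_ratio",
    "firing_rate",
]


def save_session(
    path: str | Path,
    recording: LfpRecording,
    spikes: SpikeClusterSet | None = None,
    speed: SpeedTrace | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        g.create_dataset("data", data=recording.samples)
        g.create_dataset("timestamps", data=recording.times())
        g.create_dataset("artifact_mask", data=recording.artifact_mask)
        g.attrs["sampling_rate"] = recording.sampling_rate
        g.attrs["start_time"] = recording.start_time

        c = f.create_group("channels")
        c.create_dataset(
            "channel_id", data=[ch.channel_id for ch in recording.channel_info], dtype=_STR
        )
        c.create_dataset(
            "probe_id", data=[ch.probe_id for ch in recording.channel_info], dtype=_STR
        )
        c.create_dataset("area", data=[ch.area for ch in recording.channel_info], dtype=_STR)
        for i, name in enumerate(("ap", "dv", "ml")):
            c.create_dataset(
                name, data=[float(ch.ccf_position[i]) for ch in recording.channel_info]
            )

        if spikes is not None:
            u = f.create_group("units")
            tab = u.create_group("table")
            for col in UNIT_COLUMNS:
                vals = spikes.units[col].to_numpy()
                if vals.dtype.kind in "OU":
                    tab.create_dataset(col, data=[str(v) for v in vals], dtype=_STR)
                else:
                    tab.create_dataset(col, data=vals.astype(float))
            ids = list(spikes.units["cluster_id"])
            concat = (
                np.concatenate([spikes.spike_times[c_] for c_ in ids])
                if ids
                else np.array([])
            )
            index = np.cumsum([0] + [spikes.spike_times[c_].size for c_ in ids])
            u.create_dataset("spike_times", data=concat)
            u.create_dataset("spike_index", data=index)

        if speed is not None:
            b = f.create_group("behavior")
            b.create_dataset("times", data=speed.times)
            b.create_dataset("speed", data=speed.speed)


def load_session(
    path: str | Path, format: str = "hdf5"
) -> tuple[LfpRecording, SpikeClusterSet | None, SpeedTrace | None]:
    """Load a session from the flat HDF5 layout.

    Channels with area annotations outside the known vocabulary come back
    flagged ``excluded``; a non-monotonic LFP time axis raises
    :class:`DataIntegrityError`; byte-identical traces on distinct probes
    trigger a duplicate-trace warning.
    """
    if format != "hdf5":
        raise ValueError(f"unsupported session format {format!r}; only 'hdf5' is available")
    path = Path(path)
    with h5py.File(path, "r") as f:
        for group in ("lfp", "channels"):
            if group not in f:
                raise ValueError(f"not a session file: missing required group /{group}")
        ts = f["lfp/timestamps"][()]
        if np.any(np.diff(ts) <= 0):
            raise DataIntegrityError("LFP time axis is not monotonically increasing")
        chans = [
            ChannelInfo(
                channel_id=_s(cid),
                probe_id=_s(pid),
                area=_s(area),
                ccf_position=(float(ap), float(dv), float(ml)),
            )
            for cid, pid, area, ap, dv, ml in zip(
                f["channels/channel_id"][()],
                f["channels/probe_id"][()],
                f["channels/area"][()],
                f["channels/ap"][()],
                f["channels/dv"][()],
                f["channels/ml"][()],
            )
        ]
        rec = LfpRecording(
            samples=f["lfp/data"][()],
            sampling_rate=float(f["lfp"].attrs["sampling_rate"]),
            start_time=float(f["lfp"].attrs.get("start_time", ts[0])),
            channel_info=chans,
            artifact_mask=f["lfp/artifact_mask"][()]
            if "artifact_mask" in f["lfp"]
            else None,
        )
        spikes = None
        if "units" in f:
            units = pd.DataFrame(
                {
                    col: [_s(v) for v in f[f"units/table/{col}"][()]]
                    if f[f"units/table/{col}"].dtype.kind in "OS"
                    else f[f"units/table/{col}"][()]
                    for col in UNIT_COLUMNS
                }
            )
            concat = f["units/spike_times"][()]
            index = f["units/spike_index"][()]
            spike_times = {
                cid: concat[index[i] : index[i + 1]]
                for i, cid in enumerate(units["cluster_id"])
            }
            spikes = SpikeClusterSet(units=units, spike_times=spike_times)
        speed = None
        if "behavior" in f:
            speed = SpeedTrace(times=f["behavior/times"][()], speed=f["behavior/speed"][()])
    rec.check_duplicate_traces()
    return rec, spikes, speed


def _s(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV (deterministic float format) or Parquet by suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
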