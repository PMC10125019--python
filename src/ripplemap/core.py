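"""Shared domain types: channels, LFP recordings, speed traces, M-L sectioning.

Coordinates follow the Allen Common Coordinate Framework convention used for
Neuropixels recordings: a 3-vector ``(ap, dv, ml)`` in micrometres.  The
medio-lateral (M-L) component orders recording locations along the
septal->intermediate hippocampal axis; "medial" always means the smallest M-L
coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Anatomical labels the pipeline understands.  Channels annotated with
#: anything else (compound or ambiguous labels such as plain "HPF") are
#: flagged excluded rather than silently analysed.
AREA_VOCABULARY = frozenset(
    {
        "CA1",
        "CA2",
        "CA3",
        "DG",
        "SUB",
        "ProS",
        "Isocortex",
        "TH",
        "MB",
    }
)

#: Areas counted as part of the hippocampal formation.
HIPPOCAMPAL_AREAS = frozenset({"CA1", "CA2", "CA3", "DG", "SUB", "ProS"})

SECTION_LABELS = ("medial", "central", "lateral")


class DataIntegrityError(ValueError):
    """Raised when an input session violates a structural invariant
    (e.g. a non-monotonic LFP time axis)."""


class InsufficientProbesError(ValueError):
    """Raised when fewer than three probes are available for sectioning."""


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one recording channel."""

    channel_id: str
    probe_id: str
    area: str
    ccf_position: tuple[float, float, float]  # (A-P, D-V, M-L) in um
    excluded: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.ccf_position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"ccf_position must be a 3-vector, got {self.ccf_position!r}")
        if not np.all(np.isfinite(pos)) or np.any(pos < 0):
            raise ValueError(
                f"channel {self.channel_id}: ccf_position components must be finite "
                f"and non-negative, got {self.ccf_position!r}"
            )
        if self.area not in AREA_VOCABULARY and not self.excluded:
            # Ambiguous/compound annotation: keep the channel but flag it.
            object.__setattr__(self, "excluded", True)

    @property
    def ap(self) -> float:
        return float(self.ccf_position[0])

    @property
    def dv(self) -> float:
        return float(self.ccf_position[1])

    @property
    def ml(self) -> float:
        return float(self.ccf_position[2])


@dataclass
class LfpRecording:
    """Multi-channel LFP on a uniform time grid.

    ``samples`` is (n_channels, n_times) in volts; ``artifact_mask`` is a
    per-sample boolean where True marks samples excluded from analysis.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float
    channel_info: Sequence[ChannelInfo]
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.shape[0] != len(self.channel_info):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_info)} ChannelInfo entries"
            )
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.samples.shape[1], dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != (self.samples.shape[1],):
                raise ValueError("artifact_mask length must equal the time axis length")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, channel_id: str) -> int:
        for i, ch in enumerate(self.channel_info):
            if ch.channel_id == channel_id:
                return i
        raise KeyError(f"unknown channel {channel_id!r}")

    def trace(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_index(channel_id)]

    def subset(self, channel_ids: Sequence[str]) -> "LfpRecording":
        idx = [self.channel_index(c) for c in channel_ids]
        return LfpRecording(
            samples=self.samples[idx],
            sampling_rate=self.sampling_rate,
            start_time=self.start_time,
            channel_info=[self.channel_info[i] for i in idx],
            artifact_mask=self.artifact_mask.copy(),
        )

    def check_duplicate_traces(self) -> list[tuple[str, str]]:
        """Warn about byte-identical traces on distinct probes.

        Returns the offending channel-id pairs (possibly empty).
        """
        dupes: list[tuple[str, str]] = []
        for i in range(self.n_channels):
            for j in range(i + 1, self.n_channels):
                ci, cj = self.channel_info[i], self.channel_info[j]
                if ci.probe_id == cj.probe_id:
                    continue
                if self.samples[i].tobytes() == self.samples[j].tobytes():
                    dupes.append((ci.channel_id, cj.channel_id))
        if dupes:
            warnings.warn(
                f"duplicated LFP traces across probes: {dupes}", UserWarning, stacklevel=2
            )
        return dupes


@dataclass
class SpeedTrace:
    """Behavioral running-speed trace with its z-scored version."""

    times: np.ndarray
    speed: np.ndarray
    standardized_speed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.times.shape != self.speed.shape:
            raise ValueError("times and speed must have the same shape")
        if self.standardized_speed is None:
            self.standardized_speed = standardize(self.speed)
        else:
            self.standardized_speed = np.asarray(self.standardized_speed, dtype=float)

    def __len__(self) -> int:
        return self.times.size

    def at(self, t: np.ndarray) -> np.ndarray:
        """Standardized speed at arbitrary times (previous-sample hold).

        Times outside the covered range map to NaN (no behavioral data).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, np.nan)
        if len(self) == 0:
            return out
        idx = np.searchsorted(self.times, t, side="right") - 1
        inside = (idx >= 0) & (t <= self.times[-1])
        out[inside] = self.standardized_speed[idx[inside]]
        return out


def standardize(x: np.ndarray) -> np.ndarray:
    """Z-score over non-missing samples."""
    x = np.asarray(x, dtype=float)
    valid = np.isfinite(x)
    mu = x[valid].mean() if valid.any() else 0.0
    sd = x[valid].std() if valid.any() else 1.0
    if sd == 0:
        sd = 1.0
    out = np.full_like(x, np.nan)
    out[valid] = (x[valid] - mu) / sd
    return out


@dataclass
class SectionAssignment:
    """Partition of probes into medial/central/lateral M-L tertiles."""

    section_of: dict[str, str]
    boundaries_um: tuple[float, float]

    def probes_in(self, section: str) -> list[str]:
        return [p for p, s in self.section_of.items() if s == section]

    def __getitem__(self, probe_id: str) -> str:
        return self.section_of[probe_id]


def probe_positions(channels: Sequence[ChannelInfo]) -> pd.DataFrame:
    """Per-probe representative CCF position.

    One row per probe with columns ``ap, dv, ml``; the representative is the
    median over that probe's non-excluded channels (for the usual single
    selected CA1 channel per probe this is just that channel's position).
    """
    rows = [
        {"probe_id": ch.probe_id, "ap": ch.ap, "dv": ch.dv, "ml": ch.ml}
        for ch in channels
        if not ch.excluded
    ]
    if not rows:
        raise ValueError("no non-excluded channels")
    df = pd.DataFrame(rows)
    return df.groupby("probe_id", sort=False)[["ap", "dv", "ml"]].median()


def assign_sections(channels: Sequence[ChannelInfo]) -> SectionAssignment:
    """Split probes into three contiguous M-L groups with near-equal counts.

    Probes are sorted by M-L coordinate (ties broken by probe_id) and divided
    medial -> central -> lateral; when the probe count is not divisible by 3
    the extra probes are allotted medial-first, so 7 probes split 3/2/2.
    """
    pos = probe_positions(channels)
    if len(pos) < 3:
        raise InsufficientProbesError(
            f"need >=3 probes with valid M-L coordinates, got {len(pos)}"
        )
    order = pos.sort_values(["ml"], kind="mergesort")
    order = order.loc[sorted(order.index, key=lambda p: (order.at[p, "ml"], str(p)))]
    n = len(order)
    base, rem = divmod(n, 3)
    counts = [base + (1 if i < rem else 0) for i in range(3)]
    section_of: dict[str, str] = {}
    i = 0
    edges: list[float] = []
    mls = order["ml"].to_numpy()
    for label, c in zip(SECTION_LABELS, counts):
        for probe in order.index[i : i + c]:
            section_of[str(probe)] = label
        i += c
        if i < n:
            edges.append(0.5 * (mls[i - 1] + mls[i]))
    return SectionAssignment(section_of=section_of, boundaries_um=(edges[0], edges[1]))


def pairwise_distances(channels: Sequence[ChannelInfo]) -> pd.DataFrame:
    """Symmetric Euclidean distance table (um) in 3D CCF space."""
    for ch in channels:
        if not np.all(np.isfinite(np.asarray(ch.ccf_position, dtype=float))):
            raise ValueError(f"channel {ch.channel_id} has missing coordinates")
    ids = [ch.channel_id for ch in channels]
    xyz = np.array([ch.ccf_position for ch in channels], dtype=float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return pd.DataFrame(dist, index=ids, columns=ids)


@dataclass
class SpikeClusterSet:
    """Sorted spike clusters (putative single units).

    ``units`` carries one row per cluster with columns:
    ``cluster_id, probe_id, area, ap, dv, ml, waveform_duration_ms,
    peak_trough_ratio, isi_violations, amplitude_cutoff, presence_ratio,
    firing_rate``.  ``spike_times`` maps cluster_id -> sorted spike times (s).
    """

    units: pd.DataFrame
    spike_times: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for cid, st in self.spike_times.items():
            st = np.asarray(st, dtype=float)
            if np.any(np.diff(st) < 0):
                raise ValueError(f"spike times of cluster {cid} are not sorted")
            self.spike_times[cid] = st

    def __len__(self) -> int:
        return len(self.units)

    def subset(self, cluster_ids: Sequence[str]) -> "SpikeClusterSet":
        ids = list(cluster_ids)
        units = self.units[self.units["cluster_id"].isin(ids)].reset_index(drop=True)
        return SpikeClusterSet(
            units=units,
            spike_times={c: self.spike_times[c] for c in units["cluster_id"]},
        )

    def hippocampal(self) -> "SpikeClusterSet":
        keep = self.units.loc[self.units["area"].isin(HIPPOCAMPAL_AREAS), "cluster_id"]
        return self.subset(list(keep))


def section_of_position(ml: float | np.ndarray, assignment: SectionAssignment):
    """Section label(s) for raw M-L coordinates, using the probe boundaries."""
    lo, hi = assignment.boundaries_um
    ml = np.asarray(ml, dtype=float)
    out = np.where(ml < lo, "medial", np.where(ml > hi, "lateral", "central"))
    return out if out.ndim else str(out)
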