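"""Ripple-associated spiking across the M-L axis.

All analyses are aligned to the ripple start *at the probe the unit sits on*
(the local member event of the propagation cluster), so travel delays do not
smear the peri-event windows.  Ripples enter these analyses only when their
propagation cluster engages more than half of the detecting probes and their
seed lies in the medial or lateral section (central-seed ripples are
discarded); sessions qualify with at least 100 ripples of each seed type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .core import SpikeClusterSet


@dataclass(frozen=True)
class EngagementWindows:
    """Peri-ripple analysis windows, in seconds relative to ripple start."""

    full: tuple[float, float] = (0.0, 0.12)
    early: tuple[float, float] = (0.0, 0.05)
    late: tuple[float, float] = (0.05, 0.12)
    pre: tuple[float, float] = (-0.02, 0.0)
    baseline: tuple[float, float] = (-0.12, 0.0)
    histogram_half_s: float = 0.25
    histogram_bin_s: float = 0.01

    def __post_init__(self) -> None:
        if not (self.early[1] == self.late[0] and (self.early[0], self.late[1]) == self.full):
            raise ValueError("early and late must partition the full window")

    def named(self) -> dict[str, tuple[float, float]]:
        return {
            "full": self.full,
            "early": self.early,
            "late": self.late,
            "pre": self.pre,
        }


def _counts_in_windows(
    spike_times: np.ndarray, starts: np.ndarray, w0: float, w1: float
) -> np.ndarray:
    """Spike count of one cluster in [start+w0, start+w1) per ripple."""
    a = np.searchsorted(spike_times, starts + w0, side="left")
    b = np.searchsorted(spike_times, starts + w1, side="left")
    return b - a


def peri_ripple_histogram(
    spikes: SpikeClusterSet,
    event_starts: pd.DataFrame,
    windows: EngagementWindows | None = None,
) -> pd.DataFrame:
    """Per-probe peri-ripple spike histogram.

    ``event_starts`` has columns ``event_id, probe_id, start_s`` (the local
    ripple start per probe).  For every probe, spikes of that probe's
    hippocampal clusters are binned around each local ripple start and
    averaged over ripples.  Returns a bins x probes table of mean spike
    counts per bin (index = bin centers in s).
    """
    windows = windows or EngagementWindows()
    if event_starts.empty:
        raise ValueError("no qualifying ripples (inclusion rules left nothing)")
    h = windows.histogram_half_s
    nbin = int(round(2 * h / windows.histogram_bin_s))
    edges = np.linspace(-h, h, nbin + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    units = spikes.hippocampal().units
    out = {}
    for pid, grp in event_starts.groupby("probe_id"):
        starts = grp["start_s"].to_numpy(dtype=float)
        cl = units.loc[units["probe_id"] == pid, "cluster_id"]
        acc = np.zeros(nbin)
        for cid in cl:
            st = spikes.spike_times[cid]
            lo = np.searchsorted(st, starts - h)
            hi = np.searchsorted(st, starts + h)
            for k, t in enumerate(starts):
                rel = st[lo[k] : hi[k]] - t
                acc += np.histogram(rel, bins=edges)[0]
        out[pid] = acc / max(starts.size, 1)
    return pd.DataFrame(out, index=pd.Index(centers, name="time_s"))


def seed_difference_map(
    hist_medial: pd.DataFrame,
    hist_lateral: pd.DataFrame,
    probe_ml: dict[str, float],
    n_grid: int = 50,
) -> xr.DataArray:
    """Interpolated (M-L x time) map of medial-minus-lateral ripple spiking.

    Both histograms must share the time grid.  Linear interpolation over
    M-L, no extrapolation beyond the probe span; a single probe yields a
    one-column map.
    """
    if not hist_medial.index.equals(hist_lateral.index):
        raise ValueError("histograms must share the time grid")
    probes = [p for p in hist_medial.columns if p in hist_lateral.columns]
    diff = hist_medial[probes] - hist_lateral[probes]
    mls = np.array([probe_ml[p] for p in probes], dtype=float)
    order = np.argsort(mls)
    da = xr.DataArray(
        diff.to_numpy()[:, order],
        dims=("time_s", "ml_um"),
        coords={"time_s": diff.index.to_numpy(), "ml_um": mls[order]},
        name="spiking_difference",
    )
    if len(probes) < 2:
        return da
    grid = np.linspace(mls.min(), mls.max(), n_grid)
    return da.interp(ml_um=grid)


def active_fraction(
    spikes: SpikeClusterSet,
    event_starts: pd.DataFrame,
    window: tuple[float, float] = (0.0, 0.12),
) -> pd.Series:
    """Fraction of hippocampal clusters with >=1 spike per ripple.

    A cluster is evaluated against the ripple start on its own probe; ripples
    not detected on a cluster's probe leave that cluster out of the ripple's
    denominator.  Returns one fraction per event_id.
    """
    hpf = spikes.hippocampal()
    if not len(hpf):
        raise ValueError("no hippocampal clusters")
    w0, w1 = window
    active: dict[int, int] = {}
    total: dict[int, int] = {}
    for pid, grp in event_starts.groupby("probe_id"):
        ev = grp["event_id"].to_numpy()
        starts = grp["start_s"].to_numpy(dtype=float)
        cl = hpf.units.loc[hpf.units["probe_id"] == pid, "cluster_id"]
        for cid in cl:
            counts = _counts_in_windows(hpf.spike_times[cid], starts, w0, w1)
            for e, c in zip(ev, counts):
                total[e] = total.get(e, 0) + 1
                if c > 0:
                    active[e] = active.get(e, 0) + 1
    frac = {e: active.get(e, 0) / total[e] for e in total}
    return pd.Series(frac, name="active_fraction").sort_index()


def ripple_spike_rate(
    spikes: SpikeClusterSet,
    event_starts: pd.DataFrame,
    window: tuple[float, float] = (0.0, 0.12),
) -> pd.Series:
    """Per-cluster ripple spiking rate (Hz).

    Spikes in the window divided by window length, averaged over ripples
    within each cluster (grand means over clusters are then up to the
    caller).
    """
    w0, w1 = window
    length = w1 - w0
    out = {}
    for pid, grp in event_starts.groupby("probe_id"):
        starts = grp["start_s"].to_numpy(dtype=float)
        cl = spikes.units.loc[spikes.units["probe_id"] == pid, "cluster_id"]
        for cid in cl:
            counts = _counts_in_windows(spikes.spike_times[cid], starts, w0, w1)
            out[cid] = counts.mean() / length if counts.size else np.nan
    return pd.Series(out, name="rate_hz").sort_index()


def split_putative_ei(
    units: pd.DataFrame, threshold_ms: float = 0.4
) -> pd.Series:
    """Putative E/I split by spike-waveform duration.

    Narrow waveforms (duration <= threshold) are putative inhibitory
    interneurons, broad ones putative excitatory cells; missing durations
    stay unlabeled (excluded from E/I-split analyses).
    """
    wf = units["waveform_duration_ms"]
    labels = np.where(wf <= threshold_ms, "putative_inhibitory", "putative_excitatory")
    out = pd.Series(labels, index=units.index, name="ei_label", dtype=object)
    out[wf.isna()] = pd.NA
    return out
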