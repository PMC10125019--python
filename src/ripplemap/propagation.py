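"""Ripple propagation across probes: clusters, seeds, maps, SCI, speed.

A *propagation cluster* groups one reference ripple with the events it
elicits on the other probes inside a +/-60 ms window (at most one member per
probe: the earliest).  The *seed* is the member with the earliest start.
The *strength conservation index* (SCI) is the fraction of hippocampal
sections in which the cluster's member stays in the top 10% of ripple
strength; *spatial engagement* is the fraction of ripple-detecting probes
participating in the cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .core import SECTION_LABELS, SectionAssignment

MEMBER_COLUMNS = ["cluster_id", "probe_id", "start_s", "lag_ms", "strength", "duration_s"]


def build_clusters(
    reference_events: pd.DataFrame,
    events_by_probe: dict[str, pd.DataFrame],
    half_window_s: float = 0.06,
) -> pd.DataFrame:
    """Long-format member table: one row per (cluster, probe) match.

    For every reference ripple, each probe contributes the *first* (earliest)
    of its events starting within ``+/-half_window_s`` of the reference
    start.  ``cluster_id`` indexes reference ripples in order.
    """
    ref_starts = reference_events["start_s"].to_numpy(dtype=float)
    rows = []
    for pid, df in events_by_probe.items():
        starts = df["start_s"].to_numpy(dtype=float)
        if not np.all(np.diff(starts) >= 0):
            raise ValueError(f"events of probe {pid} are not sorted by start")
        strengths = (
            df["strength"].to_numpy(dtype=float)
            if "strength" in df
            else np.full(starts.size, np.nan)
        )
        durations = (
            df["duration_s"].to_numpy(dtype=float)
            if "duration_s" in df
            else np.full(starts.size, np.nan)
        )
        lo = np.searchsorted(starts, ref_starts - half_window_s, side="left")
        inside = (lo < starts.size) & (starts[np.minimum(lo, starts.size - 1)] <= ref_starts + half_window_s)
        for k in np.flatnonzero(inside):
            i = lo[k]
            rows.append(
                {
                    "cluster_id": int(k),
                    "probe_id": pid,
                    "start_s": starts[i],
                    "lag_ms": (starts[i] - ref_starts[k]) * 1000.0,
                    "strength": strengths[i],
                    "duration_s": durations[i],
                }
            )
    members = pd.DataFrame(rows, columns=MEMBER_COLUMNS)
    return members.sort_values(["cluster_id", "probe_id"], kind="mergesort").reset_index(
        drop=True
    )


def identify_seed(
    cluster_members: pd.DataFrame, ml_of_probe: dict[str, float]
) -> tuple[str, float]:
    """Seed probe of one cluster: earliest member start, ties to the more
    medial probe.  Returns (probe_id, start_s)."""
    if cluster_members.empty:
        raise ValueError("cluster has no members")
    m = cluster_members.copy()
    m["_ml"] = m["probe_id"].map(ml_of_probe)
    m = m.sort_values(["start_s", "_ml", "probe_id"], kind="mergesort")
    top = m.iloc[0]
    return str(top["probe_id"]), float(top["start_s"])


def section_strength_thresholds(
    events_by_probe: dict[str, pd.DataFrame],
    sections: SectionAssignment,
    percentile: float = 90.0,
) -> dict[str, float]:
    """Per-section top-decile strength threshold.

    Computed, per section, on the strongest-ripple-activity probe (the one
    with the most detected ripples), mirroring the reference-channel
    convention.
    """
    thresholds: dict[str, float] = {}
    for section in SECTION_LABELS:
        probes = [p for p in sections.probes_in(section) if p in events_by_probe]
        probes = [p for p in probes if len(events_by_probe[p])]
        if not probes:
            continue
        best = max(probes, key=lambda p: (len(events_by_probe[p]), p))
        thresholds[section] = float(
            np.percentile(events_by_probe[best]["strength"].to_numpy(), percentile)
        )
    return thresholds


def sci_value(
    cluster_members: pd.DataFrame,
    thresholds: dict[str, float],
    sections: SectionAssignment,
) -> float:
    """Fraction of detecting sections where the member exceeds the section's
    top-decile strength threshold.  NaN when no section detects ripples."""
    if not thresholds:
        return np.nan
    hits = 0
    for section, thr in thresholds.items():
        probes = set(sections.probes_in(section))
        in_sec = cluster_members[cluster_members["probe_id"].isin(probes)]
        if len(in_sec) and (in_sec["strength"] > thr).any():
            hits += 1
    return hits / len(thresholds)


def propagation_speed(
    lags_ms: np.ndarray,
    ml_um: np.ndarray,
    sections_of_members: np.ndarray | None = None,
    min_lag_range_ms: float = 1.0,
) -> float:
    """Propagation speed (um/ms) of one cluster.

    Least-squares slope of member M-L position on member lag; regressing
    position on lag (rather than lag on position) makes near-synchronous
    clusters come out undefined (NaN) instead of explosive.
    Requires >=3 members spanning >=2 sections.
    """
    lags_ms = np.asarray(lags_ms, dtype=float)
    ml_um = np.asarray(ml_um, dtype=float)
    if lags_ms.size < 3:
        return np.nan
    if sections_of_members is not None and len(set(map(str, sections_of_members))) < 2:
        return np.nan
    if np.ptp(lags_ms) < min_lag_range_ms:
        return np.nan
    res = stats.linregress(lags_ms, ml_um)
    return float(res.slope)


def cluster_table(
    reference_events: pd.DataFrame,
    members: pd.DataFrame,
    sections: SectionAssignment,
    ml_of_probe: dict[str, float],
    thresholds: dict[str, float] | None = None,
    n_detecting_probes: int | None = None,
) -> pd.DataFrame:
    """One row per propagation cluster: seed, engagement, SCI, speed."""
    if n_detecting_probes is None:
        n_detecting_probes = members["probe_id"].nunique()
    rows = []
    ref_strong = (
        reference_events["is_strong"].to_numpy()
        if "is_strong" in reference_events
        else np.zeros(len(reference_events), dtype=bool)
    )
    ref_starts = reference_events["start_s"].to_numpy(dtype=float)
    for cid, grp in members.groupby("cluster_id", sort=True):
        seed_probe, seed_start = identify_seed(grp, ml_of_probe)
        seed_section = sections[seed_probe]
        mls = grp["probe_id"].map(ml_of_probe).to_numpy(dtype=float)
        secs = grp["probe_id"].map(sections.section_of).to_numpy()
        speed = propagation_speed(grp["lag_ms"].to_numpy(), mls, secs)
        rows.append(
            {
                "cluster_id": int(cid),
                "reference_start_s": float(ref_starts[int(cid)]),
                "is_strong": bool(ref_strong[int(cid)]),
                "seed_probe": seed_probe,
                "seed_section": seed_section,
                "seed_start_s": seed_start,
                "n_members": len(grp),
                "spatial_engagement": len(grp) / n_detecting_probes,
                "sci": sci_value(grp, thresholds, sections) if thresholds else np.nan,
                "speed_um_per_ms": speed,
            }
        )
    return pd.DataFrame(rows)


def filter_engaged(clusters: pd.DataFrame, min_engagement: float = 0.5) -> pd.DataFrame:
    """Downstream inclusion rule: keep clusters detected on more than half of
    the ripple-detecting probes."""
    return clusters[clusters["spatial_engagement"] > min_engagement].reset_index(drop=True)


def propagation_map(
    members: pd.DataFrame,
    clusters: pd.DataFrame,
    ml_of_probe: dict[str, float],
    strength_class: str | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Mean lag per probe plus a linearly interpolated M-L map.

    ``strength_class`` restricts to strong (``"strong"``) or common
    (``"common"``) clusters at the reference.  Interpolation is linear over
    M-L with no extrapolation; the returned frame is tidy long-format with
    columns ``ml_um, mean_lag_ms, kind`` (kind = "probe" or "grid").
    """
    sel = clusters
    if strength_class == "strong":
        sel = clusters[clusters["is_strong"]]
    elif strength_class == "common":
        sel = clusters[~clusters["is_strong"]]
    elif strength_class is not None:
        raise ValueError(f"unknown strength_class {strength_class!r}")
    use = members[members["cluster_id"].isin(sel["cluster_id"])]
    per_probe = (
        use.groupby("probe_id")["lag_ms"].mean().rename("mean_lag_ms").reset_index()
    )
    per_probe["ml_um"] = per_probe["probe_id"].map(ml_of_probe)
    per_probe = per_probe.sort_values("ml_um")
    rows = [
        {"ml_um": r.ml_um, "mean_lag_ms": r.mean_lag_ms, "kind": "probe"}
        for r in per_probe.itertuples()
    ]
    if len(per_probe) >= 2:
        grid = np.linspace(per_probe["ml_um"].min(), per_probe["ml_um"].max(), n_grid)
        interp = np.interp(grid, per_probe["ml_um"], per_probe["mean_lag_ms"])
        rows += [
            {"ml_um": float(g), "mean_lag_ms": float(v), "kind": "grid"}
            for g, v in zip(grid, interp)
        ]
    return pd.DataFrame(rows, columns=["ml_um", "mean_lag_ms", "kind"])


def average_maps(maps: list[pd.DataFrame], n_grid: int = 50) -> pd.DataFrame:
    """Across-session average: per-session grid maps re-interpolated onto a
    common M-L grid (intersection of ranges) and averaged."""
    grids = [m[m["kind"] == "grid"] for m in maps if (m["kind"] == "grid").any()]
    if not grids:
        return pd.DataFrame(columns=["ml_um", "mean_lag_ms", "kind"])
    lo = max(g["ml_um"].min() for g in grids)
    hi = min(g["ml_um"].max() for g in grids)
    common = np.linspace(lo, hi, n_grid)
    stack = np.vstack([np.interp(common, g["ml_um"], g["mean_lag_ms"]) for g in grids])
    return pd.DataFrame(
        {"ml_um": common, "mean_lag_ms": stack.mean(axis=0), "kind": "grid"}
    )


def axis_partial_correlation(
    lags_ms: np.ndarray, ml_um: np.ndarray, ap_um: np.ndarray
) -> dict[str, float]:
    """Squared partial correlation of lag with each anatomical axis,
    controlling for the other axis."""
    df = pd.DataFrame(
        {
            "lag": np.asarray(lags_ms, dtype=float),
            "ml": np.asarray(ml_um, dtype=float),
            "ap": np.asarray(ap_um, dtype=float),
        }
    ).dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 points")
    if df["ml"].nunique() < 2 or df["ap"].nunique() < 2:
        raise ValueError("both coordinates must vary")
    corr = np.corrcoef(df["ml"], df["ap"])[0, 1]
    if abs(corr) > 1 - 1e-12:
        return {"r2_ml": np.nan, "r2_ap": np.nan, "p_ml": np.nan, "p_ap": np.nan}
    res_ml = pg.partial_corr(data=df, x="ml", y="lag", covar="ap")
    res_ap = pg.partial_corr(data=df, x="ap", y="lag", covar="ml")
    pcol = "p-val" if "p-val" in res_ml.columns else "p_val"
    return {
        "r2_ml": float(res_ml["r"].iloc[0] ** 2),
        "r2_ap": float(res_ap["r"].iloc[0] ** 2),
        "p_ml": float(res_ml[pcol].iloc[0]),
        "p_ap": float(res_ap[pcol].iloc[0]),
    }


def duration_ml_regression(
    durations_s: np.ndarray, ml_um: np.ndarray
) -> tuple[float, float]:
    """OLS of ripple duration on M-L position -> (slope s/um, R^2)."""
    d = np.asarray(durations_s, dtype=float)
    m = np.asarray(ml_um, dtype=float)
    keep = np.isfinite(d) & np.isfinite(m)
    res = stats.linregress(m[keep], d[keep])
    return float(res.slope), float(res.rvalue**2)
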