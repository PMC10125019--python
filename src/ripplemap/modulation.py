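"""Ripple modulation of spike clusters by seed location.

The modulation index of a cluster is
``(ripple spiking rate - baseline spiking rate) / baseline spiking rate``,
with the baseline taken in the 120 ms before ripple start and ripple rates
in the full (0-120 ms), early (0-50 ms), late (50-120 ms) and pre-onset
(-20-0 ms) windows, separately for medially and laterally seeded ripples.
A cluster is *modulated* with at least a 50% rate increase for either seed
type, and *prefers* a seed type when that type's modulation is at least 50%
in absolute terms and at least twice the other type's.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import HIPPOCAMPAL_AREAS, SpikeClusterSet
from .spiking import EngagementWindows, _counts_in_windows

QC_RULES = {
    "peak_trough_ratio": ("<", 5.0),
    "isi_violations": ("<", 0.5),
    "amplitude_cutoff": ("<", 0.1),
    "presence_ratio": (">", 0.1),
    "firing_rate": (">", 0.1),
}

SEED_TYPES = ("medial", "lateral")


def qc_filter(
    spikes: SpikeClusterSet, rules: dict | None = None
) -> tuple[SpikeClusterSet, dict[str, int]]:
    """Quality-control filter on spike clusters.

    Keeps clusters with waveform peak-trough ratio < 5, ISI violations < 0.5,
    amplitude cutoff < 0.1, presence ratio > 0.1 and firing rate > 0.1 Hz.
    Returns the filtered set and the per-criterion exclusion counts.
    """
    rules = rules or QC_RULES
    units = spikes.units
    keep = np.ones(len(units), dtype=bool)
    log: dict[str, int] = {}
    for col, (op, thr) in rules.items():
        vals = units[col].to_numpy(dtype=float)
        ok = vals < thr if op == "<" else vals > thr
        ok &= np.isfinite(vals)
        log[col] = int((~ok).sum())
        keep &= ok
    log["n_input"] = len(units)
    log["n_kept"] = int(keep.sum())
    return spikes.subset(list(units.loc[keep, "cluster_id"])), log


def modulation_index(
    spikes: SpikeClusterSet,
    event_starts: pd.DataFrame,
    windows: EngagementWindows | None = None,
) -> pd.DataFrame:
    """Per-cluster modulation records for medial vs lateral seeded ripples.

    ``event_starts`` needs columns ``event_id, probe_id, start_s, seed_type``
    (seed_type in {"medial", "lateral"}); alignment is to the local start on
    the cluster's probe.  Rates are means over ripples; the baseline is the
    -120-0 ms window of the same ripples.  Clusters whose probe has no
    qualifying ripple of a seed type get NaN for that seed type; zero
    baselines yield NaN indices (flagged by ``baseline_defined``).
    """
    windows = windows or EngagementWindows()
    named = windows.named()
    b0, b1 = windows.baseline
    rows = []
    starts_by = {
        (str(p), str(s)): g["start_s"].to_numpy(dtype=float)
        for (p, s), g in event_starts.groupby(["probe_id", "seed_type"])
    }
    for u in spikes.units.itertuples(index=False):
        st = spikes.spike_times[u.cluster_id]
        rec = {
            "cluster_id": u.cluster_id,
            "area": u.area,
            "subfield": u.area if u.area in HIPPOCAMPAL_AREAS else np.nan,
            "ml": u.ml,
        }
        baselines = {}
        for seed in SEED_TYPES:
            starts = starts_by.get((u.probe_id, seed), np.array([]))
            rec[f"n_ripples_{seed}"] = starts.size
            if starts.size == 0:
                baselines[seed] = np.nan
                for w in named:
                    rec[f"rate_{seed}_{w}"] = np.nan
                    rec[f"modulation_{seed}_{w}"] = np.nan
                continue
            base = _counts_in_windows(st, starts, b0, b1).mean() / (b1 - b0)
            baselines[seed] = base
            for w, (w0, w1) in named.items():
                rate = _counts_in_windows(st, starts, w0, w1).mean() / (w1 - w0)
                rec[f"rate_{seed}_{w}"] = rate
                rec[f"modulation_{seed}_{w}"] = (
                    (rate - base) / base if base > 0 else np.nan
                )
        # Fig-style scatter baseline: mean of the two seed-type responses.
        rec["baseline_rate"] = np.nanmean([baselines[s] for s in SEED_TYPES])
        rec["baseline_defined"] = bool(
            np.all([baselines[s] > 0 for s in SEED_TYPES if np.isfinite(baselines[s])])
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def classify_modulated(
    records: pd.DataFrame, threshold: float = 0.5, window: str = "full"
) -> pd.DataFrame:
    """Flag clusters with at least ``threshold`` rate increase during either
    medial or lateral ripples (boundary inclusive)."""
    records = records.copy()
    med = records[f"modulation_medial_{window}"]
    lat = records[f"modulation_lateral_{window}"]
    records["is_modulated"] = (
        np.fmax(med.fillna(-np.inf), lat.fillna(-np.inf)) >= threshold
    )
    return records


def classify_preference(
    records: pd.DataFrame,
    threshold: float = 0.5,
    ratio: float = 2.0,
    window: str = "full",
) -> pd.DataFrame:
    """Seed-type preference labels and class fractions.

    A cluster prefers a seed type when its modulation for that type is at
    least ``threshold`` (a genuine rate increase) and at least ``ratio``
    times the other type's modulation.  When the other type's modulation is
    not positive the ratio is undefined; the rule then degrades to the guard
    "other <= preferred / ratio", which keeps the two preference classes
    mutually exclusive.
    """
    records = records.copy()
    med = records[f"modulation_medial_{window}"].to_numpy(dtype=float)
    lat = records[f"modulation_lateral_{window}"].to_numpy(dtype=float)

    def prefers(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        strong_enough = a >= threshold
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio_ok = np.where(b > 0, a / b >= ratio, b <= a / ratio)
        return strong_enough & ratio_ok & np.isfinite(a)

    pref = np.full(len(records), "none", dtype=object)
    pref[prefers(med, lat)] = "medial"
    pref[prefers(lat, med)] = "lateral"
    records["preference"] = pref
    n = max(len(records), 1)
    records.attrs["preference_fractions"] = {
        k: float((pref == k).sum()) / n for k in ("medial", "lateral", "none")
    }
    return records


def modulated_fraction_by_group(
    records: pd.DataFrame, group_of_area: dict[str, str]
) -> pd.Series:
    """Fraction of modulated clusters per region group (HPF, Isocortex, ...)."""
    if "is_modulated" not in records:
        raise ValueError("run classify_modulated first")
    grp = records["area"].map(group_of_area)
    return records.groupby(grp)["is_modulated"].mean()


def ml_variance_explained(
    records: pd.DataFrame,
    subfield: str | None = None,
    window: str = "full",
    response: str = "contrast",
) -> float:
    """R^2 of OLS of the medial-lateral modulation contrast on M-L position.

    ``response="contrast"`` (default) regresses
    ``modulation_medial - modulation_lateral``; ``response="medial"`` or
    ``"lateral"`` regress the raw modulation of one seed type (sensitivity
    variant).
    """
    df = records if subfield is None else records[records["subfield"] == subfield]
    if response == "contrast":
        y = (
            df[f"modulation_medial_{window}"] - df[f"modulation_lateral_{window}"]
        ).to_numpy(dtype=float)
    elif response in SEED_TYPES:
        y = df[f"modulation_{response}_{window}"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}")
    x = df["ml"].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 clusters")
    if np.var(x) == 0:
        return np.nan
    res = stats.linregress(x, y)
    return float(res.rvalue**2)
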