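"""Pairwise co-occurrence of ripples across CA1 recording locations.

Couples two kinds of measurements: how well per-ripple strength (∫Ripple,
integrated over a -100/+200 ms window around each reference ripple start)
correlates between channel pairs, and the per-ripple start-time lag between
a reference channel (always the more medial of the pair) and a target
channel, matched by nearest neighbor inside a +/-60 ms window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

RIVD_PRE_S = 0.1
RIVD_POST_S = 0.2


def ripple_strength_table(
    envelopes: dict[str, np.ndarray],
    fs: float,
    reference_starts: np.ndarray,
    pre_s: float = RIVD_PRE_S,
    post_s: float = RIVD_POST_S,
) -> pd.DataFrame:
    """Per-ripple ∫Ripple on every channel over the window around each
    reference ripple start.  Rows = ripples, columns = channels."""
    reference_starts = np.asarray(reference_starts, dtype=float)
    dt = 1.0 / fs
    out = {}
    for cid, env in envelopes.items():
        n = env.size
        vals = np.empty(reference_starts.size)
        for k, t in enumerate(reference_starts):
            i0 = max(int(round((t - pre_s) * fs)), 0)
            i1 = min(int(round((t + post_s) * fs)), n)
            vals[k] = np.trapezoid(env[i0:i1], dx=dt) if i1 > i0 else np.nan
        out[cid] = vals
    return pd.DataFrame(out)


def strength_correlation(
    strengths: pd.DataFrame, *, method: str = "integral"
) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of per-ripple strength.

    ``strengths`` is the ripples x channels table from
    :func:`ripple_strength_table` (``method="integral"``, the primary
    definition) or a samples x channels table of raw envelope traces
    (``method="envelope"``, the per-sample sensitivity variant).  Pairs with
    fewer than 3 paired observations come back NaN.
    """
    if method not in ("integral", "envelope"):
        raise ValueError(f"unknown method {method!r}")
    if strengths.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    corr = strengths.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def distance_regression(pairs: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of strength correlation on pair distance -> (slope, intercept, R^2)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = pairs["distance_um"].to_numpy(dtype=float)
    y = pairs["strength_correlation"].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("degenerate distance variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def classify_pair_distance(
    pairs: pd.DataFrame, quantiles: tuple[float, float] = (0.25, 0.75)
) -> pd.DataFrame:
    """Label pairs short/mid/long by distance quantiles (linear interpolation).

    short iff distance < Q_lo of all pair distances, long iff > Q_hi.
    """
    pairs = pairs.copy()
    d = pairs["distance_um"].to_numpy(dtype=float)
    lo, hi = np.quantile(d, quantiles)
    cls = np.where(d < lo, "short", np.where(d > hi, "long", "mid"))
    pairs["distance_class"] = cls
    pairs.attrs["distance_thresholds_um"] = (float(lo), float(hi))
    return pairs


def nearest_neighbor_lags(
    reference_starts: np.ndarray,
    target_starts: np.ndarray,
    half_window_s: float = 0.06,
) -> tuple[np.ndarray, float]:
    """Per-reference-ripple lag to the nearest target ripple.

    For each reference start the nearest target start within
    ``+/-half_window_s`` is matched (ties between an equidistant earlier and
    later event break toward the earlier one); the lag is
    ``t_target - t_reference`` in ms.  Returns the matched lags and the
    propagation fraction (matched / total reference ripples).
    """
    ref = np.asarray(reference_starts, dtype=float)
    tgt = np.asarray(target_starts, dtype=float)
    if ref.size == 0:
        return np.array([]), 0.0
    if tgt.size == 0:
        return np.array([]), 0.0
    idx = np.searchsorted(tgt, ref)
    right = np.clip(idx, 0, tgt.size - 1)
    left = np.clip(idx - 1, 0, tgt.size - 1)
    d_left = np.abs(tgt[left] - ref)
    d_right = np.abs(tgt[right] - ref)
    use_left = d_left <= d_right  # tie -> earlier event
    nearest = np.where(use_left, tgt[left], tgt[right])
    lag_s = nearest - ref
    matched = np.abs(lag_s) <= half_window_s
    return lag_s[matched] * 1000.0, float(matched.mean())


def pair_records(
    events_by_channel: dict[str, pd.DataFrame],
    channel_ml: dict[str, float],
    distances: pd.DataFrame,
    strength_corr: pd.DataFrame,
    half_window_s: float = 0.06,
) -> pd.DataFrame:
    """One row per channel pair: reference (more medial), distance,
    strength correlation, matched lags and propagation fraction."""
    ids = sorted(events_by_channel, key=lambda c: (channel_ml[c], c))
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ref, tgt = ids[i], ids[j]  # ref is the more medial
            lags, frac = nearest_neighbor_lags(
                events_by_channel[ref]["start_s"].to_numpy(),
                events_by_channel[tgt]["start_s"].to_numpy(),
                half_window_s,
            )
            rows.append(
                {
                    "reference_channel": ref,
                    "target_channel": tgt,
                    "distance_um": float(distances.loc[ref, tgt]),
                    "strength_correlation": float(strength_corr.loc[ref, tgt]),
                    "n_matched": lags.size,
                    "propagation_fraction": frac,
                    "mean_lag_ms": float(lags.mean()) if lags.size else np.nan,
                    "median_lag_ms": float(np.median(lags)) if lags.size else np.nan,
                }
            )
    return pd.DataFrame(rows)
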