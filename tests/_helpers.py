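"""Shared test utilities: event matching against ground truth."""

import numpy as np
import pandas as pd


def match_starts(
    truth_starts: np.ndarray, detected_starts: np.ndarray, tol_s: float = 0.03
) -> pd.DataFrame:
    """Match each true event to the nearest detected start within ``tol_s``.

    Returns a frame with one row per true event: ``truth_s, detected_s,
    error_ms`` (NaN when unmatched).
    """
    truth_starts = np.asarray(truth_starts, dtype=float)
    detected_starts = np.sort(np.asarray(detected_starts, dtype=float))
    rows = []
    for t in truth_starts:
        if detected_starts.size:
            i = np.argmin(np.abs(detected_starts - t))
            d = detected_starts[i]
            ok = abs(d - t) <= tol_s
        else:
            d, ok = np.nan, False
        rows.append(
            {
                "truth_s": t,
                "detected_s": d if ok else np.nan,
                "error_ms": (d - t) * 1000.0 if ok else np.nan,
            }
        )
    return pd.DataFrame(rows)


def recall_precision(
    truth_starts: np.ndarray, detected_starts: np.ndarray, tol_s: float = 0.03
) -> tuple[float, float, pd.DataFrame]:
    m = match_starts(truth_starts, detected_starts, tol_s)
    n_matched = int(m["detected_s"].notna().sum())
    recall = n_matched / max(len(m), 1)
    precision = n_matched / max(len(np.atleast_1d(detected_starts)), 1)
    return recall, precision, m


def seed_type_starts(truth) -> pd.DataFrame:
    """Ground-truth per-probe starts labeled with the seed section
    (medial/lateral only), shaped for the spiking/modulation stages."""
    starts = truth.probe_events.merge(
        truth.events[["event_id", "seed_section"]], on="event_id"
    )
    starts = starts[starts["seed_section"].isin(["medial", "lateral"])]
    return starts.rename(columns={"seed_section": "seed_type"})[
        ["event_id", "probe_id", "start_s", "seed_type"]
    ].reset_index(drop=True)
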