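"""End-to-end orchestration: detection -> metrics -> pairwise -> propagation
-> spiking -> modulation, with the session-inclusion rules applied between
stages and a row-count ledger in the summary.

Inclusion rules (each a config value):

* reference channel must carry at least ``min_ripples_reference`` ripples
  (default 1000), otherwise propagation and everything downstream is skipped;
* spiking/modulation need at least ``min_ripples_per_seed`` engaged ripples
  (default 100) seeded medially AND laterally;
* only propagation clusters engaging more than ``min_engagement`` of the
  detecting probes feed the spiking/modulation stages;
* channels with band-envelope variance below the detection config floor are
  discarded before anything else.

A stage stopped by a rule is recorded in ``summary["skipped"]`` with the
rule's name, never raised.
"""

from __future__ import annotations

import hashlib
import warnings

import yaml
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling, modulation, propagation, spiking
from .config import save_yaml, to_dict
from .core import SpikeClusterSet, assign_sections, pairwise_distances
from .detection import (
    DetectionParams,
    bandpass,
    channel_passes_activity_filter,
    detect_ripples,
    classify_strength,
    envelope,
    select_best_channel,
)
from .io import load_session, write_json, write_table
from .synthetic import REGION_GROUP, GeneratorConfig, generate_session


@dataclass
class PipelineConfig:
    simulate: GeneratorConfig | None = None
    input_path: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    min_ripples_reference: int = 1000
    min_ripples_per_seed: int = 100
    min_engagement: float = 0.5
    half_window_s: float = 0.06
    output_dir: str = "ripplemap_output"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_path is None):
            raise ValueError("exactly one of simulate/input_path must be set")
        if min(self.min_ripples_reference, self.min_ripples_per_seed) <= 0:
            raise ValueError("inclusion thresholds must be positive")


def event_starts_table(
    members: pd.DataFrame, clusters: pd.DataFrame, min_engagement: float = 0.5
) -> pd.DataFrame:
    """Per-probe local ripple starts for spiking/modulation stages.

    Keeps clusters engaging more than ``min_engagement`` of detecting probes
    and seeded medially or laterally (central-seed ripples are discarded);
    one row per (event, probe) with the seed type attached.
    """
    keep = clusters[
        (clusters["spatial_engagement"] > min_engagement)
        & clusters["seed_section"].isin(["medial", "lateral"])
    ][["cluster_id", "seed_section"]].rename(columns={"seed_section": "seed_type"})
    out = members.merge(keep, on="cluster_id", how="inner")
    return out.rename(columns={"cluster_id": "event_id"})[
        ["event_id", "probe_id", "start_s", "seed_type"]
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_yaml(config, outdir / "config.yaml")
    # hash the analysis-relevant config only: where outputs land must not
    # change what (or whether) results reproduce
    hashed = {k: v for k, v in to_dict(config).items() if k != "output_dir"}
    cfg_hash = hashlib.md5(yaml.safe_dump(hashed, sort_keys=True).encode()).hexdigest()

    summary: dict = {"config_hash": cfg_hash, "skipped": {}, "ledger": {}}
    ledger = summary["ledger"]

    if config.simulate is not None:
        from .config import generator_config_from_dict

        gen = generator_config_from_dict(
            {**to_dict(config.simulate), "rng_seed": config.rng_seed}
        )
        recording, spikes, speed, truth = generate_session(gen)
        summary["session"] = {"source": "simulated", "rng_seed": config.rng_seed}
    else:
        recording, spikes, speed = load_session(config.input_path)
        truth = None
        summary["session"] = {"source": str(config.input_path)}
    if recording is None:
        raise ValueError("pipeline requires LFP (simulate config had include_lfp=False)")

    params = config.detection

    # --- channel selection: best CA1 channel per probe, activity-filtered ---
    ca1 = [ch for ch in recording.channel_info if ch.area == "CA1" and not ch.excluded]
    selected: list[str] = []
    dropped_channels = 0
    for pid in dict.fromkeys(ch.probe_id for ch in ca1):
        probe_rec = recording.subset(
            [ch.channel_id for ch in ca1 if ch.probe_id == pid]
        )
        cid = select_best_channel(probe_rec, "CA1", params)
        if channel_passes_activity_filter(
            recording.trace(cid), recording.sampling_rate, params
        ):
            selected.append(cid)
        else:
            dropped_channels += 1
    ledger["channels"] = {
        "n_input": len(ca1),
        "n_selected": len(selected),
        "n_dropped_activity": dropped_channels,
    }
    if not selected:
        summary["skipped"]["detection"] = "no_ca1_channels"
        write_json(summary, outdir / "summary.json")
        return summary

    # --- detection ---
    events = detect_ripples(
        recording, params, speed=speed, channel_ids=selected, keep_rejected=True
    )
    accepted = events[events["accepted"]].reset_index(drop=True)
    ledger["events"] = {
        "n_candidates": int(len(events)),
        "n_accepted": int(len(accepted)),
        "n_rejected_spectrum": int((~events["accepted"]).sum()),
    }
    write_table(events, outdir / "events_all.csv")
    write_table(accepted, outdir / "events.csv")

    counts = accepted.groupby("channel_id").size()
    reference_channel = str(counts.sort_values(kind="mergesort").index[-1]) if len(counts) else None
    summary["reference_channel"] = reference_channel
    ref_events = (
        accepted[accepted["channel_id"] == reference_channel].reset_index(drop=True)
        if reference_channel
        else pd.DataFrame()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ref_events = classify_strength(ref_events, params) if len(ref_events) else ref_events
    write_table(ref_events, outdir / "reference_events.csv")
    summary["n_reference_ripples"] = int(len(ref_events))

    # --- pairwise coupling ---
    sel_chans = [recording.channel_info[recording.channel_index(c)] for c in selected]
    if len(selected) >= 2 and len(ref_events) >= 3:
        envelopes = {
            c: envelope(bandpass(recording.trace(c), recording.sampling_rate, params))
            for c in selected
        }
        strengths = coupling.ripple_strength_table(
            envelopes, recording.sampling_rate, ref_events["start_s"].to_numpy()
        )
        corr = coupling.strength_correlation(strengths)
        dist = pairwise_distances(sel_chans)
        events_by_channel = {
            c: accepted[accepted["channel_id"] == c].sort_values("start_s")
            for c in selected
        }
        ml_of_channel = {ch.channel_id: ch.ml for ch in sel_chans}
        pairs = coupling.pair_records(
            events_by_channel, ml_of_channel, dist, corr, config.half_window_s
        )
        if len(pairs) >= 4:
            pairs = coupling.classify_pair_distance(pairs)
        write_table(pairs, outdir / "pairs.csv")
        try:
            slope, intercept, r2 = coupling.distance_regression(pairs.dropna(subset=["strength_correlation"]))
            summary["distance_regression"] = {"slope": slope, "intercept": intercept, "r2": r2}
        except ValueError as e:
            summary["skipped"]["distance_regression"] = str(e)
    else:
        summary["skipped"]["pairwise"] = "min_channels_or_ripples"

    # --- propagation ---
    if len(ref_events) < config.min_ripples_reference:
        summary["skipped"]["propagation"] = "min_ripples"
        summary["skipped"]["spiking"] = "min_ripples"
        summary["skipped"]["modulation"] = "min_ripples"
        write_json(summary, outdir / "summary.json")
        return summary

    sections = assign_sections(sel_chans)
    ml_of_probe = {ch.probe_id: ch.ml for ch in sel_chans}
    ap_of_probe = {ch.probe_id: ch.ap for ch in sel_chans}
    events_by_probe = {
        ch.probe_id: accepted[accepted["probe_id"] == ch.probe_id]
        .sort_values("start_s")
        .reset_index(drop=True)
        for ch in sel_chans
    }
    members = propagation.build_clusters(ref_events, events_by_probe, config.half_window_s)
    thresholds = propagation.section_strength_thresholds(events_by_probe, sections)
    n_detecting = sum(1 for df in events_by_probe.values() if len(df))
    clusters = propagation.cluster_table(
        ref_events, members, sections, ml_of_probe, thresholds, n_detecting
    )
    engaged = propagation.filter_engaged(clusters, config.min_engagement)
    ledger["clusters"] = {
        "n_input": int(len(clusters)),
        "n_engaged": int(len(engaged)),
        "n_dropped_engagement": int(len(clusters) - len(engaged)),
    }
    write_table(members, outdir / "cluster_members.csv")
    write_table(clusters, outdir / "clusters.csv")
    maps = []
    for klass in ("strong", "common"):
        m = propagation.propagation_map(members, clusters, ml_of_probe, klass)
        m["class"] = klass
        maps.append(m)
    write_table(pd.concat(maps, ignore_index=True), outdir / "propagation_map.csv")
    mem_ml = members["probe_id"].map(ml_of_probe).to_numpy(dtype=float)
    mem_ap = members["probe_id"].map(ap_of_probe).to_numpy(dtype=float)
    try:
        summary["axis_partial_correlation"] = propagation.axis_partial_correlation(
            members["lag_ms"].to_numpy(), mem_ml, mem_ap
        )
    except ValueError as e:
        summary["skipped"]["axis_partial_correlation"] = str(e)
    seed_counts = clusters["seed_section"].value_counts().to_dict()
    summary["seed_section_counts"] = {k: int(v) for k, v in seed_counts.items()}

    # --- spiking engagement ---
    starts = event_starts_table(members, engaged, config.min_engagement)
    n_medial = int(starts.loc[starts["seed_type"] == "medial", "event_id"].nunique())
    n_lateral = int(starts.loc[starts["seed_type"] == "lateral", "event_id"].nunique())
    ledger["ripples_by_seed"] = {"medial": n_medial, "lateral": n_lateral}
    if spikes is None or min(n_medial, n_lateral) < config.min_ripples_per_seed:
        summary["skipped"]["spiking"] = (
            "no_spike_data" if spikes is None else "min_ripples_per_seed"
        )
        summary["skipped"]["modulation"] = summary["skipped"]["spiking"]
        write_json(summary, outdir / "summary.json")
        return summary

    windows = spiking.EngagementWindows()
    hists = {}
    for seed in ("medial", "lateral"):
        sel = starts[starts["seed_type"] == seed]
        hists[seed] = spiking.peri_ripple_histogram(spikes, sel, windows)
    diff = spiking.seed_difference_map(hists["medial"], hists["lateral"], ml_of_probe)
    diff.to_dataframe().reset_index().pipe(write_table, outdir / "seed_difference_map.csv")
    frac_rows = []
    for seed in ("medial", "lateral"):
        sel = starts[starts["seed_type"] == seed]
        for wname, w in windows.named().items():
            af = spiking.active_fraction(spikes, sel, w)
            rate = spiking.ripple_spike_rate(spikes.hippocampal(), sel, w)
            frac_rows.append(
                {
                    "seed_type": seed,
                    "window": wname,
                    "active_fraction_mean": float(af.mean()),
                    "active_fraction_sem": float(af.sem()),
                    "rate_hz_mean": float(rate.mean()),
                }
            )
    write_table(pd.DataFrame(frac_rows), outdir / "spiking_engagement.csv")

    # --- modulation ---
    qc_spikes, qc_log = qc_stage(spikes)
    ledger["qc"] = qc_log
    records = modulation.modulation_index(qc_spikes, starts, windows)
    records = modulation.classify_modulated(records)
    records = modulation.classify_preference(records)
    write_table(records, outdir / "modulation.csv")
    summary["preference_fractions"] = records.attrs["preference_fractions"]
    summary["modulated_fraction_by_group"] = (
        modulation.modulated_fraction_by_group(records, REGION_GROUP).round(6).to_dict()
    )
    r2 = {}
    for subfield in sorted(records["subfield"].dropna().unique()):
        for wname in ("early", "late", "pre"):
            try:
                r2[f"{subfield}_{wname}"] = modulation.ml_variance_explained(
                    records, subfield, wname
                )
            except ValueError:
                pass
    summary["ml_variance_explained"] = r2

    write_json(summary, outdir / "summary.json")
    return summary


def qc_stage(spikes: SpikeClusterSet):
    return modulation.qc_filter(spikes)
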