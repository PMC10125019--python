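# ripplemap

Detection of hippocampal **sharp-wave ripples** (SWRs) in multi-probe LFP
recordings and analysis of how they **propagate along the medio-lateral
(M-L) hippocampal axis**: who generates a ripple (its *seed*), how fast and
how reliably it travels, how well it conserves its strength, and how it
modulates spiking across brain regions.

It is aimed at electrophysiologists working with multi-probe extracellular
recordings (e.g. Neuropixels sessions spanning several CA1 locations) who
want a tested, scriptable implementation of the full analysis chain, plus a
synthetic-session generator with exact ground truth for validating every
stage.

## What it computes

**Detection.** LFP is band-passed 120–250 Hz (6th-order zero-phase
Butterworth); the ripple envelope is |Hilbert analytic signal|. An event
must reach `mean + 5·SD` of the envelope; its boundaries are the nearest
crossings of `mean + 2·SD` on a 5-sample smoothed envelope. Candidates with
start times closer than 50 ms merge, durations are gated to
(15 ms, 250 ms), a constant-detrended periodogram of the raw segment must
peak above 100 Hz, and events during running
(z-speed > P10 + 0.06) are discarded. Per event the package records

- **∫Ripple** (strength) = ∫ band-passed envelope over the event (V·s),
- **RIVD** = ∫ raw-LFP envelope over −100…+200 ms around start,
- amplitude (90th envelope percentile) and spectral peak frequency.

**Propagation.** Ripples on the reference channel (strongest ripple
activity) are tracked across probes within ±60 ms (*propagation clusters*).
Per cluster: the **seed** (earliest start; ties go medial), **spatial
engagement** (fraction of detecting probes participating), propagation
speed (µm/ms), and the **strength conservation index** —
SCI = fraction of hippocampal sections (medial/central/lateral M-L
tertiles) where the event stays in the top 10 % of ∫Ripple. Pairwise
analyses give strength-correlation matrices, distance regressions and
nearest-neighbor lags (positive lag = medial→lateral travel).

**Spiking.** Peri-ripple histograms per probe, medial-vs-lateral seed
difference maps interpolated over M-L × time, active-neuron fractions and
rates in the early (0–50 ms), late (50–120 ms) and pre-onset (−20–0 ms)
windows, putative E/I split by waveform duration, and per-cluster
**modulation indices** `(ripple rate − baseline rate) / baseline rate`
(baseline −120–0 ms) with modulated/preference classification.

**Synthetic sessions.** `generate_session(GeneratorConfig(...))` builds
multi-probe sessions with 1/f noise, calibrated ripple waveforms
(section-dependent seed probabilities, distance-dependent lags and
direction-dependent attenuation), ripple-locked Poisson spiking with
region/seed/window-specific gains, QC metadata and a running-speed trace —
all with exact ground truth (`GroundTruth`).

## Worked example

```python
import numpy as np
from ripplemap import (DetectionParams, GeneratorConfig, assign_sections,
                       classify_strength, detect_ripples, generate_session)
from ripplemap.coupling import nearest_neighbor_lags
from ripplemap.propagation import (build_clusters, cluster_table,
                                   section_strength_thresholds)

cfg = GeneratorConfig(session_length_s=600.0, rng_seed=42)
recording, spikes, speed, truth = generate_session(cfg)
events = detect_ripples(recording, DetectionParams(), speed=speed)
print(f"detected {len(events)} ripples on {events['channel_id'].nunique()} CA1 channels "
      f"({len(truth.events)} planted)")

ref_channel = events.groupby("channel_id").size().idxmax()
reference = classify_strength(events[events["channel_id"] == ref_channel].reset_index(drop=True))
print(f"reference channel {ref_channel}: {len(reference)} ripples, "
      f"{int(reference['is_strong'].sum())} strong (top decile of ∫Ripple)")

e_med = events.loc[events["probe_id"] == "probe0", "start_s"].to_numpy()
e_lat = events.loc[events["probe_id"] == "probe5", "start_s"].to_numpy()
lags, frac = nearest_neighbor_lags(e_med, e_lat)
print(f"medial→lateral pair: {100*frac:.1f}% of ripples propagate, "
      f"median lag {np.median(lags):+.1f} ms")

sections = assign_sections(recording.channel_info)
ml = {c.probe_id: c.ml for c in recording.channel_info}
by_probe = {c.probe_id: events[events["probe_id"] == c.probe_id].reset_index(drop=True)
            for c in recording.channel_info}
members = build_clusters(reference, by_probe)
clusters = cluster_table(reference, members, sections, ml,
                         section_strength_thresholds(by_probe, sections))
print("seed sections:", clusters["seed_section"].value_counts().to_dict())
print(f"mean spatial engagement {clusters['spatial_engagement'].mean():.2f}, "
      f"mean SCI {clusters['sci'].mean():.2f}")
```

prints

```
detected 926 ripples on 6 CA1 channels (154 planted)
reference channel ch0: 155 ripples, 16 strong (top decile of ∫Ripple)
medial→lateral pair: 99.4% of ripples propagate, median lag -2.8 ms
seed sections: {'lateral': 55, 'central': 50, 'medial': 50}
mean spatial engagement 0.99, mean SCI 0.14
```

154 planted events appear as ~926 channel-events because each ripple is
detected independently on each of the 6 probes. The detector recovers
essentially all of them (155 on the reference channel; 16 land in the top
decile and are classed *strong*). The median pair lag is near zero because
with the default seed probabilities ripples travel in both directions;
seeds lean lateral for common ripples, and the mean SCI of 0.14 reflects
that only top-decile events can conserve "top 10 %" status across sections.

A thin CLI mirrors the library: `ripplemap simulate`, `ripplemap detect`,
`ripplemap analyze`, `ripplemap report` (see `--help`). `analyze` runs the
full pipeline (detection → pairwise → propagation → spiking → modulation)
with the session-inclusion rules (≥1000 reference ripples, ≥100 engaged
ripples per seed type, engagement > 0.5) and writes CSV tables plus a
`summary.json` carrying a row-count ledger for every filtering stage.

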