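# Methods

This note documents the models and procedures implemented in `ripplemap`,
the parameters that matter, the design choices made where several
reasonable options existed, and what the synthetic-data tests do and do not
establish about real recordings.

## Ripple detection

The detector is a Hilbert-envelope dual-threshold scheme on a per-channel
basis:

1. band-pass 120–250 Hz, 6th-order Butterworth applied forward–backward
   (`sosfiltfilt`). Zero-phase filtering is essential: start/stop times feed
   the lag and seed analyses and must not be phase-shifted. The stated
   order is the designed order per pass, so the effective attenuation is
   doubled;
2. envelope = magnitude of the analytic signal (FFT padded to a fast
   length);
3. events must reach `mean + 5·SD` of the envelope; boundaries are the
   nearest crossings of `mean + 2·SD` on a 5-sample trailing-mean smoothed
   envelope. A trailing mean of `w` samples lags the underlying signal by
   `(w−1)/2` samples (1.6 ms at 1250 Hz); the boundary indices are shifted
   back by that group delay, otherwise every start/stop is systematically
   late;
4. candidates whose starts differ by less than 50 ms merge transitively;
   durations outside the open interval (15 ms, 250 ms) are discarded;
5. each surviving candidate's raw LFP segment gets a constant-detrended
   periodogram; the event is kept only if the spectral peak above a 50 Hz
   floor lies above 100 Hz. This is the false-positive control: line-noise
   bursts and broadband transients leak into the ripple band but keep their
   raw-signal power at low frequencies;
6. events starting while the animal runs (standardized speed above its 10th
   percentile + 0.06), in stretches without behavioral data, or overlapping
   artifact-masked samples are discarded.

**Envelope statistics.** Thresholds need the noise envelope's mean and SD,
but the plain moments of the full envelope include the ripples themselves,
so the threshold creeps up with event density and amplitude — in synthetic
sessions this inflated the effective 5-SD threshold by up to ~35 % and
biased starts and durations in a duration-dependent way. The envelope of
band-limited Gaussian noise is Rayleigh distributed, and its scale is
`median / sqrt(2 ln 2)`; the median is nearly untouched by sparse events.
The default estimator (`stats_estimator="rayleigh"`) therefore derives mean
and SD from the envelope median over artifact-free, non-running samples.
Plain moments remain available (`"moments"`), and both `mean + k·SD` and
`k·SD` threshold conventions are supported (`threshold_mode`). When the
envelope median is vanishingly small relative to its maximum (no noise
floor, e.g. noiseless traces), the estimator falls back to moments.

**Best channel.** Within an area the channel with the largest envelope SD
wins; when the SD depth profile has several local maxima (sharp waves in
stratum radiatum vs ripples in stratum pyramidale), the local maximum with
the highest envelope skewness is used.

**Per-event metrics.** Strength ∫Ripple is the trapezoidal integral of the
band-passed envelope over the event; RIVD integrates the raw-LFP envelope
over −100…+200 ms around start; amplitude is the 90th envelope percentile.
Strong ripples are the strict top decile of ∫Ripple on the session's
reference channel (ties fall to common; fewer than 10 events ⇒ all common).

## Pairwise coupling and propagation

Per-ripple strength is recomputed on every channel over the −100/+200 ms
window around each reference ripple start; the strength-correlation matrix
is the Pearson correlation of those per-ripple values across channels (a
per-sample envelope-trace correlation is available as a sensitivity
variant). Pair distances are 3-D Euclidean in CCF coordinates (µm); pairs
are classed short/long at the 25 %/75 % linear-interpolation quantiles of
all pair distances. Lags use nearest-neighbor matching of start times
within ±60 ms, reference always the more medial channel, ties toward the
earlier event.

Propagation clusters keep, per probe, the earliest event within ±60 ms of
the reference start. The seed is the earliest member; simultaneous starts
resolve to the more medial probe (deterministic and consistent with the
medial→lateral sign convention). Spatial engagement divides by the number
of probes that detect ripples at all in the session. SCI counts the
sections whose member exceeds that section's top-decile strength threshold
(computed on the section's busiest channel, mirroring the reference-channel
convention) divided by the number of sections with any detecting channel.
Propagation speed regresses member M-L position on lag — not lag on
position — so near-synchronous clusters (lag range < 1 ms) come out
undefined instead of explosive. Axis contributions use squared partial
correlations (pingouin), each axis controlling for the other.

Sectioning sorts probes by M-L coordinate (ties by probe id) and splits
them into three contiguous groups as equal as possible, remainders medial
first: 7 probes → 3/2/2. This is deterministic and order-independent.

## Spiking engagement and modulation

All peri-ripple windows are aligned to the ripple start *on the unit's own
probe* (the local member of the propagation cluster), so travel delays do
not smear the 0–50 ms / 50–120 ms windows. Only clusters engaging more than
half of the detecting probes and seeded medially or laterally enter
(central-seed ripples are discarded); sessions qualify with ≥100 ripples of
each seed type. Histograms use 10 ms bins over ±250 ms (bin width
configurable; the choice only trades resolution against per-bin counts).
Active fraction = share of hippocampal clusters with ≥1 spike in the
window, per ripple; rates aggregate as mean over ripples within cluster,
then over clusters. The putative E/I split thresholds waveform duration at
0.4 ms (configurable, recorded in output metadata).

Modulation index = `(ripple rate − baseline rate) / baseline rate`, with
the baseline in the −120–0 ms window of the same ripples and rates as means
over ripples, per seed type and window (full/early/late/pre). The pre-onset
(−20–0 ms) variant shares the −120–0 ms baseline; note those windows
overlap by construction, which slightly dilutes pre-onset contrasts — a
sensitivity caveat, not a bug. A cluster is *modulated* at a ≥50 % increase
for either seed type (boundary inclusive). A cluster *prefers* a seed type
when that type's modulation is ≥ +0.5 and at least twice the other type's;
when the other type's modulation is non-positive the ratio degrades to
`other ≤ preferred/2`. Requiring the preferred modulation to be a positive
increase keeps the two preference classes mutually exclusive (an
absolute-value rule would let two strongly suppressed responses "prefer"
both types at once). M-L variance explained is the OLS R² of the
medial-minus-lateral modulation contrast on M-L position (raw per-seed
modulation available behind a flag).

QC filtering keeps clusters with peak-trough ratio < 5, ISI violations
< 0.5, amplitude cutoff < 0.1, presence ratio > 0.1 and firing rate
> 0.1 Hz; exclusion counts per criterion are logged.

## Pipeline and inclusion rules

`run_pipeline` runs detection → metrics → pairwise → propagation → spiking
→ modulation. Sessions whose reference channel carries fewer than 1000
ripples skip propagation and everything downstream; spiking/modulation
additionally require ≥100 engaged ripples per seed type. A skipped stage is
recorded in the summary with the violated rule's name. Every filtering
stage writes input/kept/dropped counts into a row-count ledger; the summary
also carries an MD5 hash of the analysis-relevant config (the output
directory is excluded from the hash so identical analyses reproduce
byte-identically anywhere). CSVs are written with a fixed float format, so
the same config and seed give byte-identical tables.

## Synthetic sessions

The generator is a forward model of exactly the structure the analysis
assumes.

- **Geometry:** `n_probes` (default 6) evenly spaced over a 2400 µm M-L
  span starting at 6500 µm, one CA1 channel each; small A-P spread.
- **Events:** Poisson with rate 0.25/s (matching awake ripple incidence of
  ~2.5 per 10 s) with a 0.4 s dead time, placed outside running bouts.
  ~10 % of events are "strong-class" (amplitude ×1.5). Each event draws a
  seed section (separate probabilities for strong- and common-class events;
  defaults lean lateral for common and medial for strong events, following
  the seed gradients the analysis is designed to resolve), then a seed
  probe within the section. Onset at other probes = seed onset +
  distance/speed (default 110 µm/ms, i.e. ~18 ms over ~2 mm) + Gaussian
  jitter (2 ms SD, truncated at ±30 ms). Amplitude attenuates as
  `exp(−attenuation × distance)` with separate medial→lateral and
  lateral→medial coefficients.
- **Waveform:** amplitudes are parameterised in envelope z-units — an event
  of amplitude `z` peaks at `mean + z·SD` of that channel's noise-envelope
  distribution (calibrated per channel after the noise is synthesised), so
  detectability against the 5-SD rule is controlled directly. The envelope
  is attack–plateau–decay: Gaussian flanks (SD 8 ms) around a sustained
  plateau, sized so the clean envelope crosses the 2-SD boundary threshold
  exactly at the planted start and stop. This matches how ripples behave
  (fast emergence, sustained oscillation, quick decay) and keeps the
  planted boundaries well defined; a pure Gaussian envelope has such
  shallow flanks that boundary crossings become noise-dominated (several ms
  of spread with heavy early tails from zero-phase filter precursors). A
  slower sharp-wave deflection is added on a random subset of channels.
  Planted durations are `duration_mean + slope·(ML_max − ML) + noise`,
  drawn independently per probe-event so the duration-gradient R² has the
  closed form `a²·Var(ML) / (a²·Var(ML) + σ²)`.
- **Noise:** Gaussian with a 1/f^1.5 spectrum (flat below 1 Hz), 150 µV
  total SD.
- **Spiking:** per cluster, homogeneous Poisson baseline (log-normal rates
  around 4 Hz) plus window-specific surplus spikes during ripples:
  effective gain `1 + (g−1)·exp(−distance_from_seed / L)` per
  (region-group, seed-section, window) with configurable decay length `L`.
  Defaults emulate the regional picture of awake ripple modulation
  (hippocampal formation ~90 % modulated clusters, isocortex ~5 %, midbrain
  ~1 %, thalamus none) and late-phase persistence of medially seeded
  ripples (`L → ∞` for the medial-seed late window). Waveform durations are
  bimodal (putative inhibitory 0.25 ± 0.04 ms, excitatory 0.75 ± 0.12 ms);
  a configurable ~5 % of clusters fail one QC criterion.
- **Behavior:** 50 Hz speed trace, near-zero baseline jitter plus gamma-
  distributed running bouts (~1 per 100 s, ~8 s long, ~25 cm/s). Ripples
  are only placed outside bouts. Note the P10 + 0.06 running rule assumes
  genuine running epochs exist; in bout-free synthetic sessions the rule
  degenerates (the percentile lands inside the baseline noise), so
  detection-only tests run without behavior gating.

**What the synthetic tests show — and don't.** Passing recovery tests shows
the implementation chain is correct and unbiased under the generative
assumptions: stationary 1/f noise, Rayleigh envelope statistics, rigid
distance/speed lags, Poisson spiking with piecewise-constant gains. Real
recordings add non-stationary noise, movement and reference artifacts,
theta contamination, bursty non-Poisson spiking, and anatomic irregularity;
none of these is emulated, so performance numbers (recall, start error,
seed accuracy) are upper bounds on real-data performance, not predictions.

## Numerical choices and degenerate inputs

- Internal units: volts and seconds; event intervals half-open
  `[start, stop)`. The weak-channel filter (envelope variance) is applied
  on a configurable scale (µV² by default, threshold 5).
- Detected boundary indices are group-delay-compensated (see above);
  detected durations still carry ~4 ms of edge noise from envelope
  fluctuations around the 2-SD crossing, which slightly depresses recovered
  duration-gradient R² relative to the planted analytic value (by ~0.02–
  0.04 at the default settings).
- Ties: seed ties go to the more medial probe; nearest-neighbor ties to the
  earlier event; strong-classification ties to common; section-count
  remainders to the medial group first.
- Degenerate inputs: constant envelopes detect nothing (with a warning);
  empty speed traces discard all events (the running rule cannot be
  evaluated); propagation speed is NaN for <3 members, <2 sections or
  <1 ms lag range; partial correlations require both axes to vary; SCI is
  NaN when no section detects ripples.
- The modulated/unmodulated decision at exactly a 50 % planted increase is
  boundary-sensitive: the true index sits on the threshold, so any unbiased
  per-cluster estimate exceeds it with probability ~1/2 regardless of the
  number of ripples averaged. Population means recover the planted index to
  high precision; per-cluster labels near the boundary are intrinsically
  coin-flips. Interpret modulated fractions accordingly when true effects
  hover near the threshold.

## Known limitations

- NWB reading is not included; sessions use the documented flat HDF5
  layout (`/lfp`, `/channels`, `/units`, `/behavior`).
- The generator does not model biophysics (no conductance-based dynamics,
  no realistic probe geometries, no spike waveforms beyond a duration
  scalar).
- Sleep/wake staging, sharp-wave (stratum radiatum) component detection and
  within-ripple phase analyses are out of scope.
- The pre-onset window overlaps the baseline window (above); a disjoint
  baseline is a one-line config change (`EngagementWindows`) for
  sensitivity analyses.
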