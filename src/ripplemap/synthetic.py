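"""Synthetic multi-probe sessions with known ground truth.

The generator is a forward model of the statistical structure the analysis
assumes: several probes span the medio-lateral (M-L) hippocampal axis; ripple
events originate in a seed section drawn with class-dependent probabilities,
reach other probes with a distance-dependent lag (plus Gaussian jitter) and a
direction-dependent exponential strength attenuation; the LFP is 1/f noise
plus ~150 Hz oscillations under an attack-plateau-decay envelope (with a
slower sharp-wave deflection on a subset of channels); spiking is
inhomogeneous Poisson, with
window-, region- and seed-dependent gain during ripples; a running-speed
trace contains bouts during which no ripples are placed.

Ripple amplitudes are parameterised in envelope z-units: an event of
amplitude ``z`` peaks at ``mean + z*SD`` of that channel's noise-envelope
distribution, so detectability against the 5-SD threshold is controlled
directly.  The planted event duration is the width of the clean envelope
above the 2-SD boundary threshold, matching what the detector measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core import (
    ChannelInfo,
    LfpRecording,
    SECTION_LABELS,
    SpeedTrace,
    SpikeClusterSet,
    assign_sections,
)
from .detection import DetectionParams, bandpass, envelope

WINDOWS = {"pre": (-0.02, 0.0), "early": (0.0, 0.05), "late": (0.05, 0.12)}

REGION_GROUP = {
    "CA1": "HPF",
    "CA2": "HPF",
    "CA3": "HPF",
    "DG": "HPF",
    "SUB": "HPF",
    "ProS": "HPF",
    "Isocortex": "Isocortex",
    "TH": "TH",
    "MB": "MB",
}


@dataclass
class RegionModulation:
    """Ripple-locked gain structure of one region group.

    ``gains[seed_section][window]`` multiplies the baseline rate inside the
    window (windows are relative to the local ripple start); the effective
    gain decays with the cluster's distance from the ripple seed with length
    ``attenuation_len_mm[seed_section][window]`` (use a huge length for no
    spatial decay, e.g. late-phase persistence of medially seeded ripples).
    """

    fraction_modulated: float = 0.0
    gains: dict[str, dict[str, float]] = field(default_factory=dict)
    attenuation_len_mm: dict[str, dict[str, float]] = field(default_factory=dict)

    def gain(self, seed_section: str, window: str) -> float:
        return self.gains.get(seed_section, {}).get(window, 1.0)

    def attenuation(self, seed_section: str, window: str) -> float:
        return self.attenuation_len_mm.get(seed_section, {}).get(window, 1e9)


def _default_region_modulation() -> dict[str, RegionModulation]:
    hpf_gains = {
        "medial": {"pre": 1.2, "early": 3.0, "late": 2.6},
        "central": {"pre": 1.15, "early": 3.0, "late": 2.0},
        "lateral": {"pre": 1.1, "early": 3.0, "late": 1.5},
    }
    hpf_atten = {
        "medial": {"pre": 0.9, "early": 0.9, "late": 1e9},
        "central": {"pre": 0.9, "early": 0.9, "late": 0.9},
        "lateral": {"pre": 0.9, "early": 0.9, "late": 0.9},
    }
    flat = {s: {"pre": 1.0, "early": 2.0, "late": 2.0} for s in SECTION_LABELS}
    return {
        "HPF": RegionModulation(0.9, hpf_gains, hpf_atten),
        "Isocortex": RegionModulation(0.05, flat),
        "TH": RegionModulation(0.0, flat),
        "MB": RegionModulation(0.01, flat),
    }


def _default_region_probs() -> dict[str, float]:
    return {
        "CA1": 0.22,
        "CA3": 0.08,
        "DG": 0.12,
        "SUB": 0.08,
        "ProS": 0.05,
        "Isocortex": 0.25,
        "TH": 0.12,
        "MB": 0.08,
    }


@dataclass
class GeneratorConfig:
    # geometry
    n_probes: int = 6
    ml_start_um: float = 6500.0
    ml_span_um: float = 2400.0
    ap_start_um: float = 7600.0
    ap_step_um: float = 60.0
    ap_jitter_um: float = 40.0
    dv_um: float = 2200.0
    # signal
    sampling_rate: float = 1250.0
    session_length_s: float = 600.0
    noise_sd_v: float = 150e-6
    noise_exponent: float = 1.5
    # ripple events
    ripple_rate_per_s: float = 0.25  # ~2.5 events per 10 s
    n_events: int | None = None  # override the Poisson count
    min_event_separation_s: float = 0.4
    strong_fraction: float = 0.1
    seed_probs_common: tuple[float, float, float] = (0.25, 0.33, 0.42)
    seed_probs_strong: tuple[float, float, float] = (0.45, 0.30, 0.25)
    propagation_speed_um_per_ms: float = 110.0
    lag_jitter_sd_ms: float = 2.0
    attenuation_per_mm_ml: float = 0.05  # medial -> lateral travel
    attenuation_per_mm_lm: float = 0.12  # lateral -> medial travel
    amplitude_z_mean: float = 9.0
    amplitude_z_sd: float = 1.2
    amplitude_z_min: float = 6.5
    amplitude_z_max: float = 14.0
    strong_amplitude_mult: float = 1.5
    strong_duration_mult: float = 1.3
    ripple_center_freq_hz: float = 150.0
    ripple_freq_sd_hz: float = 7.0
    duration_mean_s: float = 0.055
    duration_sd_s: float = 0.012
    duration_min_s: float = 0.025
    duration_max_s: float = 0.22
    duration_ml_slope_s_per_um: float = 1.2e-5  # longer events toward the medial pole
    ripple_attack_sd_s: float = 0.008  # width of the envelope's rise/fall flanks
    sharp_wave_prob: float = 0.7
    sharp_wave_amplitude_factor: float = 1.5
    # spiking
    n_clusters_per_probe: int = 40
    region_probs: dict[str, float] = field(default_factory=_default_region_probs)
    region_modulation: dict[str, RegionModulation] = field(
        default_factory=_default_region_modulation
    )
    baseline_rate_log_mean: float = np.log(4.0)
    baseline_rate_log_sd: float = 0.5
    baseline_rate_min_hz: float = 0.3
    baseline_rate_max_hz: float = 30.0
    inhibitory_fraction: float = 0.2
    qc_fail_fraction: float = 0.05
    # behavior
    speed_sampling_rate: float = 50.0
    running_bout_rate_per_s: float = 0.01
    running_bout_duration_s: float = 8.0
    running_speed_cm_s: float = 25.0
    baseline_speed_sd_cm_s: float = 0.05
    # misc
    include_lfp: bool = True
    detectability_threshold_z: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        for name in ("seed_probs_common", "seed_probs_strong"):
            p = getattr(self, name)
            if len(p) != 3 or abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                problems.append(name)
        for name in (
            "sampling_rate",
            "session_length_s",
            "ripple_rate_per_s",
            "propagation_speed_um_per_ms",
            "duration_sd_s",
        ):
            if getattr(self, name) <= 0:
                problems.append(name)
        if self.lag_jitter_sd_ms < 0 or self.noise_sd_v < 0:
            problems.append("lag_jitter_sd_ms/noise_sd_v")
        if problems:
            raise ValueError(f"invalid GeneratorConfig fields: {sorted(set(problems))}")

    def probe_ids(self) -> list[str]:
        return [f"probe{i}" for i in range(self.n_probes)]

    def probe_ml(self) -> np.ndarray:
        if self.n_probes == 1:
            return np.array([self.ml_start_um])
        return self.ml_start_um + np.linspace(0.0, self.ml_span_um, self.n_probes)


@dataclass
class GroundTruth:
    """Truth tables for one synthetic session."""

    events: pd.DataFrame  # event_id, klass, seed_probe, seed_section, seed_time_s
    probe_events: pd.DataFrame  # event_id, probe_id, ml, start_s, duration_s, peak_z, detectable
    clusters: pd.DataFrame  # cluster_id, region, group, modulated, gains..., ei_class
    planted: dict


def one_over_f_noise(
    n: int, fs: float, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum (flat below 1 Hz)."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f >= 1.0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    return x * (sd / x.std())


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _make_speed(config: GeneratorConfig, rng: np.random.Generator):
    fs = config.speed_sampling_rate
    n = int(round(config.session_length_s * fs))
    t = np.arange(n) / fs
    speed = np.abs(rng.normal(0.0, config.baseline_speed_sd_cm_s, n))
    n_bouts = rng.poisson(config.running_bout_rate_per_s * config.session_length_s)
    bouts = []
    for _ in range(n_bouts):
        dur = rng.gamma(4.0, config.running_bout_duration_s / 4.0)
        start = rng.uniform(0.0, max(config.session_length_s - dur, 1.0))
        bouts.append((start, start + dur))
    bouts.sort()
    merged: list[list[float]] = []
    for a, b in bouts:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    for a, b in merged:
        sl = slice(int(a * fs), int(b * fs))
        speed[sl] += rng.normal(config.running_speed_cm_s, 2.0, speed[sl].size).clip(min=5.0)
    return SpeedTrace(times=t, speed=speed), [(a, b) for a, b in merged]


def _draw_event_times(
    config: GeneratorConfig, rng: np.random.Generator, bouts, n_events: int
) -> np.ndarray:
    """Seed times outside running bouts, separated by the configured minimum."""
    margin = 0.5
    lo, hi = 1.0, config.session_length_s - 1.0
    if hi <= lo:
        raise ValueError("session too short to place events")
    for factor in (6, 30, 150):
        pool = np.sort(rng.uniform(lo, hi, factor * n_events + 100))
        ok = np.ones(pool.size, dtype=bool)
        for a, b in bouts:
            ok &= ~((pool > a - margin) & (pool < b + margin))
        pool = pool[ok]
        accepted = []
        last = -np.inf
        for t in pool:
            if t - last >= config.min_event_separation_s:
                accepted.append(t)
                last = t
        if len(accepted) >= n_events:
            pick = rng.choice(len(accepted), size=n_events, replace=False)
            return np.sort(np.asarray(accepted)[np.sort(pick)])
    raise ValueError("could not place the requested number of events; session too short")


def _plan_events(
    config: GeneratorConfig, rng: np.random.Generator, bouts
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw event classes, seeds, per-probe onsets/amplitudes/durations."""
    if config.n_events is not None:
        n_events = config.n_events
    else:
        n_events = rng.poisson(config.ripple_rate_per_s * config.session_length_s)
    seed_times = _draw_event_times(config, rng, bouts, n_events)

    probe_ids = config.probe_ids()
    ml = config.probe_ml()
    if config.n_probes >= 3:
        sections = assign_sections(
            [
                ChannelInfo(f"ch{i}", probe_ids[i], "CA1", (0.0, 0.0, float(ml[i])))
                for i in range(config.n_probes)
            ]
        )
        probes_by_section = {s: sections.probes_in(s) for s in SECTION_LABELS}
    else:
        # too few probes for a tertile split: any section may seed any probe
        probes_by_section = {s: list(probe_ids) for s in SECTION_LABELS}

    is_strong = rng.random(n_events) < config.strong_fraction
    ev_rows = []
    pe_rows = []
    speed = config.propagation_speed_um_per_ms
    ml_max = ml.max()
    for k in range(n_events):
        klass = "strong" if is_strong[k] else "common"
        probs = config.seed_probs_strong if is_strong[k] else config.seed_probs_common
        section = rng.choice(SECTION_LABELS, p=np.asarray(probs, dtype=float))
        seed_probe = str(rng.choice(probes_by_section[section]))
        seed_ml = ml[probe_ids.index(seed_probe)]
        amp = _truncated_normal(
            rng,
            config.amplitude_z_mean,
            config.amplitude_z_sd,
            config.amplitude_z_min,
            config.amplitude_z_max,
            1,
        )[0]
        dur_mult = 1.0
        if is_strong[k]:
            amp *= config.strong_amplitude_mult
            dur_mult = config.strong_duration_mult
        freq = float(
            np.clip(
                rng.normal(config.ripple_center_freq_hz, config.ripple_freq_sd_hz),
                125.0,
                245.0,
            )
        )
        ev_rows.append(
            {
                "event_id": k,
                "klass": klass,
                "seed_probe": seed_probe,
                "seed_section": section,
                "seed_time_s": seed_times[k],
                "seed_amplitude_z": amp,
                "freq_hz": freq,
            }
        )
        for i, pid in enumerate(probe_ids):
            dist = abs(ml[i] - seed_ml)
            att = (
                config.attenuation_per_mm_ml
                if ml[i] >= seed_ml
                else config.attenuation_per_mm_lm
            )
            peak_z = amp * np.exp(-att * dist / 1000.0)
            if pid == seed_probe:
                lag_ms = 0.0
            else:
                jit = rng.normal(0.0, config.lag_jitter_sd_ms)
                jit = float(np.clip(jit, -30.0, 30.0))
                lag_ms = dist / speed + jit
            duration = (
                config.duration_mean_s
                + config.duration_ml_slope_s_per_um * (ml_max - ml[i])
                + rng.normal(0.0, config.duration_sd_s)
            ) * dur_mult
            duration = float(
                np.clip(duration, config.duration_min_s, config.duration_max_s)
            )
            pe_rows.append(
                {
                    "event_id": k,
                    "probe_id": pid,
                    "ml": float(ml[i]),
                    "start_s": seed_times[k] + lag_ms / 1000.0,
                    "lag_ms": lag_ms,
                    "duration_s": duration,
                    "peak_z": float(peak_z),
                    "detectable": bool(peak_z >= config.detectability_threshold_z),
                }
            )
    events = pd.DataFrame(
        ev_rows,
        columns=[
            "event_id",
            "klass",
            "seed_probe",
            "seed_section",
            "seed_time_s",
            "seed_amplitude_z",
            "freq_hz",
        ],
    )
    probe_events = pd.DataFrame(
        pe_rows,
        columns=[
            "event_id",
            "probe_id",
            "ml",
            "start_s",
            "lag_ms",
            "duration_s",
            "peak_z",
            "detectable",
        ],
    )
    return events, probe_events


def _render_lfp(
    config: GeneratorConfig,
    rng: np.random.Generator,
    events: pd.DataFrame,
    probe_events: pd.DataFrame,
    params: DetectionParams,
) -> tuple[np.ndarray, pd.DataFrame]:
    """1/f noise plus calibrated ripple waveforms; returns samples and the
    probe_events table augmented with the rendered amplitude in volts."""
    fs = config.sampling_rate
    n = int(round(config.session_length_s * fs))
    samples = np.empty((config.n_probes, n))
    amp_v = np.zeros(len(probe_events))
    freq_of = events.set_index("event_id")["freq_hz"]
    t_axis = np.arange(n) / fs
    for i, pid in enumerate(config.probe_ids()):
        noise = one_over_f_noise(n, fs, config.noise_exponent, config.noise_sd_v, rng)
        if config.noise_sd_v > 0:
            env = envelope(bandpass(noise, fs, params))
            m0, sd0 = float(env.mean()), float(env.std())
        else:
            m0, sd0 = 0.0, 10e-6  # 10 uV per z-unit on a noiseless trace
        thr_edge = m0 + params.boundary_threshold_sd * sd0
        rows = probe_events.index[probe_events["probe_id"] == pid]
        sig_a = config.ripple_attack_sd_s
        for ridx in rows:
            r = probe_events.loc[ridx]
            amp = m0 + r["peak_z"] * sd0
            amp_v[probe_events.index.get_loc(ridx)] = amp
            dur = r["duration_s"]
            # attack-plateau-decay envelope: Gaussian flanks of width sig_a
            # around a sustained plateau, sized so the clean envelope crosses
            # the 2-SD boundary threshold at `start_s` and `start_s + dur`
            # (ripples hold their amplitude and fall quickly, and sharp edges
            # keep the planted boundaries well defined against noise)
            if amp > 1.05 * thr_edge:
                k = np.sqrt(2.0 * np.log(amp / thr_edge))
            else:
                k = 1.0
            t_pk1 = r["start_s"] + sig_a * k
            t_pk2 = r["start_s"] + dur - sig_a * k
            if t_pk2 < t_pk1:  # too short for a plateau: symmetric Gaussian
                t_pk1 = t_pk2 = r["start_s"] + dur / 2.0
                sig = (dur / 2.0) / k
            else:
                sig = sig_a
            f = freq_of[r["event_id"]]
            a = max(int((t_pk1 - 5 * sig) * fs), 0)
            b = min(int((t_pk2 + 5 * sig) * fs) + 1, n)
            if b <= a:
                continue
            tt = t_axis[a:b]
            gate = np.where(
                tt < t_pk1,
                np.exp(-((tt - t_pk1) ** 2) / (2 * sig**2)),
                np.where(
                    tt > t_pk2, np.exp(-((tt - t_pk2) ** 2) / (2 * sig**2)), 1.0
                ),
            )
            phase = rng.uniform(0, 2 * np.pi)
            c_mid = 0.5 * (t_pk1 + t_pk2)
            ripple = amp * gate * np.sin(2 * np.pi * f * (tt - c_mid) + phase)
            noise[a:b] += ripple
            if rng.random() < config.sharp_wave_prob:
                sw_sig = max(dur / 2.5, 2 * sig)
                sw = (
                    -config.sharp_wave_amplitude_factor
                    * amp
                    * np.exp(-((tt - c_mid) ** 2) / (2 * sw_sig**2))
                )
                noise[a:b] += sw
        samples[i] = noise
    pe = probe_events.copy()
    pe["amplitude_v"] = amp_v
    return samples, pe


def _make_clusters(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    regions = list(config.region_probs)
    probs = np.array([config.region_probs[r] for r in regions], dtype=float)
    probs = probs / probs.sum()
    ml = config.probe_ml()
    rows = []
    cid = 0
    for i, pid in enumerate(config.probe_ids()):
        for _ in range(config.n_clusters_per_probe):
            region = str(rng.choice(regions, p=probs))
            group = REGION_GROUP[region]
            mod = config.region_modulation.get(group, RegionModulation())
            modulated = bool(rng.random() < mod.fraction_modulated)
            is_inh = rng.random() < config.inhibitory_fraction
            wf = (
                rng.normal(0.25, 0.04) if is_inh else rng.normal(0.75, 0.12)
            )
            rate = float(
                np.clip(
                    rng.lognormal(config.baseline_rate_log_mean, config.baseline_rate_log_sd),
                    config.baseline_rate_min_hz,
                    config.baseline_rate_max_hz,
                )
            )
            qc = {
                "peak_trough_ratio": rng.uniform(0.5, 4.5),
                "isi_violations": rng.uniform(0.0, 0.4),
                "amplitude_cutoff": rng.uniform(0.0, 0.08),
                "presence_ratio": rng.uniform(0.5, 1.0),
            }
            if rng.random() < config.qc_fail_fraction:
                which = rng.choice(list(qc))
                qc[which] = {
                    "peak_trough_ratio": 6.0,
                    "isi_violations": 0.8,
                    "amplitude_cutoff": 0.2,
                    "presence_ratio": 0.05,
                }[which]
            rows.append(
                {
                    "cluster_id": f"unit{cid:04d}",
                    "probe_id": pid,
                    "area": region,
                    "group": group,
                    "ap": config.ap_start_um + config.ap_step_um * i + rng.normal(0, 30),
                    "dv": config.dv_um + rng.normal(0, 100),
                    "ml": float(ml[i] + rng.normal(0, 50)),
                    "waveform_duration_ms": float(max(wf, 0.08)),
                    "ei_class": "inhibitory" if is_inh else "excitatory",
                    "baseline_rate": rate,
                    "modulated": modulated,
                    **qc,
                }
            )
            cid += 1
    return pd.DataFrame(rows)


def _make_spikes(
    config: GeneratorConfig,
    rng: np.random.Generator,
    clusters: pd.DataFrame,
    events: pd.DataFrame,
    probe_events: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Baseline Poisson spiking plus window-specific ripple-locked surplus."""
    T = config.session_length_s
    seed_section_of = events.set_index("event_id")["seed_section"]
    seed_probe_of = events.set_index("event_id")["seed_probe"]
    ml = dict(zip(config.probe_ids(), config.probe_ml()))
    pe_by_probe: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for pid, g in probe_events.groupby("probe_id"):
        ev_ids = g["event_id"].to_numpy(dtype=int)
        starts = g["start_s"].to_numpy(dtype=float)
        seed_secs = seed_section_of.loc[ev_ids].to_numpy()
        seed_ml = np.array([ml[p] for p in seed_probe_of.loc[ev_ids]])
        pe_by_probe[str(pid)] = (starts, seed_secs, np.abs(seed_ml - ml[str(pid)]) / 1000.0)
    out: dict[str, np.ndarray] = {}
    for row in clusters.itertuples(index=False):
        r = row.baseline_rate
        n_base = rng.poisson(r * T)
        spikes = [rng.uniform(0.0, T, n_base)]
        mod = config.region_modulation.get(row.group, RegionModulation())
        local = pe_by_probe.get(row.probe_id)
        if row.modulated and local is not None and len(local[0]):
            starts, seed_secs, dist_mm = local
            for wname, (w0, w1) in WINDOWS.items():
                g = np.array([mod.gain(s, wname) for s in seed_secs])
                L = np.array([mod.attenuation(s, wname) for s in seed_secs])
                g_eff = 1.0 + (g - 1.0) * np.exp(-dist_mm / L)
                lam = np.clip(g_eff - 1.0, 0.0, None) * r * (w1 - w0)
                counts = rng.poisson(lam)
                total = int(counts.sum())
                if total:
                    base = np.repeat(starts + w0, counts)
                    spikes.append(base + rng.uniform(0.0, w1 - w0, total))
        st = np.sort(np.concatenate(spikes))
        out[row.cluster_id] = st[(st >= 0) & (st <= T)]
    return out


def generate_session(
    config: GeneratorConfig,
) -> tuple[LfpRecording | None, SpikeClusterSet, SpeedTrace, GroundTruth]:
    """Generate one synthetic session; fully reproducible given rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    params = DetectionParams()
    speed, bouts = _make_speed(config, rng)
    events, probe_events = _plan_events(config, rng, bouts)

    recording = None
    if config.include_lfp:
        samples, probe_events = _render_lfp(config, rng, events, probe_events, params)
        ml = config.probe_ml()
        chans = [
            ChannelInfo(
                channel_id=f"ch{i}",
                probe_id=pid,
                area="CA1",
                ccf_position=(
                    config.ap_start_um + config.ap_step_um * i,
                    config.dv_um,
                    float(ml[i]),
                ),
            )
            for i, pid in enumerate(config.probe_ids())
        ]
        recording = LfpRecording(
            samples=samples,
            sampling_rate=config.sampling_rate,
            start_time=0.0,
            channel_info=chans,
        )

    clusters = _make_clusters(config, rng)
    spike_times = _make_spikes(config, rng, clusters, events, probe_events)
    units = clusters.copy()
    units["firing_rate"] = [
        len(spike_times[c]) / config.session_length_s for c in units["cluster_id"]
    ]
    unit_cols = [
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
    spike_set = SpikeClusterSet(units=units[unit_cols].copy(), spike_times=spike_times)

    ml_grid = config.probe_ml()
    planted = {
        "duration_ml_slope_s_per_um": config.duration_ml_slope_s_per_um,
        "duration_noise_sd_s": config.duration_sd_s,
        "ml_variance_um2": float(np.var(ml_grid)),
        "propagation_speed_um_per_ms": config.propagation_speed_um_per_ms,
        "seed_probs_common": tuple(config.seed_probs_common),
        "seed_probs_strong": tuple(config.seed_probs_strong),
        "running_bouts": bouts,
    }
    truth = GroundTruth(
        events=events, probe_events=probe_events, clusters=clusters, planted=planted
    )
    return recording, spike_set, speed, truth


def analytic_duration_r2(config: GeneratorConfig) -> float:
    """Planted R**2 of the duration-vs-M-L regression:
    a^2 Var(ML) / (a^2 Var(ML) + sigma^2)."""
    a = config.duration_ml_slope_s_per_um
    var_ml = float(np.var(config.probe_ml()))
    s2 = config.duration_sd_s**2
    return a * a * var_ml / (a * a * var_ml + s2)


def inject_artifacts(
    recording: LfpRecording,
    kind: Literal["line_noise", "flat_segments"],
    *,
    n: int = 0,
    times_s: np.ndarray | None = None,
    duration_s: float = 0.08,
    target_z: float = 8.0,
    line_freq_hz: float = 60.0,
    rng: np.random.Generator | None = None,
    params: DetectionParams | None = None,
) -> tuple[LfpRecording, pd.DataFrame]:
    """Add artifacts to a copy of the recording.

    ``line_noise`` injects square-wave line-frequency bursts calibrated so
    their in-band envelope reaches ``target_z`` SDs (they must trip the
    detector and then be rejected by spectral validation); the mask is left
    untouched.  ``flat_segments`` zeroes segments and flags them in the
    artifact mask.  ``n = 0`` with no ``times_s`` is a no-op.
    """
    params = params or DetectionParams()
    rng = rng or np.random.default_rng(0)
    fs = recording.sampling_rate
    out = LfpRecording(
        samples=recording.samples.copy(),
        sampling_rate=fs,
        start_time=recording.start_time,
        channel_info=list(recording.channel_info),
        artifact_mask=recording.artifact_mask.copy(),
    )
    if times_s is None:
        if n == 0:
            return out, pd.DataFrame(columns=["start_s", "stop_s", "kind"])
        lo = recording.start_time + 1.0
        hi = recording.start_time + recording.duration - 1.0 - duration_s
        times_s = np.sort(rng.uniform(lo, hi, n))
    times_s = np.asarray(times_s, dtype=float)
    rows = []
    n_seg = int(round(duration_s * fs))
    tt = np.arange(n_seg) / fs
    scales: np.ndarray | None = None
    template = np.sign(np.sin(2 * np.pi * line_freq_hz * tt))
    if kind == "line_noise":
        ftmp = envelope(bandpass(np.pad(template, int(0.2 * fs)), fs, params))
        peak = float(ftmp.max())
        scales = np.zeros(out.n_channels)
        for c in range(out.n_channels):
            env = envelope(bandpass(out.samples[c], fs, params))
            if peak > 0:
                scales[c] = (env.mean() + target_z * env.std()) / peak
    elif kind != "flat_segments":
        raise ValueError(f"unknown artifact kind {kind!r}")
    for t in times_s:
        i0 = int(round((t - recording.start_time) * fs))
        i1 = min(i0 + n_seg, recording.n_samples)
        if kind == "flat_segments":
            out.samples[:, i0:i1] = 0.0
            out.artifact_mask[i0:i1] = True
        else:
            seg = template[: i1 - i0]
            out.samples[:, i0:i1] += scales[:, None] * seg[None, :]
        rows.append({"start_s": t, "stop_s": t + duration_s, "kind": kind})
    return out, pd.DataFrame(rows, columns=["start_s", "stop_s", "kind"])
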