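"""Ripple detector: filtering, envelope, thresholds, merging, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from ripplemap.core import ChannelInfo, LfpRecording, SpeedTrace
from ripplemap.detection import (
    DetectionParams,
    bandpass,
    classify_strength,
    compute_metrics,
    detect_candidates,
    detect_on_channel,
    envelope,
    envelope_thresholds,
    exclude_running,
    gate_duration,
    merge_candidates,
    select_best_channel,
    validate_spectrum,
)
from ripplemap.synthetic import one_over_f_noise

FS = 1250.0
PARAMS = DetectionParams()


def tone(freq, dur=2.0, fs=FS, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t), t


class TestBandpass:
    def test_passband_identity_150hz(self):
        x, _ = tone(150.0)
        y = bandpass(x, FS, PARAMS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.std(y[mid]) == pytest.approx(np.std(x[mid]), rel=0.01)

    def test_stopband_10hz_attenuated_40db(self):
        # oracle: designed double-pass response at 10 Hz
        sos = signal.butter(6, [120.0, 250.0], btype="bandpass", fs=FS, output="sos")
        w, h = signal.sosfreqz(sos, worN=[10.0], fs=FS)
        assert 40 <= -20 * np.log10(np.abs(h[0]) ** 2)  # |H|^2: forward-backward
        x, _ = tone(10.0)
        y = bandpass(x, FS, PARAMS)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        atten_db = 20 * np.log10(np.std(x[mid]) / np.std(y[mid]))
        assert atten_db >= 40

    def test_impulse_response_time_symmetric(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        y = bandpass(x, FS, PARAMS)
        assert np.allclose(y, y[::-1], atol=1e-9)

    def test_sampling_rate_too_low(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass(np.zeros(100), 400.0, PARAMS)


class TestEnvelope:
    def test_constant_for_pure_tone(self):
        x, _ = tone(150.0, amp=2.5)
        env = envelope(x)
        mid = slice(len(x) // 4, 3 * len(x) // 4)
        assert np.allclose(env[mid], 2.5, rtol=0.01)

    def test_zero_trace(self):
        assert np.allclose(envelope(np.zeros(1000)), 0.0)

    def test_recovers_gaussian_modulator(self):
        t = np.arange(int(2 * FS)) / FS
        mod = np.exp(-((t - 1.0) ** 2) / (2 * 0.1**2))
        x = mod * np.sin(2 * np.pi * 150.0 * t)
        env = envelope(x)
        core = (t > 0.5) & (t < 1.5)
        assert np.abs(env[core] - mod[core]).max() < 0.02


class TestBestChannel:
    def _recording(self, mods):
        t = np.arange(int(4 * FS)) / FS
        carrier = np.sin(2 * np.pi * 150.0 * t)
        chans, rows = [], []
        for i, m in enumerate(mods):
            rows.append(m(t) * carrier)
            chans.append(ChannelInfo(f"c{i}", "p0", "CA1", (0.0, 40.0 * i, 100.0)))
        return LfpRecording(np.vstack(rows), FS, 0.0, chans)

    def test_single_sd_peak_wins(self):
        # envelope SDs proportional to 1, 5, 2 -> middle channel
        rng = np.random.default_rng(0)
        base = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * np.arange(int(4 * FS)) / FS)
        rec = self._recording(
            [lambda t: 1 + 0.1 * base, lambda t: 1 + 0.5 * base, lambda t: 1 + 0.2 * base]
        )
        assert select_best_channel(rec, "CA1") == "c1"

    def test_skewness_breaks_multi_peak_tie(self):
        t_len = int(4 * FS)
        smooth = 1.0 + 0.8 * np.sin(2 * np.pi * 1.0 * np.arange(t_len) / FS)

        def bursty(t):
            m = np.full(t.size, 0.8)
            for c in np.arange(0.3, 4.0, 0.5):
                m += 3.0 * np.exp(-((t - c) ** 2) / (2 * 0.01**2))
            return m

        rec = self._recording(
            [
                lambda t: np.full(t.size, 0.2),
                lambda t: smooth,  # smooth high-SD channel, low skewness
                lambda t: np.full(t.size, 0.2),
                bursty,  # second SD peak, strongly skewed
                lambda t: np.full(t.size, 0.2),
            ]
        )
        assert select_best_channel(rec, "CA1") == "c3"

    def test_single_channel(self):
        rec = self._recording([lambda t: np.ones(t.size)])
        assert select_best_channel(rec, "CA1") == "c0"

    def test_no_channels(self):
        rec = self._recording([lambda t: np.ones(t.size)])
        with pytest.raises(ValueError):
            select_best_channel(rec, "CA3")


def noise_envelope(n=int(120 * FS), seed=0):
    rng = np.random.default_rng(seed)
    return envelope(bandpass(one_over_f_noise(n, FS, 1.5, 1e-4, rng), FS, PARAMS))


def add_bump(env, t_center, z, width_s=0.03):
    """Raise the envelope to mean + z*SD along a Gaussian bump (peak exact)."""
    mu, sd, _, _ = envelope_thresholds(env, PARAMS)
    t = np.arange(env.size) / FS
    bump = (mu + z * sd) * np.exp(-((t - t_center) ** 2) / (2 * (width_s / 4) ** 2))
    return np.maximum(env, bump)


class TestDetectCandidates:
    def test_single_8sd_bump_yields_one_interval(self):
        env = add_bump(noise_envelope(), 60.0, 8.0)
        ivs = detect_candidates(env, FS, PARAMS)
        containing = [iv for iv in ivs if iv[0] <= 60.0 <= iv[1]]
        assert len(containing) == 1

    def test_subthreshold_bump_rejected(self):
        env = noise_envelope(seed=1)
        ivs = detect_candidates(add_bump(env, 60.0, 4.5), FS, PARAMS)
        assert not any(a <= 60.0 <= b for a, b in ivs)

    def test_matches_bruteforce_scan(self):
        env = noise_envelope(seed=2)
        for c, z in [(30.0, 8.0), (30.05, 9.0), (80.0, 7.0)]:
            env = add_bump(env, c, z)
        got = detect_candidates(env, FS, PARAMS)
        # independent sample-by-sample oracle
        _, _, thr_peak, thr_edge = envelope_thresholds(env, PARAMS)
        sm = pd.Series(env).rolling(5, min_periods=1).mean().to_numpy()
        above = sm >= thr_edge
        expected = []
        i = 0
        delay = 2  # trailing-window group delay compensation
        while i < env.size:
            if above[i]:
                j = i
                while j < env.size and above[j]:
                    j += 1
                if env[i:j].max() >= thr_peak:
                    expected.append((max(i - delay, 0) / FS, max(j - delay, 1) / FS))
                i = j
            else:
                i += 1
        assert got == expected

    def test_constant_envelope_warns_no_events(self):
        with pytest.warns(UserWarning, match="constant envelope"):
            assert detect_candidates(np.ones(5000), FS, PARAMS) == []


class TestMergeAndGate:
    def test_merge_rules(self):
        p = PARAMS
        assert merge_candidates([(1.0, 1.02), (1.03, 1.08)], p) == [(1.0, 1.08)]
        assert merge_candidates([(1.0, 1.02), (1.06, 1.09)], p) == [(1.0, 1.02), (1.06, 1.09)]
        # chained merge: each start within 50 ms of the previous start
        assert merge_candidates([(1.0, 1.02), (1.04, 1.06), (1.08, 1.1)], p) == [(1.0, 1.1)]

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 10.0, allow_nan=False),
                st.floats(0.001, 0.2, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_merge_is_fixpoint_of_pairwise_merging(self, raw):
        ivs = sorted((round(a, 4), round(a + d, 4)) for a, d in raw)
        got = merge_candidates(ivs, PARAMS)
        # oracle: repeat single pairwise merges until nothing changes
        cur = list(ivs)
        changed = True
        while changed:
            changed = False
            for i in range(len(cur) - 1):
                if cur[i + 1][0] - cur[i][0] < PARAMS.merge_gap_s:
                    merged = (cur[i][0], max(cur[i][1], cur[i + 1][1]))
                    cur = cur[:i] + [merged] + cur[i + 2 :]
                    changed = True
                    break
        assert got == cur
        assert merge_candidates(got, PARAMS) == got  # idempotent

    def test_duration_gate_strict_bounds(self):
        p = PARAMS
        ivs = [(0.0, 0.10), (1.0, 1.30), (0.0, 0.015), (0.0, 0.25), (4.0, 4.0249)]
        kept = gate_duration(ivs, p)
        assert (0.0, 0.10) in kept and (4.0, 4.0249) in kept
        assert (1.0, 1.30) not in kept  # too long
        assert (0.0, 0.015) not in kept  # exactly the lower bound: excluded
        assert (0.0, 0.25) not in kept  # exactly the upper bound: excluded


class TestSpectralValidation:
    def test_ripple_band_tone_accepted(self):
        x, _ = tone(150.0, dur=0.1)
        ok, peak = validate_spectrum(x, FS)
        assert ok and peak == pytest.approx(150.0, abs=11.0)

    def test_line_noise_rejected(self):
        x, _ = tone(60.0, dur=0.1)
        ok, peak = validate_spectrum(x, FS)
        assert not ok and peak < 100.0

    def test_dc_offset_removed_by_constant_detrend(self):
        x, _ = tone(150.0, dur=0.1, amp=0.01)
        ok, peak = validate_spectrum(x + 5.0, FS)
        assert ok and peak > 100.0
        # oracle: without detrending the DC term would dominate below the floor
        f, p = signal.periodogram(x + 5.0, fs=FS, detrend=False)
        assert f[np.argmax(p)] < 50.0

    def test_too_short_segment_rejected_with_warning(self):
        with pytest.warns(UserWarning):
            ok, _ = validate_spectrum(np.array([1.0]), FS)
        assert not ok


class TestRunningExclusion:
    def test_running_and_missing_behavior_removed(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 100.0, 0.02)
        speed = np.abs(rng.normal(0, 0.05, t.size))
        speed[(t > 40) & (t < 50)] += 25.0  # running bout
        tr = SpeedTrace(times=t, speed=speed)
        starts = np.array([10.0, 45.0, 80.0, 150.0])  # 150 s: no behavior
        keep = exclude_running(starts, tr, PARAMS)
        assert keep.tolist() == [True, False, True, False]

    def test_threshold_matches_direct_scan(self):
        rng = np.random.default_rng(6)
        t = np.arange(0.0, 60.0, 0.02)
        tr = SpeedTrace(times=t, speed=rng.gamma(2.0, 1.0, t.size))
        starts = t[::37] + 0.001
        keep = exclude_running(starts, tr, PARAMS)
        z = tr.standardized_speed
        thr = np.percentile(z, 10) + 0.06
        expected = z[np.searchsorted(t, starts, side="right") - 1] <= thr
        assert np.array_equal(keep, expected)

    def test_no_behavior_removes_all(self):
        with pytest.warns(UserWarning, match="no behavioral data"):
            keep = exclude_running(np.array([1.0]), SpeedTrace(np.array([]), np.array([])), PARAMS)
        assert not keep.any()


class TestMetrics:
    def test_constant_envelope_strength(self):
        env = np.full(int(FS), 1e-3)  # 1 mV
        m = compute_metrics(0.2, 0.3, env, env, FS, PARAMS)
        assert m["strength"] == pytest.approx(1e-4, rel=0.02)  # 0.1 mV*s

    def test_linearity(self):
        rng = np.random.default_rng(7)
        env = np.abs(rng.normal(0, 1e-4, int(FS)))
        m1 = compute_metrics(0.1, 0.4, env, env, FS, PARAMS)
        m2 = compute_metrics(0.1, 0.4, 2 * env, 2 * env, FS, PARAMS)
        assert m2["strength"] == pytest.approx(2 * m1["strength"])
        assert m2["amplitude"] == pytest.approx(2 * m1["amplitude"])

    def test_triangular_envelope_closed_form(self):
        h, d = 2e-4, 0.2
        t = np.arange(int(FS)) / FS
        env = np.clip(h * (1 - np.abs(t - 0.5) / (d / 2)), 0, None)
        m = compute_metrics(0.4, 0.6, env, env, FS, PARAMS)
        assert m["strength"] == pytest.approx(h * d / 2, rel=0.01)

    def test_out_of_bounds_window_truncated(self):
        env = np.ones(100)
        with pytest.warns(UserWarning, match="truncated"):
            compute_metrics(-0.01, 0.05, env, env, FS, PARAMS)


class TestStrengthClass:
    def test_top_decile(self):
        ev = pd.DataFrame({"strength": np.arange(1.0, 101.0)})
        out = classify_strength(ev)
        assert set(ev["strength"][out["is_strong"]]) == set(range(91, 101))
        ev20 = pd.DataFrame({"strength": np.arange(1.0, 21.0)})
        assert set(ev20["strength"][classify_strength(ev20)["is_strong"]]) == {19.0, 20.0}

    def test_ties_fall_to_common(self):
        ev = pd.DataFrame({"strength": np.ones(50)})
        assert not classify_strength(ev)["is_strong"].any()

    def test_fewer_than_ten_events_all_common(self):
        with pytest.warns(UserWarning):
            out = classify_strength(pd.DataFrame({"strength": [1.0, 2.0]}))
        assert not out["is_strong"].any()


@pytest.fixture(scope="module")
def noise_trace():
    return one_over_f_noise(int(300 * FS), FS, 1.5, 1.5e-4, np.random.default_rng(11))


class TestChannelDetection:
    def test_determinism(self, noise_trace):
        a = detect_on_channel(noise_trace, FS, PARAMS)
        b = detect_on_channel(noise_trace, FS, PARAMS)
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_monotonicity(self, noise_trace):
        counts = []
        for k in (3.0, 5.0, 7.0):
            p = DetectionParams(peak_threshold_sd=k)
            counts.append(len(detect_on_channel(noise_trace, FS, p)))
        assert counts[0] >= counts[1] >= counts[2]

    def test_false_positive_budget_on_pure_noise(self, noise_trace):
        ev = detect_on_channel(noise_trace, FS, PARAMS)
        accepted = ev[ev["accepted"]]
        assert len(accepted) / 300.0 <= 0.01  # < 0.01 accepted events per second

    def test_events_never_overlap_artifact_mask(self, noise_trace):
        mask = np.zeros(noise_trace.size, dtype=bool)
        mask[int(100 * FS) : int(140 * FS)] = True
        x = noise_trace.copy()
        t = np.arange(x.size) / FS
        x += 5e-4 * np.exp(-((t - 120.0) ** 2) / (2 * 0.01**2)) * np.sin(
            2 * np.pi * 150 * t
        )  # strong ripple inside the masked stretch
        ev = detect_on_channel(x, FS, PARAMS, artifact_mask=mask)
        for r in ev.itertuples():
            assert not mask[int(r.start_s * FS) : int(r.stop_s * FS)].any()
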