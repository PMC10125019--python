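"""Propagation clusters, seeds, SCI, speed, maps, partial correlations."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from ripplemap.core import ChannelInfo, assign_sections
from ripplemap.propagation import (
    axis_partial_correlation,
    build_clusters,
    cluster_table,
    duration_ml_regression,
    filter_engaged,
    identify_seed,
    propagation_map,
    propagation_speed,
    sci_value,
    section_strength_thresholds,
)

ML = {f"p{i}": 100.0 * (i + 1) for i in range(6)}


def sections6():
    chans = [ChannelInfo(f"c{i}", f"p{i}", "CA1", (0.0, 0.0, ML[f"p{i}"])) for i in range(6)]
    return assign_sections(chans)


def ev(starts, strengths=None, durations=None):
    starts = np.asarray(starts, dtype=float)
    return pd.DataFrame(
        {
            "start_s": starts,
            "strength": strengths if strengths is not None else np.ones(starts.size),
            "duration_s": durations if durations is not None else np.full(starts.size, 0.08),
        }
    )


class TestBuildClusters:
    def test_three_probe_lags(self):
        ref = ev([10.0])
        ebp = {"p0": ev([10.0]), "p1": ev([10.010]), "p2": ev([10.020])}
        members = build_clusters(ref, ebp)
        assert len(members) == 3
        assert members.set_index("probe_id")["lag_ms"].to_dict() == pytest.approx(
            {"p0": 0.0, "p1": 10.0, "p2": 20.0}
        )

    def test_first_event_per_probe_kept(self):
        ref = ev([10.0])
        members = build_clusters(ref, {"p0": ev([10.005, 10.030])})
        assert len(members) == 1
        assert members["lag_ms"].iloc[0] == pytest.approx(5.0)

    def test_matches_exhaustive_window_scan(self):
        rng = np.random.default_rng(0)
        ref = ev(np.sort(rng.uniform(0, 100, 40)))
        ebp = {
            f"p{i}": ev(np.sort(rng.uniform(0, 100, 60))) for i in range(4)
        }
        members = build_clusters(ref, ebp)
        # brute-force oracle
        rows = []
        for k, t in enumerate(ref["start_s"]):
            for pid, df in ebp.items():
                inside = df[(df["start_s"] >= t - 0.06) & (df["start_s"] <= t + 0.06)]
                if len(inside):
                    rows.append((k, pid, inside["start_s"].min()))
        expected = sorted(rows)
        got = sorted(zip(members["cluster_id"], members["probe_id"], members["start_s"]))
        assert got == pytest.approx(expected)


class TestSeed:
    def test_earliest_member_wins(self):
        m = pd.DataFrame({"probe_id": ["p4", "p1"], "start_s": [10.0, 10.004]})
        assert identify_seed(m, ML)[0] == "p4"

    def test_tie_breaks_medial(self):
        m = pd.DataFrame({"probe_id": ["p4", "p1"], "start_s": [10.0, 10.0]})
        assert identify_seed(m, ML)[0] == "p1"
        # enumerate all two-probe ties: the smaller M-L coordinate always wins
        for a in range(6):
            for b in range(6):
                if a == b:
                    continue
                m = pd.DataFrame({"probe_id": [f"p{a}", f"p{b}"], "start_s": [5.0, 5.0]})
                assert identify_seed(m, ML)[0] == f"p{min(a, b)}"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            identify_seed(pd.DataFrame(columns=["probe_id", "start_s"]), ML)


class TestSci:
    def test_fractions(self):
        sections = sections6()
        thr = {"medial": 1.0, "central": 1.0, "lateral": 1.0}

        def members(vals):
            return pd.DataFrame(
                {"probe_id": ["p0", "p2", "p4"], "start_s": [0, 0, 0], "strength": vals}
            )

        assert sci_value(members([2.0, 2.0, 2.0]), thr, sections) == 1.0
        assert sci_value(members([0.5, 0.5, 0.5]), thr, sections) == 0.0
        assert sci_value(members([2.0, 0.5, 0.5]), thr, sections) == pytest.approx(1 / 3)

    def test_no_detecting_sections_is_nan(self):
        m = pd.DataFrame({"probe_id": ["p0"], "start_s": [0.0], "strength": [1.0]})
        assert np.isnan(sci_value(m, {}, sections6()))

    def test_section_thresholds_use_busiest_channel(self):
        sections = sections6()
        ebp = {
            "p0": ev(np.arange(10.0), strengths=np.arange(10.0)),  # busiest medial
            "p1": ev([1.0], strengths=[100.0]),
            "p2": ev(np.arange(5.0), strengths=np.full(5, 7.0)),
        }
        thr = section_strength_thresholds(ebp, sections)
        assert thr["medial"] == pytest.approx(np.percentile(np.arange(10.0), 90))
        assert thr["central"] == pytest.approx(7.0)
        assert "lateral" not in thr


class TestSpeed:
    def test_exact_linear_lags_recover_speed(self):
        mls = np.array([100.0, 200.0, 300.0, 400.0, 500.0, 600.0])
        lags = (mls - 100.0) / 110.0  # 110 um/ms
        secs = np.array(["medial", "medial", "central", "central", "lateral", "lateral"])
        assert propagation_speed(lags, mls, secs) == pytest.approx(110.0, rel=0.05)

    def test_synchronous_cluster_undefined(self):
        mls = np.array([100.0, 300.0, 500.0])
        assert np.isnan(propagation_speed(np.zeros(3), mls))

    def test_too_few_members_undefined(self):
        assert np.isnan(propagation_speed(np.array([0.0, 5.0]), np.array([0.0, 500.0])))

    def test_matches_normal_equations(self):
        lags = np.array([0.0, 4.0, 9.0])
        mls = np.array([100.0, 500.0, 1100.0])
        X = np.column_stack([np.ones(3), lags])
        beta = np.linalg.solve(X.T @ X, X.T @ mls)
        assert propagation_speed(lags, mls) == pytest.approx(beta[1])


class TestPartialCorrelation:
    def test_ml_dependence_detected_ap_rejected(self):
        rng = np.random.default_rng(1)
        ml = rng.uniform(0, 2400, 300)
        ap = rng.uniform(0, 500, 300)
        lag = 0.009 * ml + rng.normal(0, 2.0, 300)
        out = axis_partial_correlation(lag, ml, ap)
        assert out["r2_ml"] > 0.6 and out["p_ml"] < 1e-6
        assert out["r2_ap"] < 0.05

    def test_pure_noise_both_small(self):
        rng = np.random.default_rng(2)
        out = axis_partial_correlation(
            rng.normal(size=200), rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
        )
        assert out["r2_ml"] < 0.05 and out["r2_ap"] < 0.05

    def test_matches_residual_regression_definition(self):
        rng = np.random.default_rng(3)
        ml = rng.uniform(0, 10, 50)
        ap = 0.4 * ml + rng.normal(0, 1, 50)
        lag = 2 * ml - ap + rng.normal(0, 1, 50)
        out = axis_partial_correlation(lag, ml, ap)
        # oracle: regress out the covariate from both, correlate the residuals

        def resid(y, x):
            X = np.column_stack([np.ones_like(x), x])
            return y - X @ np.linalg.solve(X.T @ X, X.T @ y)

        r_manual = np.corrcoef(resid(lag, ap), resid(ml, ap))[0, 1]
        assert out["r2_ml"] == pytest.approx(r_manual**2, abs=1e-10)

    def test_needs_varying_coordinates(self):
        with pytest.raises(ValueError):
            axis_partial_correlation(
                np.arange(5.0), np.ones(5), np.arange(5.0)
            )


class TestMapsAndTables:
    def test_map_linear_in_ml_for_constant_speed(self):
        ref = ev(np.arange(10.0, 400.0, 2.0))
        speed = 110.0
        ebp = {
            p: ev(ref["start_s"].to_numpy() + (ML[p] - 100.0) / speed / 1000.0)
            for p in ML
        }
        members = build_clusters(ref, ebp)
        clusters = cluster_table(ref, members, sections6(), ML)
        m = propagation_map(members, clusters, ML)
        grid = m[m["kind"] == "grid"]
        slope = np.polyfit(grid["ml_um"], grid["mean_lag_ms"], 1)[0]
        assert slope == pytest.approx(1.0 / speed, rel=1e-6)
        probe_rows = m[m["kind"] == "probe"].set_index("ml_um")["mean_lag_ms"]
        assert probe_rows.loc[600.0] == pytest.approx(500.0 / speed)

    def test_engagement_and_seed_fraction_partition(self):
        rng = np.random.default_rng(4)
        ref = ev(np.sort(rng.uniform(0, 500, 120)))
        ebp = {"p0": ref}
        for p in list(ML)[1:]:
            keep = rng.random(120) < 0.8
            ebp[p] = ev(np.sort(ref["start_s"].to_numpy()[keep] + rng.normal(0.01, 0.004, keep.sum())))
        members = build_clusters(ref, ebp)
        clusters = cluster_table(ref, members, sections6(), ML)
        assert clusters["spatial_engagement"].between(0, 1).all()
        fr = clusters["seed_section"].value_counts(normalize=True)
        assert fr.sum() == pytest.approx(1.0)
        engaged = filter_engaged(clusters, 0.5)
        assert (engaged["spatial_engagement"] > 0.5).all()

    def test_duration_regression_exact_line(self):
        ml = np.tile(np.array(list(ML.values())), 20)
        dur = 0.2 - 1e-4 * ml
        slope, r2 = duration_ml_regression(dur, ml)
        assert slope == pytest.approx(-1e-4)
        assert r2 == pytest.approx(1.0)
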