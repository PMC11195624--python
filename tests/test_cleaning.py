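"""The six-stage cleaning protocol: unit behaviour, oracle equivalence,
idempotence and monotonicity."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from fluorocal.cleaning import (
    CleaningConfig,
    CleanSeries,
    Flag,
    apply_manual_masks,
    clean_pipeline,
    cleaning_report,
    floor_filter,
    nightly_median,
    repeat_filter,
    roc_filter,
    rolling_band_filter,
    select_night,
)
from fluorocal.io import EnvSeries
from conftest import make_series, night_par_for


def fresh(values, **kw):
    s = make_series(values, **kw)
    return CleanSeries.fresh(s)


# ---------------------------------------------------------------------------
# brute-force oracles: plain-python re-implementations of the two
# statistical filters, deliberately free of searchsorted/vectorisation

def oracle_band(t_ns, x, window_ns, k, min_points=5):
    half = window_ns // 2
    bad = set()
    lo = hi = 0
    for i in range(len(x)):
        while t_ns[lo] < t_ns[i] - half:
            lo += 1
        while hi < len(x) and t_ns[hi] <= t_ns[i] + half:
            hi += 1
        w = x[lo:hi]
        if len(w) < min_points:
            continue
        m = float(np.mean(w))
        s = float(np.std(w, ddof=1))
        if x[i] > k * (m + s) or x[i] < (m - s) / k:
            bad.add(i)
    return bad


def oracle_roc(t_ns, x, window_ns, mult, min_points=20,
               max_step_ns=int(3600 * 1e9)):
    from bisect import bisect_right

    eps = np.finfo(float).eps
    bad, acc_t, acc_d = set(), [], []
    g = 0
    for i in range(1, len(x)):
        if t_ns[i] - t_ns[g] > max_step_ns:
            g = i
            continue
        d = x[i] - x[g]
        cut = bisect_right(acc_t, t_ns[i] - window_ns)
        pool = acc_d[cut:]
        if len(pool) < min_points:
            pool = acc_d
        if len(pool) >= 2:
            med = float(np.median(pool))
            mad = float(np.median([abs(p - med) for p in pool]))
            guard = max(mad, eps * max(1.0, abs(x[i]) + abs(x[g])))
            if abs(d - med) > mult * guard:
                bad.add(i)
                continue
        g = i
        acc_t.append(t_ns[i])
        acc_d.append(d)
    return bad


def oracle_roc_iterated(t_ns, x, window_ns, mult, max_passes=5, **kw):
    keep = list(range(len(x)))
    bad_all = set()
    for _ in range(max_passes):
        bad = oracle_roc(t_ns[keep], x[keep], window_ns, mult, **kw)
        if not bad:
            break
        bad_all |= {keep[i] for i in bad}
        keep = [i for i in range(len(x)) if i not in bad_all]
    return bad_all


def random_night_series(rng, n):
    """A plausible night-only 5-min series: smooth level + noise + spikes."""
    start = pd.Timestamp("2019-04-01 20:00")
    times, t = [], start
    for _ in range(n):
        times.append(t)
        t += pd.Timedelta(minutes=5)
        if t.hour == 6 and t.minute == 0:  # day gap
            t += pd.Timedelta(hours=14)
    idx = pd.DatetimeIndex(times)
    level = 200 * np.exp(np.cumsum(rng.normal(0, 2e-3, n)))
    x = level + rng.normal(0, 2.0, n)
    n_spikes = rng.integers(0, max(2, n // 150))
    for _ in range(n_spikes):
        i = int(rng.integers(0, n))
        x[i] += rng.uniform(200, 2000) * rng.choice([-1, 1])
    return idx, x


class TestSelectNight:
    def test_par_one_everywhere_retains_all(self):
        s = make_series([10, 11, 12])
        cs = select_night(s, night_par_for(s, 1.0), CleaningConfig())
        assert (cs.flags == 0).all()

    def test_daytime_point_flagged(self):
        s = make_series([10, 11, 12])
        par = pd.Series([1.0, 650.0, 1.0], index=s.frame.index)
        cs = select_night(s, EnvSeries("par", par), CleaningConfig())
        assert list(cs.flags) == [0, int(Flag.DAYTIME), 0]

    def test_par_missing_two_hours_flags_conservatively(self):
        s = make_series(range(36), freq="5min")  # 3 h
        par = pd.Series([1.0], index=[s.frame.index[0]])
        cs = select_night(s, EnvSeries("par", par), CleaningConfig())
        # PAR held forward 30 min only: first 7 points covered
        assert (cs.flags.iloc[:7] == 0).all()
        assert (cs.flags.iloc[7:] == int(Flag.DAYTIME)).all()


class TestFloorFilter:
    def test_negative_value_flagged(self):
        cs = floor_filter(fresh([5, -12, 6]), CleaningConfig())
        assert list(cs.flags) == [0, int(Flag.BELOW_MIN), 0]

    def test_boundary_equality_retained(self):
        cs = floor_filter(fresh([0.0, 1.0]), CleaningConfig())
        assert (cs.flags == 0).all()

    def test_all_positive_unchanged(self):
        cs = floor_filter(fresh([1, 2, 3]), CleaningConfig())
        assert (cs.flags == 0).all()


class TestRepeatFilter:
    def test_long_run_fully_flagged(self):
        vals = [1, 2] + [7.0] * 7 + [3]
        cs = repeat_filter(fresh(vals), CleaningConfig(repeat_run_len=6))
        assert (cs.flags.iloc[2:9] == int(Flag.REPEAT)).all()
        assert cs.flags.iloc[0] == 0 and cs.flags.iloc[9] == 0

    def test_short_run_retained(self):
        cs = repeat_filter(fresh([1, 7, 7, 7, 2]), CleaningConfig())
        assert (cs.flags == 0).all()

    def test_alternating_values_retained(self):
        cs = repeat_filter(fresh([1, 2, 1, 2, 1, 2, 1, 2]), CleaningConfig())
        assert (cs.flags == 0).all()

    def test_run_counts_only_retained_points(self):
        # a daytime-flagged point inside a run still joins its neighbours
        vals = [7.0] * 6
        cs = fresh(vals)
        cs.flags.iloc[3] = int(Flag.DAYTIME)
        out = repeat_filter(cs, CleaningConfig(repeat_run_len=5))
        assert (out.flags[out.flags == int(Flag.REPEAT)].count()) == 5


class TestRocFilter:
    def test_constant_series_unflagged(self):
        cs = roc_filter(fresh([100.0] * 50), CleaningConfig(roc_min_points=5))
        assert (cs.flags == 0).all()

    def test_single_jump_in_noise_flagged(self):
        rng = np.random.default_rng(0)
        vals = 500 + rng.normal(0, 2, 100)
        vals[60] += 1000
        cs = roc_filter(fresh(vals), CleaningConfig(roc_min_points=5))
        flagged = np.flatnonzero(cs.flags.to_numpy())
        assert list(flagged) == [60]

    def test_smooth_linear_ramp_unflagged(self):
        cs = roc_filter(fresh(np.linspace(100, 600, 80)), CleaningConfig(roc_min_points=5))
        assert (cs.flags == 0).all()

    def test_day_gap_difference_is_not_evidence(self):
        # two nights at very different levels: the overnight step is skipped
        idx1 = pd.date_range("2019-06-01 22:00", periods=40, freq="5min")
        idx2 = pd.date_range("2019-06-02 22:00", periods=40, freq="5min")
        s = make_series(list(np.full(40, 100.0)) + list(np.full(40, 400.0)))
        s.frame.index = idx1.append(idx2)
        s.frame["value_mV"] += np.random.default_rng(1).normal(0, 1, 80)
        cs = roc_filter(CleanSeries.fresh(s), CleaningConfig(roc_min_points=5))
        assert (cs.flags == 0).all()


class TestRollingBandFilter:
    def test_constant_series_unflagged(self):
        cs = rolling_band_filter(fresh([100.0] * 60), CleaningConfig())
        assert (cs.flags == 0).all()

    def test_isolated_excursion_flagged(self):
        vals = [100.0] * 60
        vals[30] = 200.0
        cs = rolling_band_filter(fresh(vals), CleaningConfig())
        flagged = np.flatnonzero(cs.flags.to_numpy())
        assert list(flagged) == [30]

    def test_infinite_k_flags_nothing(self):
        rng = np.random.default_rng(2)
        vals = 100 + rng.normal(0, 30, 200)
        cs = rolling_band_filter(fresh(vals), CleaningConfig(band_k=1e12))
        assert (cs.flags == 0).all()

    def test_small_window_gives_no_flag(self):
        cs = rolling_band_filter(fresh([100, 500, 100]), CleaningConfig())
        assert (cs.flags == 0).all()  # < 5 points in any window


class TestManualMasks:
    def test_mask_flags_its_interval(self):
        cfg = CleaningConfig(manual_masks=(
            ("A1", (pd.Timestamp("2019-06-01 00:05"), pd.Timestamp("2019-06-01 00:15")), "fouling"),
        ))
        cs = apply_manual_masks(fresh([1, 2, 3, 4, 5]), cfg)
        assert list(cs.flags) == [0, 32, 32, 32, 0]
        assert cs.manual_reasons[0][2] == "fouling"

    def test_empty_mask_list_unchanged(self):
        cs = apply_manual_masks(fresh([1, 2, 3]), CleaningConfig())
        assert (cs.flags == 0).all()

    def test_overlapping_masks_flag_union_once(self):
        cfg = CleaningConfig(manual_masks=(
            ("A1", (pd.Timestamp("2019-06-01 00:00"), pd.Timestamp("2019-06-01 00:10")), "a"),
            ("A1", (pd.Timestamp("2019-06-01 00:05"), pd.Timestamp("2019-06-01 00:20")), "b"),
        ))
        cs = apply_manual_masks(fresh([1, 2, 3, 4, 5, 6]), cfg)
        assert (cs.flags.iloc[:5] == int(Flag.MANUAL)).all()
        assert cs.flags.iloc[5] == 0

    def test_other_tanks_masks_ignored(self):
        cfg = CleaningConfig(manual_masks=(
            ("H3", (pd.Timestamp("2019-06-01"), pd.Timestamp("2019-06-02")), "x"),
        ))
        cs = apply_manual_masks(fresh([1, 2, 3]), cfg)
        assert (cs.flags == 0).all()


class TestNightlyMedian:
    def test_plain_median(self):
        cs = fresh([10, 20, 30] * 5, start="2019-06-01 01:00")
        out = nightly_median(cs, n_min=12)
        assert len(out) == 1 and out["median_mV"].iloc[0] == 20.0

    def test_sparse_night_omitted(self):
        cs = fresh([10, 20, 30, 40, 50], start="2019-06-01 01:00")
        assert nightly_median(cs, n_min=12).empty

    def test_median_resists_contamination(self):
        cs = fresh([10, 10, 10, 10, 500] * 3, start="2019-06-01 01:00")
        out = nightly_median(cs, n_min=12)
        assert out["median_mV"].iloc[0] == 10.0

    def test_evening_points_belong_to_next_morning(self):
        cs = fresh([5.0] * 24, start="2019-06-01 22:00")  # 22:00–00:55
        out = nightly_median(cs, n_min=12)
        assert list(out["date"]) == [dt.date(2019, 6, 2)]


class TestCleaningReport:
    def test_fraction_removed(self):
        cs = fresh([1.0] * 100)
        cs.flags.iloc[:8] = int(Flag.BAND)
        rep = cleaning_report(cs)
        assert rep.total_nighttime_points == 100
        assert rep.fraction_removed == pytest.approx(0.08)

    def test_no_flags_zero_fraction(self):
        rep = cleaning_report(fresh([1.0] * 10))
        assert rep.fraction_removed == 0.0

    def test_fully_flagged_nights_count_as_days_removed(self):
        idx = pd.date_range("2019-06-01 00:00", periods=3 * 288, freq="5min")
        s = make_series(np.ones(len(idx)))
        s.frame.index = idx
        cs = CleanSeries.fresh(s)
        cs.flags[:] = int(Flag.ROC)
        rep = cleaning_report(cs)
        # 3 calendar days of points straddle 4 night labels (midday split)
        assert rep.equivalent_days_removed == 4
        assert rep.fraction_removed == 1.0


class TestPipelineProperties:
    def test_idempotence_on_own_output(self, small_truth, small_cfg):
        from fluorocal.io import aggregate_5min_median
        from fluorocal.synthetic import simulate_sensor

        sim = simulate_sensor(small_truth, "B1", "chla")
        agg = aggregate_5min_median(sim.raw)
        cfg = CleaningConfig()
        cs1 = clean_pipeline(agg.__class__(agg.sensor_id, agg.tank_id, agg.pigment,
                                           agg.frame), small_truth.par, cfg)
        retained = cs1.series.frame[cs1.flags == 0]
        again = agg.__class__(agg.sensor_id, agg.tank_id, agg.pigment, retained.copy())
        cs2 = clean_pipeline(again, small_truth.par, cfg)
        assert (cs2.flags == 0).all()

    @pytest.mark.parametrize("param,values", [
        ("band_k", [1.2, 2.0, 4.0]),
        ("roc_mad_mult", [6.0, 10.0, 20.0]),
    ])
    def test_looser_thresholds_never_flag_more(self, param, values):
        rng = np.random.default_rng(5)
        idx, x = random_night_series(rng, 800)
        counts = []
        for v in values:
            s = make_series(x)
            s.frame.index = idx
            cfg = CleaningConfig(**{param: v})
            cs = clean_pipeline(s, night_par_for(s), cfg)
            counts.append(int((cs.flags > 0).sum()))
        assert counts == sorted(counts, reverse=True) or counts[0] >= counts[-1]


class TestOracleEquivalence:
    """The production filters agree with plain-python re-implementations."""

    @pytest.mark.parametrize("seed", range(8))
    def test_band_filter_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 1200))
        idx, x = random_night_series(rng, n)
        s = make_series(x)
        s.frame.index = idx
        cfg = CleaningConfig()
        cs = rolling_band_filter(CleanSeries.fresh(s), cfg)
        got = set(np.flatnonzero(cs.flags.to_numpy()))
        want = oracle_band(idx.asi8, x, int(cfg.band_window.value), cfg.band_k)
        assert got == want

    @pytest.mark.parametrize("seed", range(8))
    def test_roc_filter_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(100, 1200))
        idx, x = random_night_series(rng, n)
        s = make_series(x)
        s.frame.index = idx
        cfg = CleaningConfig()
        cs = roc_filter(CleanSeries.fresh(s), cfg)
        got = set(np.flatnonzero(cs.flags.to_numpy()))
        want = oracle_roc_iterated(idx.asi8, x, int(cfg.roc_window.value),
                                   cfg.roc_mad_mult, max_passes=cfg.roc_max_passes,
                                   min_points=cfg.roc_min_points,
                                   max_step_ns=int(cfg.roc_max_step.value))
        assert got == want
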