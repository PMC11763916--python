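"""Daily RATIO computation, partitioning, aggregation and filtering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_day
from ratioflux import ratio_core
from ratioflux.errors import ConfigurationError, ParameterError


class TestPartition:
    def test_day_length_counts_slots(self):
        df = ratio_core.partition_day_night(make_day(n_day=30))
        assert df["day"].sum() == 30
        s = ratio_core.aggregate_daily(df)
        assert s.loc[0, "day_length"] == pytest.approx(15.0)

    def test_polar_winter_day_all_night(self):
        df = make_day(n_day=0, le_day=0.0, le_night=5.0)
        labeled = ratio_core.partition_day_night(df)
        assert not labeled["day"].any()
        s = ratio_core.aggregate_daily(labeled)
        assert s.loc[0, "day_length"] == 0.0
        assert s.loc[0, "ratio"] == 0.0  # daytime sum zero -> boundary, filtered later

    def test_missing_indicator_column_raises(self):
        df = make_day().drop(columns=["sw_in_pot"])
        with pytest.raises(ConfigurationError):
            ratio_core.partition_day_night(df)
        with pytest.raises(ParameterError):
            ratio_core.partition_day_night(make_day(), rule="noon")

    def test_sw_in_threshold_rule(self):
        df = make_day(extra={"sw_in": np.r_[np.full(24, 5.0), np.full(24, 100.0)]})
        labeled = ratio_core.partition_day_night(df, rule="swin20")
        assert labeled["day"].sum() == 24


class TestDailyRatio:
    @pytest.mark.parametrize(
        "day_sum,night_sum,expected",
        [(8.0, 2.0, 0.8), (4.0, 0.0, 1.0), (4.0, -1.0, 4.0 / 3.0)],
    )
    def test_ratio_arithmetic(self, day_sum, night_sum, expected):
        le = np.array([day_sum, night_sum])
        day = np.array([True, False])
        assert ratio_core.compute_daily_ratio(le, day) == pytest.approx(expected)

    def test_zero_daily_sum_is_undefined(self):
        assert np.isnan(ratio_core.compute_daily_ratio(
            np.array([2.0, -2.0]), np.array([True, False])))


class TestAggregation:
    def test_aggregates_match_brute_force(self):
        """Site-day aggregates equal hand-computed per-period sums/means."""
        rng = np.random.default_rng(42)
        n_day = 28
        extra = {
            "ta": rng.normal(15, 3, 48),
            "vpd": rng.uniform(1, 10, 48),
            "rn": rng.normal(100, 30, 48),
            "co2": rng.normal(410, 5, 48),
            "swc": rng.uniform(10, 30, 48),
            "precip": rng.uniform(0, 0.5, 48),
            "nee": rng.normal(-2, 3, 48),
            "reco": rng.uniform(0, 4, 48),
            "gpp": rng.uniform(0, 12, 48),
        }
        df = make_day(le_day=12.0, le_night=3.0, n_day=n_day, extra=extra)
        labeled = ratio_core.partition_day_night(df)
        s = ratio_core.aggregate_daily(labeled).iloc[0]
        day = labeled["day"].to_numpy()
        # independent brute-force oracle over the 48 slots
        assert s["ta_day"] == pytest.approx(extra["ta"][day].mean())
        assert s["ta_night"] == pytest.approx(extra["ta"][~day].mean())
        assert s["delta_t"] == pytest.approx(extra["ta"][day].mean() - extra["ta"][~day].mean())
        for name in ("vpd", "rn", "co2", "swc"):
            assert s[name] == pytest.approx(extra[name].mean())
        assert s["precip"] == pytest.approx(extra["precip"].sum())
        assert s["nee_day"] == pytest.approx(extra["nee"][day].sum())
        assert s["nee_night"] == pytest.approx(extra["nee"][~day].sum())
        assert s["nee"] == pytest.approx(extra["nee"].sum())
        assert s["reco_day"] == pytest.approx(extra["reco"][day].sum())
        assert s["gpp_day"] == pytest.approx(extra["gpp"][day].sum())
        le_day = labeled.loc[labeled["day"], "le"].sum()
        assert s["ratio"] == pytest.approx(le_day / labeled["le"].sum())
        assert s["wuei_gpp"] == pytest.approx(
            extra["gpp"][day].sum() * extra["vpd"].mean() / le_day)

    def test_wuei_formula_example(self):
        # gpp_day=10, vpd=1.2, le_day=6 -> wuei = 2
        df = make_day(le_day=6.0, le_night=1.0, n_day=24, extra={
            "vpd": np.full(48, 1.2),
            "gpp": np.r_[np.zeros(12), np.full(24, 10.0 / 24), np.zeros(12)],
        })
        s = ratio_core.daily_summaries(df).iloc[0]
        assert s["wuei_gpp"] == pytest.approx(2.0)

    def test_constant_temperature_gives_zero_delta_t(self):
        df = make_day(extra={"ta": np.full(48, 15.0)})
        s = ratio_core.daily_summaries(df).iloc[0]
        assert s["ta_day"] == pytest.approx(15.0)
        assert s["delta_t"] == pytest.approx(0.0)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(3)
        df = make_day(extra={"ta": rng.normal(10, 2, 48), "gpp": rng.uniform(0, 5, 48)})
        labeled = ratio_core.partition_day_night(df)
        shuffled = labeled.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = ratio_core.aggregate_daily(labeled)
        b = ratio_core.aggregate_daily(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_low_coverage_marked_invalid(self):
        df = make_day()
        df.loc[df.index[:10], "le"] = np.nan
        s = ratio_core.daily_summaries(df, min_coverage=0.9).iloc[0]
        assert s["coverage_fraction"] == pytest.approx(38 / 48)
        assert not s["valid"]

    def test_unlabeled_records_rejected(self):
        with pytest.raises(ConfigurationError):
            ratio_core.aggregate_daily(make_day())


class TestFilter:
    def test_open_interval_rule(self):
        summaries = pd.DataFrame({
            "ratio": [0.5, 1.2, -0.1, 0.93], "valid": [True] * 4})
        kept, frac = ratio_core.filter_ratio(summaries)
        assert sorted(kept["ratio"]) == [0.5, 0.93]
        assert frac == pytest.approx(0.5)

    def test_all_in_range_discards_nothing(self):
        summaries = pd.DataFrame({"ratio": [0.2, 0.8], "valid": [True, True]})
        kept, frac = ratio_core.filter_ratio(summaries)
        assert frac == 0.0 and len(kept) == 2

    def test_kept_ratios_strictly_inside_unit_interval(self, small_net):
        summaries, _, _ = small_net
        kept, frac = ratio_core.filter_ratio(summaries)
        assert ((kept["ratio"] > 0) & (kept["ratio"] < 1)).all()
        assert 0.0 < frac < 1.0


class TestTimescale:
    def test_monthly_mean_of_daily_ratios(self):
        summaries = pd.DataFrame({
            "site_id": "A",
            "date": pd.to_datetime(["2005-06-01", "2005-06-02"]),
            "ratio": [0.8, 0.9],
        })
        out = ratio_core.aggregate_timescale(summaries, "monthly")
        assert out.loc[0, "ratio"] == pytest.approx(0.85)
        assert out.loc[0, "n_days"] == 2

    def test_single_day_period_is_identity(self):
        summaries = pd.DataFrame({
            "site_id": "A", "date": pd.to_datetime(["2005-06-01"]), "ratio": [0.77]})
        out = ratio_core.aggregate_timescale(summaries, "annual")
        assert out.loc[0, "ratio"] == pytest.approx(0.77)

    def test_unknown_scale_rejected(self):
        with pytest.raises(ParameterError):
            ratio_core.aggregate_timescale(pd.DataFrame({
                "site_id": [], "date": pd.to_datetime([]), "ratio": []}), "weekly")

    def test_mean_daily_ratio_site_subset(self, small_kept):
        sites = small_kept["site_id"].unique()[:3]
        sub = small_kept[small_kept["site_id"].isin(sites)]
        assert ratio_core.mean_daily_ratio(small_kept, sites) == pytest.approx(
            sub["ratio"].mean())


def test_wuei_identity_holds_on_network(small_kept):
    ok = small_kept["le_day"] > 0
    expect = small_kept["gpp_day"] * small_kept["vpd"] / small_kept["le_day"]
    np.testing.assert_allclose(small_kept.loc[ok, "wuei_gpp"], expect[ok], rtol=1e-10)


def test_day_and_night_lengths_sum_to_24(small_net):
    summaries, _, _ = small_net
    assert (summaries["day_length"] >= 0).all() and (summaries["day_length"] <= 24).all()
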