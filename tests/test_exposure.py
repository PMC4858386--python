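"""Exposure-metric tests: time weights, TWA, ingestion, uptake, categories."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbpexposure import (
    ExposureWindow,
    WaterUseProfile,
    categorize,
    compute_time_weights,
    correlate_metrics,
    default_factors,
    ingestion,
    integrated_uptake,
    pregnancy_windows,
    twa_concentration,
    workplace_assignment_summary,
)
from dbpexposure.concentration import ConcentrationSurface


def constant_surface(value, zones=("Z1", "Z2"), start="2006-01",
                     end="2011-12", freq="M", analyte="TTHM"):
    cells = pd.period_range(start, end, freq=freq)
    rows = [(z, c, value, np.nan, "fitted") for z in zones for c in cells]
    frame = pd.DataFrame(rows, columns=["wsz_id", "time_cell", "pred_ugL",
                                        "sd", "provenance"])
    return ConcentrationSurface(analyte=analyte, freq=freq, frame=frame)


def cellwise_surface(rng, zones, start="2006-01", end="2011-12", freq="M"):
    cells = pd.period_range(start, end, freq=freq)
    rows = [(z, c, rng.uniform(10, 90), np.nan, "fitted")
            for z in zones for c in cells]
    frame = pd.DataFrame(rows, columns=["wsz_id", "time_cell", "pred_ugL",
                                        "sd", "provenance"])
    return ConcentrationSurface(analyte="TTHM", freq=freq, frame=frame)


# ---------------------------------------------------------------------------
# windows and weights
# ---------------------------------------------------------------------------

class TestWindows:
    def test_trimester_day_ranges(self):
        w = pregnancy_windows(dt.date(2008, 1, 1), dt.date(2008, 10, 8))
        assert (w["T1"].start_day, w["T1"].end_day) == (1, 93)
        assert (w["T2"].start_day, w["T2"].end_day) == (94, 186)
        assert w["T3"].start_day == 187
        # whole window ends the day before delivery
        assert w["whole"].end_day == (dt.date(2008, 10, 8)
                                      - dt.date(2008, 1, 1)).days

    def test_pregnancy_too_short_for_t3_errors(self):
        with pytest.raises(ValueError, match="trimester 3"):
            pregnancy_windows(dt.date(2008, 1, 1), dt.date(2008, 5, 1),
                              labels=("T3",))


class TestTimeWeights:
    def test_window_inside_one_month_gets_weight_one(self):
        w = compute_time_weights(ExposureWindow("x", 3, 20),
                                 dt.date(2009, 6, 1), dt.date(2010, 3, 1),
                                 "month")
        assert list(w) == [pd.Period("2009-06", "M")]
        assert w[pd.Period("2009-06", "M")] == 1.0

    def test_t1_from_first_of_31_day_month_day_counts(self):
        # T1 = 93 days starting 1 Jan: 31 in Jan, 28 in Feb, 31 in Mar, 3 Apr
        w = compute_time_weights(ExposureWindow("T1", 1, 93),
                                 dt.date(2009, 1, 1), dt.date(2009, 10, 10),
                                 "month")
        assert w[pd.Period("2009-01", "M")] == pytest.approx(31 / 93)
        assert w[pd.Period("2009-02", "M")] == pytest.approx(28 / 93)
        assert w[pd.Period("2009-03", "M")] == pytest.approx(31 / 93)
        assert w[pd.Period("2009-04", "M")] == pytest.approx(3 / 93)

    @pytest.mark.parametrize("grid", ["month", "quarter"])
    def test_weights_sum_to_one_random_pregnancies(self, grid):
        rng = np.random.default_rng(42)
        for _ in range(50):
            conception = dt.date(2007, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, 1000)))
            gest = int(rng.integers(260, 295))
            delivery = conception + dt.timedelta(days=gest)
            for win in pregnancy_windows(conception, delivery).values():
                w = compute_time_weights(win, conception, delivery, grid)
                assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
                assert all(v >= 0 for v in w.values())

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(offset=st.integers(0, 1400), gest=st.integers(200, 300),
           grid=st.sampled_from(["month", "quarter"]))
    def test_weights_partition_any_pregnancy(self, offset, gest, grid):
        """For arbitrary dates the weights are a partition of unity."""
        conception = dt.date(2006, 1, 1) + dt.timedelta(days=offset)
        delivery = conception + dt.timedelta(days=gest)
        win = pregnancy_windows(conception, delivery, labels=("whole",))["whole"]
        w = compute_time_weights(win, conception, delivery, grid)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        assert min(w.values()) > 0

    def test_weights_match_day_by_day_oracle(self):
        """Closed-form overlap equals brute-force day iteration to 1e-9."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            conception = dt.date(2006, 6, 1) + dt.timedelta(
                days=int(rng.integers(0, 1200)))
            delivery = conception + dt.timedelta(days=int(rng.integers(260, 295)))
            win = pregnancy_windows(conception, delivery)["whole"]
            for freq in ("M", "Q"):
                w = compute_time_weights(win, conception, delivery, freq)
                oracle = {}
                for d in range(win.start_day, win.end_day + 1):
                    day = conception + dt.timedelta(days=d - 1)
                    cell = pd.Period(day, freq=freq)
                    oracle[cell] = oracle.get(cell, 0) + 1 / win.n_days
                assert set(w) == set(oracle)
                for cell in w:
                    assert w[cell] == pytest.approx(oracle[cell], abs=1e-9)


# ---------------------------------------------------------------------------
# time-weighted average concentration
# ---------------------------------------------------------------------------

class TestTwa:
    def setup_method(self):
        self.conception = dt.date(2008, 2, 10)
        self.delivery = dt.date(2008, 11, 12)
        win = pregnancy_windows(self.conception, self.delivery)["whole"]
        self.weights = compute_time_weights(win, self.conception,
                                            self.delivery, "month")

    def test_work_residence_split_hand_arithmetic(self):
        frame = constant_surface(56.0).frame
        frame.loc[frame.wsz_id == "Z2", "pred_ugL"] = 1e-12
        surf = ConcentrationSurface("TTHM", "M", frame)
        twa = twa_concentration(surf, self.weights, "Z1", "Z2")
        assert twa == pytest.approx(56 * 72 / 112, rel=1e-9)

    def test_equal_zones_give_the_common_value(self):
        surf = constant_surface(33.3)
        assert twa_concentration(surf, self.weights, "Z1", "Z2") == \
            pytest.approx(33.3)

    def test_residence_only_identity_on_constant_surface(self):
        surf = constant_surface(45.6)
        assert twa_concentration(surf, self.weights, "Z1") == pytest.approx(45.6)

    def test_uncovered_window_is_missing_not_zero(self):
        surf = constant_surface(45.6, start="2008-06", end="2008-12")
        out = twa_concentration(surf, self.weights, "Z1")
        assert np.isnan(out)

    def test_twa_matches_daily_brute_force_oracle(self):
        """Weight-based TWA equals day-by-day averaging to 1e-9."""
        rng = np.random.default_rng(11)
        surf = cellwise_surface(rng, ["Z1", "Z2"])
        for k in range(50):
            conception = dt.date(2006, 3, 1) + dt.timedelta(
                days=int(rng.integers(0, 1500)))
            delivery = conception + dt.timedelta(days=int(rng.integers(260, 295)))
            win = pregnancy_windows(conception, delivery)["whole"]
            weights = compute_time_weights(win, conception, delivery, "month")
            work = "Z2" if k % 2 else None
            got = twa_concentration(surf, weights, "Z1", work)
            daily = []
            for d in range(win.start_day, win.end_day + 1):
                day = conception + dt.timedelta(days=d - 1)
                cell = pd.Period(day, freq="M")
                c = surf.value("Z1", cell)
                if work:
                    c = (72 / 112) * c + (40 / 112) * surf.value("Z2", cell)
                daily.append(c)
            assert got == pytest.approx(np.mean(daily), abs=1e-9)


# ---------------------------------------------------------------------------
# ingestion and uptake
# ---------------------------------------------------------------------------

class TestIngestion:
    def test_hot_beverage_thm_boiling_hand_arithmetic(self, factors):
        profile = WaterUseProfile(tea_Lday=1.0)
        out = ingestion(profile, {"TTHM": 50.0}, factors)
        assert out["TTHM"] == pytest.approx(50 * (1 - 0.92))

    def test_hot_beverage_dcaa_boiling_increases(self, factors):
        profile = WaterUseProfile(tea_Lday=1.0)
        out = ingestion(profile, {"DCAA": 10.0}, factors)
        assert out["DCAA"] == pytest.approx(14.35)

    def test_zero_volumes_zero_dose(self, factors):
        profile = WaterUseProfile()
        out = ingestion(profile, {"TTHM": 50.0, "DCAA": 9.0, "TCAA": 12.0,
                                  "BDCAA": 1.3}, factors)
        assert all(v == 0.0 for v in out.values())

    def test_boil_filter_constants_applied_exactly(self, factors):
        """One litre of each drink class isolates each stated constant."""
        conc = {"TTHM": 100.0, "DCAA": 100.0, "TCAA": 100.0, "BDCAA": 100.0}
        hot = ingestion(WaterUseProfile(tea_Lday=1.0), conc, factors)
        assert hot["TTHM"] == pytest.approx(100 * (1 - 0.92))
        assert hot["DCAA"] == pytest.approx(100 * (1 + 0.435))
        assert hot["TCAA"] == pytest.approx(100 * (1 - 0.369))
        assert hot["BDCAA"] == pytest.approx(100 * (1 - 0.565))
        filt = ingestion(WaterUseProfile(tap_Lday=1.0, filter_home=True),
                         conc, factors)
        assert filt["TTHM"] == pytest.approx(100 * (1 - 0.90))
        assert filt["DCAA"] == pytest.approx(100 * (1 - 0.618))
        assert filt["TCAA"] == pytest.approx(100 * (1 - 0.674))
        assert filt["BDCAA"] == pytest.approx(100 * (1 - 0.785))

    def test_squash_never_filtered_bottled_ignored(self, factors):
        profile = WaterUseProfile(squash_Lday=1.0, bottled_Lday=5.0,
                                  filter_home=True)
        out = ingestion(profile, {"TTHM": 50.0}, factors)
        assert out["TTHM"] == pytest.approx(50.0)  # unfiltered, no bottled

    def test_aggregates_additive(self, factors):
        profile = WaterUseProfile(tap_Lday=1.5, tea_Lday=0.5)
        conc = {"TTHM": 45.6, "DCAA": 8.9, "TCAA": 12.5, "BDCAA": 1.3}
        out = ingestion(profile, conc, factors)
        assert out["HAA3"] == pytest.approx(out["DCAA"] + out["TCAA"]
                                            + out["BDCAA"])
        assert out["DBP7"] == pytest.approx(out["TTHM"] + out["HAA3"])

    def test_homogeneous_degree_one_in_concentration(self, factors):
        profile = WaterUseProfile(tap_Lday=1.2, tea_Lday=0.4, squash_Lday=0.3)
        base = ingestion(profile, {"TTHM": 40.0}, factors)["TTHM"]
        scaled = ingestion(profile, {"TTHM": 120.0}, factors)["TTHM"]
        assert scaled == pytest.approx(3 * base)


class TestIntegratedUptake:
    def test_total_is_pathway_sum(self, factors):
        profile = WaterUseProfile(tap_Lday=1.0, tea_Lday=0.5,
                                  shower_minwk=90, bath_minwk=60,
                                  swim_minwk=30)
        out = integrated_uptake(profile, {"TTHM": 45.6}, factors,
                                analytes=["TTHM"])["TTHM"]
        assert out["total"] == pytest.approx(
            out["ingestion"] + out["shower"] + out["bath"] + out["swim"])
        assert out["sbs"] == pytest.approx(
            out["shower"] + out["bath"] + out["swim"])

    def test_no_activities_reduces_to_ingestion_pathway(self, factors):
        profile = WaterUseProfile(tap_Lday=1.0)
        out = integrated_uptake(profile, {"TTHM": 45.6}, factors,
                                analytes=["TTHM"])["TTHM"]
        assert out["total"] == pytest.approx(out["ingestion"])
        assert out["sbs"] == 0.0

    def test_shower_pathway_linear_in_minutes(self, factors):
        p1 = WaterUseProfile(shower_minwk=70)
        p2 = WaterUseProfile(shower_minwk=140)
        u1 = integrated_uptake(p1, {"TTHM": 50.0}, factors, ["TTHM"])["TTHM"]
        u2 = integrated_uptake(p2, {"TTHM": 50.0}, factors, ["TTHM"])["TTHM"]
        assert u2["shower"] == pytest.approx(2 * u1["shower"])

    def test_shower_hand_arithmetic_with_fixture_factor(self):
        from dbpexposure.factors import UptakeFactorTable
        table = UptakeFactorTable(uptake_factor={
            ("ingestion", "TTHM"): 0.0, ("shower", "TTHM"): 0.001,
            ("bath", "TTHM"): 0.0, ("swim", "TTHM"): 0.0})
        profile = WaterUseProfile(shower_minwk=70)
        out = integrated_uptake(profile, {"TTHM": 50.0}, table, ["TTHM"])
        assert out["TTHM"]["shower"] == pytest.approx(50 * 0.001 * 10)

    def test_swim_uses_pool_not_tap_concentration(self, factors):
        profile = WaterUseProfile(swim_minwk=70)
        a = integrated_uptake(profile, {"TTHM": 1.0}, factors, ["TTHM"])
        b = integrated_uptake(profile, {"TTHM": 99.0}, factors, ["TTHM"])
        assert a["TTHM"]["swim"] == pytest.approx(b["TTHM"]["swim"])

    def test_haa_rejected(self, factors):
        with pytest.raises(ValueError, match="THM-only"):
            integrated_uptake(WaterUseProfile(), {"DCAA": 9.0}, factors,
                              ["DCAA"])

    def test_missing_factor_is_configuration_error(self):
        from dbpexposure.factors import UptakeFactorTable
        table = UptakeFactorTable(uptake_factor={})
        with pytest.raises(KeyError, match="no uptake factor"):
            integrated_uptake(WaterUseProfile(tap_Lday=1.0), {"TTHM": 50.0},
                              table, ["TTHM"])


# ---------------------------------------------------------------------------
# categorisation and correlation
# ---------------------------------------------------------------------------

class TestCategorize:
    def test_tertiles_of_1_to_9_split_3_3_3(self):
        cat = categorize(np.arange(1.0, 10.0), "tertile")
        counts = pd.Series(cat.codes).value_counts()
        assert counts.tolist() == [3, 3, 3]

    def test_bathing_120_min_in_middle_band(self):
        cat = categorize([0.0, 30.0, 120.0, 121.0], "bath")
        assert cat.codes.tolist() == [0.0, 1.0, 2.0, 3.0]
        assert cat.labels[2] == "61-120"

    def test_tertile_cutpoints_match_quantile_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1, 1000)
        cat = categorize(x, "tertile")
        assert cat.cutpoints == pytest.approx(
            list(np.quantile(x, [1 / 3, 2 / 3])))
        # boundary handling: lower-closed, top closed
        assert categorize(x, "tertile").codes[np.argmax(x)] == 2

    def test_missing_values_stay_missing(self):
        cat = categorize([1.0, np.nan, 3.0, 2.0], "tertile")
        assert np.isnan(cat.codes[1])
        assert np.isfinite(cat.codes[[0, 2, 3]]).all()

    def test_swim_yes_no(self):
        cat = categorize([0.0, 0.0, 45.0], "swim")
        assert cat.codes.tolist() == [0.0, 0.0, 1.0]

    def test_cold_tap_fixed_bins(self):
        cat = categorize([0.4, 0.6, 1.0, 1.2, 1.4, 1.6, 3.0], "cold_tap")
        assert cat.codes.tolist() == [0, 1, 1, 2, 2, 3, 3]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1e4, allow_nan=False), min_size=3,
                    max_size=60))
    def test_every_observed_value_gets_exactly_one_tertile(self, values):
        cat = categorize(np.array(values), "tertile")
        assert np.isin(cat.codes, [0.0, 1.0, 2.0]).all()

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown categorisation"):
            categorize([1.0, 2.0], "quartile")


class TestCorrelations:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": -x})
        out = correlate_metrics(df)
        assert out.loc["a", "a"] == 1.0
        assert out.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_metrics_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.uniform(size=1000),
                           "b": rng.uniform(size=1000)})
        assert abs(correlate_metrics(df).loc["a", "b"]) < 0.1

    def test_constant_metric_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        assert np.isnan(correlate_metrics(df).loc["a", "b"])

    def test_pairwise_complete(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, np.nan],
                           "b": [1, 2, 3, np.nan, 5.0]})
        assert correlate_metrics(df).loc["a", "b"] == pytest.approx(1.0)


class TestWorkplaceSummary:
    def test_rate_from_counts(self):
        coh = pd.DataFrame({
            "employed": [True] * 100 + [False] * 30,
            "work_wsz": ["Z1"] * 58 + [np.nan] * 42 + [np.nan] * 30,
        })
        out = workplace_assignment_summary(coh)
        assert out["n_employed"] == 100
        assert out["n_assigned"] == 58
        assert out["assignment_rate_pct"] == pytest.approx(58.0)
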