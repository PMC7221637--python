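"""Weekly aggregation, per-order ratios, SNR, Welch tests, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import alertsuppress as ap

from conftest import make_events


class TestWeeklyAggregate:
    def test_hand_counted_fixture(self):
        # 7 events across two ISO weeks (2017-W01 ends Sun Jan 8).
        rows = []
        for i, (d, action, order, supp) in enumerate([
            ("2017-01-04", "override", False, False),
            ("2017-01-05", "none", False, False),
            ("2017-01-06", "open_smartset", True, False),
            ("2017-01-08", "none", False, False),          # Sunday, W01
            ("2017-01-09", "postpone", False, False),      # Monday, W02
            ("2017-01-10", "none", False, True),           # suppressed
            ("2017-01-11", "none", False, False),
        ]):
            rows.append({"encounter_id": f"E{i}", "patient_id": f"P{i}",
                         "service_date": d, "timestamp": f"{d}T10:00:00",
                         "response_action": action, "order_placed": order,
                         "fired": not supp, "suppressed": supp})
        wk = ap.weekly_aggregate(ap.AlertLog(make_events(rows)))
        wk = wk.set_index("iso_week")
        assert wk.loc[1, "appointments"] == 4
        assert wk.loc[1, "alerts"] == 4
        assert wk.loc[1, "interacted"] == 2
        assert wk.loc[1, "orders"] == 1
        assert wk.loc[2, "appointments"] == 3
        assert wk.loc[2, "alerts"] == 2     # suppressed excluded
        assert wk.loc[2, "interacted"] == 1
        assert wk.loc[2, "suppressed"] == 1

    def test_conservation(self, default_log):
        wk = ap.weekly_aggregate(default_log)
        assert wk["alerts"].sum() == default_log.n_fired
        assert wk["orders"].sum() == default_log.n_orders

    def test_empty_log(self):
        empty = ap.AlertLog(make_events([{}])).subset(np.array([False]))
        assert len(ap.weekly_aggregate(empty)) == 0


class TestRatios:
    def test_alerts_per_order_reference_values(self):
        assert ap.alerts_per_order(6123.7, 331.3) == pytest.approx(
            18.5, abs=0.05)
        assert ap.alerts_per_order(3541.0, 326.3) == pytest.approx(
            10.9, abs=0.05)
        assert ap.alerts_per_order(100, 100) == 1.0

    def test_zero_orders_undefined(self):
        with pytest.raises(ap.UndefinedMetricError):
            ap.alerts_per_order(10, 0)

    def test_snr_reference_values(self):
        assert 100 * ap.snr(6123.7, None, 331.3,
                            "orders_as_signal") == pytest.approx(5.7,
                                                                 abs=0.05)
        assert 100 * ap.snr(6123.7, 1162.3, None,
                            "interacted_as_signal") == pytest.approx(
                                23.4, abs=0.05)
        # 10.150 prints as 10.1 (truncated); allow one printed ulp.
        assert 100 * ap.snr(3541.0, None, 326.3,
                            "orders_as_signal") == pytest.approx(10.1,
                                                                 abs=0.1)

    def test_snr_zero_signal(self):
        assert ap.snr(10, None, 0, "orders_as_signal") == 0.0

    def test_snr_zero_noise_undefined(self):
        with pytest.raises(ap.UndefinedMetricError):
            ap.snr(10, 10, None, "interacted_as_signal")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(1, 1e6), st.floats(0.0001, 0.9999))
    def test_snr_rate_identity(self, alerts, rate):
        """SNR == r / (1 - r) where r is the per-alert signal rate."""
        signal = alerts * rate
        got = ap.snr(alerts, signal, None, "interacted_as_signal")
        assert got == pytest.approx(rate / (1 - rate), rel=1e-9)

    def test_percent_change(self):
        assert ap.percent_change(0.23427, 0.46159) == pytest.approx(
            97, abs=0.5)
        assert ap.percent_change(5.0, 5.0) == 0.0
        assert ap.percent_change(6123.7, 3541.0) == pytest.approx(
            -42.2, abs=0.05)
        with pytest.raises(ap.UndefinedMetricError):
            ap.percent_change(0.0, 1.0)


class TestWelch:
    def test_reference_pvalues(self):
        _, _, p_orders = ap.welch_one_sided(326.3, 23.6, 3, 331.3, 5.1, 3)
        assert round(p_orders, 2) == 0.38
        _, _, p_inter = ap.welch_one_sided(1118.3, 71.6, 3,
                                           1162.3, 22.8, 3)
        assert round(p_inter, 2) == 0.20

    def test_identical_arms(self):
        t, _, p = ap.welch_one_sided(5.0, 1.0, 3, 5.0, 1.0, 3)
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_from_raw_values_matches_summaries(self):
        rng = np.random.default_rng(0)
        on = rng.normal(10, 2, 4)
        off = rng.normal(12, 3, 5)
        res = ap.compare_on_off(on, off, metric="orders")
        _, _, p = ap.welch_one_sided(on.mean(), on.std(ddof=1), 4,
                                     off.mean(), off.std(ddof=1), 5)
        assert res.p_value == pytest.approx(p)
        assert 0 <= res.p_value <= 1

    def test_too_few_weeks_rejected(self):
        with pytest.raises(ValueError):
            ap.compare_on_off([1.0], [2.0, 3.0])


class TestSmoothedDailyRate:
    def make_log(self, rates, start="2017-01-02", per_day=20):
        rows = []
        day = pd.Timestamp(start)
        i = 0
        for r in rates:
            while day.weekday() >= 5:
                day += pd.Timedelta(days=1)
            k = int(round(r * per_day))
            for j in range(per_day):
                rows.append({
                    "encounter_id": f"E{i}", "patient_id": f"P{i}",
                    "service_date": day.strftime("%Y-%m-%d"),
                    "timestamp": day.strftime("%Y-%m-%d") + "T09:00:00",
                    "response_action": "override" if j < k else "none"})
                i += 1
            day += pd.Timedelta(days=1)
        return ap.AlertLog(make_events(rows))

    def test_constant_rate(self):
        log = self.make_log([0.25] * 8)
        out = ap.smoothed_daily_rate(log, window=5)
        np.testing.assert_allclose(out["smoothed"], 0.25)

    def test_window_one_is_raw(self):
        rates = [0.1, 0.3, 0.2, 0.4, 0.25]
        log = self.make_log(rates)
        out = ap.smoothed_daily_rate(log, window=1)
        np.testing.assert_allclose(out["smoothed"], rates)

    def test_ten_day_fixture_hand_rolling(self):
        rates = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.4, 0.3, 0.2, 0.1]
        log = self.make_log(rates, per_day=10)
        out = ap.smoothed_daily_rate(log, window=3)
        expected = (pd.Series(rates)
                    .rolling(3, center=True, min_periods=1).mean())
        np.testing.assert_allclose(out["smoothed"], expected)

    def test_weekends_excluded(self, default_log):
        out = ap.smoothed_daily_rate(default_log)
        assert (out["date"].dt.weekday < 5).all()


class TestBuildReport:
    def test_counts_recompute_exactly(self, small_pilot):
        pilot, _, _ = small_pilot
        rep = ap.build_report(pilot)
        ev = pilot.events.events
        total_fired = int(ev["fired"].sum())
        got = sum(rep[f"arm_{a}"]["alerts_total"]
                  for a in ("on", "off") if rep[f"arm_{a}"]["present"])
        assert got == total_fired
        assert rep["arm_on"]["suppressed_total"] == int(
            ev["suppressed"].sum())

    def test_empty_arm_marked_absent(self):
        from datetime import date
        gen = ap.GeneratorConfig(n_clinicians=30, n_patients=400,
                                 mean_encounters_per_day=15,
                                 date_range=(date(2017, 5, 1),
                                             date(2017, 6, 30)), seed=13)
        pipe = ap.PipelineConfig(window_start=date(2017, 5, 1),
                                 pilot_weeks=1, on_first=False, seed=13)
        pilot = ap.simulate_study(gen, pipe)
        rep = ap.build_report(pilot)
        assert rep["arm_on"]["present"] is False
        assert rep["arm_off"]["present"] is True

    def test_injected_volume_spike_flagged(self, small_pilot):
        pilot, _, _ = small_pilot
        ev = pilot.events.events.copy()
        # Duplicate one weekday's events tenfold.
        spike_day = ev.loc[ev["service_date"].dt.weekday < 5,
                           "service_date"].iloc[-1]
        extra = []
        day_rows = ev[ev["service_date"] == spike_day]
        for r in range(9):
            dup = day_rows.copy()
            dup["alert_id"] = dup["alert_id"] + f"_s{r}"
            dup["encounter_id"] = dup["encounter_id"] + f"_s{r}"
            extra.append(dup)
        spiked = ap.AlertLog(pd.concat([ev, *extra], ignore_index=True))
        from alertsuppress.evaluation import _volume_anomalies
        daily = ap.smoothed_daily_rate(spiked)
        flags = _volume_anomalies(daily)
        assert spike_day.date().isoformat() in flags

    def test_empty_pilot_rejected(self, small_pilot):
        pilot, _, _ = small_pilot
        import dataclasses
        empty = dataclasses.replace(
            pilot, events=pilot.events.subset(
                np.zeros(pilot.events.n_events, bool)))
        with pytest.raises(ValueError):
            ap.build_report(empty)
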