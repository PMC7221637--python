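"""Leakage safety of history features, label rules, provider assignment."""

import numpy as np
import pandas as pd
import pytest

import alertsuppress as ap
from alertsuppress.features import SHORT_WINDOW_DAYS

from conftest import make_events


def brute_force_history(events: pd.DataFrame, key: str, ident: str,
                        as_of: pd.Timestamp) -> dict:
    """Independent oracle: plain scan of the prior event stream."""
    prior = events[(events[key] == ident)
                   & (events["timestamp"] < as_of)
                   & events["fired"]]
    inter = prior["fired"] & (prior["response_action"] != "none")
    win = prior[prior["timestamp"]
                >= as_of - pd.Timedelta(days=SHORT_WINDOW_DAYS)]
    win_inter = win["fired"] & (win["response_action"] != "none")
    return {
        "long_n": len(prior),
        "long_rate": inter.mean() if len(prior) else np.nan,
        "short_n": len(win),
        "short_rate": win_inter.mean() if len(win) else np.nan,
        "orders": int(prior["order_placed"].sum()),
        "interactions": int(inter.sum()),
    }


class TestHistoryOracle:
    def test_random_rows_match_bruteforce(self, default_log, default_table):
        """Every history feature equals an independent scan of the prior
        event stream, for 100 randomly chosen rows (exact equality)."""
        rng = np.random.default_rng(123)
        frame = default_table.frame
        ev = default_log.events
        idx = rng.choice(len(frame), size=100, replace=False)
        for i in idx:
            row = frame.iloc[i]
            as_of = pd.Timestamp(row["as_of"])
            clin = brute_force_history(ev, "clinician_id",
                                       row["clinician_id"], as_of)
            pat = brute_force_history(ev, "patient_id",
                                      row["patient_id"], as_of)
            assert row["clin_long_n"] == clin["long_n"]
            np.testing.assert_equal(row["clin_long_rate"],
                                    clin["long_rate"])
            np.testing.assert_equal(row["clin_short_rate"],
                                    clin["short_rate"])
            assert row["clin_short_n"] == clin["short_n"]
            assert row["pat_prior_alerts"] == pat["long_n"]
            assert row["pat_prior_interactions"] == pat["interactions"]
            assert row["pat_prior_orders"] == pat["orders"]

    def test_first_alert_has_missing_history(self):
        ev = make_events([{"service_date": "2017-01-10",
                           "timestamp": "2017-01-10T09:00:00"}])
        table = ap.build_features(ap.AlertLog(ev))
        row = table.frame.iloc[0]
        assert np.isnan(row["clin_short_rate"])
        assert np.isnan(row["clin_long_rate"])
        assert row["clin_recent_encounters"] == 0

    def test_four_prior_alerts_one_interacted(self):
        rows = [{"service_date": "2017-01-02",
                 "timestamp": f"2017-01-0{d}T09:00:00",
                 "encounter_id": f"E{d}", "patient_id": f"P{d}",
                 "service_date": f"2017-01-0{d}",
                 "response_action": "override" if d == 2 else "none"}
                for d in range(2, 6)]
        rows.append({"service_date": "2017-01-20",
                     "timestamp": "2017-01-20T09:00:00",
                     "encounter_id": "E9", "patient_id": "P9"})
        table = ap.build_features(ap.AlertLog(make_events(rows)))
        last = table.frame.sort_values("as_of").iloc[-1]
        assert last["clin_short_rate"] == pytest.approx(0.25)
        assert last["clin_long_rate"] == pytest.approx(0.25)
        assert last["clin_long_n"] == 4

    def test_old_history_only_long_rate(self):
        # 10 prior alerts (2 interacted) all > 30 days before the target.
        rows = [{"timestamp": f"2017-01-{d:02d}T09:00:00",
                 "service_date": f"2017-01-{d:02d}",
                 "encounter_id": f"E{d}", "patient_id": f"P{d}",
                 "response_action": "override" if d <= 2 else "none"}
                for d in range(1, 11)]
        rows.append({"timestamp": "2017-04-01T09:00:00",
                     "service_date": "2017-04-01",
                     "encounter_id": "E99", "patient_id": "P99"})
        table = ap.build_features(ap.AlertLog(make_events(rows)))
        last = table.frame.sort_values("as_of").iloc[-1]
        assert last["clin_long_rate"] == pytest.approx(0.2)
        assert np.isnan(last["clin_short_rate"])

    def test_same_day_events_excluded(self):
        # Two encounters on the same date: neither sees the other.
        rows = [{"timestamp": "2017-01-10T09:00:00",
                 "service_date": "2017-01-10", "encounter_id": "Ea",
                 "response_action": "override"},
                {"timestamp": "2017-01-10T15:00:00",
                 "service_date": "2017-01-10", "encounter_id": "Eb",
                 "patient_id": "P2"}]
        table = ap.build_features(ap.AlertLog(make_events(rows)))
        assert (table.frame["clin_long_n"] == 0).all()


class TestInvariantProperties:
    def test_permutation_safety(self, default_log):
        ev = default_log.events
        rng = np.random.default_rng(5)
        shuffled = ap.AlertLog(
            ev.sample(frac=1, random_state=rng.integers(1 << 30)))
        a = ap.build_features(default_log).frame
        b = ap.build_features(shuffled).frame
        pd.testing.assert_frame_equal(a, b)

    def test_monotone_history(self, default_log):
        """Appending future events never alters earlier feature rows."""
        ev = default_log.events
        cut = ev["service_date"] < pd.Timestamp("2017-04-01")
        early = default_log.subset(cut.to_numpy())
        full = ap.build_features(default_log).frame
        part = ap.build_features(early).frame
        merged = full.iloc[: len(part)]
        pd.testing.assert_frame_equal(
            part.reset_index(drop=True), merged.reset_index(drop=True))


class TestLabels:
    def test_label_rules(self):
        ev = make_events([
            {"response_action": "open_smartset", "order_placed": True},
            {},
            {"response_action": "override", "encounter_id": "Ec"},
        ])
        log = ap.AlertLog(ev)
        default = ap.build_labels(log)
        ordered_only = ap.build_labels(log, ap.LabelSpec("ordered_only"))
        by_id = dict(zip(log.events["alert_id"], default.to_numpy()))
        by_id_o = dict(zip(log.events["alert_id"],
                           ordered_only.to_numpy()))
        assert by_id["A0"] == 1 and by_id_o["A0"] == 1  # ordered
        assert by_id["A1"] == 0 and by_id_o["A1"] == 0  # ignored
        assert by_id["A2"] == 1 and by_id_o["A2"] == 0  # override, no order


class TestAssignProvider:
    def records(self, rows):
        return pd.DataFrame(rows)

    def test_single_clinician(self):
        rec = self.records([{"encounter_id": "E1", "clinician_id": "C1",
                             "interacted": False,
                             "timestamp": pd.Timestamp("2017-01-01")}])
        assert ap.assign_provider(rec)["E1"] == "C1"

    def test_interactor_wins(self):
        rec = self.records([
            {"encounter_id": "E1", "clinician_id": "Ca",
             "interacted": False, "timestamp": pd.Timestamp("2017-01-01")},
            {"encounter_id": "E1", "clinician_id": "Cb",
             "interacted": True,
             "timestamp": pd.Timestamp("2017-01-01 01:00")},
        ])
        assert ap.assign_provider(rec)["E1"] == "Cb"

    def test_tie_breaks_lexicographic(self):
        ts = pd.Timestamp("2017-01-01")
        rec = self.records([
            {"encounter_id": "E1", "clinician_id": "Cz",
             "interacted": False, "timestamp": ts},
            {"encounter_id": "E1", "clinician_id": "Ca",
             "interacted": False, "timestamp": ts},
        ])
        assert ap.assign_provider(rec)["E1"] == "Ca"

    def test_earlier_action_breaks_interaction_tie(self):
        rec = self.records([
            {"encounter_id": "E1", "clinician_id": "Cz", "interacted": True,
             "timestamp": pd.Timestamp("2017-01-01 08:00")},
            {"encounter_id": "E1", "clinician_id": "Ca", "interacted": True,
             "timestamp": pd.Timestamp("2017-01-01 09:00")},
        ])
        assert ap.assign_provider(rec)["E1"] == "Cz"

    def test_missing_clinician_rejected(self):
        rec = self.records([{"encounter_id": "E1", "clinician_id": None,
                             "interacted": False,
                             "timestamp": pd.Timestamp("2017-01-01")}])
        with pytest.raises(ValueError, match="E1"):
            ap.assign_provider(rec)
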