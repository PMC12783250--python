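import numpy as np
import pandas as pd
import pytest

from conftest import make_station_table
from habscale.stations import (
    StationError,
    bootstrap_balanced,
    dedupe_within_buffer,
    drop_undetecting_surveys,
    filter_min_effort,
    partition_train_test,
    prevalence,
    validate_stations,
)


def table_from(rows):
    df = pd.DataFrame(rows)
    defaults = {"survey_id": "sv0", "x": 0.0, "y": 0.0, "year": 2015, "effort_days": 60, "detected": 0}
    for k, v in defaults.items():
        if k not in df.columns:
            df[k] = v
        else:
            df[k] = df[k].fillna(v)
    df["detected"] = df["detected"].astype(int)
    df["effort_days"] = df["effort_days"].astype(int)
    return validate_stations(df)


class TestEffortFilter:
    def test_threshold_is_inclusive_at_30_days(self):
        t = table_from([
            {"station_id": "a", "effort_days": 29},
            {"station_id": "b", "effort_days": 30},
        ])
        out = filter_min_effort(t)
        assert list(out["station_id"]) == ["b"]

    def test_empty_input_passes_through(self):
        t = make_station_table(4, 1).iloc[0:0]
        assert len(filter_min_effort(t)) == 0

    def test_counts_retained(self):
        t = table_from([
            {"station_id": c, "effort_days": e}
            for c, e in zip("abcd", [10, 30, 45, 29])
        ])
        assert len(filter_min_effort(t)) == 2


class TestDedupe:
    def _two(self, dist):
        return table_from([
            {"station_id": "a", "x": 0.0},
            {"station_id": "b", "x": float(dist)},
        ])

    def test_within_buffer_drops_one(self):
        assert len(dedupe_within_buffer(self._two(400))) == 1

    def test_outside_buffer_keeps_both(self):
        assert len(dedupe_within_buffer(self._two(600))) == 2

    def test_chain_keeps_endpoints(self):
        # A-B 400 m, B-C 400 m, A-C 800 m: greedy in id order keeps A and C
        t = table_from([
            {"station_id": "a", "x": 0.0},
            {"station_id": "b", "x": 400.0},
            {"station_id": "c", "x": 800.0},
        ])
        assert list(dedupe_within_buffer(t)["station_id"]) == ["a", "c"]

    def test_presences_preferred_over_absences(self):
        t = table_from([
            {"station_id": "a", "x": 0.0, "detected": 0},
            {"station_id": "b", "x": 300.0, "detected": 1},
        ])
        out = dedupe_within_buffer(t)
        assert list(out["station_id"]) == ["b"]

    def test_idempotent(self):
        t = make_station_table(60, 6, spacing=400.0, seed=3)
        once = dedupe_within_buffer(t)
        twice = dedupe_within_buffer(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDropUndetectingSurveys:
    def test_empty_survey_fully_removed(self):
        rows = [{"station_id": f"s{i}", "survey_id": "dead"} for i in range(50)]
        rows += [{"station_id": "p", "survey_id": "live", "detected": 1}]
        out = drop_undetecting_surveys(table_from(rows))
        assert set(out["survey_id"]) == {"live"}

    def test_one_detection_saves_whole_survey(self):
        rows = [{"station_id": f"s{i}", "survey_id": "sv"} for i in range(99)]
        rows += [{"station_id": "p", "survey_id": "sv", "detected": 1}]
        assert len(drop_undetecting_surveys(table_from(rows))) == 100

    def test_mixed_surveys(self):
        rows = (
            [{"station_id": f"a{i}", "survey_id": "s0"} for i in range(3)]
            + [{"station_id": f"b{i}", "survey_id": "s1", "detected": int(i < 2)} for i in range(4)]
            + [{"station_id": f"c{i}", "survey_id": "s2"} for i in range(2)]
        )
        out = drop_undetecting_surveys(table_from(rows))
        assert set(out["survey_id"]) == {"s1"}

    def test_all_empty_errors(self):
        with pytest.raises(StationError):
            drop_undetecting_surveys(table_from([{"station_id": "a"}]))

    def test_idempotent(self):
        t = make_station_table(100, 10, n_surveys=4, seed=2)
        once = drop_undetecting_surveys(t)
        pd.testing.assert_frame_equal(once, drop_undetecting_surveys(once))


class TestBootstrapBalanced:
    def test_balanced_row_count_doubles_presences(self):
        t = make_station_table(1455, 138, n_surveys=3, seed=1)
        reps = bootstrap_balanced(t, n_replicates=10, seed=7)
        assert len(reps) == 10
        for rep in reps:
            assert len(rep.rows) == 276
            assert rep.n_presences == rep.n_absences == 138

    def test_per_survey_absence_counts_match_presences(self):
        rows = [{"station_id": f"p{i}", "survey_id": "sv0", "detected": 1} for i in range(3)]
        rows += [{"station_id": f"a{i}", "survey_id": "sv0"} for i in range(40)]
        rows += [{"station_id": "q0", "survey_id": "sv1", "detected": 1}]
        rows += [{"station_id": f"b{i}", "survey_id": "sv1"} for i in range(5)]
        reps = bootstrap_balanced(table_from(rows), n_replicates=4, seed=3)
        for rep in reps:
            per_survey = rep.rows[rep.rows["detected"] == 0].groupby("survey_id").size()
            assert per_survey["sv0"] == 3
            assert per_survey["sv1"] == 1

    def test_every_presence_kept_exactly_once(self):
        t = make_station_table(300, 30, n_surveys=2, seed=5)
        pres_ids = set(t.loc[t["detected"] == 1, "station_id"])
        for rep in bootstrap_balanced(t, 3, seed=1):
            got = list(rep.rows.loc[rep.rows["detected"] == 1, "station_id"])
            assert sorted(got) == sorted(pres_ids)

    def test_replicates_differ_but_are_seed_deterministic(self):
        t = make_station_table(200, 20, n_surveys=2, seed=4)
        a = bootstrap_balanced(t, 2, seed=9)
        b = bootstrap_balanced(t, 2, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.rows, y.rows)
        assert not a[0].rows.equals(a[1].rows)

    def test_survey_without_absences_errors(self):
        rows = [{"station_id": "p", "survey_id": "sv0", "detected": 1}]
        rows += [{"station_id": "q", "survey_id": "sv1", "detected": 1}]
        rows += [{"station_id": "a", "survey_id": "sv1"}]
        with pytest.raises(StationError, match="sv0"):
            bootstrap_balanced(table_from(rows), 2, seed=1)

    def test_with_replacement_fallback_when_absences_scarce(self, caplog):
        rows = [{"station_id": f"p{i}", "survey_id": "sv0", "detected": 1} for i in range(5)]
        rows += [{"station_id": f"a{i}", "survey_id": "sv0"} for i in range(2)]
        with caplog.at_level("WARNING"):
            reps = bootstrap_balanced(table_from(rows), 1, seed=1)
        assert reps[0].n_absences == 5
        assert "replacement" in caplog.text


class TestPartition:
    def test_276_rows_split_220_train_56_test(self):
        t = make_station_table(1455, 138, n_surveys=3, seed=1)
        rep = bootstrap_balanced(t, 1, seed=2)[0]
        part = partition_train_test(rep, seed=3)
        assert len(part.train_rows()) == 220
        assert len(part.test_rows()) == 56
        for cls in (0, 1):
            assert (part.test_rows()["detected"] == cls).sum() == 28

    def test_ten_rows_split_eight_two(self):
        rows = [{"station_id": f"p{i}", "survey_id": "sv0", "detected": 1} for i in range(5)]
        rows += [{"station_id": f"a{i}", "survey_id": "sv0"} for i in range(9)]
        rep = bootstrap_balanced(table_from(rows), 1, seed=1)[0]
        part = partition_train_test(rep, seed=1)
        assert len(part.train_rows()) == 8
        assert len(part.test_rows()) == 2

    def test_both_classes_in_test(self):
        t = make_station_table(400, 40, n_surveys=2, seed=6)
        rep = bootstrap_balanced(t, 1, seed=4)[0]
        part = partition_train_test(rep, seed=5)
        assert set(part.test_rows()["detected"]) == {0, 1}

    def test_too_few_rows_errors(self):
        rows = [{"station_id": f"p{i}", "survey_id": "sv0", "detected": 1} for i in range(3)]
        rows += [{"station_id": f"a{i}", "survey_id": "sv0"} for i in range(8)]
        rep = bootstrap_balanced(table_from(rows), 1, seed=1)[0]
        with pytest.raises(StationError):
            partition_train_test(rep, seed=1)


class TestPrevalence:
    def test_low_prevalence_dataset(self):
        t = make_station_table(1455, 138, seed=1)
        assert prevalence(t) == pytest.approx(138 / 1455)
        assert prevalence(t) < 0.1

    def test_filters_are_order_stable_compositions(self):
        t = make_station_table(500, 40, n_surveys=4, spacing=600.0, seed=8)
        t.loc[:49, "effort_days"] = 10
        chain = drop_undetecting_surveys(
            dedupe_within_buffer(filter_min_effort(t))
        )
        again = drop_undetecting_surveys(
            dedupe_within_buffer(filter_min_effort(chain))
        )
        pd.testing.assert_frame_equal(chain, again)
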