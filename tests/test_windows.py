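"""Index visits, inclusion, observation windows, and per-year aggregation."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from conftest import make_patient, make_visit, patients_frame, visits_frame
from husegment.windows import (
    aggregate_window,
    age_in_years,
    apply_inclusion,
    build_windows,
    find_index_visits,
)


class TestIndexVisits:
    def test_first_visit_inside_study_window(self, study_window):
        v = visits_frame([
            make_visit(visit_id="V1", admission_date="2005-12-30"),
            make_visit(visit_id="V2", admission_date="2006-03-01"),
        ])
        idx = find_index_visits(v, *study_window)
        assert idx.loc["P1"] == pd.Timestamp("2006-03-01")

    def test_last_enrolment_day_qualifies(self, study_window):
        v = visits_frame([make_visit(admission_date="2012-12-31")])
        idx = find_index_visits(v, *study_window)
        assert idx.loc["P1"] == pd.Timestamp("2012-12-31")
        v2 = visits_frame([make_visit(admission_date="2013-01-01")])
        assert "P1" not in find_index_visits(v2, *study_window).index

    def test_same_day_tie_is_idempotent(self, study_window):
        v = visits_frame([
            make_visit(visit_id="V2", admission_date="2006-05-05"),
            make_visit(visit_id="V1", admission_date="2006-05-05"),
        ])
        assert find_index_visits(v, *study_window).loc["P1"] == pd.Timestamp("2006-05-05")


class TestInclusion:
    def test_exactly_21_at_index_is_included(self):
        pats = patients_frame([make_patient(birth_date="1985-03-01")])
        idx = pd.Series([pd.Timestamp("2006-03-01")], index=pd.Index(["P1"], name="patient_id"))
        assert list(apply_inclusion(pats, idx)) == ["P1"]

    def test_one_day_short_of_21_is_excluded(self):
        pats = patients_frame([make_patient(birth_date="1985-03-02")])
        idx = pd.Series([pd.Timestamp("2006-03-01")], index=pd.Index(["P1"], name="patient_id"))
        assert list(apply_inclusion(pats, idx)) == []

    def test_underage_filtered_by_bruteforce_comparison(self):
        rows, idx_rows = [], {}
        for i in range(10):
            pid = f"P{i}"
            byear = 1990 if i < 3 else 1960  # 3 patients aged 16, 7 aged 46
            rows.append(make_patient(patient_id=pid, birth_date=f"{byear}-06-01"))
            idx_rows[pid] = pd.Timestamp("2006-06-01")
        idx = pd.Series(idx_rows).rename_axis("patient_id")
        included = apply_inclusion(patients_frame(rows), idx)
        assert len(included) == 7 and not {"P0", "P1", "P2"} & set(included)


def test_windows_are_contiguous_and_disjoint():
    idx = pd.Series([pd.Timestamp("2006-03-01")], index=pd.Index(["P1"], name="patient_id"))
    w = build_windows(idx).iloc[0]
    assert w["year1_end"] == w["year1_start"] + pd.Timedelta(days=365)
    assert w["year2_end"] == w["year1_end"] + pd.Timedelta(days=365)


class TestAggregation:
    def idx(self, pids, day="2006-01-01"):
        return pd.Series(
            [pd.Timestamp(day)] * len(pids), index=pd.Index(pids, name="patient_id")
        )

    def test_short_stays_count_as_admissions_but_not_los(self):
        rows = [
            make_visit(visit_id="V1", visit_type="inpatient",
                       admission_date="2006-01-01", discharge_date="2006-01-04"),
            make_visit(visit_id="V2", visit_type="inpatient",
                       admission_date="2006-02-01", discharge_date="2006-02-05"),
            make_visit(visit_id="V3", visit_type="inpatient", short_stay=True,
                       admission_date="2006-03-01", discharge_date="2006-03-01"),
        ]
        agg = aggregate_window(
            visits_frame(rows), self.idx(["P1"]), patients_frame([make_patient()]), "year1"
        ).iloc[0]
        assert agg["admissions"] == 3
        assert agg["los_total"] == 7

    def test_boundary_spanning_stay_attributed_to_admission_window(self):
        rows = [
            make_visit(visit_type="inpatient", admission_date="2006-12-31",
                       discharge_date="2007-01-06"),  # day 364, LOS 6
        ]
        y1 = aggregate_window(
            visits_frame(rows), self.idx(["P1"]), patients_frame([make_patient()]), "year1"
        ).iloc[0]
        y2 = aggregate_window(
            visits_frame(rows), self.idx(["P1"]), patients_frame([make_patient()]), "year2"
        ).iloc[0]
        assert y1["los_total"] == 6 and y1["admissions"] == 1
        assert y2["admissions"] == 0 and y2["los_total"] == 0

    def test_same_day_nonshort_stay_counts_one_day(self):
        rows = [make_visit(visit_type="inpatient", admission_date="2006-05-01",
                           discharge_date="2006-05-01")]
        agg = aggregate_window(
            visits_frame(rows), self.idx(["P1"]), patients_frame([make_patient()]), "year1"
        ).iloc[0]
        assert agg["los_total"] == 1

    def test_mixed_settings_match_handcomputed_table(self):
        """5-patient fixture checked against brute-force per-visit summation."""
        rows = []
        expected = {}
        rng = np.random.default_rng(7)
        pids = [f"P{i}" for i in range(5)]
        for pid in pids:
            exp = dict(cost=0.0, adm=0, los=0, soc=0, ed=0)
            for j in range(int(rng.integers(1, 6))):
                vt = ["inpatient", "soc", "ed", "therapy"][int(rng.integers(0, 4))]
                day = int(rng.integers(0, 365))
                cost = float(np.round(rng.uniform(10, 5000), 2))
                short = bool(vt == "inpatient" and rng.random() < 0.3)
                losd = int(rng.integers(0, 10)) if vt == "inpatient" and not short else 0
                adm = pd.Timestamp("2006-01-01") + pd.Timedelta(days=day)
                rows.append(
                    make_visit(
                        patient_id=pid, visit_id=f"{pid}V{j}", visit_type=vt,
                        admission_date=adm,
                        discharge_date=adm + pd.Timedelta(days=losd)
                        if vt == "inpatient" else pd.NaT,
                        cost=cost, short_stay=short,
                    )
                )
                exp["cost"] += cost
                if vt == "inpatient":
                    exp["adm"] += 1
                    if not short:
                        exp["los"] += max(losd, 1)
                elif vt == "soc":
                    exp["soc"] += 1
                elif vt == "ed":
                    exp["ed"] += 1
            expected[pid] = exp
        agg = aggregate_window(
            visits_frame(rows), self.idx(pids),
            patients_frame([make_patient(patient_id=p) for p in pids]), "year1",
        ).set_index("patient_id")
        for pid, exp in expected.items():
            row = agg.loc[pid]
            assert row["cost_total"] == pytest.approx(exp["cost"])
            assert row["admissions"] == exp["adm"]
            assert row["los_total"] == exp["los"]
            assert row["soc_visits"] == exp["soc"]
            assert row["ed_attendances"] == exp["ed"]

    def test_cost_conservation_and_permutation_invariance(self):
        rng = np.random.default_rng(11)
        pids = [f"P{i}" for i in range(8)]
        rows = []
        for pid in pids:
            for j in range(4):
                day = int(rng.integers(0, 730))
                rows.append(
                    make_visit(patient_id=pid, visit_id=f"{pid}V{j}",
                               admission_date=pd.Timestamp("2006-01-01")
                               + pd.Timedelta(days=day),
                               cost=float(rng.integers(1, 1000)))
                )
        v = visits_frame(rows)
        pats = patients_frame([make_patient(patient_id=p) for p in pids])
        y1 = aggregate_window(v, self.idx(pids), pats, "year1")
        y2 = aggregate_window(v, self.idx(pids), pats, "year2")
        assert y1["cost_total"].sum() + y2["cost_total"].sum() == pytest.approx(
            v["cost"].sum()
        )
        shuffled = v.sample(frac=1, random_state=3).reset_index(drop=True)
        y1b = aggregate_window(shuffled, self.idx(pids), pats, "year1")
        pd.testing.assert_frame_equal(
            y1.sort_values("patient_id").reset_index(drop=True),
            y1b.sort_values("patient_id").reset_index(drop=True),
        )

    def test_year2_not_produced_for_year1_decedents(self):
        pats = patients_frame([
            make_patient(patient_id="P1", death_date="2006-06-01"),
            make_patient(patient_id="P2"),
        ])
        v = visits_frame([make_visit(patient_id=p) for p in ("P1", "P2")])
        y1 = aggregate_window(v, self.idx(["P1", "P2"]), pats, "year1")
        y2 = aggregate_window(v, self.idx(["P1", "P2"]), pats, "year2")
        assert set(y1["patient_id"]) == {"P1", "P2"}
        assert y1.set_index("patient_id").loc["P1", "died_in_window"]
        assert set(y2["patient_id"]) == {"P2"}

    def test_visits_without_index_are_ignored_with_count(self, caplog):
        v = visits_frame([make_visit(patient_id="GHOST")])
        with caplog.at_level("WARNING"):
            agg = aggregate_window(
                v, self.idx(["P1"]), patients_frame([make_patient()]), "year1"
            )
        assert "ignored" in caplog.text
        assert agg.iloc[0]["cost_total"] == 0


def test_age_in_years_handles_day_boundaries():
    b = pd.Series([pd.Timestamp("1985-03-01"), pd.Timestamp("1985-03-02")])
    a = pd.Series([pd.Timestamp("2006-03-01")] * 2)
    assert list(age_in_years(b, a)) == [21, 20]
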