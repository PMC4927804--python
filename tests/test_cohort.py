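"""Eligibility, anthropometrics, BMI classification and the attrition flow."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ehrcohort as ec
from ehrcohort.schemas import EnrollmentSpan, TableSet, VitalRecord
from ehrcohort.synth import SimulationConfig, default_sites, generate_population

W = ec.StudyWindow()
D = dt.date


def span(s, e, pid="p1"):
    return EnrollmentSpan(pid, D.fromisoformat(s), D.fromisoformat(e))


def vit(date, kind, value, seq=0, pid="p1"):
    return VitalRecord(pid, D.fromisoformat(date), kind, value, seq)


class TestContinuousEnrollment:
    def test_full_window_span_qualifies(self):
        assert ec.continuous_enrollment_ok([span("2012-01-01", "2013-12-31")], W, 0)

    def test_one_day_gap_bridged_only_with_tolerance(self):
        # 274 + 181 days, neither span 12 months alone; one uncovered day between
        spans = [span("2012-01-01", "2012-09-30"), span("2012-10-02", "2013-03-31")]
        assert not ec.continuous_enrollment_ok(spans, W, 0)
        assert ec.continuous_enrollment_ok(spans, W, 1)

    def test_span_with_182_inwindow_days_fails(self):
        # 2011-01-01..2012-06-30 intersects the window for 182 days only
        assert not ec.continuous_enrollment_ok([span("2011-01-01", "2012-06-30")], W, 0)

    def test_empty_span_list_is_false(self):
        assert not ec.continuous_enrollment_ok([], W, 0)

    def test_adjacent_spans_merge_to_qualify(self):
        spans = [span("2012-01-01", "2012-12-31"), span("2013-01-01", "2013-12-31")]
        assert ec.continuous_enrollment_ok(spans, W, 0)


class TestSafetyNetEligibility:
    def test_single_inwindow_encounter_qualifies(self):
        assert ec.eligible_safety_net([D(2012, 3, 15)], W)

    def test_out_of_window_encounters_do_not(self):
        assert not ec.eligible_safety_net([D(2011, 3, 15), D(2011, 12, 31)], W)

    def test_no_encounters_do_not(self):
        assert not ec.eligible_safety_net([], W)


class TestAgeAt:
    @pytest.mark.parametrize(
        ("birth", "ref", "expected"),
        [
            (D(1995, 12, 31), D(2013, 12, 31), 18),  # birthday on reference date
            (D(1996, 1, 1), D(2013, 12, 31), 17),  # day before the birthday
            (D(1950, 6, 15), D(2013, 12, 31), 63),
            (D(1950, 6, 15), D(2013, 6, 14), 62),
        ],
    )
    def test_completed_years(self, birth, ref, expected):
        assert ec.age_at(birth, ref) == expected

    def test_birth_after_reference_is_error(self):
        with pytest.raises(ValueError):
            ec.age_at(D(2014, 1, 1), D(2013, 12, 31))


class TestLatestVital:
    def test_most_recent_inwindow_weight_wins(self):
        records = [vit("2012-03-01", "weight", 80.0, 1), vit("2013-05-01", "weight", 85.0, 2)]
        assert ec.latest_vital(records, "weight", W).value == 85.0

    def test_height_search_is_not_window_restricted(self):
        records = [vit("2008-01-01", "height", 1.7, 1)]
        assert ec.latest_vital(records, "height", None).value == 1.7
        assert ec.latest_vital(records, "height", W) is None

    def test_same_day_tie_broken_by_ingestion_ordinal(self):
        records = [vit("2013-05-01", "weight", 80.0, 5), vit("2013-05-01", "weight", 82.0, 9)]
        assert ec.latest_vital(records, "weight", W).record_seq == 9


class TestComputeBmi:
    @pytest.mark.parametrize(
        ("w", "h", "expected"), [(70, 1.0, 70.0), (81, 1.8, 25.0), (100, 1.75, 100 / 1.75**2)]
    )
    def test_weight_over_height_squared(self, w, h, expected):
        assert ec.compute_bmi(w, h) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            ec.compute_bmi(0, 1.7)


class TestPlausibility:
    B = ec.PlausibilityBounds()

    @pytest.mark.parametrize(
        ("kind", "value", "expected"),
        [
            ("height", 1.2192, True),  # exactly 4 ft: only *less than* 4 ft excluded
            ("height", 1.2191, False),
            ("height", 2.4384, False),  # exactly 8 ft: equal-or-greater excluded
            ("weight", 453.59237, False),  # exactly 1000 lb
            ("weight", 22.6796185, True),  # exactly 50 lb
            ("bmi", 90.0, False),
            ("bmi", 89.99, True),
            ("bmi", 5.0, True),
        ],
    )
    def test_half_open_bounds(self, kind, value, expected):
        assert ec.plausible(kind, value, self.B) is expected

    def test_unknown_kind_is_error(self):
        with pytest.raises(ValueError):
            ec.plausible("pulse", 60, self.B)


class TestClassifyBmi:
    @pytest.mark.parametrize(
        ("bmi", "category"),
        [
            (23.0, "healthy"),
            (24.9, "healthy"),
            (25.0, "overweight"),
            (29.95, "overweight"),
            (30.0, "obese1"),
            (35.0, "obese2"),
            (40.0, "obese3"),
            (49.99, "obese3"),
            (50.0, "obese4"),  # half-open partition leaves no 49.9-50 gap
            (89.99, "obese4"),
            (22.9, "below_threshold"),
            (5.0, "below_threshold"),
        ],
    )
    def test_half_open_partition(self, bmi, category):
        assert ec.classify_bmi(bmi) == category

    def test_implausible_bmi_must_be_filtered_first(self):
        with pytest.raises(ValueError):
            ec.classify_bmi(90.0)
        with pytest.raises(ValueError):
            ec.classify_bmi(4.9)

    @given(st.floats(min_value=5.0, max_value=89.99), st.floats(min_value=5.0, max_value=89.99))
    def test_monotone_step_function(self, a, b):
        order = ["below_threshold"] + list(ec.config.BMI_CATEGORIES)
        lo, hi = sorted((a, b))
        assert order.index(ec.classify_bmi(lo)) <= order.index(ec.classify_bmi(hi))


class TestResolvePersonBmi:
    def test_recorded_bmi_takes_precedence_over_computed(self):
        vitals = [
            vit("2013-06-01", "bmi", 31.2, 1),
            vit("2013-06-01", "weight", 90.0, 2),
            vit("2010-01-01", "height", 1.71, 3),
        ]
        assert ec.resolve_person_bmi(vitals, W) == (31.2, "recorded")

    def test_computed_from_inwindow_weight_and_any_height(self):
        vitals = [vit("2013-06-01", "weight", 81.0, 1), vit("2009-01-01", "height", 1.8, 2)]
        value, source = ec.resolve_person_bmi(vitals, W)
        assert (value, source) == (25.0, "computed")

    def test_weight_without_any_height_is_absent(self):
        assert ec.resolve_person_bmi([vit("2013-06-01", "weight", 81.0)], W) is None


def _single_person_tables(birth, vitals_rows, spans=None):
    import pandas as pd

    spans = spans or [("p1", "2011-01-01", "2014-01-01")]
    empty = lambda cols: pd.DataFrame(columns=cols)
    return TableSet(
        persons=pd.DataFrame(
            [("p1", pd.Timestamp(birth), "male", "white", "s1", "private")],
            columns=["person_id", "birth_date", "sex", "race_ethnicity", "site_id", "insurance"],
        ),
        enrollment=pd.DataFrame(
            [(p, pd.Timestamp(s), pd.Timestamp(e)) for p, s, e in spans],
            columns=["person_id", "start_date", "end_date"],
        ),
        vitals=pd.DataFrame(
            [(p, pd.Timestamp(d), k, v, q) for p, d, k, v, q in vitals_rows],
            columns=["person_id", "measure_date", "kind", "value", "record_seq"],
        ),
        labs=empty(["person_id", "result_date", "test", "value"]),
        diagnoses=empty(["person_id", "dx_date", "code", "setting"]),
        procedures=empty(["person_id", "px_date", "code", "code_system"]),
        dispenses=empty(["person_id", "dispense_date", "drug_class"]),
        encounters=empty(["person_id", "encounter_date", "encounter_type"]),
        geocodes=empty(["person_id", "block_group_id"]),
        block_groups=empty(["block_group_id", "domain", "level", "probability"]),
    )


class TestBuildCohort:
    def test_underage_person_with_implausible_weight_counts_under18_only(self):
        tables = _single_person_tables(
            "1997-06-01", [("p1", "2012-05-01", "weight", 500.0, 1), ("p1", "2010-01-01", "height", 1.7, 2)]
        )
        _, flow = ec.build_cohort(tables, ec.Config())
        assert flow.excluded_under18 == 1
        assert flow.excluded_implausible == 0
        assert flow.final_cohort == 0

    def test_recorded_bmi_only_person_falls_at_implausibility_when_out_of_range(self):
        tables = _single_person_tables("1980-06-01", [("p1", "2012-05-01", "bmi", 92.0, 1)])
        _, flow = ec.build_cohort(tables, ec.Config())
        assert flow.excluded_no_height_weight == 0
        assert flow.excluded_implausible == 1

    def test_empty_person_table_is_error(self):
        import pandas as pd

        tables = _single_person_tables("1980-06-01", [])
        tables.persons = tables.persons.iloc[0:0]
        with pytest.raises(ValueError, match="empty person table"):
            ec.build_cohort(tables, ec.Config())

    def test_all_eligible_population_has_zero_exclusions(self):
        from ehrcohort.synth import BmiBandMixture, MeasurementModel

        cfg = SimulationConfig(
            seed=3,
            sites=(ec.SiteSpec("s1", 10, age_min=20.0, age_mean=45.0, age_sd=10.0),),
            bmi_model=BmiBandMixture(
                band_probs={"below_threshold": 0.0, "healthy": 0.5, "overweight": 0.5,
                            "obese1": 0.0, "obese2": 0.0, "obese3": 0.0, "obese4": 0.0}
            ),
            measurement=MeasurementModel(1.0, 1.0, 1.0),
            implausible_rate=0.0,
            pregnancy_rate=0.0,
            enrollment_gap_rate=0.0,
        )
        tables, _ = generate_population(cfg)
        members, flow = ec.build_cohort(tables, ec.Config())
        assert flow.final_cohort == 10
        assert sum(flow.exclusions().values()) == 0
        assert set(members["bmi_category"]) <= {"healthy", "overweight"}

    def test_flow_matches_generator_manifest_exactly(self, small_population, small_cohort):
        _, manifest = small_population
        members, flow = small_cohort
        assert flow.entering_members == manifest["entering_members"]
        assert flow.exclusions() == {k: manifest[k] for k in flow.exclusions()}
        assert flow.final_cohort == manifest["final_cohort"]
        assert members["bmi_category"].value_counts().to_dict() == {
            k: v for k, v in manifest["category_counts"].items() if v
        }
        assert int(members["nested_2009"].sum()) == manifest["nested_2009"]

    def test_conservation_holds(self, small_cohort):
        _, flow = small_cohort
        assert flow.conserved
        assert flow.entering_members - sum(flow.exclusions().values()) == flow.final_cohort

    def test_final_membership_invariant_under_row_shuffling(self, small_population, pipeline_config):
        tables, _ = small_population
        rng = np.random.default_rng(7)
        shuffled = TableSet(
            **{
                name: df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
                for name, df in tables.tables().items()
            }
        )
        base, flow_a = ec.build_cohort(tables, pipeline_config)
        perm, flow_b = ec.build_cohort(shuffled, pipeline_config)
        assert set(base["person_id"]) == set(perm["person_id"])
        assert flow_a == flow_b
        merged = base.merge(perm, on="person_id", suffixes=("_a", "_b"))
        assert (merged["bmi_value_a"] == merged["bmi_value_b"]).all()
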