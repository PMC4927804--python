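"""Glycemic, hypertension, bariatric and Charlson rule behaviour."""

import datetime as dt

import pytest

import ehrcohort as ec
from ehrcohort.config import CharlsonCondition, CharlsonMap
from ehrcohort.schemas import DispenseRecord, EncounterDiagnosis, LabRecord, ProcedureRecord

import helpers_oracle as oracle

W = ec.StudyWindow()
THR = ec.GlycemicThresholds()
D = dt.date


def dx(date, code, setting="outpatient", pid="p1"):
    return EncounterDiagnosis(pid, D.fromisoformat(date), code, setting)


def lab(date, test, value, pid="p1"):
    return LabRecord(pid, D.fromisoformat(date), test, value)


def rx(date, pid="p1"):
    return DispenseRecord(pid, D.fromisoformat(date), "anti_hyperglycemic")


def px(date, code, system="cpt4", pid="p1"):
    return ProcedureRecord(pid, D.fromisoformat(date), code, system)


class TestDiabetes:
    def test_single_inpatient_diagnosis_qualifies(self):
        assert ec.diabetes_status([dx("2012-04-01", "250.00", "inpatient")], [], [], W, THR)

    def test_outpatient_dx_plus_dispense_on_distinct_dates_qualifies(self):
        assert ec.diabetes_status(
            [dx("2012-02-01", "250.00")], [rx("2012-02-15")], [], W, THR
        )

    def test_single_outpatient_dx_does_not_qualify(self):
        assert not ec.diabetes_status([dx("2012-02-01", "250.00")], [], [], W, THR)

    def test_two_events_same_day_need_the_toggle(self):
        events = ([dx("2012-02-01", "250.00")], [rx("2012-02-01")], [])
        assert not ec.diabetes_status(*events, W, THR, distinct_dates=True)
        assert ec.diabetes_status(*events, W, THR, distinct_dates=False)

    def test_two_qualifying_labs_on_distinct_dates_qualify(self):
        labs = [lab("2012-03-01", "hba1c", 6.5), lab("2013-03-01", "fasting_glucose", 126.0)]
        assert ec.diabetes_status([], [], labs, W, THR)

    def test_out_of_window_events_ignored(self):
        assert not ec.diabetes_status(
            [dx("2011-02-01", "250.00")], [rx("2011-02-15")], [], W, THR
        )


class TestPrediabetes:
    def test_hba1c_band_lower_endpoint_inclusive(self):
        assert ec.prediabetes_status([], [lab("2012-05-01", "hba1c", 5.7)], W, THR, has_diabetes=False)

    def test_superseded_by_diabetes(self):
        assert not ec.prediabetes_status(
            [], [lab("2012-05-01", "fasting_glucose", 118.0)], W, THR, has_diabetes=True
        )

    def test_ogtt_below_band_does_not_qualify(self):
        assert not ec.prediabetes_status([], [lab("2012-05-01", "ogtt_2h", 139.0)], W, THR, has_diabetes=False)

    @pytest.mark.parametrize("code", ["790.2", "790.29", "790.21", "790.22"])
    def test_listed_outpatient_codes_qualify(self, code):
        assert ec.prediabetes_status([dx("2012-05-01", code)], [], W, THR, has_diabetes=False)

    def test_inpatient_790_code_does_not_qualify(self):
        assert not ec.prediabetes_status(
            [dx("2012-05-01", "790.21", "inpatient")], [], W, THR, has_diabetes=False
        )


class TestHypertension:
    def test_two_outpatient_codes_on_distinct_dates(self):
        assert ec.hypertension_status([dx("2012-03-01", "401.9"), dx("2013-01-10", "401.9")], W)

    def test_single_inpatient_code(self):
        assert ec.hypertension_status([dx("2012-03-01", "405.01", "inpatient")], W)

    def test_two_outpatient_same_day_need_the_toggle(self):
        same_day = [dx("2012-03-01", "401.9"), dx("2012-03-01", "402.90")]
        assert not ec.hypertension_status(same_day, W, distinct_dates=True)
        assert ec.hypertension_status(same_day, W, distinct_dates=False)

    def test_codes_outside_401_405_ignored(self):
        assert not ec.hypertension_status([dx("2012-03-01", "410.1"), dx("2013-01-10", "410.1")], W)


class TestBariatric:
    CODES = ec.Config().bariatric_codes

    def test_listed_cpt_code_in_lookback(self):
        assert ec.bariatric_status([px("2010-05-01", "43644")], self.CODES)

    def test_code_before_lookback_window(self):
        assert not ec.bariatric_status([px("2008-12-31", "44.95", "icd9_proc")], self.CODES)

    def test_unlisted_code(self):
        assert not ec.bariatric_status([px("2010-05-01", "43999")], self.CODES)

    def test_exact_match_not_prefix(self):
        # 43.8 is not in the list even though 43.82 and 43.89 are
        assert not ec.bariatric_status([px("2010-05-01", "43.8", "icd9_proc")], self.CODES)


class TestCharlson:
    CMAP = ec.default_charlson_map()

    def test_no_diagnoses_scores_zero(self):
        assert ec.charlson_score([], self.CMAP) == 0

    def test_single_weight_one_condition(self):
        assert ec.charlson_score([dx("2012-06-01", "428.0")], self.CMAP) == 1

    def test_two_conditions_sum_weights(self):
        # CHF (1) + renal (2), no hierarchy between them -> 3
        rows = [dx("2012-06-01", "428.0"), dx("2013-06-01", "585.6")]
        assert ec.charlson_score(rows, self.CMAP) == 3

    def test_hierarchy_supersession_counts_once(self):
        # metastatic (6) silences solid tumour (2)
        rows = [dx("2012-06-01", "174.9"), dx("2013-06-01", "197.0")]
        assert ec.charlson_score(rows, self.CMAP) == 6

    def test_repeat_codes_count_once(self):
        rows = [dx("2012-06-01", "428.0"), dx("2013-06-01", "428.9")]
        assert ec.charlson_score(rows, self.CMAP) == 1

    def test_out_of_window_diagnoses_ignored(self):
        assert ec.charlson_score([dx("2011-06-01", "428.0")], self.CMAP) == 0

    def test_duplicate_condition_names_rejected(self):
        c = CharlsonCondition
        with pytest.raises(ValueError, match="unique"):
            CharlsonMap((c("a", ("410",), 1), c("a", ("428",), 1)))

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            CharlsonMap((CharlsonCondition("a", ("410",), 0),))

    def test_overlapping_nonhierarchy_prefixes_warn(self):
        c = CharlsonCondition
        cmap = CharlsonMap((c("a", ("428",), 1), c("b", ("428.0",), 1)))
        with pytest.warns(UserWarning, match="overlapping"):
            ec.phenotypes.validate_charlson_overlap(cmap)


class TestPhenotypeAll:
    def test_member_with_no_clinical_records_is_all_negative(self, pipeline_config):
        import pandas as pd

        from ehrcohort.synth import generate_population, SimulationConfig

        tables, _ = generate_population(SimulationConfig(seed=5, sites=(ec.SiteSpec("s1", 5),)))
        cohort = pd.DataFrame({"person_id": ["ghost-000001"]})
        out = ec.phenotype_all(cohort, tables, ec.Config())
        row = out.iloc[0]
        assert row["glycemic_status"] == "none"
        assert not row["hypertension"] and not row["bariatric_surgery"]
        assert row["charlson_score"] == 0

    def test_prediabetes_and_diabetes_disjoint(self, small_phenotypes):
        assert set(small_phenotypes["glycemic_status"]) <= {"none", "prediabetes", "diabetes"}

    def test_positive_counts_match_generator_manifest(self, small_population, small_phenotypes):
        _, manifest = small_population
        phen = small_phenotypes
        counts = phen["glycemic_status"].value_counts()
        assert counts.get("diabetes", 0) == manifest["phenotype_counts"]["diabetes"]
        assert counts.get("prediabetes", 0) == manifest["phenotype_counts"]["prediabetes"]
        assert int(phen["hypertension"].sum()) == manifest["phenotype_counts"]["hypertension"]
        assert int(phen["bariatric_surgery"].sum()) == manifest["phenotype_counts"]["bariatric"]

    def test_permutation_invariance(self, small_population, small_cohort, pipeline_config):
        from ehrcohort.schemas import TableSet

        tables, _ = small_population
        members, _ = small_cohort
        shuffled = TableSet(
            **{
                name: df.sample(frac=1.0, random_state=11).reset_index(drop=True)
                for name, df in tables.tables().items()
            }
        )
        a = ec.phenotype_all(members, tables, pipeline_config).set_index("person_id")
        b = ec.phenotype_all(members, shuffled, pipeline_config).set_index("person_id")
        assert a.sort_index().equals(b.sort_index())

    def test_adding_events_never_retracts_a_positive(self):
        # diabetes stays positive; prediabetes may flip only via diabetes
        diag = [dx("2012-02-01", "250.00")]
        labs = [lab("2012-05-01", "hba1c", 5.9)]
        assert ec.prediabetes_status(diag, labs, W, THR, has_diabetes=False)
        more_diag = diag + [dx("2012-08-01", "250.02")]
        dm = ec.diabetes_status(more_diag, [], labs, W, THR)
        assert dm  # two outpatient dx, distinct dates
        assert not ec.prediabetes_status(more_diag, labs, W, THR, has_diabetes=dm)


class TestOracleAgreement:
    def test_engine_agrees_with_bruteforce_on_sample(self, small_population, small_cohort, small_phenotypes, pipeline_config):
        tables, _ = small_population
        members, _ = small_cohort
        engine = small_phenotypes.set_index("person_id")
        sample = members["person_id"].iloc[:120]
        for pid in sample:
            expect = oracle.oracle_all(tables, pid, pipeline_config)
            got = engine.loc[pid]
            for key, val in expect.items():
                assert got[key] == val, f"{pid}: {key} engine={got[key]} oracle={val}"
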