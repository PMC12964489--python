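"""Index dates, CRPC/metastasis detection, criteria, subgroups."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from mcrpcseq import RunConfig, phenotype_cohort, phenotype_patient
from mcrpcseq.phenotyping import (
    detect_crpc,
    detect_metastasis,
    first_pc_diagnosis,
    month_end,
    other_malignancy_present,
    summarize_comorbidities,
)

from conftest import dx_frame, lab_frame, minimal_patient, rx_frame

CFG = RunConfig()


def run_minimal(**kwargs):
    birth_year = kwargs.pop("birth_year", 1950)
    dx, rx, labs = minimal_patient(**kwargs)
    return phenotype_patient(
        "X", dx, rx, labs, birth_year=birth_year, sex="male", config=CFG
    )


# --- index date 1 -------------------------------------------------------

def test_first_pc_no_codes_absent():
    assert first_pc_diagnosis(dx_frame([("X", "I10", "2016-01-01")]), CFG) is None


def test_first_pc_earliest_wins():
    dx = dx_frame([("X", "C61", "2016-03-15"), ("X", "C61", "2015-07-01")])
    assert first_pc_diagnosis(dx, CFG) == date(2015, 7, 1)


def test_first_pc_outside_window_absent():
    assert first_pc_diagnosis(dx_frame([("X", "C61", "2014-12-31")]), CFG) is None


# --- CRPC detection -----------------------------------------------------

def test_crpc_code_normalized_to_month_end():
    dx = dx_frame([("X", "8848040", "2016-02-10")])
    got = detect_crpc(dx, lab_frame([]), [], date(2016, 2, 1), CFG)
    assert got == (date(2016, 2, 29), "code")


def test_crpc_code_before_index1_month_ignored():
    dx = dx_frame([("X", "8848040", "2016-01-31")])
    assert detect_crpc(dx, lab_frame([]), [], date(2016, 2, 1), CFG) is None


def test_psa_rule_requires_both_thresholds():
    # nadir 4.0: 4.9 fails the absolute rise (>1), 5.2 satisfies both
    labs = lab_frame(
        [
            ("X", "PSA", "2016-01-01", 4.0),
            ("X", "PSA", "2016-04-01", 4.9),
            ("X", "PSA", "2016-07-01", 5.2),
        ]
    )
    adt = [(date(2015, 12, 1), date(2017, 1, 1))]
    got = detect_crpc(dx_frame([]), labs, adt, date(2015, 12, 1), CFG)
    assert got == (date(2016, 7, 1), "psa")


def test_psa_large_relative_rise_without_absolute_is_not_crpc():
    labs = lab_frame(
        [("X", "PSA", "2016-01-01", 0.5), ("X", "PSA", "2016-04-01", 1.45)]
    )
    adt = [(date(2015, 12, 1), date(2017, 1, 1))]
    assert detect_crpc(dx_frame([]), labs, adt, date(2015, 12, 1), CFG) is None


def test_psa_outside_adt_exposure_not_evaluable():
    labs = lab_frame(
        [("X", "PSA", "2016-01-01", 4.0), ("X", "PSA", "2016-04-01", 9.0)]
    )
    assert detect_crpc(dx_frame([]), labs, [], date(2015, 12, 1), CFG) is None
    adt = [(date(2017, 1, 1), date(2017, 6, 1))]  # measurements precede exposure
    assert detect_crpc(dx_frame([]), labs, adt, date(2015, 12, 1), CFG) is None


def test_earliest_mechanism_wins_and_code_breaks_ties():
    labs = lab_frame(
        [("X", "PSA", "2016-01-01", 4.0), ("X", "PSA", "2016-03-31", 5.2)]
    )
    adt = [(date(2015, 12, 1), date(2017, 1, 1))]
    dx = dx_frame([("X", "8848040", "2016-03-05")])
    got = detect_crpc(dx, labs, adt, date(2015, 12, 1), CFG)
    assert got == (date(2016, 3, 31), "code")  # tie on the date -> code


# --- metastasis ---------------------------------------------------------

def test_met_before_index1_only_is_absent():
    dx = dx_frame([("X", "C79.5", "2015-06-01")])
    when, sites = detect_metastasis(dx, date(2016, 1, 1), CFG)
    assert when is None and sites == frozenset()


def test_met_earliest_date_and_site_union():
    dx = dx_frame([("X", "C79.5", "2016-01-10"), ("X", "C78.0", "2015-11-02")])
    when, sites = detect_metastasis(dx, date(2015, 10, 1), CFG)
    assert when == date(2015, 11, 2)
    assert sites == frozenset({"bone", "lung"})


# --- cohort criteria ----------------------------------------------------

def test_minimal_patient_is_included():
    p = run_minimal()
    assert p.included
    assert p.mcrpc_date == date(2017, 3, 31)
    assert p.index2 == date(2017, 4, 15)
    assert p.subgroup == 1  # met 2016-06-01 precedes CRPC


@pytest.mark.parametrize("birth_year, reason", [(1998, "under_age"), (1996, "")])
def test_age_boundary_at_20(birth_year, reason):
    p = run_minimal(birth_year=birth_year)  # index1 2016 -> ages 18 and 20
    assert p.exclusion_reason == reason


@pytest.mark.parametrize(
    "index2, reason",
    [("2017-06-29", ""), ("2017-06-30", "late_initiation")],  # mcrpc + 90 / + 91
)
def test_initiation_90_day_boundary_inclusive(index2, reason):
    p = run_minimal(index2=index2)
    assert p.exclusion_reason == reason


@pytest.mark.parametrize(
    "offset, reason", [(179, "insufficient_followup"), (180, "")]
)
def test_followup_180_day_boundary(offset, reason):
    p = run_minimal(last_record_offset=offset)
    assert p.exclusion_reason == reason


@pytest.mark.parametrize("days_before, reason", [(179, "insufficient_baseline"), (180, "")])
def test_baseline_180_day_boundary(days_before, reason):
    index2 = pd.Timestamp("2017-04-15")
    index1 = (index2 - pd.Timedelta(days=days_before)).date().isoformat()
    p = run_minimal(index1=index1, met="2016-11-01")
    assert p.exclusion_reason == reason


def test_other_malignancy_excludes():
    p = run_minimal(extra_dx=[("C34.1", "2016-08-01")])
    assert p.exclusion_reason == "other_malignancy"


def test_met_codes_do_not_count_as_other_malignancy():
    dx = dx_frame(
        [("X", "C79.5", "2016-01-01"), ("X", "C77", "2016-02-01"), ("X", "C61", "2016-01-01")]
    )
    assert not other_malignancy_present(dx, CFG)
    assert other_malignancy_present(dx_frame([("X", "C50.1", "2016-01-01")]), CFG)


def test_no_metastasis_reason_precedes_late_initiation():
    p = run_minimal(met=None, index2="2017-08-01")
    assert p.exclusion_reason == "no_metastasis"


# --- subgroups ----------------------------------------------------------

def test_subgroup_tie_goes_to_2():
    # metastasis code on the CRPC month-end date itself
    p = run_minimal(met="2017-03-31")
    assert p.included and p.subgroup == 2


def test_subgroup_2_when_crpc_first():
    p = run_minimal(met="2017-04-02", index2="2017-04-15")
    assert p.included and p.subgroup == 2
    assert p.mcrpc_date == date(2017, 4, 2)


def test_partition_of_included(clean_results):
    _, phenotypes, _, _ = clean_results
    inc = phenotypes[phenotypes["included"]]
    assert set(inc["subgroup"].unique()) <= {1, 2}
    assert (phenotypes.loc[~phenotypes["included"], "subgroup"] == 0).all()


# --- month-end duration convention (published footnote) ------------------

def test_same_month_1l_duration_is_zero():
    p = run_minimal(
        met="2016-06-01", crpc_claim="2017-03-10", index2="2017-03-20"
    )
    assert p.included
    assert p.mcrpc_date == date(2017, 3, 31)  # after index2
    assert p.mcrpc_to_index2_days == 0


# --- comorbidities ------------------------------------------------------

def test_comorbidity_window_and_ranges():
    index2 = date(2017, 4, 15)
    dx = dx_frame(
        [
            ("X", "K72", "2017-04-05"),  # liver, 10 days before index2
            ("X", "I25", "2016-09-27"),  # cardiovascular but 200 days before
            ("X", "N40", "2017-02-01"),  # prostatic
            ("X", "E11", "2017-03-01"),  # metabolic
        ]
    )
    got = summarize_comorbidities(dx, index2)
    assert got == frozenset({"liver", "prostatic", "metabolic"})


def test_n510_is_prostatic_but_n51_alone_is_not():
    index2 = date(2017, 4, 15)
    assert summarize_comorbidities(
        dx_frame([("X", "N51.0", "2017-04-01")]), index2
    ) == frozenset({"prostatic"})
    assert summarize_comorbidities(
        dx_frame([("X", "N51", "2017-04-01")]), index2
    ) == frozenset()


# --- robustness properties ----------------------------------------------

def test_order_invariance_of_phenotyping(small_cohort):
    cfg = RunConfig()
    base, _, base_lines = phenotype_cohort(
        small_cohort.diagnoses,
        small_cohort.prescriptions,
        small_cohort.labs,
        small_cohort.patients,
        cfg,
    )
    rng = np.random.default_rng(5)
    shuffled = [
        df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
        for df in (
            small_cohort.diagnoses,
            small_cohort.prescriptions,
            small_cohort.labs,
            small_cohort.patients,
        )
    ]
    again, _, again_lines = phenotype_cohort(*shuffled, cfg)
    pd.testing.assert_frame_equal(base, again)
    key = ["patient_id", "ordinal", "start", "end", "regimen"]
    pd.testing.assert_frame_equal(
        base_lines[key].sort_values(key).reset_index(drop=True),
        again_lines[key].sort_values(key).reset_index(drop=True),
    )


def test_later_crpc_code_never_moves_date_later():
    dx, rx, labs = minimal_patient()
    base = phenotype_patient("X", dx, rx, labs, birth_year=1950, sex="male", config=CFG)
    extra = pd.concat(
        [dx, dx_frame([("X", "8848040", "2017-05-10")])], ignore_index=True
    )
    again = phenotype_patient("X", extra, rx, labs, birth_year=1950, sex="male", config=CFG)
    assert again.crpc_date == base.crpc_date


def test_removing_labs_does_not_change_code_patients():
    dx, rx, labs = minimal_patient()
    labs2 = lab_frame([("X", "PSA", "2016-06-01", 12.0)])
    a = phenotype_patient("X", dx, rx, labs, birth_year=1950, sex="male", config=CFG)
    b = phenotype_patient("X", dx, rx, labs2, birth_year=1950, sex="male", config=CFG)
    assert (a.crpc_date, a.crpc_mechanism) == (b.crpc_date, b.crpc_mechanism)


def test_month_end_helper():
    assert month_end(date(2016, 2, 10)) == date(2016, 2, 29)
    assert month_end(date(2017, 12, 1)) == date(2017, 12, 31)
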