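"""Cohort selection, Charlson scoring, complications, prior cancers, HCRU."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import claimspath as cp
from claimspath.cohort import (
    EXCLUSION_RULES,
    SelectionRules,
    compute_cci,
    compute_hcru,
    detect_complications,
    flag_prior_cancers,
)

# ---------------------------------------------------------------------------
# Charlson comorbidity index


def test_cci_hand_examples():
    assert compute_cci(["I50.0", "E11.9"]) == 2  # CHF + uncomplicated diabetes
    assert compute_cci([]) == 0
    # study lymphoma codes: excluded when modified, malignancy weight otherwise
    assert compute_cci(["C83.3"], modified=True) == 0
    assert compute_cci(["C83.3"], modified=False) == 2
    # hierarchies: complicated diabetes supersedes; metastatic supersedes
    assert compute_cci(["E11.9", "E11.2"]) == 2
    assert compute_cci(["C18.9", "C78.0"]) == 6
    assert compute_cci(["K70.0", "K70.4"]) == 3  # severe liver over mild
    with pytest.raises(ValueError):
        compute_cci(["I50.0"], cci_map={"categories": {}})


_CCI_CODES = ["I21.0", "I50.0", "I70.9", "I63.9", "F03", "J44.9", "M05.9",
              "K25.9", "K70.0", "E11.9", "E11.2", "G81.9", "N18.9", "C18.9",
              "K70.4", "C78.0", "B24", "J06.9", "Z00.0"]


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(_CCI_CODES), max_size=10),
       st.sampled_from(_CCI_CODES))
def test_cci_monotone_and_modified_never_larger(codes, extra):
    base = compute_cci(codes)
    assert compute_cci(codes + [extra]) >= base  # adding a code never lowers it
    assert compute_cci(codes + ["C83.3"], modified=True) == base
    assert compute_cci(codes, modified=True) <= compute_cci(codes, modified=False)


# ---------------------------------------------------------------------------
# prior/concurrent cancers


def test_prior_cancer_range_rules():
    assert flag_prior_cancers(["C18.9"]) == 1
    assert flag_prior_cancers(["C83.3"]) == 0  # lymphoma range excluded
    assert flag_prior_cancers(["C96.9"]) == 1  # past the excluded subrange
    assert flag_prior_cancers(["I50.0", "J06.9"]) == 0
    assert flag_prior_cancers([]) == 0


def test_prior_cancer_against_brute_force_enumeration():
    for num in range(0, 97):
        code = f"C{num:02d}.1"
        expected = int(not 77 <= num <= 89)
        assert flag_prior_cancers([code]) == expected, code


# ---------------------------------------------------------------------------
# complications


def _dx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "service_date", "icd10_code"])


IDX = dt.date(2016, 6, 1)
END = dt.date(2018, 6, 1)


def test_complication_requires_no_history():
    dx = _dx([("p", IDX - dt.timedelta(days=10), "I20.0"),
              ("p", IDX + dt.timedelta(days=30), "I20.0")])
    assert detect_complications(dx, IDX, END)["heart"] == 0


def test_first_ever_event_after_index_flags():
    dx = _dx([("p", IDX + dt.timedelta(days=5), "N17.9")])
    flags = detect_complications(dx, IDX, END)
    assert flags["kidney"] == 1 and flags["heart"] == 0 and flags["liver"] == 0


def test_history_before_first_line_suppresses_flag():
    dx = _dx([("p", IDX - dt.timedelta(days=400), "K75.9"),
              ("p", IDX + dt.timedelta(days=90), "K75.9")])
    assert detect_complications(dx, IDX, END)["liver"] == 0
    assert detect_complications(None, IDX, END) == {"heart": 0, "kidney": 0, "liver": 0}
    assert detect_complications(dx, IDX, END, code_sets={"liver": ()})["liver"] == 0


# ---------------------------------------------------------------------------
# HCRU


def _enc(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "admit_date", "discharge_date", "setting"]
    )


def test_hcru_length_of_stay_arithmetic():
    e = _enc([("p", IDX, IDX + dt.timedelta(days=9), "inpatient"),
              ("p", IDX + dt.timedelta(days=20), IDX + dt.timedelta(days=24), "inpatient")])
    h = compute_hcru(e, IDX, END)
    assert h["n_hospitalizations"] == 2 and h["los_days"] == 15


def test_hcru_empty_and_icu_inside_stay():
    assert compute_hcru(_enc([]), IDX, END)["los_days"] == 0
    e = _enc([("p", IDX, IDX + dt.timedelta(days=9), "inpatient"),
              ("p", IDX + dt.timedelta(days=1), IDX + dt.timedelta(days=2), "ICU")])
    h = compute_hcru(e, IDX, END)
    assert h["any_icu"] == 1 and h["n_hospitalizations"] == 1 and h["los_days"] == 10


def test_hcru_stay_straddling_index_counts_in_window_days_only():
    e = _enc([("p", IDX - dt.timedelta(days=5), IDX + dt.timedelta(days=4), "inpatient")])
    h = compute_hcru(e, IDX, END)
    assert h["los_days"] == 5 and h["n_hospitalizations"] == 1
    bad = _enc([("p", IDX, IDX - dt.timedelta(days=1), "inpatient")])
    with pytest.raises(ValueError):
        compute_hcru(bad, IDX, END)


# ---------------------------------------------------------------------------
# selection


def test_invalid_cohort_label_rejected(small_bundle, small_lines):
    with pytest.raises(ValueError):
        cp.select_cohort(small_bundle, small_lines, SelectionRules(), "4L")
    with pytest.raises(ValueError):
        SelectionRules(lookback_days=0)


def test_exclusion_ledger_counts_reconcile(small_bundle, small_lines):
    cb = cp.corrupt_bundle(small_bundle, "short_followup", fraction=0.3, seed=5)
    lines = cp.derive_lines(cb.drug_claims, encounters=cb.encounters)
    cohort, ledger = cp.select_cohort(cb, lines, SelectionRules(), "2L")
    assert ledger["n_input"] - ledger["n_selected"] == sum(
        ledger[r] for r in EXCLUSION_RULES
    )
    flagged = set(cb.truth.loc[cb.truth["corrupt_scenario"] != "", "patient_id"])
    assert set(cb.truth["patient_id"]) - set(cohort["patient_id"]) == flagged
    assert ledger["followup_lt_12mo"] == len(flagged)


def test_third_line_cohort_is_subset_of_patients_with_three_lines(
    small_bundle, small_lines
):
    c3, _ = cp.select_cohort(small_bundle, small_lines, SelectionRules(), "3L")
    n_lines = small_lines.groupby("patient_id")["line_number"].max()
    assert set(c3["patient_id"]) <= set(n_lines[n_lines >= 3].index)
    c2, _ = cp.select_cohort(small_bundle, small_lines, SelectionRules(), "2L")
    assert set(c3["patient_id"]) <= set(c2["patient_id"])  # overlapping cohorts
    # 3L index is the start of the third line
    lines3 = small_lines[small_lines["line_number"] == 3].set_index("patient_id")
    got = c3.set_index("patient_id")["index_date"]
    assert (got == lines3.loc[got.index, "start_date"]).all()


def test_analysis_table_matches_planted_truth(small_bundle, small_lines):
    table, ledger, cost_table = cp.build_analysis_table(
        small_bundle, small_lines, which="2L"
    )
    assert ledger["n_selected"] == len(small_bundle.patients)
    truth = small_bundle.truth.set_index("patient_id")
    tab = table.set_index("patient_id")
    check_cols = [
        "female", "age_66_70", "age_71_75", "age_76_80", "age_81_85", "age_85p",
        "index_year", "cci_3", "cci_4", "cci_5p", "prior_cancer",
        "comp_heart", "comp_liver", "comp_kidney",
        "itr_r_chase", "itr_gdp", "itr_r_epoch", "itr_other_r",
        "los_days", "n_hospitalizations", "any_icu", "any_sct", "any_pet",
        "any_mri", "any_ct", "any_er", "any_radiation", "followup_days",
    ]
    for c in check_cols:
        assert (tab[c].astype(float) == truth.loc[tab.index, c].astype(float)).all(), c
    assert (tab["thcc_adj_usd"] - truth.loc[tab.index, "thcc_adj_usd"]).abs().max() < 1e-6
    # exactly one age dummy or none (reference <66)
    age_cols = ["age_66_70", "age_71_75", "age_76_80", "age_81_85", "age_85p"]
    assert tab[age_cols].sum(axis=1).isin([0, 1]).all()
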