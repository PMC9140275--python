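"""Cohort selection and covariate construction.

Applies the study's selection flow to a claims bundle — identification-window
treatment claim, 6-month lookback with at least one claim, minimum 12 months
of follow-up, at least one claim in every 6-month period, reaching the
requested line of therapy, and exclusion of rituximab combined with another
immunotherapy — and assembles one fully coded analysis row per selected
patient: demographic dummies, modified Charlson comorbidity index bands,
prior/concurrent cancers, post-index complications, healthcare resource use,
and the inflation-adjusted total healthcare cost over follow-up.

Selection rules are anchored at the first DLBCL treatment (study entry); the
cohort index date is the first administration of the requested line, and all
covariates, resource counts and costs are measured relative to that index.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import load_cci_map, load_complication_codes, load_regimen_config
from .costs import RateTables, aggregate_costs, claim_cost_table, default_rate_tables

__all__ = [
    "SelectionRules",
    "EXCLUSION_RULES",
    "select_cohort",
    "compute_cci",
    "detect_complications",
    "flag_prior_cancers",
    "compute_hcru",
    "build_analysis_table",
    "ITR_DUMMY_COLUMNS",
]

#: exclusion attribution order (a patient is counted at the first failing rule)
EXCLUSION_RULES = (
    "no_dlbcl_claim_in_window",
    "no_lookback_claim",
    "followup_lt_12mo",
    "missing_claim_in_6mo_period",
    "did_not_reach_line",
    "rituximab_immunotherapy_combo",
)

_REGIMEN_CATEGORIES = (
    "r_devic", "r_chase", "gdp", "r_bendamustine", "r_epoch", "r_eshap",
    "eshap", "r_ice", "r_dhap", "other_r", "conditioning_auto_sct", "nos",
)
# reference: other chemotherapy without rituximab (carries no dummy)
ITR_DUMMY_COLUMNS = tuple(f"itr_{c}" for c in _REGIMEN_CATEGORIES)

AGE_BANDS = (
    ("age_66_70", 66, 70),
    ("age_71_75", 71, 75),
    ("age_76_80", 76, 80),
    ("age_81_85", 81, 85),
    ("age_85p", 86, 200),
)


@dataclasses.dataclass(frozen=True)
class SelectionRules:
    id_window: tuple = (dt.date(2008, 10, 1), dt.date(2019, 6, 30))
    lookback_days: int = 183
    min_followup_days: int = 365
    claim_period_days: int = 183
    dlbcl_dx_prefixes: tuple = ("C833", "C852")

    def __post_init__(self):
        if self.lookback_days <= 0 or self.min_followup_days <= 0 or self.claim_period_days <= 0:
            raise ValueError("rule durations must be positive")


def _date(x) -> dt.date:
    return x if isinstance(x, dt.date) and not isinstance(x, dt.datetime) else pd.Timestamp(x).date()


def _claim_dates_by_patient(bundle) -> dict:
    """All claim/encounter dates per patient as sorted numpy date arrays."""
    frames = [
        bundle.drug_claims[["patient_id", "service_date"]].rename(columns={"service_date": "d"}),
        bundle.dx_claims[["patient_id", "service_date"]].rename(columns={"service_date": "d"}),
        bundle.encounters[["patient_id", "admit_date"]].rename(columns={"admit_date": "d"}),
    ]
    allc = pd.concat(frames, ignore_index=True)
    allc["d"] = pd.to_datetime(allc["d"])
    out = {}
    for pid, grp in allc.groupby("patient_id"):
        out[pid] = np.sort(grp["d"].to_numpy())
    return out


def select_cohort(bundle, lines: pd.DataFrame, rules: SelectionRules, which: str):
    """Apply the selection flow and return (cohort, exclusion ledger).

    Parameters
    ----------
    bundle : ClaimsBundle
    lines : DataFrame
        Output of :func:`claimspath.lot.derive_lines` for all patients.
    which : {"2L", "3L"}

    Returns
    -------
    cohort : DataFrame with patient_id, index_date, end_of_followup
    ledger : dict with n_input, per-rule exclusion counts (in order), n_selected
    """
    if which not in ("2L", "3L"):
        raise ValueError(f"which must be '2L' or '3L', got {which!r}")
    line_no = 2 if which == "2L" else 3
    reg_cfg = load_regimen_config()
    immuno = reg_cfg["immunotherapy_components"]

    claim_dates = _claim_dates_by_patient(bundle)
    censor = dict(
        zip(bundle.patients["patient_id"],
            pd.to_datetime(bundle.patients["death_or_censor_date"]))
    )
    dx_by_pid = {
        pid: grp for pid, grp in bundle.dx_claims.groupby("patient_id")
    }
    lines_by_pid = {pid: grp.sort_values("line_number") for pid, grp in lines.groupby("patient_id")}

    w0 = pd.Timestamp(rules.id_window[0])
    w1 = pd.Timestamp(rules.id_window[1])
    drug = bundle.drug_claims
    mapped = drug["drug_code"].isin(reg_cfg["drug_to_component"])
    ddt = pd.to_datetime(drug["service_date"])
    in_window_treated = set(
        drug.loc[mapped & (ddt >= w0) & (ddt <= w1), "patient_id"]
    )

    ledger = {r: 0 for r in EXCLUSION_RULES}
    selected = []
    for pid in bundle.patients["patient_id"]:
        pl = lines_by_pid.get(pid)
        dxg = dx_by_pid.get(pid)
        has_dx = dxg is not None and (
            dxg["icd10_code"].astype(str).str.replace(".", "", regex=False)
            .str.startswith(rules.dlbcl_dx_prefixes).any()
        )
        if pl is None or pid not in in_window_treated or not has_dx:
            ledger["no_dlbcl_claim_in_window"] += 1
            continue
        t1 = pd.Timestamp(pl["start_date"].iloc[0])
        dates = claim_dates[pid]
        lb_lo = t1 - pd.Timedelta(days=rules.lookback_days)
        n_lb = np.searchsorted(dates, np.datetime64(t1)) - np.searchsorted(
            dates, np.datetime64(lb_lo)
        )
        if n_lb < 1:
            ledger["no_lookback_claim"] += 1
            continue
        end = min(censor[pid], pd.Timestamp(dates[-1]))
        if (end - t1).days < rules.min_followup_days:
            ledger["followup_lt_12mo"] += 1
            continue
        ok = True
        ws = t1
        while ws < end:
            we = ws + pd.Timedelta(days=rules.claim_period_days)
            cnt = np.searchsorted(dates, np.datetime64(min(we, end + pd.Timedelta(days=1)))) - \
                np.searchsorted(dates, np.datetime64(ws))
            if cnt < 1:
                ok = False
                break
            ws = we
        if not ok:
            ledger["missing_claim_in_6mo_period"] += 1
            continue
        if len(pl) < line_no:
            ledger["did_not_reach_line"] += 1
            continue
        combo = False
        for comps in pl["components"]:
            cs = set(str(comps).split("|"))
            if "rituximab" in cs and cs & immuno:
                combo = True
                break
        if combo:
            ledger["rituximab_immunotherapy_combo"] += 1
            continue
        idx_row = pl[pl["line_number"] == line_no].iloc[0]
        selected.append(
            {"patient_id": pid,
             "index_date": _date(idx_row["start_date"]),
             "first_treatment_date": _date(t1),
             "end_of_followup": _date(end)}
        )
    cohort = pd.DataFrame(selected, columns=["patient_id", "index_date",
                                             "first_treatment_date", "end_of_followup"])
    out_ledger = {"n_input": int(len(bundle.patients)), **{k: int(v) for k, v in ledger.items()},
                  "n_selected": int(len(cohort))}
    return cohort, out_ledger


# ---------------------------------------------------------------------------
# Covariates


def _norm_codes(codes) -> list:
    return [str(c).replace(".", "").upper() for c in codes]


def compute_cci(codes: Sequence[str], cci_map: dict | None = None, modified: bool = True) -> int:
    """Charlson comorbidity index from ICD-10 codes (Quan coding).

    The score sums the weights of distinct comorbidity categories present,
    with hierarchy rules (complicated diabetes over diabetes, moderate/severe
    liver over mild, metastatic tumor over any malignancy).  With
    ``modified=True`` the study lymphoma codes are removed first, so the
    disease under study does not count as its own comorbidity.
    """
    cci_map = cci_map or load_cci_map()
    if not cci_map.get("categories"):
        raise ValueError("empty comorbidity mapping")
    norm = _norm_codes(codes)
    if modified:
        dl = tuple(cci_map["dlbcl_codes"])
        norm = [c for c in norm if not c.startswith(dl)]
    present = set()
    for cat, info in cci_map["categories"].items():
        prefixes = tuple(info["codes"])
        if any(c.startswith(prefixes) for c in norm):
            present.add(cat)
    for winner, loser in cci_map["hierarchy"]:
        if winner in present:
            present.discard(loser)
    return sum(cci_map["categories"][c]["weight"] for c in present)


def flag_prior_cancers(codes: Sequence[str]) -> int:
    """1 if any code lies in C00-C96 excluding C77-C89 (secondary/lymphoma)."""
    for c in _norm_codes(codes):
        if len(c) >= 3 and c[0] == "C" and c[1:3].isdigit():
            num = int(c[1:3])
            if 0 <= num <= 96 and not 77 <= num <= 89:
                return 1
    return 0


def detect_complications(
    dx: pd.DataFrame,
    index_date,
    end_of_followup,
    code_sets: Mapping[str, tuple] | None = None,
) -> dict:
    """New-event complication flags: first matching code strictly after index
    with no matching code at any time on or before it (history during or
    before prior lines suppresses the flag)."""
    code_sets = code_sets or load_complication_codes()
    out = {}
    if dx is None or not len(dx):
        return {k: 0 for k in code_sets}
    codes = np.array(_norm_codes(dx["icd10_code"]))
    dates = pd.to_datetime(dx["service_date"]).to_numpy()
    idx = np.datetime64(pd.Timestamp(index_date))
    end = np.datetime64(pd.Timestamp(end_of_followup))
    for name, prefixes in code_sets.items():
        if not prefixes:
            out[name] = 0
            continue
        m = np.array([c.startswith(tuple(prefixes)) for c in codes])
        history = bool((m & (dates <= idx)).any())
        new = bool((m & (dates > idx) & (dates <= end)).any())
        out[name] = int(new and not history)
    return out


def compute_hcru(encounters: pd.DataFrame, index_date, end_of_followup) -> dict:
    """Resource-use measures over the closed follow-up window.

    Hospital stays straddling the window contribute only their in-window days;
    a stay counts as one hospitalization if it overlaps the window at all.
    """
    idx = pd.Timestamp(index_date)
    end = pd.Timestamp(end_of_followup)
    out = {"n_hospitalizations": 0, "los_days": 0, "any_icu": 0, "any_er": 0,
           "any_pet": 0, "any_mri": 0, "any_ct": 0, "any_radiation": 0,
           "any_sct": 0}
    if encounters is None or not len(encounters):
        return out
    adm = pd.to_datetime(encounters["admit_date"])
    dis = pd.to_datetime(encounters["discharge_date"])
    if (dis < adm).any():
        raise ValueError("discharge before admission")
    overlap = (dis >= idx) & (adm <= end)
    e = encounters[overlap]
    adm, dis = adm[overlap], dis[overlap]
    inp = e["setting"] == "inpatient"
    out["n_hospitalizations"] = int(inp.sum())
    if inp.any():
        los = (dis[inp].clip(upper=end) - adm[inp].clip(lower=idx)).dt.days + 1
        out["los_days"] = int(los.sum())
    settings = set(e["setting"])
    out["any_icu"] = int("ICU" in settings)
    out["any_er"] = int("ER" in settings)
    out["any_pet"] = int("PET" in settings)
    out["any_mri"] = int("MRI" in settings)
    out["any_ct"] = int("CT" in settings)
    out["any_radiation"] = int("radiation" in settings)
    out["any_sct"] = int(bool(settings & {"SCT-auto", "SCT-allo"}))
    return out


# ---------------------------------------------------------------------------
# Analysis table


def build_analysis_table(
    bundle,
    lines: pd.DataFrame,
    rules: SelectionRules | None = None,
    which: str = "2L",
    rates: RateTables | None = None,
):
    """Select the cohort and assemble one AnalysisRow per patient.

    Returns
    -------
    table : DataFrame
        Model-ready rows: demographic/CCI/ITR/complication dummies, HCRU
        measures, adjusted total cost, follow-up days.
    ledger : dict
        Exclusion counts per rule.
    cost_table : DataFrame
        Per-patient per-category adjusted-USD costs (for cost summaries).
    """
    rules = rules or SelectionRules()
    rates = rates or default_rate_tables()
    reg_cfg = load_regimen_config()
    cohort, ledger = select_cohort(bundle, lines, rules, which)
    line_no = 2 if which == "2L" else 3

    dx_by_pid = {pid: grp for pid, grp in bundle.dx_claims.groupby("patient_id")}
    enc_by_pid = {pid: grp for pid, grp in bundle.encounters.groupby("patient_id")}
    lines_by_pid = {pid: grp for pid, grp in lines.groupby("patient_id")}
    costs_all = claim_cost_table(
        bundle.drug_claims, bundle.encounters, reg_cfg["drug_to_component"]
    )
    costs_by_pid = {pid: grp for pid, grp in costs_all.groupby("patient_id")}
    pat = bundle.patients.set_index("patient_id")

    comp_sets = load_complication_codes()
    rows = []
    cost_rows = []
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        index, end = rec.index_date, rec.end_of_followup
        dxg = dx_by_pid.get(pid)
        row = {"patient_id": pid, "cohort": which, "index_date": index,
               "followup_days": (pd.Timestamp(end) - pd.Timestamp(index)).days}

        age = int(index.year - pat.loc[pid, "birth_year"])
        row["female"] = int(pat.loc[pid, "sex"] == "F")
        for name, lo, hi in AGE_BANDS:
            row[name] = int(lo <= age <= hi)
        row["age"] = age
        row["index_year"] = index.year - 2008

        # modified CCI over the 6 months before the cohort index
        if dxg is not None:
            d = pd.to_datetime(dxg["service_date"])
            lb = dxg[(d >= pd.Timestamp(index) - pd.Timedelta(days=rules.lookback_days))
                     & (d < pd.Timestamp(index))]
            score = compute_cci(lb["icd10_code"], modified=True)
            row["prior_cancer"] = flag_prior_cancers(lb["icd10_code"])
        else:
            score = 0
            row["prior_cancer"] = 0
        row["cci_score"] = score
        row["cci_3"] = int(score == 3)
        row["cci_4"] = int(score == 4)
        row["cci_5p"] = int(score >= 5)

        comps = detect_complications(dxg, index, end, comp_sets)
        for k in ("heart", "liver", "kidney"):
            row[f"comp_{k}"] = comps.get(k, 0)

        idx_line = lines_by_pid[pid]
        cat = idx_line[idx_line["line_number"] == line_no]["regimen_category"].iloc[0]
        for col, c in zip(ITR_DUMMY_COLUMNS, _REGIMEN_CATEGORIES):
            row[col] = int(cat == c)
        row["itr_category"] = cat

        row.update(compute_hcru(enc_by_pid.get(pid), index, end))

        cc = costs_by_pid.get(pid)
        agg = aggregate_costs(
            cc if cc is not None else pd.DataFrame(columns=costs_all.columns),
            index, end, rates,
        )
        row["thcc_adj_usd"] = agg["total"]
        rows.append(row)
        cost_rows.append({"patient_id": pid, **agg})

    table = pd.DataFrame(rows)
    cost_table = pd.DataFrame(cost_rows)
    return table, ledger, cost_table
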