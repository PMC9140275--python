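"""Cost aggregation, currency conversion and inflation adjustment.

Claim-level costs arrive in nominal JPY.  They are converted to USD with the
exchange rate of the first month of the claim's service year and adjusted for
Japanese inflation to a reference year (default 2020) with the calendar-year
average CPI:

    nominal_usd  = cost_jpy / fx[year]
    adjusted_usd = nominal_usd * cpi[reference_year] / cpi[year]

Costs aggregate into the reporting categories: total, inpatient, ICU,
outpatient (including imaging, emergency room and radiation encounters),
cancer treatment drugs, other pharmacy, and SCT (any/auto/allo).  Negative
claim amounts (real fee-schedule adjustments) are tolerated and simply sum.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .config import load_rates_csv

__all__ = [
    "RateTables",
    "convert_and_adjust",
    "aggregate_costs",
    "summarize_costs",
    "SETTING_CATEGORY",
    "COST_CATEGORIES",
]

#: encounter setting -> cost category
SETTING_CATEGORY = {
    "inpatient": "inpatient",
    "ICU": "icu",
    "outpatient": "outpatient",
    "ER": "outpatient",
    "PET": "outpatient",
    "MRI": "outpatient",
    "CT": "outpatient",
    "radiation": "outpatient",
    "SCT-auto": "auto_sct",
    "SCT-allo": "allo_sct",
}

COST_CATEGORIES = (
    "total",
    "inpatient",
    "icu",
    "outpatient",
    "cancer_treatment",
    "other_pharmacy",
    "any_sct",
    "allo_sct",
    "auto_sct",
)


@dataclasses.dataclass(frozen=True)
class RateTables:
    """Year-indexed JPY/USD exchange rates and CPI series."""

    fx: Mapping[int, float]
    cpi: Mapping[int, float]
    reference_year: int = 2020

    def __post_init__(self):
        if any(v <= 0 for v in self.fx.values()) or any(
            v <= 0 for v in self.cpi.values()
        ):
            raise ValueError("all rates must be positive")
        if self.reference_year not in self.cpi:
            raise ValueError(f"reference year {self.reference_year} missing from CPI")

    @classmethod
    def from_csv(cls, path: str | None = None, reference_year: int = 2020):
        df = load_rates_csv(path)
        return cls(
            fx=dict(zip(df["year"].astype(int), df["fx_jpy_per_usd"].astype(float))),
            cpi=dict(zip(df["year"].astype(int), df["cpi"].astype(float))),
            reference_year=reference_year,
        )

    def fx_of(self, year) -> np.ndarray:
        return _lookup(self.fx, year, "exchange rate")

    def cpi_of(self, year) -> np.ndarray:
        return _lookup(self.cpi, year, "CPI")


def _lookup(table, year, what):
    years = np.atleast_1d(np.asarray(year, dtype=int))
    missing = sorted({int(y) for y in years} - set(table))
    if missing:
        raise KeyError(f"{what} missing for year(s) {missing}")
    out = np.array([table[int(y)] for y in years], dtype=float)
    return out if np.ndim(year) else float(out[0])


def default_rate_tables() -> RateTables:
    return RateTables.from_csv()


def convert_and_adjust(cost_jpy, service_year, rates: RateTables):
    """JPY -> (nominal USD, inflation-adjusted USD). Vectorized over arrays."""
    nominal = np.asarray(cost_jpy, float) / rates.fx_of(service_year)
    adjusted = nominal * rates.cpi[rates.reference_year] / rates.cpi_of(service_year)
    if np.ndim(cost_jpy) == 0 and np.ndim(service_year) == 0:
        return float(nominal), float(adjusted)
    return nominal, adjusted


def claim_cost_table(
    drug_claims: pd.DataFrame,
    encounters: pd.DataFrame,
    drug_to_component: Mapping[str, str],
    strict: bool = False,
) -> pd.DataFrame:
    """Flatten drug claims and encounters into (patient_id, date, category, cost_jpy).

    Drug claims whose code maps to a treatment component are cancer-treatment
    costs; unmapped drug codes are other-pharmacy costs (``strict=True`` raises
    on unknown encounter settings instead of skipping them).
    """
    frames = []
    if len(drug_claims):
        d = drug_claims.loc[:, ["patient_id", "service_date", "drug_code", "cost_jpy"]].copy()
        mapped = d["drug_code"].isin(drug_to_component)
        d["category"] = np.where(mapped, "cancer_treatment", "other_pharmacy")
        frames.append(d.rename(columns={"service_date": "date"})[
            ["patient_id", "date", "category", "cost_jpy"]
        ])
    if len(encounters):
        e = encounters.copy()
        known = e["setting"].isin(SETTING_CATEGORY)
        if strict and not known.all():
            bad = sorted(e.loc[~known, "setting"].unique())
            raise KeyError(f"unmapped encounter settings: {bad}")
        e = e[known]
        e["category"] = e["setting"].map(SETTING_CATEGORY)
        e["date"] = e["admit_date"]
        frames.append(e[["patient_id", "date", "category", "cost_jpy"]])
    if not frames:
        return pd.DataFrame(columns=["patient_id", "date", "category", "cost_jpy"])
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"])
    return out


def aggregate_costs(
    costs: pd.DataFrame,
    index_date,
    end_of_followup,
    rates: RateTables,
) -> dict:
    """Per-category adjusted-USD totals for one patient over the follow-up.

    Parameters
    ----------
    costs : DataFrame
        Output of :func:`claim_cost_table` restricted to one patient.
    index_date, end_of_followup
        Closed follow-up window; claims outside contribute nothing.

    Notes
    -----
    ``total`` is the sum of all in-window claims.  In real fee schedules the
    subcategories may overlap (e.g. SCT costs billed inside an inpatient stay),
    so no component-sum identity is asserted; the synthetic generator allocates
    disjointly, in which case total equals the component sum exactly.
    """
    out = {c: 0.0 for c in COST_CATEGORIES}
    if len(costs):
        dates = pd.to_datetime(costs["date"])
        w = costs[(dates >= pd.Timestamp(index_date)) & (dates <= pd.Timestamp(end_of_followup))]
        if len(w):
            years = pd.to_datetime(w["date"]).dt.year.to_numpy()
            _, adj = convert_and_adjust(w["cost_jpy"].to_numpy(float), years, rates)
            out["total"] = float(adj.sum())
            for cat, grp in zip(w["category"], adj):
                out[cat] = out.get(cat, 0.0) + float(grp)
    out["any_sct"] = out["auto_sct"] + out["allo_sct"]
    return out


def summarize_costs(cost_rows: pd.DataFrame) -> pd.DataFrame:
    """Descriptive cost summary per category (the cost-table layout).

    Parameters
    ----------
    cost_rows : DataFrame
        One row per patient with one column per category (adjusted USD).

    Returns
    -------
    DataFrame indexed by category with n (patients with any non-zero cost in
    the category; all patients for ``total``), mean, sd, median, q1, q3, min,
    max.  A single-observation SD is reported as 0 with a warning.  Quantiles
    use linear interpolation; SD uses the n-1 denominator.
    """
    if not len(cost_rows):
        raise ValueError("empty cohort")
    rows = {}
    for cat in [c for c in COST_CATEGORIES if c in cost_rows.columns]:
        vals = cost_rows[cat].to_numpy(float)
        if cat != "total":
            vals = vals[vals != 0]
        if len(vals) == 0:
            rows[cat] = dict.fromkeys(
                ["n", "mean", "sd", "median", "q1", "q3", "min", "max"], np.nan
            ) | {"n": 0}
            continue
        if len(vals) == 1:
            warnings.warn(f"single observation in category {cat!r}; SD reported as 0")
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        rows[cat] = {
            "n": int(len(vals)),
            "mean": float(np.mean(vals)),
            "sd": sd,
            "median": float(np.median(vals)),
            "q1": float(np.quantile(vals, 0.25)),
            "q3": float(np.quantile(vals, 0.75)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
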