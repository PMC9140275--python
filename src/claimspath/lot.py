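"""Line-of-therapy derivation from drug claims.

A patient's dated drug claims are segmented into numbered treatment lines.
The initiation drug set of a line is everything administered within the
initiation window (default 30 days) of the line's first claim; a new line
starts when a drug outside the current initiation set appears more than the
grace period (default 30 days) after the line's start, or after a treatment
gap longer than 90 days.  Stem cell transplants never start a line: an SCT is
merged into the line that started on or before the transplant date.  Each line
is then classified into a hierarchical regimen taxonomy on the component level
(drug codes are first mapped to components, so brand/generic variants of one
component cannot trigger a line change).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import load_regimen_config

__all__ = ["LotRules", "TreatmentLine", "assign_lines", "classify_regimen", "derive_lines"]


@dataclasses.dataclass(frozen=True)
class LotRules:
    """Segmentation and classification parameters.

    initiation_window_days
        Drugs within this many days of a line's first claim belong to the
        line's initiation regimen (applied to every line, not only the first).
    new_drug_grace_days
        A drug outside the initiation set starts a new line only when it
        appears strictly more than this many days after the line started.
    gap_days
        A gap between consecutive claims strictly greater than this starts a
        new line regardless of drugs.
    """

    initiation_window_days: int = 30
    new_drug_grace_days: int = 30
    gap_days: int = 90
    sct_merge: bool = True
    regimen_config: dict | None = None

    def __post_init__(self):
        for f in ("initiation_window_days", "new_drug_grace_days", "gap_days"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.regimen_config is None:
            object.__setattr__(self, "regimen_config", load_regimen_config())

    @property
    def drug_to_component(self) -> Mapping[str, str]:
        return self.regimen_config["drug_to_component"]


@dataclasses.dataclass
class TreatmentLine:
    patient_id: object
    line_number: int
    start_date: dt.date
    end_date: dt.date
    drug_set: frozenset  # raw codes
    components: frozenset
    regimen_category: str = "nos"
    sct_within_line: str = "none"  # none | auto | allo

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def assign_lines(
    claims: Sequence[Mapping] | pd.DataFrame,
    rules: LotRules,
    sct_events: Iterable[tuple] = (),
    strict: bool = False,
) -> list[TreatmentLine]:
    """Segment one patient's drug claims into treatment lines.

    Parameters
    ----------
    claims
        Records with ``service_date`` and ``drug_code`` (a DataFrame or list of
        mappings) for a single patient; order is irrelevant — same-day claims
        are processed as a set, so the output is invariant to input order.
    sct_events
        ``(date, kind)`` pairs with kind ``auto``/``allo``; each transplant is
        merged into the line whose start is the latest on or before its date.
    strict
        Raise on drug codes missing from the component map instead of
        excluding them (missing codes usually mean an incomplete config).
    """
    if isinstance(claims, pd.DataFrame):
        records = claims.to_dict("records")
    else:
        records = list(claims)
    if not records:
        raise ValueError("no claims supplied")
    mapping = rules.drug_to_component
    pid = records[0].get("patient_id")

    by_date: dict = {}
    for r in records:
        code = r["drug_code"]
        comp = mapping.get(code)
        if comp is None:
            if strict:
                raise KeyError(
                    f"drug code {code!r} not in drug_to_component map"
                )
            continue  # non-treatment pharmacy; never defines a line
        by_date.setdefault(_as_date(r["service_date"]), set()).add((code, comp))
    if not by_date:
        raise ValueError("no mappable treatment claims supplied")

    lines: list[dict] = []
    cur = None
    last_date = None
    for day in sorted(by_date):
        codes_comps = by_date[day]
        comps = {c for _, c in codes_comps}
        new_line = False
        if cur is None:
            new_line = True
        elif (day - last_date).days > rules.gap_days:
            new_line = True
        elif (day - cur["start"]).days > rules.new_drug_grace_days and not (
            comps <= cur["init"]
        ):
            new_line = True
        if new_line:
            cur = {"start": day, "init": set(comps), "all": set(comps),
                   "codes": {c for c, _ in codes_comps}, "end": day}
            lines.append(cur)
        else:
            if (day - cur["start"]).days <= rules.initiation_window_days:
                cur["init"] |= comps
            cur["all"] |= comps
            cur["codes"] |= {c for c, _ in codes_comps}
            cur["end"] = day
        last_date = day

    out = [
        TreatmentLine(
            patient_id=pid,
            line_number=i + 1,
            start_date=ln["start"],
            end_date=ln["end"],
            drug_set=frozenset(ln["codes"]),
            components=frozenset(ln["all"]),
        )
        for i, ln in enumerate(lines)
    ]

    if rules.sct_merge:
        starts = [ln.start_date for ln in out]
        for date, kind in sct_events:
            date = _as_date(date)
            target = 0
            for i, s in enumerate(starts):
                if s <= date:
                    target = i
            ln = out[target]
            if ln.sct_within_line == "none" or kind == "auto":
                ln.sct_within_line = kind

    for ln in out:
        ln.regimen_category = classify_regimen(
            ln.components, ln.sct_within_line == "auto", rules
        )
    return out


def classify_regimen(
    components: frozenset | set, auto_sct_within_line: bool, rules: LotRules
) -> str:
    """Hierarchical regimen classification of one line's component set.

    Conditioning regimens are resolved first: a line containing a full
    conditioning set is 'conditioning_auto_sct' when an autologous transplant
    occurred within the line and 'other_chemo_without_r' otherwise.  Named
    categories are then matched in the configured order (first subset match
    wins, honoring with/without-rituximab variants); remaining lines fall
    through to other-R-based, other chemotherapy without R, or
    not-otherwise-specified for lines with no classifiable component.
    """
    cfg = rules.regimen_config
    comps = set(components)
    has_r = "rituximab" in comps

    for cond in cfg["conditioning_sets"].values():
        if cond <= comps:
            return "conditioning_auto_sct" if auto_sct_within_line else "other_chemo_without_r"

    for cat in cfg["categories"]:
        if not cat["required"] <= comps:
            continue
        if cat["any_of"] and not (cat["any_of"] & comps):
            continue
        if cat["rituximab"] == "required" and not has_r:
            continue
        return cat["id"]

    if has_r:
        return "other_r"
    if comps & cfg["chemo_components"]:
        return "other_chemo_without_r"
    return "nos"


def derive_lines(
    drug_claims: pd.DataFrame,
    rules: LotRules | None = None,
    encounters: pd.DataFrame | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Assign lines for every patient in a drug-claims table.

    SCT encounters (settings ``SCT-auto``/``SCT-allo``) are merged into lines
    when an encounters table is given.  Returns one row per TreatmentLine.
    """
    rules = rules or LotRules()
    sct_by_pid: dict = {}
    if encounters is not None and len(encounters):
        sct = encounters[encounters["setting"].isin(("SCT-auto", "SCT-allo"))]
        for pid, grp in sct.groupby("patient_id"):
            sct_by_pid[pid] = [
                (d, s.split("-", 1)[1])
                for d, s in zip(grp["admit_date"], grp["setting"])
            ]
    rows = []
    for pid, grp in drug_claims.groupby("patient_id", sort=True):
        try:
            lines = assign_lines(grp, rules, sct_by_pid.get(pid, ()), strict=strict)
        except ValueError:
            continue  # patient with no mappable treatment claims
        for ln in lines:
            rows.append(
                {
                    "patient_id": pid,
                    "line_number": ln.line_number,
                    "start_date": ln.start_date,
                    "end_date": ln.end_date,
                    "regimen_category": ln.regimen_category,
                    "sct_within_line": ln.sct_within_line,
                    "n_components": len(ln.components),
                    "components": "|".join(sorted(ln.components)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "line_number", "start_date", "end_date",
            "regimen_category", "sct_within_line", "n_components", "components",
        ],
    )
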