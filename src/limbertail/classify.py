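"""Stage-2 case/control classification from tail questionnaires.

The case definition: the dog showed some degree of tail flaccidity
(limp at the end and/or along the entire length) with no alternative
cause reported.  A provisional case whose questionnaire shows no
limpness is excluded from the case arm; a provisional control whose
questionnaire shows unexplained limpness is promoted to case.  An
"unsure" answer on a limpness sign counts as "no" — the definition
requires positive flaccidity — and any concrete cause attribution
(injury, anal glands, other) vetoes case status even when limpness is
reported.  Classification is a pure function of (response, provisional
status): no imputation, no interactive input.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "SIGN_FIELDS",
    "FinalStatus",
    "classify_dog",
    "reclassify_cohort",
    "recode_duration",
]

SIGN_FIELDS = (
    "sign_limp_end",
    "sign_limp_length",
    "sign_stiff_base",
    "sign_hair_on_end",
    "sign_painful",
)
_ATTRIBUTIONS = ("none", "injury", "anal_glands", "other_cause")
_ANSWERS = ("yes", "no", "unsure")


@dataclass(frozen=True)
class FinalStatus:
    dog_id: str
    provisional: str  # case | control
    final: str  # case | control | excluded
    reason: str  # limpness_confirmed | no_limpness | attributed_other_cause
    #             | signs_without_limpness | no_signs


def _get(response, key):
    try:
        return response[key]
    except (KeyError, IndexError):
        raise ValueError(f"questionnaire response missing field {key!r}") from None


def classify_dog(response: Mapping | pd.Series, provisional: str) -> FinalStatus:
    """Final status for one dog from its sign profile and attribution."""
    if provisional not in ("case", "control"):
        raise ValueError(f"provisional must be case/control, got {provisional!r}")
    answers = {}
    for f in SIGN_FIELDS:
        v = str(_get(response, f)).lower()
        if v not in _ANSWERS:
            raise ValueError(f"sign field {f} must be yes/no/unsure, got {v!r}")
        answers[f] = v
    attribution = str(_get(response, "attribution")).lower()
    if attribution not in _ATTRIBUTIONS:
        raise ValueError(f"unknown attribution {attribution!r}")
    dog_id = str(_get(response, "dog_id"))

    limpness = answers["sign_limp_end"] == "yes" or answers["sign_limp_length"] == "yes"
    any_sign = any(answers[f] == "yes" for f in SIGN_FIELDS)

    if limpness and attribution == "none":
        return FinalStatus(dog_id, provisional, "case", "limpness_confirmed")
    if provisional == "case":
        if not limpness:
            return FinalStatus(dog_id, provisional, "excluded", "no_limpness")
        return FinalStatus(dog_id, provisional, "control", "attributed_other_cause")
    # provisional control
    if not any_sign:
        return FinalStatus(dog_id, provisional, "control", "no_signs")
    if attribution != "none":
        return FinalStatus(dog_id, provisional, "control", "attributed_other_cause")
    return FinalStatus(dog_id, provisional, "control", "signs_without_limpness")


def reclassify_cohort(
    responses: pd.DataFrame, provisional: Mapping[str, str] | pd.Series
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every responding dog and tally the status transitions.

    Returns the per-dog status table and a transition summary.  The
    excluded provisional cases are reported both as exclusions (they
    enter neither analysis arm) and folded into
    ``controls_incl_excluded_cases`` for comparison with flow accounts
    that return them to the control pool.
    """
    prov = dict(provisional)
    if responses.empty:
        cols = ["dog_id", "provisional", "final", "reason"]
        return pd.DataFrame(columns=cols), {
            "n_responses": 0, "n_provisional_cases": 0, "n_provisional_controls": 0,
            "cases_confirmed": 0, "cases_excluded": 0, "cases_reattributed": 0,
            "controls_promoted": 0, "controls_retained": 0,
            "n_cases_final": 0, "n_controls_final": 0, "n_excluded": 0,
            "controls_incl_excluded_cases": 0,
        }
    statuses = []
    for rec in responses.to_dict("records"):
        dog = str(rec["dog_id"])
        if dog not in prov:
            raise ValueError(f"dog {dog} has a response but no provisional status")
        statuses.append(classify_dog(rec, prov[dog]))
    table = pd.DataFrame([s.__dict__ for s in statuses])

    pc = table[table["provisional"] == "case"]
    pk = table[table["provisional"] == "control"]
    summary = {
        "n_responses": len(table),
        "n_provisional_cases": len(pc),
        "n_provisional_controls": len(pk),
        "cases_confirmed": int((pc["final"] == "case").sum()),
        "cases_excluded": int((pc["final"] == "excluded").sum()),
        "cases_reattributed": int((pc["final"] == "control").sum()),
        "controls_promoted": int((pk["final"] == "case").sum()),
        "controls_retained": int((pk["final"] == "control").sum()),
        "n_cases_final": int((table["final"] == "case").sum()),
        "n_controls_final": int((table["final"] == "control").sum()),
        "n_excluded": int((table["final"] == "excluded").sum()),
    }
    summary["controls_incl_excluded_cases"] = (
        summary["n_controls_final"] + summary["n_excluded"]
    )
    return table, summary


_DURATION_MAP = {
    "a few hours": 3 / 24,
    "a few days": 3.0,
    "a week or more": 8.0,
}
_NUMERIC_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(day|days|hour|hours|hr|hrs)?\s*$")


def recode_duration(duration_category: str | float) -> float:
    """Recode an episode-duration category to days.

    "a few hours" -> 0.125 (three hours), "a few days" -> 3, "a week or
    more" -> 8; explicit counts ("2 days", "36 hours", bare numbers in
    days) pass through.  Unrecognised categories are flagged with a
    warning and returned as NaN so summaries can drop them.
    """
    if isinstance(duration_category, (int, float)):
        return float(duration_category)
    s = str(duration_category).strip().lower()
    if s in _DURATION_MAP:
        return _DURATION_MAP[s]
    m = _NUMERIC_RE.match(s)
    if m:
        value = float(m.group(1))
        unit = m.group(2) or "days"
        return value / 24 if unit.startswith("h") else value
    warnings.warn(f"unrecognised duration category {duration_category!r}; excluded")
    return float("nan")
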