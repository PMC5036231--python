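"""Keyword screening of free-text illness reports.

Stage-1 rule: a report is a candidate limber-tail incident when the
text contains the word "tail" together with at least one keyword from a
fixed stem list.  Texts containing "tail" but no keyword are queued for
manual review rather than discarded — that channel catches owner
phrasings like "she couldn't wag it".  Matching is case-insensitive
plain substring matching: the printed stems ("limb", "swim", "drop")
only make sense as substrings, and the review queue plus an override
file absorb the occasional false positive.  Manual review decisions are
supplied as a reproducible overrides table, never interactively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .epi import BinomialEstimate, clopper_pearson_ci

__all__ = [
    "DEFAULT_KEYWORDS",
    "IllnessReport",
    "ScreenResult",
    "ScreeningSummary",
    "screen_report",
    "screen_cohort",
]

DEFAULT_KEYWORDS: tuple[str, ...] = (
    "cold", "dead", "droopy", "drop", "limb", "limber", "limp",
    "rudder", "staved", "stiff", "stride", "swim", "swimmers",
)


@dataclass(frozen=True)
class IllnessReport:
    dog_id: str
    report_date: str
    text: str
    vet_visit: bool = False


@dataclass(frozen=True)
class ScreenResult:
    dog_id: str
    matched: bool
    matched_keywords: tuple[str, ...]
    needs_review: bool


def screen_report(report, keyword_set: Iterable[str] = DEFAULT_KEYWORDS) -> ScreenResult:
    """Apply the keyword rule to a single report.

    ``report`` may be an :class:`IllnessReport` or any mapping with
    ``dog_id`` and ``text``.  Empty or tail-free text matches nothing.
    """
    keywords = tuple(keyword_set)
    if not keywords:
        raise ValueError("keyword_set must be non-empty")
    if isinstance(report, IllnessReport):
        dog_id, text = report.dog_id, report.text
    else:
        dog_id, text = report["dog_id"], report["text"]
    low = (text or "").lower()
    has_tail = "tail" in low
    hits = tuple(k for k in keywords if k.lower() in low) if has_tail else ()
    matched = has_tail and bool(hits)
    return ScreenResult(
        dog_id=dog_id,
        matched=matched,
        matched_keywords=hits,
        needs_review=has_tail and not matched,
    )


@dataclass
class ScreeningSummary:
    results: pd.DataFrame  # per report: matched, needs_review, matched_keywords
    candidates: list[str]  # dogs with >= 1 candidate incident (after overrides)
    incident_counts: pd.Series  # incidents per candidate dog
    multiplicity: dict[int, int]  # incidents-per-dog -> number of dogs
    n_incidents: int
    n_dogs_vet_visit: int
    missed_by_vet: BinomialEstimate | None  # fraction of candidate dogs with no vet visit
    overrides_applied: dict[str, str] = field(default_factory=dict)

    @property
    def needs_review(self) -> pd.DataFrame:
        return self.results[self.results["needs_review"]]


def _normalise_overrides(overrides) -> dict[str, str]:
    if overrides is None:
        return {}
    if isinstance(overrides, pd.DataFrame):
        overrides = dict(zip(overrides["dog_id"], overrides["decision"]))
    out = {}
    for dog, decision in dict(overrides).items():
        if decision not in ("include", "exclude"):
            raise ValueError(f"override decision must be include/exclude, got {decision!r}")
        out[str(dog)] = decision
    return out


def screen_cohort(
    reports: pd.DataFrame,
    keyword_set: Iterable[str] = DEFAULT_KEYWORDS,
    overrides: Mapping[str, str] | pd.DataFrame | None = None,
    level: float = 0.95,
) -> ScreeningSummary:
    """Screen a reports table and summarise candidate incidents per dog.

    Matched reports of one dog sharing a report date collapse into one
    incident; reports on distinct dates count separately.  Overrides
    promote a dog from the review queue (``include``) or remove it
    (``exclude``).  The vet-visit summary estimates the fraction of
    candidate dogs a practice-records study would miss (no vet visit
    for any of the dog's candidate incidents), with an exact binomial CI.
    """
    ov = _normalise_overrides(overrides)
    if reports.empty:
        empty = pd.DataFrame(
            columns=["dog_id", "report_date", "matched", "needs_review",
                     "matched_keywords", "vet_visit"]
        )
        return ScreeningSummary(empty, [], pd.Series(dtype=int), {}, 0, 0, None, ov)

    res = []
    for rec in reports.to_dict("records"):
        r = screen_report(rec, keyword_set)
        res.append(
            {
                "dog_id": rec["dog_id"],
                "report_date": rec.get("report_date", ""),
                "matched": r.matched,
                "needs_review": r.needs_review,
                "matched_keywords": ";".join(r.matched_keywords),
                "vet_visit": bool(rec.get("vet_visit", False)),
            }
        )
    results = pd.DataFrame(res)

    include_dogs = {d for d, v in ov.items() if v == "include"}
    exclude_dogs = {d for d, v in ov.items() if v == "exclude"}
    is_candidate = results["matched"] | (
        results["needs_review"] & results["dog_id"].isin(include_dogs)
    )
    cand_rows = results[is_candidate & ~results["dog_id"].isin(exclude_dogs)]
    # one incident per (dog, date)
    incidents = cand_rows.drop_duplicates(["dog_id", "report_date"])
    counts = incidents.groupby("dog_id").size().sort_values(ascending=False)
    candidates = sorted(counts.index)
    multiplicity: dict[int, int] = (
        counts.value_counts().sort_index().to_dict() if len(counts) else {}
    )
    vet_by_dog = cand_rows.groupby("dog_id")["vet_visit"].any()
    n_vet = int(vet_by_dog.sum())
    missed = (
        clopper_pearson_ci(len(candidates) - n_vet, len(candidates), level)
        if candidates
        else None
    )
    return ScreeningSummary(
        results=results,
        candidates=candidates,
        incident_counts=counts,
        multiplicity={int(k): int(v) for k, v in multiplicity.items()},
        n_incidents=int(len(incidents)),
        n_dogs_vet_visit=n_vet,
        missed_by_vet=missed,
        overrides_applied=ov,
    )
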