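"""Rule-based risk-of-bias categorisation at the study level.

Studies start from a design-determined category — randomised: low; ITS
(controlled or not): moderate; non-randomised: high — and are dropped by one
level for every applicable domain judged "not done" and for every two
applicable domains judged "unclear" (complete pairs only; an odd leftover
"unclear" does not drop a level).  "Not applicable" domains are excluded
from both counts.  The scale is ordered low < moderate < high < very_high
with a floor at very_high: downgrading never improves a study and cannot
pass very_high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .study_db import RobDomainStatus, Study, StudyDatabase

LEVELS: tuple[str, ...] = ("low", "moderate", "high", "very_high")

_INITIAL = {
    "randomised": "low",
    "its": "moderate",
    "its_controlled": "moderate",
    "non_randomised": "high",
}


@dataclass(frozen=True)
class RobAssessment:
    initial_level: str
    n_not_done: int
    n_unclear: int
    final_level: str


def initial_category(design: str) -> str:
    """Design-based starting category (randomised -> low, ITS -> moderate,
    non-randomised -> high)."""
    try:
        return _INITIAL[design]
    except KeyError:
        raise ValueError(f"unknown study design {design!r}") from None


def downgrade(initial: str, domains: Iterable[RobDomainStatus]) -> RobAssessment:
    """Drop the category by one level per applicable 'not done' domain and
    per complete pair of applicable 'unclear' domains, clamped at very_high."""
    if initial not in LEVELS:
        raise ValueError(f"unknown risk-of-bias level {initial!r}")
    applicable = [d for d in domains if d.status != "not_applicable"]
    n_not_done = sum(d.status == "not_done" for d in applicable)
    n_unclear = sum(d.status == "unclear" for d in applicable)
    drops = n_not_done + n_unclear // 2
    final = LEVELS[min(LEVELS.index(initial) + drops, len(LEVELS) - 1)]
    return RobAssessment(initial, n_not_done, n_unclear, final)


def score_study(study: Study) -> RobAssessment:
    return downgrade(initial_category(study.design), study.rob_domains)


def score_database(db: StudyDatabase) -> pd.DataFrame:
    """Risk-of-bias table: one row per study with initial/final levels."""
    rows = []
    for study in db.iter_studies():
        a = score_study(study)
        rows.append(
            {
                "study_id": study.study_id,
                "initial_level": a.initial_level,
                "n_not_done": a.n_not_done,
                "n_unclear": a.n_unclear,
                "rob_level": a.final_level,
            }
        )
    return pd.DataFrame(rows, columns=["study_id", "initial_level", "n_not_done",
                                       "n_unclear", "rob_level"])
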