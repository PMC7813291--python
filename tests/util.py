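"""Hand-built database fixtures shared across the test modules."""

from __future__ import annotations

import pandas as pd

from hcpmeta.study_db import SCHEMA, StudyDatabase


def _frame(name: str, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    return df.reindex(columns=SCHEMA[name])


def study_row(study_id: str, **kw) -> dict:
    row = dict(study_id=study_id, design="randomised", cadre="professional",
               country_income="middle", strategy_start_month=0.0,
               publication_year=2010, is_equivalency=0, rob_domains="")
    row.update(kw)
    return row


def arm_row(arm_id: str, study_id: str, **kw) -> dict:
    row = dict(arm_id=arm_id, study_id=study_id, is_control=0, is_gold_standard=0)
    row.update(kw)
    return row


def attr_row(arm_id: str, **kw) -> dict:
    row = dict(arm_id=arm_id, duration_days=5.0, lecture="yes",
               interactive_discussion="no", clinical_practice="no",
               role_play="no", other_method="no", printed_materials="no",
               computers="no", group_size=15, topic_complexity="single",
               professional_trainers="no", content_expert_trainers="yes",
               onsite="all_offsite", multiple_sessions="no")
    row.update(kw)
    return row


def meas_row(outcome_id: str, study_id: str, arm_id: str, time_month: float,
             value: float, scale: str = "percentage",
             direction: str = "increase_improves", n: float = 100) -> dict:
    return dict(outcome_id=outcome_id, study_id=study_id, scale=scale,
                direction=direction, arm_id=arm_id, time_month=time_month,
                value=value, n=n)


def make_db(studies, arms, components=(), attributes=(), outcomes=(), costs=()) -> StudyDatabase:
    db = StudyDatabase(
        studies=_frame("studies", list(studies)),
        arms=_frame("arms", list(arms)),
        components=_frame("components", list(components)),
        attributes=_frame("attributes", list(attributes)),
        outcomes=_frame("outcomes", list(outcomes)),
        costs=_frame("costs", list(costs)),
    )
    return db


def one_study_db(baseline: float = 40.0, effect: float = 7.3,
                 followup: float = 4.0, control_change: float = 0.0) -> StudyDatabase:
    """One randomised in-service-training study with a single percentage
    outcome whose diff-in-diff effect size is exactly ``effect``."""
    sid, ia, ca = "S1", "S1_int", "S1_ctl"
    f_ctl = baseline + control_change
    f_int = baseline + control_change + effect
    return make_db(
        studies=[study_row(sid)],
        arms=[arm_row(ia, sid), arm_row(ca, sid, is_control=1)],
        components=[dict(arm_id=ia, component_code="group_inservice")],
        attributes=[attr_row(ia)],
        outcomes=[
            meas_row("o1", sid, ia, -1.0, baseline),
            meas_row("o1", sid, ca, -1.0, baseline),
            meas_row("o1", sid, ia, followup, f_int),
            meas_row("o1", sid, ca, followup, f_ctl),
        ],
    )
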