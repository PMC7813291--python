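"""Oriented percentage-point effect sizes for non-ITS study comparisons.

The effect size is an absolute %-point change, calculated so that positive
values indicate improvement.  For outcomes expressed as a percentage the
effect is a difference in differences of raw percentages when baselines
exist, or a follow-up difference otherwise.  For unbounded continuous
outcomes the effect is a difference in relative (percent) changes, which is
undefined when a required denominator is zero; such effect sizes are
excluded rather than erroring.

Measurement selection uses the baseline value closest in time to the start
of the strategy and the follow-up value furthest from it.  Percentage effect
sizes whose baseline is at or above the ceiling (default 95%) are excluded
because there is little room for improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import its_engine
from .study_db import StudyDatabase

logger = logging.getLogger("hcpmeta")

INCLUDED = "included"
EXCLUDED_CEILING = "excluded_ceiling"
EXCLUDED_UNDEFINED = "excluded_undefined"

CEILING_THRESHOLD = 95.0


@dataclass
class EffectSizeRecord:
    """One oriented effect size (or exclusion) for one outcome of a comparison."""

    comparison_id: str
    study_id: str
    outcome_id: str
    scale: str
    es_value: Optional[float]  # %-points; None unless status == included
    followup_month: Optional[float]  # time since strategy start of follow-up used
    baseline_level: Optional[float]  # intervention-arm baseline, raw scale (ceiling rule)
    status: str = INCLUDED
    reason: str = ""
    equation: str = ""
    #: baseline performance on the improvement-oriented scale (the modelling
    #: confounder): equals the raw baseline for increase-improves outcomes
    #: and 100 - baseline for percentage outcomes that decrease to improve
    baseline_performance: Optional[float] = None


# --------------------------------------------------------------------------
# Measurement selection
# --------------------------------------------------------------------------


def select_measurements(measurements: pd.DataFrame) -> tuple[Optional[pd.Series], pd.Series]:
    """Pick the analysis baseline and follow-up rows for one arm's series.

    Baseline is the pre-strategy measurement (``time_month < 0``) closest to
    the strategy start; follow-up is the measurement furthest in time
    (``time_month >= 0``).  Ties are broken by first row in file order with a
    warning.  Returns ``(None, followup)`` when no baseline exists; raises
    ``ValueError`` when there is no follow-up measurement.
    """
    t = measurements["time_month"].to_numpy(float)
    post_idx = np.flatnonzero(t >= 0)
    if post_idx.size == 0:
        raise ValueError("no follow-up measurement (time_month >= 0) for arm")

    def pick(idx: np.ndarray, label: str) -> pd.Series:
        best = t[idx].max()
        hits = idx[t[idx] == best]
        if hits.size > 1:
            logger.warning(
                "tie at %s time %.3g for outcome %s; using first row in file order",
                label, best, measurements.iloc[hits[0]]["outcome_id"],
            )
        return measurements.iloc[hits[0]]

    followup = pick(post_idx, "follow-up")
    pre_idx = np.flatnonzero(t < 0)
    baseline = pick(pre_idx, "baseline") if pre_idx.size else None
    return baseline, followup


# --------------------------------------------------------------------------
# The four effect-size forms
# --------------------------------------------------------------------------


def _check_baseline_presence(b_i, b_c):
    if (b_i is None) != (b_c is None):
        raise ValueError(
            "mixed baseline presence: both arms must have baselines or neither"
        )


def effect_size_percentage(
    b_i: Optional[float], f_i: float, b_c: Optional[float], f_c: float
) -> float:
    """%-point effect for a percentage outcome.

    With baselines: intervention improvement minus reference improvement,
    ``(f_i - b_i) - (f_c - b_c)``.  Without baselines: ``f_i - f_c``.
    """
    _check_baseline_presence(b_i, b_c)
    for v in (b_i, f_i, b_c, f_c):
        if v is not None and not (0.0 <= v <= 100.0):
            raise ValueError(f"percentage value {v} outside [0, 100]")
    if b_i is None:
        return float(f_i - f_c)
    return float((f_i - b_i) - (f_c - b_c))


def effect_size_continuous(
    b_i: Optional[float], f_i: float, b_c: Optional[float], f_c: float
) -> Optional[float]:
    """%-point effect for an unbounded continuous outcome.

    With baselines: ``100 * ((f_i - b_i)/b_i - (f_c - b_c)/b_c)``; undefined
    (returns ``None``) when either baseline is zero.  Without baselines:
    ``100 * (f_i - f_c)/f_c``; undefined when the reference follow-up is
    zero.  Undefined is a status (the record is excluded), not an error.
    """
    _check_baseline_presence(b_i, b_c)
    if b_i is None:
        if f_c == 0:
            return None
        return float(100.0 * (f_i - f_c) / f_c)
    if b_i == 0 or b_c == 0:
        return None
    return float(100.0 * ((f_i - b_i) / b_i - (f_c - b_c) / b_c))


def orient_effect(es: float, direction: str) -> float:
    """Sign effect sizes so positive always indicates improvement.

    Outcomes that decrease to indicate improvement are multiplied by -1.
    """
    if not np.isfinite(es):
        raise ValueError("effect size must be finite")
    if direction == "decrease_improves":
        return -es
    if direction == "increase_improves":
        return float(es)
    raise ValueError(f"unknown direction {direction!r}")


def apply_ceiling_exclusion(
    record: EffectSizeRecord,
    baseline_control: Optional[float] = None,
    rule: str = "intervention",
    threshold: float = CEILING_THRESHOLD,
) -> EffectSizeRecord:
    """Exclude percentage effect sizes with baseline at/above the ceiling.

    The rule tests the intervention-arm baseline by default; ``rule="either"``
    excludes when either arm's baseline reaches the threshold.  Continuous
    outcomes and records without baselines are unaffected.
    """
    if record.scale != "percentage" or record.status != INCLUDED:
        return record
    if record.baseline_level is None:
        return record
    trigger = record.baseline_level >= threshold
    other_high = baseline_control is not None and baseline_control >= threshold
    if rule == "either":
        trigger = trigger or other_high
    elif other_high and not trigger:
        logger.warning(
            "comparison %s outcome %s: reference-arm baseline %.1f >= %.0f but "
            "intervention-arm rule keeps the record",
            record.comparison_id, record.outcome_id, baseline_control, threshold,
        )
    if trigger:
        return replace(
            record,
            es_value=None,
            status=EXCLUDED_CEILING,
            reason=f"baseline {record.baseline_level:.1f} >= {threshold:g}%",
        )
    return record


# --------------------------------------------------------------------------
# Database-level orchestration
# --------------------------------------------------------------------------


def _value(row: Optional[pd.Series]) -> Optional[float]:
    return None if row is None else float(row["value"])


def compute_effects(
    db: StudyDatabase,
    comparisons: pd.DataFrame,
    ceiling_rule: str = "intervention",
) -> pd.DataFrame:
    """Compute one oriented effect size per (comparison, outcome).

    Non-ITS outcomes use the four closed-form effect-size equations after
    measurement selection; outcomes of ITS-design studies are delegated to
    the segmented-regression engine and use its summary effect.  Returns a
    table of :class:`EffectSizeRecord` fields with a ``status`` column;
    excluded records carry a machine-readable reason so that
    included + excluded counts always reconcile with the input.
    """
    records: list[EffectSizeRecord] = []
    designs = dict(zip(db.studies["study_id"].astype(str), db.studies["design"]))

    # index measurement rows once; the per-comparison loops below then touch
    # only small per-(outcome, arm) frames
    by_oa: dict[tuple[str, str], pd.DataFrame] = {
        (str(o), str(a)): g for (o, a), g in db.outcomes.groupby(
            ["outcome_id", "arm_id"], sort=False)
    }
    meta_by_oid = db.outcomes.drop_duplicates("outcome_id").set_index("outcome_id")
    oids_by_study = {
        str(s): list(dict.fromkeys(str(x) for x in g["outcome_id"]))
        for s, g in db.outcomes.groupby("study_id", sort=False)
    }

    for _, comp in comparisons.iterrows():
        study_id = str(comp["study_id"])
        cid = str(comp["comparison_id"])
        int_arm = str(comp["intervention_arm"])
        ref_arm = comp["reference_arm"]
        ref_arm = None if (ref_arm is None or ref_arm != ref_arm or ref_arm == "") else str(ref_arm)
        is_its = designs[study_id] in ("its", "its_controlled")

        for oid in oids_by_study.get(study_id, []):
            meta = meta_by_oid.loc[oid]
            scale, direction = meta["scale"], meta["direction"]
            m_int = by_oa.get((oid, int_arm))
            m_ref = None if ref_arm is None else by_oa.get((oid, ref_arm))
            if is_its:
                rec = _its_record(cid, study_id, oid, scale, direction, m_int, m_ref)
            else:
                rec = _non_its_record(cid, study_id, oid, scale, direction,
                                      m_int, m_ref, ceiling_rule)
            if rec is not None:
                records.append(rec)

    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["comparison_id", "study_id", "outcome_id", "scale", "es_value",
                               "followup_month", "baseline_level", "baseline_performance",
                               "status", "reason", "equation"])
    n_inc = int((df["status"] == INCLUDED).sum()) if len(df) else 0
    logger.info("effect sizes: %d total, %d included, %d excluded", len(df), n_inc, len(df) - n_inc)
    return df


def _non_its_record(cid, study_id, oid, scale, direction, m_int, m_ref, ceiling_rule):
    if m_int is None or m_int.empty or m_ref is None or m_ref.empty:
        return None
    b_i_row, f_i_row = select_measurements(m_int)
    b_c_row, f_c_row = select_measurements(m_ref)
    b_i, f_i = _value(b_i_row), _value(f_i_row)
    b_c, f_c = _value(b_c_row), _value(f_c_row)
    followup = float(f_i_row["time_month"])

    if scale == "percentage":
        es = effect_size_percentage(b_i, f_i, b_c, f_c)
        equation = "eq1" if b_i is not None else "eq2"
        baseline_level = b_i
    else:
        es = effect_size_continuous(b_i, f_i, b_c, f_c)
        equation = "eq3" if b_i is not None else "eq4"
        baseline_level = b_i
        if es is None:
            return EffectSizeRecord(
                cid, study_id, oid, scale, None, followup, baseline_level,
                status=EXCLUDED_UNDEFINED,
                reason="zero denominator in relative-change effect size",
                equation=equation,
            )

    rec = EffectSizeRecord(
        cid, study_id, oid, scale, orient_effect(es, direction), followup,
        baseline_level, status=INCLUDED, equation=equation,
        baseline_performance=_oriented_baseline(baseline_level, scale, direction),
    )
    if scale == "percentage":
        rec = apply_ceiling_exclusion(rec, baseline_control=b_c, rule=ceiling_rule)
    return rec


def _oriented_baseline(baseline, scale, direction):
    if baseline is None:
        return None
    if scale == "percentage" and direction == "decrease_improves":
        return 100.0 - baseline
    return baseline


def _its_record(cid, study_id, oid, scale, direction, m_int, m_ref):
    if m_int is None or m_int.empty:
        return None
    fit_int = its_engine.fit_segmented(
        m_int["time_month"].to_numpy(float), m_int["value"].to_numpy(float)
    )
    if m_ref is not None and not m_ref.empty:
        fit_ref = its_engine.fit_segmented(
            m_ref["time_month"].to_numpy(float), m_ref["value"].to_numpy(float)
        )
        es = its_engine.controlled_its_effect(fit_int, fit_ref)
    else:
        es = fit_int.summary_effect
    baseline_level = fit_int.beta0  # pre-trend level at strategy start
    rec = EffectSizeRecord(
        cid, study_id, oid, scale, orient_effect(es, direction),
        fit_int.midpoint_month, baseline_level, status=INCLUDED, equation="its",
        baseline_performance=_oriented_baseline(baseline_level, scale, direction),
    )
    if scale == "percentage":
        rec = apply_ceiling_exclusion(rec)
    return rec
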