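"""Classify arm strategies and enumerate typed study comparisons.

Five comparison types are analysed:

* ``T1`` — a training strategy alone versus a (no-intervention or placebo)
  control group;
* ``T2`` — one training strategy alone versus a different training strategy
  alone;
* ``T3`` — training combined with a specific group of other strategy
  components versus that same group of components alone (the marginal
  effect of training);
* ``T4`` — two different training strategies each combined with the same
  group of other components;
* ``T5`` — equivalency: a training strategy versus a gold-standard
  comparison group, where success is an effect size close to zero.

Printed materials bundled with a training course are not a separate
component (the strategy "training plus printed guideline" is "training
alone"), so standalone-printed-material codes are absorbed into the
training classification.  For T3/T4 the non-training component sets of the
two arms must be strictly identical.  Uncontrolled ITS studies emit a T1
comparison whose reference is the arm's own extended pre-trend (reference
arm empty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .study_db import (
    PLACEBO,
    TRAINING_CATEGORIES,
    Study,
    StudyArm,
    StudyDatabase,
)

logger = logging.getLogger("hcpmeta")

COMPARISON_TYPES = ("T1", "T2", "T3", "T4", "T5")

TYPE_LABELS = {
    "T1": "training_vs_control",
    "T2": "training_vs_training",
    "T3": "training_plus_x_vs_x",
    "T4": "trainingA_plus_x_vs_trainingB_plus_x",
    "T5": "equivalency",
}


class ClassificationConflictError(ValueError):
    """An arm is coded with two mutually exclusive training categories."""


@dataclass
class Comparison:
    comparison_id: str
    study_id: str
    intervention_arm: str
    reference_arm: Optional[str]  # None for uncontrolled ITS (pre-trend reference)
    comparison_type: str  # T1..T5
    training_category_int: Optional[str]
    training_category_ref: Optional[str]
    shared_components: frozenset[str]


def classify_training(arm: StudyArm) -> Optional[str]:
    """Return the arm's training category, or None for non-training arms.

    The five categories are mutually exclusive; two training codes on one
    arm raise :class:`ClassificationConflictError`.
    """
    cats = sorted(arm.components & set(TRAINING_CATEGORIES),
                  key=TRAINING_CATEGORIES.index)
    if len(cats) > 1:
        raise ClassificationConflictError(
            f"arm {arm.arm_id}: multiple training categories {cats}"
        )
    return cats[0] if cats else None


def nontraining_components(arm: StudyArm) -> frozenset[str]:
    """The arm's non-training component set, after absorbing bundled printed
    materials into a present training component and dropping placebo codes."""
    comps = set(arm.components) - set(TRAINING_CATEGORIES) - {PLACEBO}
    if classify_training(arm) is not None:
        comps -= {"printed_materials_standalone"}
    return frozenset(comps)


def _is_control(arm: StudyArm) -> bool:
    return arm.is_control or arm.components <= {PLACEBO}


def _pair_type(study: Study, a: StudyArm, b: StudyArm) -> Optional[tuple[str, StudyArm, StudyArm]]:
    """Type an unordered arm pair; returns (type, intervention, reference) or None."""
    ta, tb = classify_training(a), classify_training(b)
    xa, xb = nontraining_components(a), nontraining_components(b)

    # Equivalency: training arm versus a gold-standard reference.
    if study.is_equivalency:
        for trained, gold in ((a, b), (b, a)):
            if gold.is_gold_standard and classify_training(trained) is not None:
                return "T5", trained, gold
        return None

    for trained, other in ((a, b), (b, a)):
        t_cat = classify_training(trained)
        if t_cat is None:
            continue
        x_t = nontraining_components(trained)
        if _is_control(other):
            if not x_t:
                return "T1", trained, other
            continue
        o_cat = classify_training(other)
        x_o = nontraining_components(other)
        if o_cat is None:
            # training + X vs X: the same specific group of other components
            if x_t and x_t == x_o:
                return "T3", trained, other
            continue
        # both arms trained: require identical shared components and
        # different training categories
        if t_cat != o_cat and x_t == x_o:
            typ = "T2" if not x_t else "T4"
            # deterministic direction: canonical training-category order
            first, second = sorted(
                (trained, other), key=lambda arm: TRAINING_CATEGORIES.index(classify_training(arm))
            )
            return typ, first, second
    return None


def build_comparisons(study: Study, arms: list[StudyArm]) -> list[Comparison]:
    """Enumerate every valid typed comparison among a study's arms.

    All valid pairings are emitted (multi-arm studies can contribute several
    comparisons); arms whose non-training components differ beyond the
    training contrast produce no comparison.  Single-arm uncontrolled ITS
    studies emit one T1 comparison against the arm's own pre-trend.
    """
    out: list[Comparison] = []
    seen: set[tuple[str, str]] = set()

    if study.design == "its" and len(arms) == 1:
        arm = arms[0]
        cat = classify_training(arm)
        if cat is not None and not nontraining_components(arm):
            out.append(Comparison(
                comparison_id=f"{study.study_id}:{arm.arm_id}:pretrend",
                study_id=study.study_id,
                intervention_arm=arm.arm_id,
                reference_arm=None,
                comparison_type="T1",
                training_category_int=cat,
                training_category_ref=None,
                shared_components=frozenset(),
            ))
        return out

    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            typed = _pair_type(study, a, b)
            if typed is None:
                continue
            typ, trained, ref = typed
            key = (trained.arm_id, ref.arm_id)
            if key in seen or trained.arm_id == ref.arm_id:
                continue
            seen.add(key)
            out.append(Comparison(
                comparison_id=f"{study.study_id}:{trained.arm_id}:{ref.arm_id}",
                study_id=study.study_id,
                intervention_arm=trained.arm_id,
                reference_arm=ref.arm_id,
                comparison_type=typ,
                training_category_int=classify_training(trained),
                training_category_ref=classify_training(ref),
                shared_components=nontraining_components(trained)
                if typ in ("T3", "T4") else frozenset(),
            ))
    if not out:
        logger.warning("study %s: no valid comparison among %d arms",
                       study.study_id, len(arms))
    return out


def validate_comparison(comp: Comparison, arms_by_id: dict[str, StudyArm],
                        study: Study) -> bool:
    """Re-derive the comparison type from the arms and check it matches."""
    if comp.reference_arm is None:
        return comp.comparison_type == "T1"
    a = arms_by_id[comp.intervention_arm]
    b = arms_by_id[comp.reference_arm]
    typed = _pair_type(study, a, b)
    return typed is not None and typed[0] == comp.comparison_type and \
        typed[1].arm_id == comp.intervention_arm


def build_all_comparisons(db: StudyDatabase) -> pd.DataFrame:
    """Comparison table for a whole database (deterministic given the data)."""
    rows = []
    for study in db.iter_studies():
        arms = db.arms_of(study.study_id)
        for c in build_comparisons(study, arms):
            rows.append({
                "comparison_id": c.comparison_id,
                "study_id": c.study_id,
                "intervention_arm": c.intervention_arm,
                "reference_arm": "" if c.reference_arm is None else c.reference_arm,
                "comparison_type": c.comparison_type,
                "training_category_int": c.training_category_int or "",
                "training_category_ref": c.training_category_ref or "",
                "shared_components": "|".join(sorted(c.shared_components)),
            })
    return pd.DataFrame(rows, columns=[
        "comparison_id", "study_id", "intervention_arm", "reference_arm",
        "comparison_type", "training_category_int", "training_category_ref",
        "shared_components",
    ])
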