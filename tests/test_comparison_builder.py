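"""Arm classification and typed comparison enumeration."""

import pytest

from hcpmeta.comparison_builder import (
    ClassificationConflictError,
    build_all_comparisons,
    build_comparisons,
    classify_training,
    nontraining_components,
    validate_comparison,
)
from hcpmeta.study_db import StudyArm
from util import arm_row, attr_row, make_db, meas_row, study_row


def _arm(arm_id, components, is_control=False, gold=False):
    return StudyArm(arm_id=arm_id, study_id="S", components=frozenset(components),
                    is_control=is_control, is_gold_standard=gold)


def _study(**kw):
    db = make_db(studies=[study_row("S", **kw)], arms=[arm_row("x", "S", is_control=1)],
                 outcomes=[meas_row("o", "S", "x", 1.0, 50.0)])
    return db.study("S")


class TestClassification:
    def test_printed_materials_are_absorbed_into_training(self):
        arm = _arm("a", {"group_inservice", "printed_materials_standalone"})
        assert classify_training(arm) == "group_inservice"
        assert nontraining_components(arm) == frozenset()

    def test_empty_arm_has_no_training(self):
        assert classify_training(_arm("a", set())) is None

    def test_training_plus_other_component(self):
        arm = _arm("a", {"eov", "supervision"})
        assert classify_training(arm) == "eov"
        assert nontraining_components(arm) == frozenset({"supervision"})

    def test_two_training_categories_conflict(self):
        with pytest.raises(ClassificationConflictError):
            classify_training(_arm("a", {"eov", "group_inservice"}))

    def test_standalone_printed_materials_remain_a_component(self):
        arm = _arm("a", {"printed_materials_standalone"})
        assert classify_training(arm) is None
        assert nontraining_components(arm) == frozenset({"printed_materials_standalone"})


class TestPairEnumeration:
    def test_training_versus_control_is_t1(self):
        comps = build_comparisons(_study(), [
            _arm("t", {"group_inservice"}), _arm("c", set(), is_control=True)])
        (c,) = comps
        assert c.comparison_type == "T1"
        assert c.intervention_arm == "t" and c.reference_arm == "c"

    def test_training_plus_x_versus_x_is_t3(self):
        comps = build_comparisons(_study(), [
            _arm("t", {"eov", "supervision"}), _arm("r", {"supervision"})])
        (c,) = comps
        assert c.comparison_type == "T3"
        assert c.shared_components == frozenset({"supervision"})

    def test_three_arms_give_two_t1_and_one_t2(self):
        comps = build_comparisons(_study(), [
            _arm("a", {"group_inservice"}), _arm("b", {"self_study"}),
            _arm("c", set(), is_control=True)])
        types = sorted(c.comparison_type for c in comps)
        assert types == ["T1", "T1", "T2"]
        t2 = next(c for c in comps if c.comparison_type == "T2")
        # canonical direction: in-service training precedes self-study
        assert t2.training_category_int == "group_inservice"
        assert t2.training_category_ref == "self_study"

    def test_same_shared_components_required_for_t4(self):
        comps = build_comparisons(_study(), [
            _arm("a", {"eov", "supervision"}),
            _arm("b", {"group_inservice", "supervision"})])
        (c,) = comps
        assert c.comparison_type == "T4"
        assert c.shared_components == frozenset({"supervision"})

    def test_differing_shared_components_yield_nothing(self):
        comps = build_comparisons(_study(), [
            _arm("a", {"eov", "supervision"}),
            _arm("b", {"group_inservice", "ict"})])
        assert comps == []

    def test_equivalency_study_emits_t5(self):
        comps = build_comparisons(_study(is_equivalency=1), [
            _arm("t", {"group_inservice"}), _arm("g", set(), is_control=True, gold=True)])
        (c,) = comps
        assert c.comparison_type == "T5"
        assert c.reference_arm == "g"

    def test_no_self_pairing(self):
        comps = build_comparisons(_study(), [
            _arm("a", {"group_inservice"}), _arm("c", set(), is_control=True)])
        assert all(c.intervention_arm != c.reference_arm for c in comps)


class TestUncontrolledIts:
    def test_single_arm_its_compares_against_pretrend(self):
        db = make_db(
            studies=[study_row("S", design="its")],
            arms=[arm_row("a", "S")],
            components=[dict(arm_id="a", component_code="eov")],
            attributes=[attr_row("a")],
            outcomes=[meas_row("o", "S", "a", float(t), 50.0)
                      for t in range(-4, 5)],
        )
        comps = build_comparisons(db.study("S"), db.arms_of("S"))
        (c,) = comps
        assert c.comparison_type == "T1" and c.reference_arm is None


def test_generated_comparisons_revalidate(small_noisy_db):
    """Every emitted comparison satisfies its own type predicate."""
    db, _ = small_noisy_db
    table = build_all_comparisons(db)
    assert len(table) == len(db.studies)  # one comparison per generated study
    for _, r in table.iterrows():
        study = db.study(str(r["study_id"]))
        arms = {a.arm_id: a for a in db.arms_of(study.study_id)}
        from hcpmeta.comparison_builder import Comparison
        comp = Comparison(
            comparison_id=r["comparison_id"], study_id=r["study_id"],
            intervention_arm=r["intervention_arm"],
            reference_arm=r["reference_arm"] or None,
            comparison_type=r["comparison_type"],
            training_category_int=r["training_category_int"] or None,
            training_category_ref=r["training_category_ref"] or None,
            shared_components=frozenset(
                s for s in str(r["shared_components"]).split("|") if s),
        )
        assert validate_comparison(comp, arms, study)
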