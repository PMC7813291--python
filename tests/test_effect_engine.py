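"""Effect-size equations, orientation, measurement selection, ceiling rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcpmeta.effect_engine import (
    EXCLUDED_CEILING,
    EffectSizeRecord,
    apply_ceiling_exclusion,
    compute_effects,
    effect_size_continuous,
    effect_size_percentage,
    orient_effect,
    select_measurements,
)
from hcpmeta.comparison_builder import build_all_comparisons
from util import meas_row, one_study_db

pct = st.floats(min_value=0, max_value=100, allow_nan=False)
real = st.floats(min_value=-1e3, max_value=1e3, allow_nan=False)


class TestPercentageEquations:
    @pytest.mark.parametrize("b_i,f_i,b_c,f_c,expected", [
        (40, 60, 40, 45, 15.0),     # diff-in-diff hand oracle
        (10, 10, 90, 90, 0.0),      # no change in either arm
        (0, 100, 0, 0, 100.0),
        (None, 55, None, 45, 10.0),  # no-baseline follow-up difference
    ])
    def test_hand_oracles(self, b_i, f_i, b_c, f_c, expected):
        assert effect_size_percentage(b_i, f_i, b_c, f_c) == pytest.approx(expected)

    def test_mixed_baseline_presence_is_an_error(self):
        with pytest.raises(ValueError, match="mixed baseline"):
            effect_size_percentage(40.0, 60.0, None, 45.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            effect_size_percentage(40.0, 104.0, 40.0, 45.0)

    @given(b_i=pct, f_i=pct, b_c=pct, f_c=pct)
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_under_arm_exchange(self, b_i, f_i, b_c, f_c):
        es = effect_size_percentage(b_i, f_i, b_c, f_c)
        assert effect_size_percentage(b_c, f_c, b_i, f_i) == pytest.approx(-es)

    @given(b_i=st.floats(10, 40), f_i=st.floats(10, 40), b_c=st.floats(10, 40),
           f_c=st.floats(10, 40), c=st.floats(-10, 10))
    @settings(max_examples=100, derandomize=True)
    def test_translation_invariance_of_diff_in_diff(self, b_i, f_i, b_c, f_c, c):
        es = effect_size_percentage(b_i, f_i, b_c, f_c)
        shifted = effect_size_percentage(b_i + c, f_i + c, b_c + c, f_c + c)
        assert shifted == pytest.approx(es, abs=1e-9)


class TestContinuousEquations:
    @pytest.mark.parametrize("b_i,f_i,b_c,f_c,expected", [
        (2, 3, 2, 2, 50.0),         # 100*(0.5 - 0)
        (5, 5, 7, 7, 0.0),          # no change in either arm
        (None, 12, None, 10, 20.0),  # 100*(12-10)/10
    ])
    def test_hand_oracles(self, b_i, f_i, b_c, f_c, expected):
        assert effect_size_continuous(b_i, f_i, b_c, f_c) == pytest.approx(expected)

    @pytest.mark.parametrize("b_i,f_i,b_c,f_c", [
        (0.0, 3.0, 2.0, 2.0),   # intervention baseline zero
        (2.0, 3.0, 0.0, 2.0),   # reference baseline zero
        (None, 3.0, None, 0.0),  # reference follow-up zero, no baselines
    ])
    def test_zero_denominator_is_undefined_not_error(self, b_i, f_i, b_c, f_c):
        assert effect_size_continuous(b_i, f_i, b_c, f_c) is None

    def test_matches_percentage_equation_when_baselines_are_100(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            f_i, f_c = rng.uniform(0, 100, 2)
            eq3 = effect_size_continuous(100.0, f_i, 100.0, f_c)
            eq1 = effect_size_percentage(100.0, f_i, 100.0, f_c)
            assert eq3 == pytest.approx(eq1, abs=1e-9)


class TestOrientation:
    def test_decreasing_outcomes_flip_sign(self):
        assert orient_effect(-4.0, "decrease_improves") == 4.0
        assert orient_effect(0.0, "decrease_improves") == 0.0

    @given(real)
    @settings(max_examples=50, derandomize=True)
    def test_double_flip_is_identity(self, es):
        once = orient_effect(es, "decrease_improves")
        assert orient_effect(once, "decrease_improves") == pytest.approx(es)


class TestMeasurementSelection:
    def _frame(self, times):
        return pd.DataFrame([meas_row("o", "S", "a", t, 50.0) for t in times])

    def test_closest_baseline_furthest_followup(self):
        b, f = select_measurements(self._frame([-6, -1, 3, 9]))
        assert b["time_month"] == -1
        assert f["time_month"] == 9

    def test_no_baseline_returns_none(self):
        b, f = select_measurements(self._frame([2]))
        assert b is None and f["time_month"] == 2

    def test_no_followup_is_an_error(self):
        with pytest.raises(ValueError, match="no follow-up"):
            select_measurements(self._frame([-3, -1]))

    def test_tie_takes_first_row_in_file_order(self):
        df = self._frame([-2, -2, 5])
        df.loc[0, "value"] = 10.0
        df.loc[1, "value"] = 20.0
        b, _ = select_measurements(df)
        assert b["value"] == 10.0


class TestCeilingRule:
    def _rec(self, baseline, scale="percentage"):
        return EffectSizeRecord("c", "s", "o", scale, 5.0, 4.0, baseline)

    def test_boundary_95_is_excluded(self):
        rec = apply_ceiling_exclusion(self._rec(95.0))
        assert rec.status == EXCLUDED_CEILING and rec.es_value is None
        assert "95.0" in rec.reason

    def test_just_below_boundary_is_included(self):
        assert apply_ceiling_exclusion(self._rec(94.9)).status == "included"

    def test_continuous_scale_is_out_of_scope(self):
        assert apply_ceiling_exclusion(self._rec(99.0, scale="continuous")).status == "included"

    def test_either_arm_rule_checks_reference_baseline(self):
        rec = apply_ceiling_exclusion(self._rec(50.0), baseline_control=96.0,
                                      rule="either")
        assert rec.status == EXCLUDED_CEILING
        kept = apply_ceiling_exclusion(self._rec(50.0), baseline_control=96.0)
        assert kept.status == "included"


class TestDatabaseOrchestration:
    def test_single_study_effect(self):
        db = one_study_db(baseline=40.0, effect=7.3)
        comps = build_all_comparisons(db)
        es = compute_effects(db, comps)
        assert len(es) == 1
        assert es.loc[0, "es_value"] == pytest.approx(7.3)
        assert es.loc[0, "equation"] == "eq1"
        assert es.loc[0, "followup_month"] == 4.0

    def test_filter_conservation_against_truth(self, small_noisy_db):
        """Included + excluded counts reconcile with the generated outcomes
        that reach a valid comparison."""
        db, truth = small_noisy_db
        es = compute_effects(db, build_all_comparisons(db))
        assert len(es) == len(truth.outcomes)
        n_inc = (es["status"] == "included").sum()
        n_exc = es["status"].str.startswith("excluded").sum()
        assert n_inc + n_exc == len(es)
        assert (es.loc[es["status"] != "included", "reason"] != "").all()
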