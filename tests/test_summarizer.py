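"""MES collapsing and stratified distribution summaries."""

import numpy as np
import pandas as pd
import pytest

from hcpmeta.summarizer import (
    collapse_mes,
    cost_summary,
    equivalency_summary,
    rob_sensitivity,
    summarize_strata,
)
from util import arm_row, make_db, study_row


def _effects(values, comparison_id="c1", scale="percentage"):
    return pd.DataFrame({
        "comparison_id": comparison_id,
        "study_id": "s1",
        "outcome_id": [f"o{i}" for i in range(len(values))],
        "scale": scale,
        "es_value": values,
        "status": "included",
    })


def _comparisons(cid="c1", ctype="T1"):
    return pd.DataFrame({
        "comparison_id": [cid], "study_id": ["s1"], "comparison_type": [ctype],
        "training_category_int": ["group_inservice"],
        "training_category_ref": [""],
    })


class TestCollapseMes:
    @pytest.mark.parametrize("values,expected", [
        ([3, 7, 20], 7.0),
        ([5.5], 5.5),
        ([1, 2, 3, 10], 2.5),  # mean of middle two for even counts
    ])
    def test_median_of_included_effects(self, values, expected):
        mes = collapse_mes(_effects(values), _comparisons())
        assert mes.loc[0, "mes"] == pytest.approx(expected)
        assert mes.loc[0, "n_effect_sizes"] == len(values)

    def test_replicating_the_effect_list_leaves_mes_unchanged(self):
        base = collapse_mes(_effects([1, 4, 9]), _comparisons()).loc[0, "mes"]
        tripled = collapse_mes(_effects([1, 4, 9] * 3), _comparisons()).loc[0, "mes"]
        assert tripled == base

    def test_excluded_effects_never_contribute(self):
        df = _effects([1.0, 50.0])
        df.loc[1, "status"] = "excluded_ceiling"
        mes = collapse_mes(df, _comparisons())
        assert mes.loc[0, "mes"] == 1.0 and mes.loc[0, "n_effect_sizes"] == 1

    def test_comparison_with_no_included_effects_is_dropped(self):
        df = _effects([2.0])
        df["status"] = "excluded_undefined"
        assert collapse_mes(df, _comparisons()).empty


class TestStratifiedSummaries:
    def _mes(self, values, **cols):
        df = pd.DataFrame({
            "comparison_id": [f"c{i}" for i in range(len(values))],
            "study_id": "s", "scale": "percentage", "mes": values,
            "n_effect_sizes": 1, "comparison_type": "T1",
            "training_category_int": "group_inservice",
            "training_category_ref": "", "cadre": "professional",
            "rob_level": "low",
        })
        for k, v in cols.items():
            df[k] = v
        return df

    def test_quantiles_match_linear_interpolation_oracle(self):
        vals = [1.0, 2.0, 4.0, 8.0, 16.0]
        row = summarize_strata(self._mes(vals)).iloc[0]
        assert row["median_mes"] == np.quantile(vals, 0.5)
        assert row["q1"] == np.quantile(vals, 0.25)
        assert row["q3"] == np.quantile(vals, 0.75)
        assert (row["min"], row["max"]) == (1.0, 16.0)
        assert row["n_rob_low"] == 5

    def test_permutation_invariance(self):
        vals = list(np.random.default_rng(2).uniform(-20, 60, 9))
        a = summarize_strata(self._mes(vals))
        b = summarize_strata(self._mes(vals[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_shift_equivariance(self):
        vals = [0.0, 3.0, 5.0, 9.0]
        a = summarize_strata(self._mes(vals)).iloc[0]
        b = summarize_strata(self._mes([v + 10 for v in vals])).iloc[0]
        for col in ("median_mes", "q1", "q3", "min", "max"):
            assert b[col] == pytest.approx(a[col] + 10)

    def test_sparse_strata_suppress_iqr_and_single_suppresses_range(self):
        two = summarize_strata(self._mes([4.6, 14.0])).iloc[0]
        assert np.isnan(two["q1"]) and np.isnan(two["q3"])
        assert two["median_mes"] == pytest.approx(9.3)
        assert (two["min"], two["max"]) == (4.6, 14.0)
        one = summarize_strata(self._mes([4.0])).iloc[0]
        assert one["median_mes"] == 4.0
        assert np.isnan(one["min"]) and np.isnan(one["max"])

    def test_equivalency_comparisons_are_kept_apart(self):
        df = pd.concat([self._mes([5.0, 6.0, 7.0]),
                        self._mes([0.5], comparison_type="T5")],
                       ignore_index=True)
        pooled = summarize_strata(df)
        assert pooled["n_comparisons"].sum() == 3
        eq = equivalency_summary(df)
        assert len(eq) == 1 and eq.loc[0, "abs_mes"] == 0.5

    def test_rob_split_partitions_the_stratum(self):
        df = self._mes([1.0, 2.0, 3.0, 4.0])
        df.loc[2:, "rob_level"] = "very_high"
        split = rob_sensitivity(df)
        assert split["n_comparisons"].sum() == len(df)
        groups = dict(zip(split["rob_group"], split["median_mes"]))
        assert groups["low_moderate"] == pytest.approx(1.5)
        assert groups["high_very_high"] == pytest.approx(3.5)


class TestCostSummary:
    def _db(self, costs):
        studies = [study_row(f"S{i}", country_income="low" if i % 3 == 0 else "middle")
                   for i in range(len(costs))]
        arms = [arm_row(f"a{i}", f"S{i}", is_control=1) for i in range(len(costs))]
        cost_rows = [dict(arm_id=f"a{i}", total_cost_usd=c[0],
                          n_hcps_trained=c[1], duration_days=c[2])
                     for i, c in enumerate(costs)]
        return make_db(studies=studies, arms=arms, costs=cost_rows)

    def test_single_record_arithmetic(self):
        db = self._db([(1000.0, 10, 5.0)])
        row = cost_summary(db).iloc[0]
        assert row["median_mes"] == pytest.approx(20.0)

    def test_quartiles_match_sort_oracle_on_fifteen_records(self):
        rng = np.random.default_rng(9)
        per_day = rng.uniform(1, 95, 15)
        costs = [(p * 10 * 4.0, 10, 4.0) for p in per_day]
        row = cost_summary(self._db(costs)).iloc[0]
        assert row["median_mes"] == pytest.approx(np.quantile(per_day, 0.5))
        assert row["q1"] == pytest.approx(np.quantile(per_day, 0.25))
        assert row["q3"] == pytest.approx(np.quantile(per_day, 0.75))
        assert row["min"] == pytest.approx(per_day.min())
        assert row["max"] == pytest.approx(per_day.max())

    def test_income_stratification(self):
        db = self._db([(100.0, 1, 1.0)] * 6)
        rows = cost_summary(db, strata=("country_income",))
        assert set(rows["country_income"]) == {"low", "middle"}
        assert rows["n_comparisons"].sum() == 6
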