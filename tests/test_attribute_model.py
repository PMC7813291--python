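"""Tier filters, mixed-model estimation, waning extrapolation, head-to-head."""

import numpy as np
import pandas as pd
import pytest

from hcpmeta import (
    GeneratorConfig,
    build_all_comparisons,
    compute_effects,
    generate_database,
)
from hcpmeta.attribute_model import (
    EmptyModelDatabaseError,
    ModelFit,
    ModelSpec,
    TIERS,
    build_model_database,
    fit_random_effects,
    head_to_head_summary,
    waning_time,
)


@pytest.fixture(scope="module")
def pipeline_150():
    cfg = GeneratorConfig(n_studies=150, seed=77)
    db, truth = generate_database(cfg)
    comps = build_all_comparisons(db)
    es = compute_effects(db, comps)
    return db, truth, comps, es


class TestModelDatabase:
    def test_tier_tables_are_nested(self, pipeline_150):
        db, _, comps, es = pipeline_150
        keys = {}
        for tier in TIERS:
            t = build_model_database(db, es, comps, tier=tier)
            keys[tier] = set(zip(t["comparison_id"], t["outcome_id"]))
        assert keys["training_alone"] <= keys["training_pm_supervision"]
        assert keys["training_pm_supervision"] <= keys["training_any_components"]

    def test_long_duration_studies_are_excluded(self, pipeline_150):
        db, _, comps, es = pipeline_150
        t = build_model_database(db, es, comps, tier="training_any_components")
        dur = pd.to_numeric(t["duration_days"], errors="coerce")
        assert ((dur < 20) | dur.isna()).all()
        # the generator's duration distribution produces >=20-day courses,
        # so the filter is actually exercised
        all_durations = [a.training_attributes.duration_days
                         for sid in db.studies["study_id"].astype(str)
                         for a in db.arms_of(sid)
                         if a.training_attributes and a.training_attributes.duration_days]
        assert max(all_durations) >= 20

    def test_percentage_and_professional_only(self, pipeline_150):
        db, _, comps, es = pipeline_150
        t = build_model_database(db, es, comps, tier="training_any_components")
        cadres = dict(zip(db.studies["study_id"].astype(str), db.studies["cadre"]))
        assert all(cadres[s] == "professional" for s in t["study_id"].astype(str))

    def test_training_alone_tier_excludes_shared_components(self, pipeline_150):
        db, _, comps, es = pipeline_150
        t = build_model_database(db, es, comps, tier="training_alone")
        assert (t["supervision"] == 0).all()
        comp_cols = [c for c in t.columns if c.startswith("component_")]
        assert (t[comp_cols].to_numpy() == 0).all()

    def test_empty_result_names_the_filter(self, pipeline_150):
        db, _, comps, es = pipeline_150
        continuous_only = es[es["scale"] == "continuous"]
        with pytest.raises(EmptyModelDatabaseError, match="percentage"):
            build_model_database(db, continuous_only, comps)


class TestMixedModel:
    def test_noiseless_recovery_is_near_exact(self):
        """Deterministic data generated with onsite +8 and clinical practice
        +7 recover the configured coefficients to numerical tolerance."""
        cfg = GeneratorConfig(
            n_studies=80, seed=31,
            within_study_sd=0.0, between_study_sd=0.0, measurement_noise_sd=0.0,
            waning_slope=0.0, baseline_gradient=-0.13,
            prop_no_baseline=0.0, prop_onsite_missing=0.0,
            prop_duration_missing=0.0, control_drift_sd=0.0,
            baseline_mean=40.0, baseline_sd=8.0,
        )
        db, _ = generate_database(cfg)
        comps = build_all_comparisons(db)
        es = compute_effects(db, comps)
        table = build_model_database(db, es, comps, tier="training_any_components")
        fit = fit_random_effects(table, ModelSpec(
            tier="training_any_components",
            covariates=("onsite", "clinical_practice")))
        assert fit.params["onsite_yes"] == pytest.approx(8.0, abs=1e-5)
        assert fit.params["clinical_practice_yes"] == pytest.approx(7.0, abs=1e-5)
        assert fit.params["baseline_level"] == pytest.approx(-0.13, abs=1e-5)
        assert fit.params["time_since_training"] == pytest.approx(0.0, abs=1e-5)

    def test_intercept_only_limit_matches_mean(self):
        rng = np.random.default_rng(5)
        n = 60
        table = pd.DataFrame({
            "es": rng.normal(7.0, 2.0, n),
            "study_id": [f"s{i}" for i in range(n)],
            "comparison_id": "c", "outcome_id": [f"o{i}" for i in range(n)],
            "time_since_training": 0.0, "baseline_level": 50.0,
            "duration_days": 5.0, "n_methods": 1, "group_size": 10,
            "topic_complexity": "single", "supervision": 0,
        })
        fit = fit_random_effects(table, ModelSpec(covariates=(),
                                                  adjust_components=False))
        assert fit.params["intercept"] == pytest.approx(table["es"].mean(), abs=1e-6)

    def test_single_outcome_per_study_equals_ols(self):
        """With one observation per group and no between-study signal the
        mixed model collapses to ordinary least squares."""
        rng = np.random.default_rng(8)
        n = 80
        x = rng.random(n) < 0.5
        t = rng.uniform(1, 8, n)
        y = 5.0 + 4.0 * x + 0.3 * t + rng.normal(0, 2, n)
        table = pd.DataFrame({
            "es": y, "study_id": [f"s{i}" for i in range(n)],
            "comparison_id": "c", "outcome_id": [f"o{i}" for i in range(n)],
            "time_since_training": t, "baseline_level": 50.0,
            "duration_days": 5.0, "n_methods": 1, "group_size": 10,
            "topic_complexity": "single", "supervision": 0,
            "onsite": np.where(x, "some_or_all_onsite", "all_offsite"),
        })
        fit = fit_random_effects(table, ModelSpec(covariates=("onsite",),
                                                  adjust_components=False))
        X = np.column_stack([np.ones(n), t, x.astype(float)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.params["intercept"] == pytest.approx(beta[0], abs=1e-6)
        assert fit.params["time_since_training"] == pytest.approx(beta[1], abs=1e-6)
        assert fit.params["onsite_yes"] == pytest.approx(beta[2], abs=1e-6)

    def test_adjusted_r2_definition(self, pipeline_150):
        db, _, comps, es = pipeline_150
        table = build_model_database(db, es, comps, tier="training_any_components")
        fit = fit_random_effects(table, ModelSpec(
            tier="training_any_components",
            covariates=("onsite", "clinical_practice")))
        r2 = np.corrcoef(fit.observed, fit.fixed_pred)[0, 1] ** 2
        n, p = fit.n_effect_sizes, len(fit.params) - 1
        assert fit.adjusted_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - p - 1))
        assert -1.0 <= fit.adjusted_r2 <= 1.0
        assert fit.n_effect_sizes >= fit.n_studies


class TestWaning:
    def _fit_stub(self, slope, effect_at_zero, mean_time=4.0):
        params = pd.Series({"intercept": effect_at_zero,
                            "time_since_training": slope})
        pred = effect_at_zero + slope * np.full(10, mean_time)
        return ModelFit(params=params, bse=params * 0, pvalues=params * 0,
                        re_var=0, resid_var=1, r2=0, adjusted_r2=0,
                        n_studies=10, n_effect_sizes=10,
                        spec=ModelSpec(), fixed_pred=pred,
                        observed=pred, mean_time=mean_time)

    def test_linear_extrapolation_arithmetic(self):
        assert waning_time(self._fit_stub(-1.0, 20.0)) == pytest.approx(20.0)

    def test_non_negative_slope_means_no_waning(self):
        assert waning_time(self._fit_stub(0.2, 20.0)) is None
        assert waning_time(self._fit_stub(0.0, 20.0)) is None

    def test_recovery_of_configured_waning_horizon(self):
        """Configured waning of -0.9 %-points/month with a mean effect of
        about 18 at time zero extrapolates to roughly 20 months."""
        cfg = GeneratorConfig(n_studies=400, seed=19, effect_median=14.4,
                              within_study_sd=2.0, between_study_sd=4.0,
                              measurement_noise_sd=0.5,
                              attribute_effects={}, baseline_gradient=0.0)
        db, _ = generate_database(cfg)
        comps = build_all_comparisons(db)
        es = compute_effects(db, comps)
        table = build_model_database(db, es, comps, tier="training_any_components")
        fit = fit_random_effects(table, ModelSpec(
            tier="training_any_components", covariates=()))
        months = waning_time(fit)
        assert months == pytest.approx(20.0, abs=3.0)


class TestHeadToHead:
    def test_direct_evidence_table(self):
        head = pd.DataFrame({
            "attribute": ["duration", "group_size", "duration"],
            "mes": [4.6, 5.3, 14.0],
        })
        out = head_to_head_summary(head, attributes=["duration", "group_size",
                                                     "onsite"])
        by = out.set_index("attribute")
        assert by.loc["duration", "median_mes"] == pytest.approx(9.3)
        assert by.loc["group_size", "median_mes"] == pytest.approx(5.3)
        assert by.loc["onsite", "direct_evidence"] == "none"
        assert by.loc["onsite", "n_comparisons"] == 0
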