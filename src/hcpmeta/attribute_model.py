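"""Random-effects modelling of training attributes on outcome-level effects.

The dependent variable is the outcome-specific %-point effect size (effects
from the same study are *not* collapsed to a median here).  A linear mixed
model with a study-level random intercept, estimated by restricted maximum
likelihood on unweighted observations, accounts for the clustering of
multiple outcomes within a study.  Modelling is restricted to percentage
outcomes from professional-HCP studies of group in-service training with
duration under 20 days (studies with missing duration are retained via an
indicator), over three nested databases:

* ``training_alone`` — training versus a no-intervention control;
* ``training_pm_supervision`` — training with or without supervision;
* ``training_any_components`` — training with or without any other
  component, adjusted by presence indicators for the eleven non-training
  component categories (a deliberately simple adjustment).

Confounders (baseline performance level, time since training) are always
included.  Missing continuous covariates are zero-filled with an indicator;
missing categorical attributes get an explicit "missing" level, so rows are
never dropped for missingness.  No multiple-testing adjustment is applied:
p-values are hypothesis-screening quantities, and are labelled as such in
the output.

The reported adjusted R-squared uses the squared correlation between the
observed effects and the fixed-effects-only predictions,
``adj = 1 - (1 - R^2) (n - 1)/(n - p - 1)`` with ``n`` effect sizes and
``p`` fixed covariates (a documented convention: the mixed-model R-squared
is not otherwise defined).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .study_db import OTHER_CATEGORIES, StudyDatabase

logger = logging.getLogger("hcpmeta")

TIERS = ("training_alone", "training_pm_supervision", "training_any_components")

BASELINE_CENTER = 50.0  # %-points; centring constant for baseline performance

#: Box-style attribute covariates the design-matrix builder understands.
SUPPORTED_COVARIATES = (
    "duration",
    "n_methods",
    "lecture",
    "interactive_discussion",
    "clinical_practice",
    "role_play",
    "other_method",
    "printed_materials",
    "computers",
    "group_size",
    "topic_complexity",
    "professional_trainers",
    "content_expert_trainers",
    "onsite",
    "multiple_sessions",
    "supervision",
)


class EmptyModelDatabaseError(ValueError):
    """Every row was removed; the message names the responsible filter."""


class ModelFitError(RuntimeError):
    """The mixed-model optimiser failed to converge."""


# --------------------------------------------------------------------------
# Modelling table
# --------------------------------------------------------------------------


def build_model_database(
    db: StudyDatabase,
    effects: pd.DataFrame,
    comparisons: pd.DataFrame,
    tier: str = "training_any_components",
    training_category: str = "group_inservice",
    max_duration_days: float = 20.0,
) -> pd.DataFrame:
    """One row per included outcome-level effect size eligible for the tier.

    Filters: included effects only; percentage outcomes; professional-HCP
    studies; intervention training category (group in-service by default);
    training duration under ``max_duration_days`` or missing; and the tier's
    restriction on the non-training components shared by both arms.
    Attribute covariates of the intervention arm and shared-component
    indicators are joined in.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")

    df = effects[effects["status"] == "included"].merge(
        comparisons, on=["comparison_id", "study_id"], how="inner"
    )

    def narrow(mask: pd.Series, rule: str) -> pd.DataFrame:
        nonlocal df
        df = df[mask]
        if df.empty:
            raise EmptyModelDatabaseError(f"no rows left after filter: {rule}")
        return df

    narrow(df["scale"] == "percentage", "percentage outcomes only")
    cadres = dict(zip(db.studies["study_id"].astype(str), db.studies["cadre"]))
    narrow(df["study_id"].map(cadres) == "professional", "professional cadre only")
    narrow(df["training_category_int"] == training_category,
           f"intervention training category == {training_category}")

    shared = df["shared_components"].fillna("").map(
        lambda s: frozenset(s.split("|")) - {""}
    )
    if tier == "training_alone":
        narrow((df["comparison_type"] == "T1") & (shared.loc[df.index].map(len) == 0),
               "tier training_alone: training versus control, no other components")
    elif tier == "training_pm_supervision":
        ok = (df["comparison_type"] == "T1") | (
            (df["comparison_type"] == "T3")
            & shared.loc[df.index].map(lambda x: x <= {"supervision"})
        )
        narrow(ok, "tier training_pm_supervision: shared components within {supervision}")
    else:
        narrow(df["comparison_type"].isin(["T1", "T3"]),
               "tier training_any_components: training versus control or shared components")

    # intervention-arm training attributes
    arm_rows = []
    for _, r in df.drop_duplicates("comparison_id").iterrows():
        arm = next(a for a in db.arms_of(str(r["study_id"]))
                   if a.arm_id == str(r["intervention_arm"]))
        attrs = arm.training_attributes
        shared_set = frozenset(str(r["shared_components"]).split("|")) - {""}
        row = {
            "comparison_id": r["comparison_id"],
            "duration_days": attrs.duration_days if attrs else None,
            "group_size": attrs.group_size if attrs else None,
            "topic_complexity": attrs.topic_complexity if attrs else None,
            "printed_materials": attrs.printed_materials if attrs else None,
            "computers": attrs.computers if attrs else None,
            "professional_trainers": attrs.professional_trainers if attrs else None,
            "content_expert_trainers": attrs.content_expert_trainers if attrs else None,
            "onsite": attrs.onsite if attrs else None,
            "multiple_sessions": attrs.multiple_sessions if attrs else None,
            "n_methods": attrs.n_methods if attrs else None,
            "supervision": int("supervision" in shared_set),
        }
        for m in ("lecture", "interactive_discussion", "clinical_practice",
                  "role_play", "other_method"):
            row[m] = (None if attrs is None or not attrs.methods_observed
                      else ("yes" if m in attrs.methods else "no"))
        for c in OTHER_CATEGORIES:
            row[f"component_{c}"] = int(c in shared_set)
        arm_rows.append(row)
    df = df.merge(pd.DataFrame(arm_rows), on="comparison_id", how="left")

    dur = pd.to_numeric(df["duration_days"], errors="coerce")
    narrow(dur.isna() | (dur < max_duration_days),
           f"training duration < {max_duration_days:g} days (missing retained)")

    df = df.rename(columns={"followup_month": "time_since_training",
                            "es_value": "es"})
    # the modelling confounder is baseline performance on the improvement-
    # oriented scale, not the raw baseline the ceiling rule inspects
    df["baseline_level"] = df["baseline_performance"]
    keep = (["es", "study_id", "comparison_id", "outcome_id",
             "time_since_training", "baseline_level", "duration_days",
             "n_methods", "group_size", "topic_complexity", "supervision"]
            + ["lecture", "interactive_discussion", "clinical_practice",
               "role_play", "other_method", "printed_materials", "computers",
               "professional_trainers", "content_expert_trainers", "onsite",
               "multiple_sessions"]
            + [f"component_{c}" for c in OTHER_CATEGORIES])
    out = df[keep].reset_index(drop=True)
    logger.info("model database (%s): %d effect sizes from %d studies",
                tier, len(out), out["study_id"].nunique())
    return out


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Which attribute covariates and interactions enter the fixed part.

    Confounders (baseline performance, time since training) are always
    included; tier eligibility is applied by :func:`build_model_database`.
    """

    tier: str = "training_any_components"
    covariates: tuple[str, ...] = ("onsite", "clinical_practice")
    interaction_complexity_duration: bool = False
    interaction_time_supervision: bool = False
    #: adjust for the 11 non-training component indicators; default only in
    #: the widest tier, mirroring its "with any components" eligibility
    adjust_components: Optional[bool] = None

    def wants_component_adjusters(self) -> bool:
        if self.adjust_components is not None:
            return self.adjust_components
        return self.tier == "training_any_components"


def _yesno(col: pd.Series, name: str, X: dict) -> None:
    X[f"{name}_yes"] = (col == "yes").astype(float)
    miss = col.isna() | (col == "")
    if miss.any():
        X[f"{name}_missing"] = miss.astype(float)


def _numeric_with_indicator(col: pd.Series, name: str, X: dict, fill=0.0) -> None:
    v = pd.to_numeric(col, errors="coerce")
    miss = v.isna()
    X[name] = v.fillna(fill).astype(float)
    if miss.any():
        X[f"{name}_missing"] = miss.astype(float)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Fixed-effects design matrix, response and grouping for a model table."""
    unknown = set(spec.covariates) - set(SUPPORTED_COVARIATES)
    if unknown:
        raise ValueError(f"unsupported covariates: {sorted(unknown)}")

    X: dict[str, pd.Series] = {}
    X["intercept"] = pd.Series(1.0, index=table.index)
    # confounders, always present
    X["time_since_training"] = table["time_since_training"].astype(float)
    base = pd.to_numeric(table["baseline_level"], errors="coerce")
    X["baseline_level"] = (base - BASELINE_CENTER).fillna(0.0)
    if base.isna().any():
        X["baseline_missing"] = base.isna().astype(float)

    for cov in spec.covariates:
        if cov == "duration":
            _numeric_with_indicator(table["duration_days"], "duration_days", X)
        elif cov == "group_size":
            _numeric_with_indicator(table["group_size"], "group_size", X)
        elif cov == "n_methods":
            _numeric_with_indicator(table["n_methods"], "n_methods", X)
        elif cov == "topic_complexity":
            col = table["topic_complexity"]
            X["complexity_multiple"] = (col == "multiple").astype(float)
            if (col.isna() | (col == "")).any():
                X["complexity_missing"] = (col.isna() | (col == "")).astype(float)
        elif cov == "onsite":
            col = table["onsite"]
            X["onsite_yes"] = (col == "some_or_all_onsite").astype(float)
            if (col.isna() | (col == "")).any():
                X["onsite_missing"] = (col.isna() | (col == "")).astype(float)
        elif cov == "supervision":
            X["supervision"] = table["supervision"].astype(float)
        else:
            _yesno(table[cov], cov, X)

    if spec.interaction_complexity_duration:
        dur = pd.to_numeric(table["duration_days"], errors="coerce")
        ln_dur = np.log(dur.where(dur > 0)).fillna(0.0)
        mult = (table["topic_complexity"] == "multiple").astype(float)
        X["complexity_x_ln_duration"] = mult * ln_dur
    if spec.interaction_time_supervision:
        X["time_x_supervision"] = (
            table["time_since_training"].astype(float)
            * table["supervision"].astype(float)
        )
    if spec.wants_component_adjusters():
        for c in OTHER_CATEGORIES:
            col = f"component_{c}"
            if col in table.columns:
                X[col] = table[col].astype(float)

    Xdf = pd.DataFrame(X, index=table.index)
    # constant columns (other than the intercept) carry no information and
    # break the optimiser; drop them with a note
    keep = ["intercept"] + [c for c in Xdf.columns[1:] if Xdf[c].nunique() > 1]
    dropped = set(Xdf.columns) - set(keep)
    if dropped:
        logger.info("dropping constant design columns: %s", sorted(dropped))
    y = table["es"].to_numpy(float)
    groups = table["study_id"].to_numpy()
    return Xdf[keep], y, groups


# --------------------------------------------------------------------------
# Mixed-model fit
# --------------------------------------------------------------------------


@dataclass
class ModelFit:
    """REML fit of the study-random-intercept model.

    ``params``/``bse``/``pvalues`` index the fixed effects (%-points per
    covariate unit); p-values are screening quantities (no multiplicity
    adjustment).
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    re_var: float  # between-study variance
    resid_var: float
    r2: float
    adjusted_r2: float
    n_studies: int
    n_effect_sizes: int
    spec: ModelSpec
    fixed_pred: np.ndarray = field(repr=False, default=None)
    observed: np.ndarray = field(repr=False, default=None)
    mean_time: float = 0.0

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats as _stats  # lazy; scipy ships with statsmodels

        z = _stats.norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coefficient": self.params,
            "se": self.bse,
            "p_screening": self.pvalues,
        })


def fit_random_effects(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the linear mixed model for one tier's modelling table.

    Study-level random intercept only, REML estimation, unweighted
    observations.  A boundary (zero) random-effect variance is retained with
    a warning; optimiser non-convergence raises :class:`ModelFitError`.
    """
    if table.empty:
        raise EmptyModelDatabaseError("empty modelling table")
    X, y, groups = build_design(table, spec)

    # prune linearly dependent columns (small tier tables can make two
    # dummies coincide); QR with column pivoting keeps a maximal
    # well-conditioned subset, always retaining the intercept
    Xa_full = np.asarray(X, float)
    from scipy.linalg import qr as _qr

    _, R, piv = _qr(Xa_full, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xa_full.shape) * np.finfo(float).eps * 1e3
    independent = sorted(piv[: int((diag > tol).sum())])
    if len(independent) < Xa_full.shape[1]:
        dropped = [X.columns[i] for i in range(Xa_full.shape[1])
                   if i not in independent]
        logger.warning("dropping collinear design columns: %s", dropped)
        X = X.iloc[:, independent]

    names = list(X.columns)
    k = len(names)
    Xa = np.asarray(X, float)

    # a deterministic response (zero residual variance) has no likelihood
    # surface for REML; the fit degenerates to least squares with a zero
    # random-effect variance
    ols = sm.OLS(y, Xa).fit()
    degenerate = float(np.var(ols.resid)) < 1e-12
    if degenerate:
        logger.warning("response is deterministic given the design; "
                       "returning least-squares fit with zero variance components")
        params = pd.Series(ols.params, index=names)
        bse = pd.Series(ols.bse, index=names)
        pvalues = pd.Series(ols.pvalues, index=names)
        re_var, resid_var = 0.0, float(np.var(ols.resid))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary-variance chatter
            model = sm.MixedLM(endog=y, exog=Xa, groups=groups)
            res = None
            last_exc: Optional[Exception] = None
            for method in ("lbfgs", "powell", "cg"):
                try:
                    res = model.fit(reml=True, method=method)
                except np.linalg.LinAlgError as exc:
                    last_exc = exc
                    continue
                if res.converged:
                    break
            if res is None:
                raise ModelFitError(
                    f"mixed-model estimation failed: {last_exc}") from last_exc
        if not res.converged:
            raise ModelFitError(
                "mixed-model optimiser did not converge; "
                f"last parameter vector: {np.asarray(res.params)}"
            )
        params = pd.Series(np.asarray(res.fe_params, float), index=names)
        bse = pd.Series(np.asarray(res.bse)[:k].astype(float), index=names)
        pvalues = pd.Series(np.asarray(res.pvalues)[:k].astype(float), index=names)
        re_var = float(np.asarray(res.cov_re)[0, 0])
        resid_var = float(res.scale)
        if re_var <= 1e-10:
            logger.warning("between-study variance estimated at the zero boundary")

    fixed_pred = Xa @ params.to_numpy()
    n = len(y)
    p = k - 1  # fixed covariates excluding the intercept
    if np.std(fixed_pred) > 0 and np.std(y) > 0:
        r2 = float(np.corrcoef(y, fixed_pred)[0, 1] ** 2)
    else:
        r2 = 0.0
    adjusted = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)

    return ModelFit(
        params=params, bse=bse, pvalues=pvalues,
        re_var=re_var, resid_var=resid_var,
        r2=r2, adjusted_r2=float(adjusted),
        n_studies=int(pd.Series(groups).nunique()),
        n_effect_sizes=n, spec=spec,
        fixed_pred=fixed_pred, observed=y,
        mean_time=float(np.mean(table["time_since_training"].astype(float))),
    )


# --------------------------------------------------------------------------
# Waning-time extrapolation and head-to-head summaries
# --------------------------------------------------------------------------


def waning_time(fit: ModelFit) -> Optional[float]:
    """Months until the mean training effect is predicted to reach zero.

    The predicted effect at time zero is the mean fixed-effects prediction
    with the time-since-training term removed; dividing by the (negative)
    waning slope extrapolates the time at which the mean effect hits zero.
    Returns ``None`` when the slope is non-negative (no waning).
    """
    slope = float(fit.params.get("time_since_training", 0.0))
    if slope >= 0:
        return None
    effect_at_zero = float(np.mean(fit.fixed_pred)) - slope * fit.mean_time
    return effect_at_zero / abs(slope)


def head_to_head_summary(
    head_mes: pd.DataFrame,
    attributes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-attribute direct-evidence table from head-to-head comparisons.

    ``head_mes`` has one MES row per head-to-head (training-vs-training)
    comparison with an ``attribute`` column naming the contrasted attribute
    and ``mes`` oriented toward the first-listed level.  Attributes with no
    head-to-head study are reported with ``direct_evidence == "none"``,
    alongside a missing median — the table is meant to sit next to the
    model's indirect estimates.
    """
    wanted = list(attributes) if attributes is not None else sorted(
        head_mes["attribute"].unique()
    )
    rows = []
    for attr in wanted:
        grp = head_mes[head_mes["attribute"] == attr]
        if grp.empty:
            rows.append({"attribute": attr, "n_comparisons": 0,
                         "median_mes": np.nan, "direct_evidence": "none"})
        else:
            rows.append({
                "attribute": attr,
                "n_comparisons": int(len(grp)),
                "median_mes": float(np.median(grp["mes"].to_numpy(float))),
                "direct_evidence": "head_to_head",
            })
    return pd.DataFrame(rows, columns=["attribute", "n_comparisons",
                                       "median_mes", "direct_evidence"])
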