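"""Synthetic study databases with known ground truth.

The generator emulates the statistical structure of the review database the
pipeline analyses — heterogeneous %-point effects with a heavy-tailed
between-study distribution, several correlated outcomes per comparison,
follow-up times centred near 4 months, attribute-dependent effect
modification (on-site training, clinical practice), linear waning of the
effect with time since training, and a negative baseline-performance
gradient — so that every downstream stage has a parameter-recovery test
surface without any download.

The oriented true effect for outcome ``k`` of study ``j``, measured at time
``t`` (months since strategy start) with baseline performance ``b``, is

    es_jk = effect_median
            + sum_a beta_a * (x_aj - p_a)         (attribute effects, centred)
            + waning_slope * (t - followup_median_month)
            + baseline_gradient * (b - 50)        (percentage outcomes)
            + u_j + e_jk

with ``u_j`` a between-study random effect (double-exponential by default,
matching the heavy tails of observed effect-size distributions) and ``e_jk``
Gaussian within-study noise.  Measurement values are constructed by exactly
inverting the effect-size equations the engine applies, so with all noise
terms at zero the full pipeline reproduces every configured effect exactly
(conservation of signal).  Percentage measurements are clipped to [0, 100]
and clipping events are counted.

One pseudo-random stream is derived per study from ``(seed, study index)``,
so enlarging a database never perturbs the studies already generated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .study_db import (
    SCHEMA,
    TRAINING_METHODS,
    RobDomainStatus,
    StudyDatabase,
    encode_rob_domains,
)

logger = logging.getLogger("hcpmeta")

#: Binary attribute prevalences used both to draw attribute levels and to
#: centre their contributions so the configured effect_median stays the
#: marginal centre of the true-effect distribution.
ATTRIBUTE_PREVALENCE: dict[str, float] = {
    "onsite": 0.35,
    "clinical_practice": 0.35,
    "lecture": 0.80,
    "interactive_discussion": 0.50,
    "role_play": 0.25,
    "other_method": 0.20,
    "printed_materials": 0.60,
    "computers": 0.10,
    "professional_trainers": 0.40,
    "content_expert_trainers": 0.55,
    "multiple_sessions": 0.30,
    "supervision": 0.12,
}

_ROB_DOMAIN_NAMES = (
    "dataset_completeness",
    "baseline_balance",
    "allocation_concealment",
    "outcome_assessor_blinding",
    "protection_against_contamination",
)

_OTHER_SHARED_POOL = (
    "community_support",
    "patient_support",
    "infrastructure",
    "group_problem_solving",
    "other_management",
    "ict",
)

_CATEGORY_PROBS = {
    "group_inservice": 0.70,
    "eov": 0.12,
    "group_preservice": 0.06,
    "self_study": 0.06,
    "peer_to_peer": 0.06,
}


class ConfigError(ValueError):
    """An impossible generator configuration (e.g. a negative SD)."""


@dataclass
class GeneratorConfig:
    """Study-portfolio generator settings (units: %-points and months).

    Defaults emulate the review's reported conditions: a median effect near
    7.3 %-points with a wide, heavy-tailed spread; about five outcomes per
    comparison; follow-up with median 4 months (IQR roughly 2-7.5); on-site
    training +8 and clinical practice +7 %-points; effect waning at
    -0.9 %-points/month; and a -0.13 %-point gradient per %-point of
    baseline performance.  Between- and within-study variance components are
    free parameters of the generator (documented as such).
    """

    n_studies: int = 150
    seed: int = 0
    effect_median: float = 7.3
    #: Laplace scale of the between-study effect; None derives it from
    #: between_study_sd (variance-matched).
    effect_iqr_scale: Optional[float] = None
    between_study_sd: float = 8.0
    within_study_sd: float = 4.0
    measurement_noise_sd: float = 1.0
    outcomes_per_comparison_mean: float = 5.0
    attribute_effects: dict[str, float] = field(
        default_factory=lambda: {"onsite": 8.0, "clinical_practice": 7.0}
    )
    waning_slope: float = -0.9  # %-points per month (negative = waning)
    baseline_gradient: float = -0.13  # %-points per %-point of baseline
    followup_median_month: float = 4.0
    followup_log_sd: float = 0.95
    prop_its: float = 0.15
    prop_lay: float = 0.05
    prop_continuous: float = 0.15
    prop_no_baseline: float = 0.15
    prop_decrease_improves: float = 0.20
    prop_ceiling_baseline: float = 0.02
    prop_extra_measurements: float = 0.30
    prop_shared_supervision: float = 0.12
    prop_shared_other: float = 0.48
    prop_duration_missing: float = 0.15
    prop_onsite_missing: float = 0.15
    baseline_mean: float = 45.0
    baseline_sd: float = 12.0
    control_drift_sd: float = 2.0
    random_effect_dist: str = "laplace"  # or "normal"
    #: training-plus-supervision studies stop waning (interaction switch)
    supervision_blocks_waning: bool = False

    def validate(self) -> "GeneratorConfig":
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        for name in ("between_study_sd", "within_study_sd", "measurement_noise_sd",
                     "followup_log_sd", "baseline_sd", "control_drift_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.effect_iqr_scale is not None and self.effect_iqr_scale < 0:
            raise ConfigError("effect_iqr_scale must be >= 0")
        if self.outcomes_per_comparison_mean < 1:
            raise ConfigError("outcomes_per_comparison_mean must be >= 1")
        for name in ("prop_its", "prop_lay", "prop_continuous", "prop_no_baseline",
                     "prop_decrease_improves", "prop_ceiling_baseline",
                     "prop_extra_measurements", "prop_shared_supervision",
                     "prop_shared_other", "prop_duration_missing",
                     "prop_onsite_missing"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.prop_shared_supervision + self.prop_shared_other > 1.0:
            raise ConfigError("prop_shared_supervision + prop_shared_other > 1")
        if self.random_effect_dist not in ("laplace", "normal"):
            raise ConfigError("random_effect_dist must be 'laplace' or 'normal'")
        unknown = set(self.attribute_effects) - set(ATTRIBUTE_PREVALENCE)
        if unknown:
            raise ConfigError(f"unknown attribute_effects keys: {sorted(unknown)}")
        return self

    @property
    def laplace_scale(self) -> float:
        if self.effect_iqr_scale is not None:
            return self.effect_iqr_scale
        return self.between_study_sd / np.sqrt(2.0)


@dataclass
class GroundTruth:
    """Everything needed to score an estimator's recovery error."""

    config: dict
    studies: pd.DataFrame  # per-study truth: u_j, attribute levels, base effect
    outcomes: pd.DataFrame  # per-outcome truth: the oriented target effect size
    n_clipped: int = 0

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "config": self.config,
            "n_clipped": self.n_clipped,
            "studies": self.studies.to_dict(orient="records"),
            "outcomes": self.outcomes.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=payload["config"],
            studies=pd.DataFrame(payload["studies"]),
            outcomes=pd.DataFrame(payload["outcomes"]),
            n_clipped=payload["n_clipped"],
        )


# --------------------------------------------------------------------------
# ITS series primitive
# --------------------------------------------------------------------------


def generate_its_series(
    level: float,
    pre_slope: float,
    level_change: float,
    slope_change: float,
    n_pre: int,
    n_post: int,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Monthly observations from the segmented linear model.

    Pre-intervention months are ``-n_pre .. -1`` and post months
    ``0 .. n_post - 1``; the value at month ``m >= 0`` is
    ``level + pre_slope*m + level_change + slope_change*m`` plus Gaussian
    noise.  With ``noise_sd = 0`` the points lie exactly on the two
    segments.  Requires at least three points per segment.
    """
    if n_pre < 3 or n_post < 3:
        raise ConfigError("generate_its_series needs n_pre >= 3 and n_post >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(-n_pre, n_post, dtype=float)
    post = (t >= 0).astype(float)
    y = level + pre_slope * t + level_change * post + slope_change * t * post
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(t))
    return pd.DataFrame({"time_month": t, "value": y})


# --------------------------------------------------------------------------
# Database generation
# --------------------------------------------------------------------------


def _draw_truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


class _Tables:
    """Row accumulator for the six schema tables."""

    def __init__(self):
        self.rows: dict[str, list[dict]] = {name: [] for name in SCHEMA}
        self.n_clipped = 0

    def add(self, table: str, **row):
        self.rows[table].append(row)

    def to_database(self) -> StudyDatabase:
        frames = {}
        for name, cols in SCHEMA.items():
            df = pd.DataFrame(self.rows[name], columns=cols)
            frames[name] = df
        return StudyDatabase(**frames)


def _clip_pct(tables: _Tables, value: float) -> float:
    clipped = float(np.clip(value, 0.0, 100.0))
    if clipped != value:
        tables.n_clipped += 1
    return clipped


def _median_offset(config: GeneratorConfig, n_draws: int = 100_000) -> float:
    """Median of the non-intercept effect components, by Monte Carlo.

    The attribute, waning and baseline-gradient contributions are centred on
    their means, but the median of their (skewed) sum is not zero.  The
    generator subtracts this offset from the intercept so that the empirical
    median of true effects converges to ``effect_median``.  A fixed internal
    stream keeps the calibration deterministic and independent of the data
    seed.
    """
    rng = np.random.default_rng(987654321)
    total = np.zeros(n_draws)
    sup = rng.random(n_draws) < ATTRIBUTE_PREVALENCE["supervision"]
    for a, beta in config.attribute_effects.items():
        p = ATTRIBUTE_PREVALENCE[a]
        x = sup if a == "supervision" else (rng.random(n_draws) < p)
        total += beta * (x.astype(float) - p)
    # follow-up time: lognormal for parallel designs, the ITS midpoint grid
    # for the ITS fraction
    t = np.exp(rng.normal(np.log(config.followup_median_month),
                          config.followup_log_sd, n_draws))
    its = rng.random(n_draws) < config.prop_its
    t[its] = (rng.integers(4, 11, its.sum()) - 1) / 2.0
    slope = np.full(n_draws, config.waning_slope)
    if config.supervision_blocks_waning:
        slope[sup] = 0.0
    total += slope * (t - config.followup_median_month)
    if config.baseline_gradient != 0.0:
        bs = np.clip(rng.normal(config.baseline_mean, config.baseline_sd, n_draws),
                     7.0, 85.0)
        b = np.clip(rng.normal(bs, 4.0), 7.0, 85.0)
        pct = rng.random(n_draws) >= config.prop_continuous
        total += config.baseline_gradient * (b - 50.0) * pct
    if config.random_effect_dist == "laplace":
        if config.laplace_scale > 0:
            total += rng.laplace(0.0, config.laplace_scale, n_draws)
    elif config.between_study_sd > 0:
        total += rng.normal(0.0, config.between_study_sd, n_draws)
    if config.within_study_sd > 0:
        total += rng.normal(0.0, config.within_study_sd, n_draws)
    return float(np.median(total))


def generate_database(config: GeneratorConfig) -> tuple[StudyDatabase, GroundTruth]:
    """Generate a validated study database plus its ground-truth record."""
    config.validate()
    tables = _Tables()
    truth_studies: list[dict] = []
    truth_outcomes: list[dict] = []
    intercept = config.effect_median - _median_offset(config)

    for j in range(config.n_studies):
        rng = np.random.default_rng([config.seed, j])
        _generate_study(config, j, rng, tables, truth_studies, truth_outcomes,
                        intercept)

    db = tables.to_database().validate()
    if tables.n_clipped:
        logger.info("generator clipped %d percentage measurement(s) to [0, 100]",
                    tables.n_clipped)
    truth = GroundTruth(
        config=dataclasses.asdict(config),
        studies=pd.DataFrame(truth_studies),
        outcomes=pd.DataFrame(truth_outcomes),
        n_clipped=tables.n_clipped,
    )
    return db, truth


def _generate_study(config, j, rng, tables, truth_studies, truth_outcomes,
                    intercept):
    sid = f"S{j:04d}"

    # ----- design, cadre, setting ----------------------------------------
    u = rng.random()
    if u < config.prop_its:
        design = "its_controlled" if rng.random() < 0.5 else "its"
    else:
        design = "randomised" if rng.random() < 0.65 else "non_randomised"
    cadre = "lay" if rng.random() < config.prop_lay else "professional"
    country_income = rng.choice(["low", "middle", "unknown"], p=[0.45, 0.50, 0.05])
    publication_year = int(rng.integers(1990, 2017))

    domains = [
        RobDomainStatus(name, rng.choice(
            ["done", "not_done", "unclear", "not_applicable"],
            p=[0.60, 0.20, 0.15, 0.05]))
        for name in _ROB_DOMAIN_NAMES
    ]

    # ----- strategy structure --------------------------------------------
    cats = list(_CATEGORY_PROBS)
    category = str(rng.choice(cats, p=[_CATEGORY_PROBS[c] for c in cats]))
    u = rng.random()
    if u < config.prop_shared_supervision:
        shared = {"supervision"}
    elif u < config.prop_shared_supervision + config.prop_shared_other:
        k = int(rng.integers(1, 3))
        shared = set(rng.choice(_OTHER_SHARED_POOL, size=k, replace=False))
    else:
        shared = set()
    if design == "its":
        # an uncontrolled ITS contrasts an arm with its own pre-trend, which
        # isolates the training effect only when training stands alone
        shared = set()
    has_supervision = "supervision" in shared
    add_printed = rng.random() < 0.10  # exercise printed-material absorption

    # ----- training attributes (true levels; some recorded as missing) ----
    duration = float(np.exp(rng.normal(np.log(5.0), 0.8)))
    duration_missing = rng.random() < config.prop_duration_missing
    attr_true: dict[str, int] = {}
    for name in ("lecture", "interactive_discussion", "clinical_practice",
                 "role_play", "other_method", "printed_materials", "computers",
                 "professional_trainers", "content_expert_trainers",
                 "multiple_sessions", "onsite"):
        attr_true[name] = int(rng.random() < ATTRIBUTE_PREVALENCE[name])
    onsite_missing = rng.random() < config.prop_onsite_missing
    group_size = int(rng.integers(5, 41))
    group_size_missing = rng.random() < 0.30
    complexity = str(rng.choice(["single", "multiple", ""], p=[0.45, 0.45, 0.10]))

    # ----- study-level effect components ----------------------------------
    if config.random_effect_dist == "laplace":
        u_j = float(rng.laplace(0.0, config.laplace_scale)) if config.laplace_scale > 0 else 0.0
    else:
        u_j = float(rng.normal(0.0, config.between_study_sd)) if config.between_study_sd > 0 else 0.0
    followup = float(np.exp(rng.normal(np.log(config.followup_median_month),
                                       config.followup_log_sd)))
    baseline_mean_j = _draw_truncated_normal(
        rng, config.baseline_mean, config.baseline_sd, 7.0, 85.0)
    drift_j = _draw_truncated_normal(rng, 0.5, config.control_drift_sd, -6.0, 6.0)

    covariate_x = dict(attr_true)
    covariate_x["supervision"] = int(has_supervision)

    def attr_contrib() -> float:
        return sum(beta * (covariate_x[a] - ATTRIBUTE_PREVALENCE[a])
                   for a, beta in config.attribute_effects.items())

    def waning_at(t: float) -> float:
        slope = config.waning_slope
        if config.supervision_blocks_waning and has_supervision:
            slope = 0.0
        return slope * (t - config.followup_median_month)

    def true_effect(t: float, baseline: Optional[float], scale: str) -> float:
        es = intercept + attr_contrib() + waning_at(t) + u_j
        if scale == "percentage" and baseline is not None:
            es += config.baseline_gradient * (baseline - 50.0)
        return es

    # ----- studies / arms / components / attributes rows -------------------
    tables.add("studies", study_id=sid, design=design, cadre=cadre,
               country_income=country_income, strategy_start_month=0.0,
               publication_year=publication_year, is_equivalency=0,
               rob_domains=encode_rob_domains(domains))

    int_arm = f"{sid}_int"
    uncontrolled = design == "its"
    ref_arm = None if uncontrolled else f"{sid}_ctl"

    tables.add("arms", arm_id=int_arm, study_id=sid, is_control=0, is_gold_standard=0)
    int_components = {category} | shared
    if add_printed:
        int_components.add("printed_materials_standalone")
    for c in sorted(int_components):
        tables.add("components", arm_id=int_arm, component_code=c)
    if ref_arm is not None:
        tables.add("arms", arm_id=ref_arm, study_id=sid,
                   is_control=int(not shared), is_gold_standard=0)
        for c in sorted(shared):
            tables.add("components", arm_id=ref_arm, component_code=c)

    tables.add(
        "attributes",
        arm_id=int_arm,
        duration_days=None if duration_missing else round(duration, 2),
        **{m: ("yes" if attr_true[m] else "no") for m in TRAINING_METHODS
           if m != "clinical_practice"},
        clinical_practice="yes" if attr_true["clinical_practice"] else "no",
        printed_materials="yes" if attr_true["printed_materials"] else "no",
        computers="yes" if attr_true["computers"] else "no",
        group_size=None if group_size_missing else group_size,
        topic_complexity=complexity or None,
        professional_trainers="yes" if attr_true["professional_trainers"] else "no",
        content_expert_trainers="yes" if attr_true["content_expert_trainers"] else "no",
        onsite=None if onsite_missing else (
            "some_or_all_onsite" if attr_true["onsite"] else "all_offsite"),
        multiple_sessions="yes" if attr_true["multiple_sessions"] else "no",
    )

    truth_studies.append({
        "study_id": sid, "design": design, "cadre": cadre,
        "category": category, "u": u_j, "followup_month": followup,
        "drift": drift_j, "baseline_mean": baseline_mean_j,
        "supervision": int(has_supervision),
        **{f"x_{a}": covariate_x[a] for a in ATTRIBUTE_PREVALENCE},
        "true_effect_at_followup": true_effect(followup, baseline_mean_j, "percentage"),
    })

    # ----- outcomes --------------------------------------------------------
    n_out = 1 + int(rng.poisson(max(config.outcomes_per_comparison_mean - 1.0, 0.0)))
    is_its = design in ("its", "its_controlled")
    for k in range(n_out):
        oid = f"{sid}_o{k}"
        scale = "continuous" if rng.random() < config.prop_continuous else "percentage"
        direction = ("decrease_improves"
                     if rng.random() < config.prop_decrease_improves
                     else "increase_improves")
        if is_its:
            _gen_its_outcome(config, rng, tables, truth_outcomes, sid, oid,
                             int_arm, ref_arm, scale, direction, baseline_mean_j,
                             drift_j, true_effect)
        else:
            _gen_simple_outcome(config, rng, tables, truth_outcomes, sid, oid,
                                int_arm, ref_arm, scale, direction,
                                baseline_mean_j, followup, drift_j, true_effect)

    # ----- costs -----------------------------------------------------------
    if (category == "group_inservice" and cadre == "professional"
            and not duration_missing and rng.random() < 0.20):
        per_day = float(np.clip(np.exp(rng.normal(np.log(26.0), 1.5)), 1.0, 120.0))
        n_hcps = int(rng.integers(20, 201))
        tables.add("costs", arm_id=int_arm,
                   total_cost_usd=round(per_day * n_hcps * duration, 2),
                   n_hcps_trained=n_hcps, duration_days=round(duration, 2))


def _measure(config, rng, tables, scale, raw: float) -> float:
    if config.measurement_noise_sd > 0:
        raw = raw + rng.normal(0.0, config.measurement_noise_sd)
    if scale == "percentage":
        raw = _clip_pct(tables, raw)
    return float(raw)


def _gen_simple_outcome(config, rng, tables, truth_outcomes, sid, oid, int_arm,
                        ref_arm, scale, direction, baseline_mean_j, followup,
                        drift_j, true_effect):
    """Non-ITS outcome: invert the applicable effect-size equation exactly."""
    has_baseline = rng.random() >= config.prop_no_baseline
    ceiling = (scale == "percentage" and has_baseline
               and direction == "increase_improves"
               and rng.random() < config.prop_ceiling_baseline)
    if scale == "percentage":
        b = (float(rng.uniform(95.5, 99.0)) if ceiling
             else _draw_truncated_normal(rng, baseline_mean_j, 4.0, 7.0, 85.0))
    else:
        b = 100.0  # continuous outcomes are generated on a reference scale of 100

    e_within = rng.normal(0.0, config.within_study_sd) if config.within_study_sd > 0 else 0.0
    es = true_effect(followup, b if scale == "percentage" else None, scale) + e_within
    sign = 1.0 if direction == "increase_improves" else -1.0
    b_raw = b if (scale == "continuous" or direction == "increase_improves") else 100.0 - b
    drift_raw = sign * drift_j

    tb = float(rng.uniform(-3.0, -0.5))
    extra = rng.random() < config.prop_extra_measurements
    n_units = int(rng.integers(30, 301))
    clips_before = tables.n_clipped

    def row(arm, t, value):
        tables.add("outcomes", outcome_id=oid, study_id=sid, scale=scale,
                   direction=direction, arm_id=arm, time_month=round(t, 3),
                   value=_measure(config, rng, tables, scale, value), n=n_units)

    def f_int_at(t: float, f_ctl: float) -> float:
        """Invert the engine's equation so the computed effect equals es_raw."""
        e = sign * (true_effect(t, b if scale == "percentage" else None, scale)
                    + e_within)
        if scale == "percentage":
            return (b_raw + (f_ctl - b_raw) + e) if has_baseline else (f_ctl + e)
        if has_baseline:
            return b_raw * (1.0 + e / 100.0 + (f_ctl - b_raw) / b_raw)
        return f_ctl * (1.0 + e / 100.0)

    f_ctl = b_raw + drift_raw
    if has_baseline:
        row(int_arm, tb, b_raw)
        row(ref_arm, tb, b_raw)
        if extra:
            row(int_arm, tb - 3.0, b_raw)
            row(ref_arm, tb - 3.0, b_raw)
    if extra:
        t_mid = followup / 2.0
        f_ctl_mid = b_raw + drift_raw * 0.5
        row(int_arm, t_mid, f_int_at(t_mid, f_ctl_mid))
        row(ref_arm, t_mid, f_ctl_mid)
    row(int_arm, followup, f_int_at(followup, f_ctl))
    row(ref_arm, followup, f_ctl)

    truth_outcomes.append({
        "study_id": sid, "outcome_id": oid, "scale": scale,
        "direction": direction, "baseline": b if has_baseline else None,
        "followup_month": followup, "target_es": es,
        "has_baseline": bool(has_baseline), "is_its": False,
        "ceiling": bool(ceiling),
        "clipped": tables.n_clipped > clips_before,
    })


def _gen_its_outcome(config, rng, tables, truth_outcomes, sid, oid, int_arm,
                     ref_arm, scale, direction, baseline_mean_j, drift_j,
                     true_effect):
    """ITS outcome: segmented series whose summary effect equals the truth."""
    if scale == "percentage":
        b = _draw_truncated_normal(rng, baseline_mean_j, 4.0, 7.0, 85.0)
    else:
        b = 100.0
    n_pre = int(rng.integers(4, 9))
    n_post = int(rng.integers(4, 11))
    midpoint = (n_post - 1) / 2.0

    e_within = rng.normal(0.0, config.within_study_sd) if config.within_study_sd > 0 else 0.0
    es = true_effect(midpoint, b if scale == "percentage" else None, scale) + e_within
    sign = 1.0 if direction == "increase_improves" else -1.0
    es_raw = sign * es
    b_raw = b if (scale == "continuous" or direction == "increase_improves") else 100.0 - b
    drift_raw = sign * drift_j
    pre_slope = float(rng.normal(0.0, 0.15))
    n_units = int(rng.integers(30, 301))
    clips_before = tables.n_clipped

    controlled = ref_arm is not None
    level_change_int = es_raw + (drift_raw if controlled else 0.0)
    series_int = generate_its_series(b_raw, pre_slope, level_change_int, 0.0,
                                     n_pre, n_post, 0.0, rng)
    for _, r in series_int.iterrows():
        tables.add("outcomes", outcome_id=oid, study_id=sid, scale=scale,
                   direction=direction, arm_id=int_arm,
                   time_month=float(r["time_month"]),
                   value=_measure(config, rng, tables, scale, float(r["value"])),
                   n=n_units)
    if controlled:
        series_ctl = generate_its_series(b_raw, pre_slope, drift_raw, 0.0,
                                         n_pre, n_post, 0.0, rng)
        for _, r in series_ctl.iterrows():
            tables.add("outcomes", outcome_id=oid, study_id=sid, scale=scale,
                       direction=direction, arm_id=ref_arm,
                       time_month=float(r["time_month"]),
                       value=_measure(config, rng, tables, scale, float(r["value"])),
                       n=n_units)

    truth_outcomes.append({
        "study_id": sid, "outcome_id": oid, "scale": scale,
        "direction": direction, "baseline": b,
        "followup_month": midpoint, "target_es": es,
        "has_baseline": True, "is_its": True, "ceiling": False,
        "clipped": tables.n_clipped > clips_before,
    })
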