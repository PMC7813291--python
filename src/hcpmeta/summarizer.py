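"""Median-effect-size (MES) collapsing and stratified distribution summaries.

Multiple outcomes from the same study comparison are collapsed into a single
number: the median of the comparison's included effect sizes (MES).  MES
distributions are then described with a median, IQR, minimum and maximum,
stratified by outcome scale, HCP cadre, comparison type and training
category, with risk-of-bias counts per stratum.  Equivalency comparisons
(success = effect size close to zero) are never pooled with the other
types; they are reported separately with |MES| as the success metric.

Quantiles use linear interpolation between order statistics (numpy's
default, R type 7) — documented so R and Python implementations can match
bit-for-bit.  Strata with fewer than three comparisons report the median
and range but suppress the IQR (and with a single comparison the range) as
not applicable.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .study_db import StudyDatabase

logger = logging.getLogger("hcpmeta")

ROB_ORDER = ("low", "moderate", "high", "very_high")
MIN_N_FOR_IQR = 3


def collapse_mes(
    effects: pd.DataFrame,
    comparisons: pd.DataFrame,
    studies: Optional[pd.DataFrame] = None,
    rob: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Collapse included effect sizes to one MES row per (comparison, scale).

    The MES is the median of the comparison's included effect sizes on that
    outcome scale (mean of the middle two for even counts).  Comparisons
    with no included effect size are dropped with a warning.  Study
    metadata (cadre) and risk-of-bias levels are joined in when provided.
    """
    inc = effects[effects["status"] == "included"]
    dropped = set(effects["comparison_id"]) - set(inc["comparison_id"])
    for cid in sorted(dropped):
        logger.warning("comparison %s: no included effect sizes; dropped", cid)

    rows = []
    for (cid, scale), grp in inc.groupby(["comparison_id", "scale"], sort=True):
        rows.append({
            "comparison_id": cid,
            "study_id": grp["study_id"].iloc[0],
            "scale": scale,
            "mes": float(np.median(grp["es_value"].to_numpy(float))),
            "n_effect_sizes": int(len(grp)),
        })
    mes = pd.DataFrame(rows, columns=["comparison_id", "study_id", "scale",
                                      "mes", "n_effect_sizes"])
    meta_cols = ["comparison_id", "comparison_type",
                 "training_category_int", "training_category_ref"]
    mes = mes.merge(comparisons[meta_cols], on="comparison_id", how="left")
    if studies is not None:
        mes = mes.merge(studies[["study_id", "cadre"]], on="study_id", how="left")
    if rob is not None:
        mes = mes.merge(rob[["study_id", "rob_level"]], on="study_id", how="left")
    return mes


def _quantile(x: np.ndarray, q: float) -> float:
    return float(np.quantile(x, q))  # linear interpolation (type 7)


def _summary_row(values: np.ndarray, rob_levels: Optional[pd.Series]) -> dict:
    n = len(values)
    row: dict = {"n_comparisons": n}
    if rob_levels is not None:
        counts = rob_levels.value_counts()
        for lvl in ROB_ORDER:
            row[f"n_rob_{lvl}"] = int(counts.get(lvl, 0))
    if n == 0:
        row.update(median_mes=np.nan, q1=np.nan, q3=np.nan, min=np.nan, max=np.nan)
        return row
    row["median_mes"] = _quantile(values, 0.5)
    if n >= MIN_N_FOR_IQR:
        row["q1"] = _quantile(values, 0.25)
        row["q3"] = _quantile(values, 0.75)
    else:
        row["q1"] = np.nan  # IQR reported as NA for sparse strata
        row["q3"] = np.nan
    if n >= 2:
        row["min"] = float(values.min())
        row["max"] = float(values.max())
    else:
        row["min"] = np.nan
        row["max"] = np.nan
    return row


def summarize_strata(
    mes_records: pd.DataFrame,
    strata: Sequence[str] = ("comparison_type", "training_category_int",
                             "training_category_ref", "scale", "cadre"),
    include_equivalency: bool = False,
) -> pd.DataFrame:
    """One distribution summary row per stratum combination.

    Permutation-invariant in the record order.  Equivalency (T5) comparisons
    are excluded unless requested (they are summarised separately on |MES|).
    """
    df = mes_records
    if not include_equivalency and "comparison_type" in df.columns:
        df = df[df["comparison_type"] != "T5"]
    rows = []
    has_rob = "rob_level" in df.columns
    for key, grp in df.groupby(list(strata), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(strata, key))
        row.update(_summary_row(grp["mes"].to_numpy(float),
                                grp["rob_level"] if has_rob else None))
        rows.append(row)
    return pd.DataFrame(rows)


def equivalency_summary(mes_records: pd.DataFrame) -> pd.DataFrame:
    """Separate table for equivalency comparisons; success is |MES| near 0."""
    df = mes_records[mes_records["comparison_type"] == "T5"].copy()
    df["abs_mes"] = df["mes"].abs()
    return df[["comparison_id", "study_id", "scale", "mes", "abs_mes",
               "n_effect_sizes"]].reset_index(drop=True)


def rob_sensitivity(
    mes_records: pd.DataFrame,
    strata: Sequence[str] = ("comparison_type", "training_category_int", "scale"),
) -> pd.DataFrame:
    """Paired summaries: low/moderate versus high/very-high risk of bias.

    Splits every stratum into the two risk-of-bias groups and summarises
    each, so effect-size inflation in weaker studies is visible.
    """
    df = mes_records[mes_records["comparison_type"] != "T5"].copy()
    df["rob_group"] = np.where(df["rob_level"].isin(["low", "moderate"]),
                               "low_moderate", "high_very_high")
    return summarize_strata(df, strata=list(strata) + ["rob_group"])


def cost_summary(
    db: StudyDatabase,
    strata: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Distribution of cost per HCP per day of training (USD).

    Per-arm value = total cost / (number of HCPs trained x training days);
    positivity of the denominator is a type invariant of the cost table.
    Optionally stratified by study columns such as ``country_income``.
    """
    recs = db.cost_records()
    if not recs:
        return pd.DataFrame(columns=["n_comparisons", "median_mes", "q1", "q3",
                                     "min", "max"])
    df = pd.DataFrame({
        "arm_id": [r.arm_id for r in recs],
        "cost_per_hcp_day": [r.cost_per_hcp_per_day for r in recs],
    })
    arm_study = db.arms[["arm_id", "study_id"]].astype(str)
    df = df.merge(arm_study, on="arm_id", how="left")
    df = df.merge(db.studies[["study_id", "country_income"]].astype(str),
                  on="study_id", how="left")
    if strata:
        rows = []
        for key, grp in df.groupby(list(strata), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            row = dict(zip(strata, key))
            row.update(_summary_row(grp["cost_per_hcp_day"].to_numpy(float), None))
            rows.append(row)
        return pd.DataFrame(rows)
    return pd.DataFrame([_summary_row(df["cost_per_hcp_day"].to_numpy(float), None)])
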