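"""Segmented linear regression for interrupted time series (ITS) outcomes.

Each ITS series is modelled by ordinary least squares as

    Y_t = beta0 + beta1*t + beta2*post_t + beta3*t*post_t + e_t

with time ``t`` in months centred at the strategy start (``post_t = 1`` for
``t >= 0``), so ``beta2`` is the level change at the start and ``beta3`` the
slope change per month.  The summary effect size incorporates both level and
trend effects: it is the model-predicted outcome level at the midpoint of
the follow-up period minus the counterfactual level obtained by extending
the pre-intervention trend to that midpoint.  Under this parameterisation
the summary effect equals ``beta2 + beta3 * midpoint`` exactly.

No autocorrelation correction is applied; the residual standard deviation is
reported descriptively.  (A Newey-West-style robust option is stubbed but
switched off.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("hcpmeta")

MIN_POINTS_PER_SEGMENT = 3


class ItsEstimationError(ValueError):
    """Raised when a segmented fit is infeasible (too few points, rank loss)."""


@dataclass
class ItsFit:
    """Segmented-regression fit for one arm's ITS series (outcome units)."""

    beta0: float  # pre-period intercept at strategy start
    beta1: float  # pre-period slope per month
    beta2: float  # level change at strategy start
    beta3: float  # slope change per month
    residual_sd: float
    midpoint_month: float  # midpoint of the follow-up period
    summary_effect: float  # beta2 + beta3 * midpoint_month

    def predicted(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        post = (t >= 0).astype(float)
        return self.beta0 + self.beta1 * t + self.beta2 * post + self.beta3 * t * post

    def counterfactual(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.beta0 + self.beta1 * t


def fit_segmented(times: np.ndarray, values: np.ndarray,
                  newey_west: bool = False) -> ItsFit:
    """Fit the four-parameter segmented model to one series.

    Requires at least three pre-intervention (``t < 0``) and three
    post-intervention (``t >= 0``) time points — the smallest counts that
    identify two slopes while leaving a residual degree of freedom.
    """
    if newey_west:  # pragma: no cover - stub, deliberately off
        raise NotImplementedError("autocorrelation-robust errors are not enabled")
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    post = (t >= 0).astype(float)
    n_pre = int((post == 0).sum())
    n_post = int((post == 1).sum())
    if n_pre < MIN_POINTS_PER_SEGMENT or n_post < MIN_POINTS_PER_SEGMENT:
        raise ItsEstimationError(
            f"need >= {MIN_POINTS_PER_SEGMENT} points per segment, "
            f"got {n_pre} pre and {n_post} post"
        )

    X = np.column_stack([np.ones_like(t), t, post, t * post])
    if np.linalg.matrix_rank(X) < 4:
        raise ItsEstimationError("rank-deficient design (degenerate time points)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(t) - 4
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else float("nan")

    post_times = t[post == 1]
    midpoint = float((post_times.min() + post_times.max()) / 2.0)
    summary = float(beta[2] + beta[3] * midpoint)
    return ItsFit(
        beta0=float(beta[0]), beta1=float(beta[1]),
        beta2=float(beta[2]), beta3=float(beta[3]),
        residual_sd=residual_sd, midpoint_month=midpoint, summary_effect=summary,
    )


def controlled_its_effect(fit_int: ItsFit, fit_ctl: ItsFit) -> float:
    """Between-arm ITS effect: intervention minus control summary effect.

    Uncontrolled ITS series use the intervention summary effect alone (the
    counterfactual is the arm's own extended pre-trend).  Midpoints that
    differ by more than 25% of the follow-up span trigger a warning but the
    difference is still computed.
    """
    span = max(abs(fit_int.midpoint_month), abs(fit_ctl.midpoint_month), 1e-12)
    if abs(fit_int.midpoint_month - fit_ctl.midpoint_month) > 0.25 * 2 * span:
        logger.warning(
            "ITS arms have poorly matched follow-up midpoints (%.2f vs %.2f months)",
            fit_int.midpoint_month, fit_ctl.midpoint_month,
        )
    return float(fit_int.summary_effect - fit_ctl.summary_effect)
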