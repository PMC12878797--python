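"""Validity suite: heterogeneity, pleiotropy, leave-one-out, funnel, Steiger."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.errors import InsufficientInstrumentsError, MissingSampleSizeError
from mrmediate.estimators import MREstimate, ivw, mr_egger
from mrmediate.instruments import _steiger_r2
from mrmediate.summary_stats import HarmonizedSet


@dataclass
class SteigerResult:
    """Directionality evidence: variance explained in exposure vs outcome."""

    r2_exposure: float
    r2_outcome: float
    correct_causal_direction: bool
    steiger_pval: float


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: Optional[float]
    egger_intercept_se: Optional[float]
    egger_intercept_pval: Optional[float]
    loo: List[Tuple[str, float, float, float]]
    funnel: List[Tuple[str, float, float]]
    steiger: Optional[SteigerResult]


def cochran_q(h: HarmonizedSet) -> Tuple[float, int, float]:
    """Cochran's Q over per-SNP ratios around the fixed-effect IVW estimate.

    Q = sum_j w_j (theta_j - theta_ivw)^2 with w_j = (bX_j/seY_j)^2,
    referred to chi-square with k-1 df.
    """
    kept = h.retained
    k = len(kept)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 retained rows")
    bX = kept["beta_exposure"].to_numpy(dtype=float)
    bY = kept["beta_outcome"].to_numpy(dtype=float)
    seY = kept["se_outcome"].to_numpy(dtype=float)
    theta = bY / bX
    w = (bX / seY) ** 2
    theta_ivw = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_ivw) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(
    h: HarmonizedSet,
) -> Tuple[float, float, Optional[float]]:
    """Directional-pleiotropy test: Egger intercept, SE, t-based p (k-2 df).

    A degenerate zero-residual fit reports ``None`` for the p-value rather
    than dividing by zero.
    """
    est = mr_egger(h)
    return (
        est.extra["egger_intercept"],
        est.extra["egger_intercept_se"],
        est.extra["egger_intercept_pval"],
    )


def leave_one_out(
    h: HarmonizedSet, effects_model: str = "auto"
) -> List[Tuple[str, float, float, float]]:
    """Recompute IVW excluding each retained variant in turn."""
    kept = h.retained
    k = len(kept)
    if k < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 retained rows")
    out = []
    for snp in kept["snp_id"]:
        reduced = HarmonizedSet(
            h.exposure_id,
            h.outcome_id,
            kept[kept["snp_id"] != snp].copy(),
            h.n_exposure,
            h.n_outcome,
        )
        est = ivw(reduced, effects_model=effects_model)
        out.append((snp, est.beta, est.se, est.pval))
    return out


def funnel_data(h: HarmonizedSet) -> List[Tuple[str, float, float]]:
    """Per-SNP Wald ratios paired with inverse first-order SEs (no plotting)."""
    kept = h.retained
    if not len(kept):
        raise InsufficientInstrumentsError("funnel data needs >= 1 retained row")
    bX = kept["beta_exposure"].to_numpy(dtype=float)
    bY = kept["beta_outcome"].to_numpy(dtype=float)
    seY = kept["se_outcome"].to_numpy(dtype=float)
    theta = bY / bX
    inv_se = np.abs(bX) / seY
    return list(zip(kept["snp_id"], map(float, theta), map(float, inv_se)))


def steiger_directionality(
    h: HarmonizedSet,
    n_exposure: Optional[float] = None,
    n_outcome: Optional[float] = None,
) -> SteigerResult:
    """Compare instrument variance explained in exposure vs outcome.

    Per-SNP r2 from the t-statistic transform r2 = t^2/(t^2 + n - 2) is
    summed across instruments (independence post-clumping, capped at 1);
    the p-value is a two-sample z-test on Fisher-transformed correlations
    sqrt(r2) with the respective sample sizes.
    """
    n_x = n_exposure if n_exposure is not None else h.n_exposure
    n_y = n_outcome if n_outcome is not None else h.n_outcome
    if n_x is None or n_y is None:
        raise MissingSampleSizeError("Steiger test needs sample sizes for both traits")
    kept = h.retained
    if not len(kept):
        raise InsufficientInstrumentsError("Steiger test needs >= 1 retained row")
    r2x = float(
        min(
            1.0,
            np.sum(
                _steiger_r2(
                    kept["beta_exposure"].to_numpy(dtype=float),
                    kept["se_exposure"].to_numpy(dtype=float),
                    n_x,
                )
            ),
        )
    )
    r2y = float(
        min(
            1.0,
            np.sum(
                _steiger_r2(
                    kept["beta_outcome"].to_numpy(dtype=float),
                    kept["se_outcome"].to_numpy(dtype=float),
                    n_y,
                )
            ),
        )
    )
    rx = min(np.sqrt(r2x), 1.0 - 1e-15)
    ry = min(np.sqrt(r2y), 1.0 - 1e-15)
    z = (np.arctanh(rx) - np.arctanh(ry)) / np.sqrt(
        1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0)
    )
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2x,
        r2_outcome=r2y,
        correct_causal_direction=bool(r2x > r2y),
        steiger_pval=pval,
    )


def sensitivity_report(
    h: HarmonizedSet,
    n_exposure: Optional[float] = None,
    n_outcome: Optional[float] = None,
    effects_model: str = "auto",
) -> SensitivityReport:
    """Assemble the full validity suite for one harmonized set.

    Components needing more instruments than available are reported as
    missing rather than raising.
    """
    k = h.nsnp
    if k >= 2:
        q, df, qp = cochran_q(h)
    else:
        q, df, qp = float("nan"), 0, float("nan")
    if k >= 3:
        e_int, e_se, e_p = egger_intercept_test(h)
        loo = leave_one_out(h, effects_model=effects_model)
    else:
        e_int = e_se = e_p = None
        loo = []
    funnel = funnel_data(h)
    try:
        steiger = steiger_directionality(h, n_exposure, n_outcome)
    except MissingSampleSizeError:
        steiger = None
    return SensitivityReport(
        q_stat=q,
        q_df=df,
        q_pval=qp,
        egger_intercept=e_int,
        egger_intercept_se=e_se,
        egger_intercept_pval=e_p,
        loo=loo,
        funnel=funnel,
        steiger=steiger,
    )
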