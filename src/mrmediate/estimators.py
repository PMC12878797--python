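"""Causal-effect estimators for harmonized exposure/outcome summary data.

Implements the Wald ratio, inverse-variance-weighted (IVW), Egger
regression, weighted median, and simple/weighted mode estimators, plus
odds-ratio reporting. All estimators operate on the retained rows of a
:class:`~mrmediate.summary_stats.HarmonizedSet` and are invariant to a
simultaneous sign flip of (beta_exposure, beta_outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from mrmediate.errors import DomainError, InsufficientInstrumentsError
from mrmediate.summary_stats import HarmonizedSet

Z_95 = 1.959964  # two-sided 95% normal quantile as conventionally rounded

METHOD_LABELS = {
    "wald_ratio": "Wald ratio",
    "ivw": "Inverse variance weighted",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}


@dataclass
class MREstimate:
    """One method's causal estimate with OR-scale reporting."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    extra: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.or_, self.ci_low, self.ci_high = to_odds_ratio(self.beta, self.se)


@dataclass
class MRResultSet:
    """All applicable estimates for one exposure/outcome pair."""

    exposure_id: str
    outcome_id: str
    estimates: Dict[str, MREstimate]
    primary_method: str

    @property
    def primary(self) -> MREstimate:
        return self.estimates[self.primary_method]

    @property
    def significant(self) -> bool:
        """Primary (IVW or Wald) p < 0.05 — the headline evidence rule."""
        return bool(self.primary.pval < 0.05)


def to_odds_ratio(beta: float, se: float) -> Tuple[float, float, float]:
    """Exponentiate a log-scale effect and its 95% Wald interval."""
    if se < 0:
        raise DomainError(f"se must be >= 0, got {se}")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
    )


def _retained_arrays(h: HarmonizedSet):
    kept = h.retained
    return (
        kept["beta_exposure"].to_numpy(dtype=float),
        kept["se_exposure"].to_numpy(dtype=float),
        kept["beta_outcome"].to_numpy(dtype=float),
        kept["se_outcome"].to_numpy(dtype=float),
    )


def wald_ratio(
    bX: float, seX: float, bY: float, seY: float, second_order: bool = False
) -> MREstimate:
    """Single-SNP ratio estimate bY/bX with delta-method standard error.

    First-order SE (the default) is seY/|bX|; ``second_order`` adds the
    bY^2 seX^2 / bX^4 term.
    """
    if bX == 0:
        raise DomainError("Wald ratio undefined for bX = 0")
    beta = bY / bX
    var = (seY / bX) ** 2
    if second_order:
        var += bY**2 * seX**2 / bX**4
    se = float(np.sqrt(var))
    pval = _norm_p(beta, se)
    return MREstimate(method="wald_ratio", beta=float(beta), se=se, pval=pval, nsnp=1)


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _q_statistic(bX, bY, seY, beta_ivw) -> float:
    theta = bY / bX
    w = (bX / seY) ** 2
    return float(np.sum(w * (theta - beta_ivw) ** 2))


def ivw(h: HarmonizedSet, effects_model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of bY on bX through the origin.

    ``effects_model``: ``fixed``, ``multiplicative_random`` (SE inflated by
    sqrt(Q/(k-1)) floored at 1), or ``auto`` — fixed for k <= 3, random
    otherwise.
    """
    bX, seX, bY, seY = _retained_arrays(h)
    k = len(bX)
    if k < 1:
        raise InsufficientInstrumentsError("IVW needs at least one retained row")
    if k == 1:
        est = wald_ratio(bX[0], seX[0], bY[0], seY[0])
        return MREstimate("ivw", est.beta, est.se, est.pval, 1, extra={"delegated": 1.0})
    if np.all(bX == 0):
        raise DomainError("all exposure betas are zero: degenerate instruments")
    if effects_model == "auto":
        effects_model = "fixed" if k <= 3 else "multiplicative_random"
    if effects_model not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown effects model {effects_model!r}")

    w = 1.0 / seY**2
    denom = float(np.sum(w * bX**2))
    beta = float(np.sum(w * bX * bY)) / denom
    se = denom**-0.5
    q = _q_statistic(bX, bY, seY, beta)
    scale = 1.0
    if effects_model == "multiplicative_random":
        scale = max(1.0, np.sqrt(q / (k - 1)))
        se *= scale
    return MREstimate(
        "ivw",
        beta,
        float(se),
        _norm_p(beta, se),
        k,
        extra={"Q": q, "Q_df": float(k - 1), "se_inflation": float(scale)},
    )


def _weighted_linear_fit(x, y, w):
    """WLS of y on [1, x]; returns (coefs, cov_unit, rss_w)."""
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    coefs = np.linalg.solve(xtwx, Xw.T @ y)
    resid = y - X @ coefs
    rss_w = float(np.sum(w * resid**2))
    return coefs, np.linalg.inv(xtwx), rss_w


def mr_egger(h: HarmonizedSet) -> MREstimate:
    """Egger regression: weighted fit of bY on bX with a free intercept.

    Rows are oriented so bX >= 0; weights are 1/seY^2. The slope is the
    causal estimate; the intercept (directional-pleiotropy term), its SE
    and t-based p-value (k-2 df) land in ``extra``. Standard WLS inference
    with the estimated residual scale keeps the intercept test exact at
    its nominal level under the null.
    """
    bX, _, bY, seY = _retained_arrays(h)
    k = len(bX)
    if k < 3:
        raise InsufficientInstrumentsError("Egger regression needs >= 3 retained rows")
    sign = np.where(bX < 0, -1.0, 1.0)
    x = bX * sign
    y = bY * sign
    w = 1.0 / seY**2
    coefs, cov_unit, rss_w = _weighted_linear_fit(x, y, w)
    df = k - 2
    sigma2 = rss_w / df
    degenerate = rss_w < 1e-18 * max(1.0, float(np.sum(w * y**2)))
    se_int, se_slope = np.sqrt(np.diag(cov_unit) * sigma2)
    slope, intercept = float(coefs[1]), float(coefs[0])

    def _t_p(est, se) -> Optional[float]:
        if degenerate:
            return None  # zero-residual fit: inference undefined, flagged
        return float(2.0 * stats.t.sf(abs(est) / se, df))

    slope_p = _t_p(slope, se_slope)
    extra = {
        "egger_intercept": intercept,
        "egger_intercept_se": float(se_int),
        "egger_intercept_pval": _t_p(intercept, se_int),
        "residual_sigma2": float(sigma2),
        "degenerate_fit": float(degenerate),
    }
    return MREstimate(
        "egger",
        slope,
        float(se_slope),
        slope_p if slope_p is not None else (0.0 if slope != 0 else 1.0),
        k,
        extra=extra,
    )


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 1/2."""
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(th[0])
    if cum[-1] <= 0.5:
        return float(th[-1])
    below = int(np.searchsorted(cum, 0.5, side="right")) - 1
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(th[below] + frac * (th[below + 1] - th[below]))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator, robust to <50% invalid instrument weight.

    Per-SNP ratios are weighted by their inverse first-order variance; the
    SE comes from a seeded parametric bootstrap of (bX, bY).
    """
    bX, seX, bY, seY = _retained_arrays(h)
    k = len(bX)
    if k < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 retained rows")
    theta = bY / bX
    weights = bX**2 / seY**2  # 1 / var(theta_j), first order
    beta = _weighted_median_point(theta, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(bX, seX)
        by = rng.normal(bY, seY)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        boots[b] = _weighted_median_point(by / bx, bx**2 / seY**2)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", beta, se, _norm_p(beta, se), k)


def _kde_mode(theta: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Mode of a weighted normal-kernel density over the ratio estimates."""
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, abs(iqr) / 1.34) if iqr != 0 else sd
    bw = phi * 1.06 * spread * len(theta) ** (-0.2)
    if bw <= 0 or not np.isfinite(bw):
        # all ratios (essentially) identical
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * bw, theta.max() + 3 * bw, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / bw) ** 2) @ weights
    return float(grid[int(np.argmax(dens))])


def mode_estimators(
    h: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> Tuple[MREstimate, MREstimate]:
    """Simple-mode (unweighted) and weighted-mode kernel density estimates.

    Bandwidth is ``phi * 1.06 * min(sd, IQR/1.34) * k**(-1/5)``; SEs come
    from a shared seeded parametric bootstrap.
    """
    bX, seX, bY, seY = _retained_arrays(h)
    k = len(bX)
    if k < 3:
        raise InsufficientInstrumentsError("mode estimators need >= 3 retained rows")
    theta = bY / bX
    w_inv_var = bX**2 / seY**2
    ones = np.ones(k)
    beta_simple = _kde_mode(theta, ones, phi)
    beta_weighted = _kde_mode(theta, w_inv_var / w_inv_var.sum() * k, phi)

    rng = np.random.default_rng(seed)
    boots_s = np.empty(n_boot)
    boots_w = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(bX, seX)
        by = rng.normal(bY, seY)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        th = by / bx
        wv = bx**2 / seY**2
        boots_s[b] = _kde_mode(th, ones, phi)
        boots_w[b] = _kde_mode(th, wv / wv.sum() * k, phi)
    se_s = float(np.std(boots_s, ddof=1))
    se_w = float(np.std(boots_w, ddof=1))
    return (
        MREstimate("simple_mode", beta_simple, se_s, _norm_p(beta_simple, se_s), k),
        MREstimate("weighted_mode", beta_weighted, se_w, _norm_p(beta_weighted, se_w), k),
    )


def run_all_methods(
    h: HarmonizedSet,
    effects_model: str = "auto",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResultSet:
    """Apply every estimator whose instrument-count minimum is met.

    One retained row gives the Wald ratio alone; two rows add IVW; three
    or more enable all five methods. IVW (or the Wald ratio at k=1) is the
    primary estimate.
    """
    kept = h.retained
    k = len(kept)
    if k < 1:
        raise InsufficientInstrumentsError("no retained rows to analyse")
    estimates: Dict[str, MREstimate] = {}
    if k == 1:
        row = kept.iloc[0]
        estimates["wald_ratio"] = wald_ratio(
            float(row["beta_exposure"]),
            float(row["se_exposure"]),
            float(row["beta_outcome"]),
            float(row["se_outcome"]),
        )
        primary = "wald_ratio"
    else:
        estimates["ivw"] = ivw(h, effects_model=effects_model)
        primary = "ivw"
        if k >= 3:
            estimates["egger"] = mr_egger(h)
            estimates["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
            simple, weighted = mode_estimators(h, phi=phi, n_boot=n_boot, seed=seed + 1)
            estimates["simple_mode"] = simple
            estimates["weighted_mode"] = weighted
    return MRResultSet(
        exposure_id=h.exposure_id,
        outcome_id=h.outcome_id,
        estimates=estimates,
        primary_method=primary,
    )
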