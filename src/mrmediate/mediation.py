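"""Three-node mediation: six directional MR assessments and the decomposition.

For an exposure -> mediator -> outcome triple the mediated effect is the
product of the exposure->mediator and mediator->outcome estimates, the
direct effect is the total minus the mediated effect, and the mediated
proportion is their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from mrmediate.config import AnalysisConfig
from mrmediate.errors import DomainError, InsufficientInstrumentsError
from mrmediate.estimators import MRResultSet, run_all_methods
from mrmediate.instruments import LDMatrix, select_instruments, steiger_filter
from mrmediate.summary_stats import HarmonizedSet, SummaryStatsTable, harmonise

FORWARD_LEGS = ("exposure_outcome", "mediator_outcome", "exposure_mediator")
REVERSE_LEGS = ("outcome_exposure", "outcome_mediator", "mediator_exposure")


@dataclass
class MediationResult:
    """Effect decomposition for one exposure -> mediator -> outcome triple."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_all: float
    beta1: float
    beta2: float
    beta_mediation: float
    beta_direct: float
    beta_mediation_ratio: float
    assessments: Dict[str, Optional[MRResultSet]] = field(default_factory=dict)
    valid_pathway: bool = False
    evaluable: bool = True
    failed_leg: Optional[str] = None


def mediation_product(beta1: float, beta2: float) -> float:
    """Mediated (indirect) effect: product of the two pathway legs."""
    return beta1 * beta2


def mediation_decompose(
    beta_all: float, beta_mediation: float
) -> Tuple[float, float]:
    """Split a total effect into (direct effect, mediated proportion)."""
    if beta_all == 0:
        raise DomainError("mediated proportion undefined for beta_all = 0")
    return beta_all - beta_mediation, beta_mediation / beta_all


def _delta_se(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """Optional delta-method SE of the product term (extension, not default)."""
    return float(np.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2))


def _run_leg(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    cfg: AnalysisConfig,
) -> Tuple[Optional[MRResultSet], Optional[HarmonizedSet], Optional[str]]:
    """One directional MR assessment: select, harmonise, Steiger, estimate."""
    inst = select_instruments(
        exposure,
        ld,
        p_threshold=cfg.p_threshold,
        r2_threshold=cfg.r2_threshold,
        window_kb=cfg.window_kb,
        f_threshold=cfg.f_threshold,
        min_snps=cfg.min_snps,
    )
    if inst.insufficient:
        return None, None, "insufficient_instruments"
    sub = SummaryStatsTable(
        trait_id=exposure.trait_id,
        df=exposure.df[exposure.df["snp_id"].isin(inst.snp_ids)].copy(),
        trait_type=exposure.trait_type,
        ancestry_label=exposure.ancestry_label,
    )
    try:
        h = harmonise(sub, outcome, palindrome_maf_band=cfg.palindrome_maf_band)
    except Exception:
        return None, None, "no_overlap"
    if cfg.apply_steiger_filter and h.n_exposure is not None and h.n_outcome is not None:
        h = steiger_filter(h)
    if h.nsnp < cfg.min_snps:
        return None, h, "insufficient_instruments"
    try:
        res = run_all_methods(
            h,
            effects_model=cfg.effects_model,
            phi=cfg.phi,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        )
    except InsufficientInstrumentsError:
        return None, h, "insufficient_instruments"
    return res, h, None


def _reverse_cleared(res: Optional[MRResultSet], reason: Optional[str], alpha: float) -> bool:
    """A reverse leg is cleared when Steiger-filtered instruments leave no
    significant reverse signal (or no instruments at all)."""
    if res is None:
        return reason == "insufficient_instruments" or reason == "no_overlap"
    return res.primary.pval >= alpha


def run_mediation(
    exposure: SummaryStatsTable,
    mediator: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    config: Optional[AnalysisConfig] = None,
) -> MediationResult:
    """Run the six directional assessments and decompose the total effect.

    Forward legs (exposure->outcome, mediator->outcome, exposure->mediator)
    supply beta_all, beta2 and beta1 from their primary (IVW or Wald)
    estimates; reverse legs are run with Steiger filtering to rule out
    reverse causation. A pathway is valid when all forward legs are
    significant and all reverse legs are cleared.
    """
    cfg = config or AnalysisConfig()
    pairs = {
        "exposure_outcome": (exposure, outcome),
        "outcome_exposure": (outcome, exposure),
        "mediator_outcome": (mediator, outcome),
        "outcome_mediator": (outcome, mediator),
        "exposure_mediator": (exposure, mediator),
        "mediator_exposure": (mediator, exposure),
    }
    assessments: Dict[str, Optional[MRResultSet]] = {}
    reasons: Dict[str, Optional[str]] = {}
    for leg, (exp_t, out_t) in pairs.items():
        res, _, reason = _run_leg(exp_t, out_t, ld, cfg)
        assessments[leg] = res
        reasons[leg] = reason

    for leg in FORWARD_LEGS:
        if assessments[leg] is None:
            return MediationResult(
                exposure_id=exposure.trait_id,
                mediator_id=mediator.trait_id,
                outcome_id=outcome.trait_id,
                beta_all=float("nan"),
                beta1=float("nan"),
                beta2=float("nan"),
                beta_mediation=float("nan"),
                beta_direct=float("nan"),
                beta_mediation_ratio=float("nan"),
                assessments=assessments,
                valid_pathway=False,
                evaluable=False,
                failed_leg=leg,
            )

    beta_all = assessments["exposure_outcome"].primary.beta
    beta1 = assessments["exposure_mediator"].primary.beta
    beta2 = assessments["mediator_outcome"].primary.beta
    beta_med = mediation_product(beta1, beta2)
    if beta_all != 0:
        beta_direct, ratio = mediation_decompose(beta_all, beta_med)
    else:
        beta_direct, ratio = -beta_med, float("nan")

    alpha = cfg.significance_alpha
    forward_ok = all(assessments[leg].significant for leg in FORWARD_LEGS)
    reverse_ok = all(
        _reverse_cleared(assessments[leg], reasons[leg], alpha) for leg in REVERSE_LEGS
    )
    return MediationResult(
        exposure_id=exposure.trait_id,
        mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
        beta_all=beta_all,
        beta1=beta1,
        beta2=beta2,
        beta_mediation=beta_med,
        beta_direct=beta_direct,
        beta_mediation_ratio=ratio,
        assessments=assessments,
        valid_pathway=bool(forward_ok and reverse_ok),
    )


def screen_mediation_pathways(
    results: List[MediationResult], require_valid: bool = True
) -> List[MediationResult]:
    """Keep pathways whose mediated proportion is strictly positive.

    A positive proportion means the mediated effect is sign-concordant with
    the total effect. Results are sorted by descending proportion.
    """
    kept = [
        r
        for r in results
        if np.isfinite(r.beta_mediation_ratio)
        and r.beta_mediation_ratio > 0
        and (r.valid_pathway or not require_valid)
    ]
    return sorted(kept, key=lambda r: -r.beta_mediation_ratio)
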