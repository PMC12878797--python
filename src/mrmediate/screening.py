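"""Batch screening of many exposures against one outcome, with FDR control.

Per exposure: select instruments, harmonise, run all estimators and the
sensitivity suite; flag significance on the primary estimate; attach
Benjamini-Hochberg q-values across the batch; classify effect direction;
emit deterministic report tables.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from mrmediate.config import AnalysisConfig
from mrmediate.errors import DomainError
from mrmediate.estimators import MRResultSet, METHOD_LABELS
from mrmediate.instruments import LDMatrix, select_instruments, steiger_filter
from mrmediate.sensitivity import SensitivityReport, sensitivity_report
from mrmediate.summary_stats import (
    HarmonizedSet,
    SummaryStatsTable,
    harmonise,
)

# screening runs reuse the shared analysis configuration
ScreenConfig = AnalysisConfig


@dataclass
class ScreenRow:
    exposure_id: str
    outcome_id: str
    results: MRResultSet
    sensitivity: SensitivityReport
    harmonized: HarmonizedSet
    significant: bool
    direction: str  # protective | risk | null
    qval: float = float("nan")


@dataclass
class ScreenResult:
    rows: List[ScreenRow] = field(default_factory=list)
    skipped: List[Tuple[str, str]] = field(default_factory=list)  # (exposure_id, reason)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def significant_rows(self) -> List[ScreenRow]:
        return [r for r in self.rows if r.significant]


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _exposure_seed(base_seed: int, exposure_id: str) -> int:
    """Deterministic per-exposure seed: blake2 of the id mixed with the base."""
    digest = hashlib.blake2b(exposure_id.encode(), digest_size=8).digest()
    return (int.from_bytes(digest, "big") ^ (base_seed * 0x9E3779B97F4A7C15)) % 2**63


def run_exposure_screen(
    exposures: Sequence[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    config: Optional[ScreenConfig] = None,
) -> ScreenResult:
    """Screen every exposure against the outcome.

    Exposures without sufficient instruments are logged and skipped, never
    silently dropped. All bootstrap randomness derives from the config seed
    expanded per exposure, so results do not depend on input order.
    """
    cfg = config or ScreenConfig()
    result = ScreenResult()
    for exposure in sorted(exposures, key=lambda t: t.trait_id):
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
            result.skipped.append((exposure.trait_id, "insufficient_instruments"))
            continue
        sub = SummaryStatsTable(
            trait_id=exposure.trait_id,
            df=exposure.df[exposure.df["snp_id"].isin(inst.snp_ids)].copy(),
            trait_type=exposure.trait_type,
            ancestry_label=exposure.ancestry_label,
        )
        try:
            h = harmonise(sub, outcome, palindrome_maf_band=cfg.palindrome_maf_band)
        except Exception:
            result.skipped.append((exposure.trait_id, "no_overlap"))
            continue
        if cfg.apply_steiger_filter and h.n_exposure is not None and h.n_outcome is not None:
            h = steiger_filter(h)
        if h.nsnp < max(cfg.min_snps, 1):
            result.skipped.append((exposure.trait_id, "insufficient_instruments"))
            continue
        from mrmediate.estimators import run_all_methods  # local to avoid cycle

        res = run_all_methods(
            h,
            effects_model=cfg.effects_model,
            phi=cfg.phi,
            n_boot=cfg.n_boot,
            seed=_exposure_seed(cfg.seed, exposure.trait_id),
        )
        sens = sensitivity_report(h, effects_model=cfg.effects_model)
        or_ = res.primary.or_
        if or_ < 1:
            direction = "protective"
        elif or_ > 1:
            direction = "risk"
        else:
            direction = "null"
        result.rows.append(
            ScreenRow(
                exposure_id=exposure.trait_id,
                outcome_id=outcome.trait_id,
                results=res,
                sensitivity=sens,
                harmonized=h,
                significant=res.primary.pval < cfg.significance_alpha,
                direction=direction,
            )
        )
    if result.rows:
        qvals = bh_fdr([r.results.primary.pval for r in result.rows])
        for row, q in zip(result.rows, qvals):
            row.qval = float(q)
    return result


def classify_effects(screen: ScreenResult) -> Dict[str, int]:
    """Partition significant rows into protective (OR<1) / risk (OR>1) counts."""
    sig = screen.significant_rows
    n_protective = sum(1 for r in sig if r.direction == "protective")
    n_risk = sum(1 for r in sig if r.direction == "risk")
    n_null = sum(1 for r in sig if r.direction == "null")
    return {
        "n_protective": n_protective,
        "n_risk": n_risk,
        "n_unclassified": n_null,
        "n_significant": len(sig),
        "n_total": len(screen.rows),
    }


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return "" if np.isnan(v) else format(v, ".10g")
    return str(v)


def _write_tsv(path: str, header: List[str], rows: List[List]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_report(screen: ScreenResult, outdir: str) -> List[str]:
    """Emit the tabular report files (forest, scatter, per-SNP, sensitivity).

    All orderings are deterministic; re-running with the same seed
    reproduces byte-identical output.
    """
    os.makedirs(outdir, exist_ok=True)
    written: List[str] = []

    forest = []
    scatter = []
    single = []
    funnel = []
    loo = []
    het = []
    pleio = []
    steiger = []
    for row in screen.rows:
        for method in sorted(row.results.estimates):
            est = row.results.estimates[method]
            forest.append(
                [
                    row.exposure_id,
                    row.outcome_id,
                    METHOD_LABELS.get(method, method),
                    est.nsnp,
                    est.beta,
                    est.se,
                    est.pval,
                    est.or_,
                    est.ci_low,
                    est.ci_high,
                ]
            )
            for snp_row in row.harmonized.retained.itertuples(index=False):
                scatter.append(
                    [
                        row.exposure_id,
                        row.outcome_id,
                        METHOD_LABELS.get(method, method),
                        snp_row.snp_id,
                        snp_row.beta_exposure,
                        snp_row.beta_outcome,
                        est.beta,
                        est.extra.get("egger_intercept", 0.0) if method == "egger" else 0.0,
                    ]
                )
        for snp, theta, inv_se in row.sensitivity.funnel:
            single.append([row.exposure_id, row.outcome_id, snp, theta, 1.0 / inv_se])
            funnel.append([row.exposure_id, row.outcome_id, snp, theta, inv_se])
        for snp, beta, se, pval in row.sensitivity.loo:
            loo.append([row.exposure_id, row.outcome_id, snp, beta, se, pval])
        het.append(
            [
                row.exposure_id,
                row.outcome_id,
                "Inverse variance weighted",
                row.sensitivity.q_stat,
                row.sensitivity.q_df,
                row.sensitivity.q_pval,
            ]
        )
        pleio.append(
            [
                row.exposure_id,
                row.outcome_id,
                row.sensitivity.egger_intercept,
                row.sensitivity.egger_intercept_se,
                row.sensitivity.egger_intercept_pval,
            ]
        )
        if row.sensitivity.steiger is not None:
            st = row.sensitivity.steiger
            steiger.append(
                [
                    row.exposure_id,
                    row.outcome_id,
                    "TRUE" if st.correct_causal_direction else "FALSE",
                    st.steiger_pval,
                ]
            )

    summary = []
    for row in screen.rows:
        summary.append(
            [
                row.exposure_id,
                row.outcome_id,
                row.results.primary_method,
                row.results.primary.pval,
                row.qval,
                "TRUE" if row.significant else "FALSE",
                row.direction,
            ]
        )

    files = {
        "forest.tsv": (
            ["exposure", "outcome", "method", "nsnp", "beta", "se", "pval", "or", "ci_low", "ci_high"],
            forest,
        ),
        "scatter.tsv": (
            ["exposure", "outcome", "method", "snp_id", "beta_exposure", "beta_outcome", "slope", "intercept"],
            scatter,
        ),
        "single_snp.tsv": (["exposure", "outcome", "snp_id", "beta", "se"], single),
        "funnel.tsv": (["exposure", "outcome", "snp_id", "beta", "inv_se"], funnel),
        "loo.tsv": (["exposure", "outcome", "excluded_snp", "beta", "se", "pval"], loo),
        "heterogeneity.tsv": (
            ["id.exposure", "id.outcome", "method", "Q", "Q_df", "Q_pval"],
            het,
        ),
        "pleiotropy.tsv": (
            ["id.exposure", "id.outcome", "egger_intercept", "se", "pval"],
            pleio,
        ),
        "steiger.tsv": (
            ["id.exposure", "id.outcome", "correct_causal_direction", "steiger_pval"],
            steiger,
        ),
        "summary.tsv": (
            ["exposure", "outcome", "method", "pval", "qval", "significant", "direction"],
            summary,
        ),
        "skipped.tsv": (["exposure", "reason"], [list(t) for t in screen.skipped]),
    }
    for name, (header, rows) in files.items():
        path = os.path.join(outdir, name)
        _write_tsv(path, header, rows)
        written.append(path)
    return written
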