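"""Instrument selection: significance filter, LD clumping, F-statistic, Steiger.

The selection pipeline is p-filter -> greedy LD clump -> weak-instrument
(F) filter, with every exclusion recorded in a selection log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from mrmediate.errors import DomainError, FormatError, MissingSampleSizeError
from mrmediate.summary_stats import (
    DROP_STEIGER,
    HarmonizedSet,
    SummaryStatsTable,
)


@dataclass
class LDMatrix:
    """Pairwise squared correlations for a panel of SNPs."""

    snp_ids: List[str]
    r2: np.ndarray
    positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise FormatError(f"LD matrix shape {self.r2.shape} does not match {k} SNPs")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise FormatError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-6):
            raise FormatError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-8 or self.r2.max() > 1 + 1e-8:
            raise FormatError("LD r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, snp_a: str, snp_b: str) -> float:
        try:
            return float(self.r2[self._index[snp_a], self._index[snp_b]])
        except KeyError as exc:
            raise FormatError(f"SNP {exc.args[0]!r} absent from LD matrix") from None

    @classmethod
    def read(cls, path) -> "LDMatrix":
        """Read either a square TSV matrix or long (snp_a, snp_b, r2) format."""
        head = pd.read_csv(path, sep="\t", nrows=1)
        if list(head.columns[:3]) == ["snp_a", "snp_b", "r2"]:
            long = pd.read_csv(path, sep="\t")
            ids = sorted(set(long["snp_a"]) | set(long["snp_b"]))
            idx = {s: i for i, s in enumerate(ids)}
            r2 = np.eye(len(ids))
            for a, b, v in zip(long["snp_a"], long["snp_b"], long["r2"]):
                r2[idx[a], idx[b]] = v
                r2[idx[b], idx[a]] = v
            return cls(ids, r2)
        wide = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(wide.columns), wide.to_numpy(dtype=float))

    def write(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class InstrumentSet:
    """Outcome of instrument selection for one exposure."""

    exposure_id: str
    snp_ids: List[str]
    per_snp_f: Dict[str, float]
    mean_f: float
    selection_log: List[Tuple[str, str, str]] = field(default_factory=list)
    insufficient: bool = False

    def __len__(self) -> int:
        return len(self.snp_ids)


def per_variant_f(beta: float, se: float) -> float:
    """Per-variant instrument-strength F-statistic, approximated as (beta/se)^2."""
    if not se > 0:
        raise DomainError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def per_variant_f_exact(eaf: float, beta: float, se: float, n: float) -> float:
    """Exact F from variance explained: F = (n-2) r2 / (1 - r2).

    r2 is computed from eaf, beta and n assuming a standardized trait.
    """
    if not se > 0:
        raise DomainError(f"se must be > 0, got {se}")
    if n is None or np.isnan(n):
        raise MissingSampleSizeError("exact F requires sample size n")
    if not 0 < eaf < 1:
        raise DomainError("exact F requires eaf in (0, 1)")
    var_g = 2.0 * eaf * (1.0 - eaf)
    r2 = beta**2 * var_g / (beta**2 * var_g + se**2 * var_g * n)
    return (n - 2) * r2 / (1 - r2)


def _chrom_key(chrom: str):
    s = str(chrom)
    return (0, int(s)) if s.isdigit() else (1, s)


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> Tuple[List[str], List[Tuple[str, str, str]]]:
    """Greedy LD clumping.

    Repeatedly takes the smallest-p unprocessed candidate as an index SNP and
    discards unprocessed candidates on the same chromosome within
    ``window_kb`` kilobases whose r2 with the index exceeds ``r2_threshold``.
    Ties in p are broken by (chromosome, position, snp_id) so the result is
    independent of input row order.

    ``candidates`` needs columns snp_id, chrom, pos, pval.
    """
    if not 0 < r2_threshold <= 1:
        raise DomainError("r2_threshold must lie in (0, 1]")
    if not window_kb > 0:
        raise DomainError("window_kb must be > 0")
    for snp in candidates["snp_id"]:
        if snp not in ld._index:
            raise FormatError(f"candidate SNP {snp!r} absent from LD matrix")

    order = sorted(
        candidates.itertuples(index=False),
        key=lambda r: (r.pval, _chrom_key(r.chrom), int(r.pos), r.snp_id),
    )
    window_bp = window_kb * 1000
    retained: List[str] = []
    log: List[Tuple[str, str, str]] = []
    processed: set = set()
    for idx_row in order:
        if idx_row.snp_id in processed:
            continue
        retained.append(idx_row.snp_id)
        processed.add(idx_row.snp_id)
        for other in order:
            if other.snp_id in processed:
                continue
            if str(other.chrom) != str(idx_row.chrom):
                continue
            if abs(int(other.pos) - int(idx_row.pos)) > window_bp:
                continue
            r2 = ld.lookup(idx_row.snp_id, other.snp_id)
            if r2 > r2_threshold:
                processed.add(other.snp_id)
                log.append(
                    (
                        other.snp_id,
                        "clumped",
                        f"r2={r2:.4g} with index {idx_row.snp_id} within {window_kb} kb",
                    )
                )
    return retained, log


def select_instruments(
    exposure: SummaryStatsTable,
    ld: LDMatrix,
    p_threshold: float = 5e-6,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    f_threshold: float = 10.0,
    min_snps: int = 1,
) -> InstrumentSet:
    """Full selection pipeline: p-filter, LD clump, weak-instrument filter.

    The default ``p_threshold`` of 5e-6 and ``min_snps`` of 1 are the
    screening settings actually applied in the reference analysis; 5e-8
    and a strict three-instrument minimum are available by argument.
    """
    df = exposure.df
    log: List[Tuple[str, str, str]] = []

    passing = df[df["pval"] < p_threshold]
    for snp, p in zip(df["snp_id"], df["pval"]):
        if p >= p_threshold:
            log.append((snp, "p_filter", f"pval={p:.3g} >= {p_threshold:g}"))

    if len(passing):
        retained, clump_log = ld_clump(passing, ld, r2_threshold, window_kb)
        log.extend(clump_log)
    else:
        retained = []

    sub = df.set_index("snp_id")
    per_f: Dict[str, float] = {}
    final: List[str] = []
    for snp in retained:
        f = per_variant_f(float(sub.loc[snp, "beta"]), float(sub.loc[snp, "se"]))
        if f < f_threshold:
            log.append((snp, "weak_instrument", f"F={f:.4g} < {f_threshold:g}"))
        else:
            per_f[snp] = f
            final.append(snp)

    mean_f = float(np.mean(list(per_f.values()))) if per_f else float("nan")
    return InstrumentSet(
        exposure_id=exposure.trait_id,
        snp_ids=final,
        per_snp_f=per_f,
        mean_f=mean_f,
        selection_log=log,
        insufficient=len(final) < min_snps,
    )


def _steiger_r2(beta: np.ndarray, se: np.ndarray, n: float) -> np.ndarray:
    """Per-SNP variance explained from the t-statistic transform."""
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2.0)


def steiger_filter(h: HarmonizedSet) -> HarmonizedSet:
    """Drop rows whose instruments explain more outcome than exposure variance."""
    if h.n_exposure is None or h.n_outcome is None:
        raise MissingSampleSizeError(
            "Steiger filtering needs sample sizes for both traits"
        )
    kept = h.retained
    if not len(kept):
        return h
    r2x = _steiger_r2(
        kept["beta_exposure"].to_numpy(), kept["se_exposure"].to_numpy(), h.n_exposure
    )
    r2y = _steiger_r2(
        kept["beta_outcome"].to_numpy(), kept["se_outcome"].to_numpy(), h.n_outcome
    )
    failing = kept.loc[r2y > r2x, "snp_id"]
    return h.drop(failing, DROP_STEIGER)
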