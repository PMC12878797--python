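"""Synthetic three-node GWAS studies for offline testing.

Generates individual-level cohorts under an exposure -> mediator -> outcome
causal diagram (with optional pleiotropy, LD blocks, confounding and
extreme case-control imbalance), computes marginal per-SNP summary
statistics for each trait from its own non-overlapping cohort, and emits a
ground-truth sidecar so every pipeline stage can be checked against the
generative model.

SNP panel layout: the first ``n_snps - n_snps_mediator`` variants carry
direct effects on the exposure; the remaining ``n_snps_mediator`` carry
direct effects on the mediator (so the mediator has its own valid
instruments and the mediator->outcome leg is identified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.errors import DomainError
from mrmediate.instruments import LDMatrix
from mrmediate.summary_stats import SummaryStatsTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Generative model for one three-node study."""

    n_snps: int = 100
    n_snps_mediator: Optional[int] = None  # default: half the panel
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 50_000
    n_mediator: int = 50_000
    n_outcome: int = 50_000
    h2_exposure: float = 0.3
    h2_mediator: float = 0.3
    theta_direct: float = 0.1
    beta1_true: float = 0.1
    beta2_true: float = 0.2
    pleiotropy: Tuple = ("none",)  # ("none",) | ("balanced", sd) | ("directional", mean, sd)
    confounding_strength: float = 0.0
    outcome_type: str = "continuous"  # continuous | binary
    case_fraction: float = 0.01
    ld_blocks: Optional[List[Tuple[int, float]]] = None
    scramble_alleles: bool = True
    palindromic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2_exposure < 1:
            raise DomainError("h2_exposure must lie in [0, 1)")
        if not 0 <= self.h2_mediator < 1:
            raise DomainError("h2_mediator must lie in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise DomainError("case_fraction must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DomainError("maf_range must satisfy 0 < low <= high <= 0.5")
        if min(self.n_exposure, self.n_mediator, self.n_outcome) <= 0:
            raise DomainError("cohort sizes must be > 0")
        if self.n_snps_mediator is None:
            self.n_snps_mediator = self.n_snps // 2
        if not 0 <= self.n_snps_mediator <= self.n_snps:
            raise DomainError("n_snps_mediator must lie in [0, n_snps]")
        if self.ld_blocks is not None:
            total = sum(size for size, _ in self.ld_blocks)
            if total > self.n_snps:
                raise DomainError("ld_blocks cover more SNPs than n_snps")
            for size, r2 in self.ld_blocks:
                if not (0 <= r2 <= 1):
                    raise DomainError(f"infeasible within-block r2 {r2}")
        if self.pleiotropy[0] not in ("none", "balanced", "directional"):
            raise DomainError(f"unknown pleiotropy model {self.pleiotropy[0]!r}")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.beta1_true * self.beta2_true


@dataclass
class CohortTruth:
    """Ground-truth sidecar for one simulated study."""

    snp_ids: List[str]
    maf: np.ndarray
    beta_exposure_true: np.ndarray  # joint per-allele effects on the exposure
    beta_mediator_true: np.ndarray  # b1 * a_j + direct mediator effects
    beta_outcome_true: np.ndarray  # includes mediated, direct and pleiotropic parts
    alpha_pleiotropy: np.ndarray
    theta_total: float
    # per-trait allele-scramble log: snp_id -> action in
    # {identity, swap, complement, complement_swap}
    scrambles: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "maf": self.maf,
                "beta_exposure_true": self.beta_exposure_true,
                "beta_mediator_true": self.beta_mediator_true,
                "beta_outcome_true": self.beta_outcome_true,
                "alpha_pleiotropy": self.alpha_pleiotropy,
            }
        )


@dataclass
class _SnpPanel:
    """Shared variant panel: frequencies, positions, alleles, LD structure."""

    snp_ids: List[str]
    maf: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: List[str]
    other_allele: List[str]
    blocks: List[Tuple[np.ndarray, float]]  # (member indices, copy prob q)


def _make_panel(config: SimulationConfig, rng: np.random.Generator) -> _SnpPanel:
    m = config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    blocks: List[Tuple[np.ndarray, float]] = []
    cursor = 0
    if config.ld_blocks:
        for size, r2 in config.ld_blocks:
            idx = np.arange(cursor, cursor + size)
            maf[idx] = maf[cursor]  # block-constant frequency keeps r2 tractable
            q = float(r2) ** 0.25  # haplotype copy prob: corr = q^2, r2 = q^4
            blocks.append((idx, q))
            cursor += size
    for j in range(cursor, m):
        blocks.append((np.arange(j, j + 1), 1.0))

    pal = rng.random(m) < config.palindromic_fraction
    eff, oth = [], []
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if pal[j] else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        eff.append(a)
        oth.append(b)
    # one SNP per 500 kb keeps everything inside a single clumping window
    pos = 1 + np.arange(m, dtype=np.int64) * 500_000
    return _SnpPanel(
        snp_ids=[f"rs{j + 1:06d}" for j in range(m)],
        maf=maf,
        chrom=np.array(["1"] * m),
        pos=pos,
        effect_allele=eff,
        other_allele=oth,
        blocks=blocks,
    )


def _draw_genotypes(
    panel: _SnpPanel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-individual allele counts with block LD via latent haplotype copying."""
    m = len(panel.snp_ids)
    g = np.empty((n, m), dtype=np.int8)
    singles = np.array([idx[0] for idx, _ in panel.blocks if len(idx) == 1], dtype=int)
    if len(singles):
        p_row = panel.maf[singles][None, :]
        counts = (rng.random((n, len(singles))) < p_row).view(np.int8)
        counts += (rng.random((n, len(singles))) < p_row).view(np.int8)
        g[:, singles] = counts
    for idx, q in panel.blocks:
        if len(idx) == 1:
            continue
        p = panel.maf[idx[0]]
        if q >= 1.0:
            shared = (rng.random((n, 2)) < p).view(np.int8).sum(axis=1, dtype=np.int8)
            g[:, idx] = shared[:, None]
            continue
        latent = (rng.random((n, 2)) < p).view(np.int8)
        for j in idx:
            copy_mask = rng.random((n, 2)) < q
            fresh = (rng.random((n, 2)) < p).view(np.int8)
            hap = np.where(copy_mask, latent, fresh)
            g[:, j] = hap.sum(axis=1, dtype=np.int8)
    return g


def simulate_genotypes(
    config: SimulationConfig,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, LDMatrix]:
    """Draw a genotype matrix and the LD matrix realized from it."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    panel = _make_panel(config, rng)
    g = _draw_genotypes(panel, n if n is not None else config.n_exposure, rng)
    return g, realized_ld(panel.snp_ids, g, panel.pos)


def realized_ld(snp_ids: List[str], genotypes: np.ndarray, positions=None) -> LDMatrix:
    gz = genotypes.astype(float)
    sd = gz.std(axis=0)
    sd[sd == 0] = 1.0
    corr = np.corrcoef(gz, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    r2 = np.clip(corr**2, 0.0, 1.0)
    return LDMatrix(list(snp_ids), r2, positions)


def _theoretical_score_var(panel: _SnpPanel, effects: np.ndarray) -> float:
    """Var of sum_j effects_j * g_j under the panel's block-LD model."""
    var = 0.0
    for idx, q in panel.blocks:
        p = panel.maf[idx[0]]
        vg = 2.0 * p * (1.0 - p)
        a = effects[idx]
        corr = q**2
        var += vg * (np.sum(a**2) + corr * (np.sum(a) ** 2 - np.sum(a**2)))
    return float(var)


def _draw_effects(
    config: SimulationConfig, panel: _SnpPanel, rng: np.random.Generator
):
    m = config.n_snps
    n_med = config.n_snps_mediator
    n_exp = m - n_med
    a = np.zeros(m)
    d = np.zeros(m)  # direct mediator effects
    if n_exp and config.h2_exposure > 0:
        a[:n_exp] = rng.normal(size=n_exp)
        a *= np.sqrt(config.h2_exposure / _theoretical_score_var(panel, a))
    if n_med and config.h2_mediator > 0:
        d[n_exp:] = rng.normal(size=n_med)
        d *= np.sqrt(config.h2_mediator / _theoretical_score_var(panel, d))

    kind = config.pleiotropy[0]
    alpha = np.zeros(m)
    if kind == "balanced":
        sd = config.pleiotropy[1]
        alpha[:n_exp] = rng.normal(0.0, sd, size=n_exp)
    elif kind == "directional":
        mean, sd = config.pleiotropy[1], config.pleiotropy[2]
        # aligned with the exposure-increasing allele so the mean survives
        # the bX >= 0 orientation used by Egger regression
        draw = rng.normal(mean, sd, size=n_exp)
        alpha[:n_exp] = np.where(a[:n_exp] < 0, -draw, draw)
    return a, d, alpha


def simulate_phenotypes(
    genotypes: np.ndarray,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    effects: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
    panel: Optional[_SnpPanel] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, CohortTruth]:
    """Generate (exposure, mediator, outcome-liability/status) for one cohort.

    X = G a + c U + eX,  M = b1 X + G d + c U + eM,
    Y = theta_direct X + b2 M + G alpha + c U + eY;
    a binary outcome thresholds the realized liability at the
    ``case_fraction`` upper quantile.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if panel is None:
        panel = _make_panel(config, np.random.default_rng(config.seed))
    if effects is None:
        effects = _draw_effects(config, panel, np.random.default_rng(config.seed + 1))
    a, d, alpha = effects
    n = genotypes.shape[0]
    g = genotypes.astype(float)
    c = config.confounding_strength
    u = rng.standard_normal(n)

    var_gx = _theoretical_score_var(panel, a)
    e_x = np.sqrt(max(1.0 - var_gx - c**2, 1e-12))
    x = g @ a + c * u + e_x * rng.standard_normal(n)

    var_gm = _theoretical_score_var(panel, d)
    e_m = np.sqrt(max(1.0 - var_gm - c**2, 1e-12))
    m_ = config.beta1_true * x + g @ d + c * u + e_m * rng.standard_normal(n)

    liability = (
        config.theta_direct * x
        + config.beta2_true * m_
        + g @ alpha
        + c * u
        + rng.standard_normal(n)
    )
    if config.outcome_type == "binary":
        cut = np.quantile(liability, 1.0 - config.case_fraction)
        y = (liability > cut).astype(float)
    else:
        y = liability

    b1, b2, td = config.beta1_true, config.beta2_true, config.theta_direct
    truth = CohortTruth(
        snp_ids=panel.snp_ids,
        maf=panel.maf.copy(),
        beta_exposure_true=a.copy(),
        beta_mediator_true=b1 * a + d,
        beta_outcome_true=a * (td + b1 * b2) + d * b2 + alpha,
        alpha_pleiotropy=alpha.copy(),
        theta_total=config.theta_total,
    )
    return x, m_, y, truth


def _scramble_actions(
    panel: _SnpPanel, rng: np.random.Generator
) -> pd.DataFrame:
    actions = rng.choice(
        ["identity", "swap", "complement", "complement_swap"], size=len(panel.snp_ids)
    )
    return pd.DataFrame({"snp_id": panel.snp_ids, "action": actions})


def marginal_summary_stats(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    outcome_type: str = "continuous",
    panel: Optional[_SnpPanel] = None,
    trait_id: str = "trait",
    scramble: Optional[pd.DataFrame] = None,
    snp_ids: Optional[List[str]] = None,
) -> SummaryStatsTable:
    """Per-SNP simple (linear-probability for binary) regression summaries.

    Binary traits are regressed on the 0/1 status scale, matching sources
    whose reported "log-odds" are in fact linear-probability effects.
    Constant genotype columns are emitted with missing beta and flagged in
    the table's ``flagged_snps`` attribute.
    """
    n, m = genotypes.shape
    g = genotypes.astype(float)
    y = np.asarray(phenotype, dtype=float)
    gbar = g.mean(axis=0)
    gc = g - gbar
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    ok = sxx > 0
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.ones(m)
    beta[ok] = sxy[ok] / sxx[ok]
    rss = syy - beta[ok] * sxy[ok]
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.abs(beta[ok] / se[ok])
    p_ok = 2.0 * stats.t.sf(tstat, n - 2)
    pval[ok] = np.clip(np.where(np.isnan(p_ok), 0.0, p_ok), 5e-324, 1.0)
    eaf = gbar / 2.0

    if panel is not None:
        ids = panel.snp_ids
        chrom, pos = panel.chrom, panel.pos
        eff = list(panel.effect_allele)
        oth = list(panel.other_allele)
    else:
        ids = snp_ids if snp_ids is not None else [f"snp{j + 1}" for j in range(m)]
        chrom = np.array(["1"] * m)
        pos = 1 + np.arange(m, dtype=np.int64) * 500_000
        eff = ["A"] * m
        oth = ["G"] * m

    if scramble is not None:
        act = scramble.set_index("snp_id").loc[ids, "action"].to_numpy()
        for j, action in enumerate(act):
            if action in ("swap", "complement_swap"):
                eff[j], oth[j] = oth[j], eff[j]
                beta[j] = -beta[j]
                eaf[j] = 1.0 - eaf[j]
            if action in ("complement", "complement_swap"):
                eff[j] = _COMPLEMENT[eff[j]]
                oth[j] = _COMPLEMENT[oth[j]]

    df = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": eff,
            "other_allele": oth,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": float(n),
        }
    )
    table = SummaryStatsTable(
        trait_id=trait_id,
        df=df,
        trait_type="binary" if outcome_type == "binary" else "continuous",
    )
    table.flagged_snps = [ids[j] for j in range(m) if not ok[j]]
    return table


def simulate_three_node_study(
    config: SimulationConfig,
) -> Tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable, LDMatrix, CohortTruth]:
    """Full two-sample fixture: three non-overlapping cohorts, one SNP panel.

    Each trait's summary statistics come from its own cohort; the LD matrix
    is computed from the exposure cohort's realized genotypes. With
    ``scramble_alleles`` the mediator and outcome tables get random allele
    relabelings (recorded in the truth sidecar) to exercise harmonisation;
    the exposure table stays in the panel frame.
    """
    rng = np.random.default_rng(config.seed)
    panel = _make_panel(config, rng)
    effects = _draw_effects(config, panel, rng)

    rng_x = np.random.default_rng(rng.integers(2**63))
    rng_m = np.random.default_rng(rng.integers(2**63))
    rng_y = np.random.default_rng(rng.integers(2**63))
    rng_scramble = np.random.default_rng(rng.integers(2**63))

    g_x = _draw_genotypes(panel, config.n_exposure, rng_x)
    x, _, _, truth = simulate_phenotypes(g_x, config, rng_x, effects, panel)
    g_m = _draw_genotypes(panel, config.n_mediator, rng_m)
    _, m_, _, _ = simulate_phenotypes(g_m, config, rng_m, effects, panel)
    g_y = _draw_genotypes(panel, config.n_outcome, rng_y)
    _, _, y, _ = simulate_phenotypes(g_y, config, rng_y, effects, panel)

    identity = pd.DataFrame({"snp_id": panel.snp_ids, "action": "identity"})
    if config.scramble_alleles:
        scr_m = _scramble_actions(panel, rng_scramble)
        scr_y = _scramble_actions(panel, rng_scramble)
    else:
        scr_m = identity.copy()
        scr_y = identity.copy()
    truth.scrambles = {"exposure": identity, "mediator": scr_m, "outcome": scr_y}

    exposure = marginal_summary_stats(
        g_x, x, "continuous", panel, trait_id="exposure", scramble=identity
    )
    mediator = marginal_summary_stats(
        g_m, m_, "continuous", panel, trait_id="mediator", scramble=scr_m
    )
    outcome = marginal_summary_stats(
        g_y, y, config.outcome_type, panel, trait_id="outcome", scramble=scr_y
    )
    ld = realized_ld(panel.snp_ids, g_x, panel.pos)
    return exposure, mediator, outcome, ld, truth
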