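"""Shared analysis configuration for the screening and mediation pipelines."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class AnalysisConfig:
    """Thresholds and knobs for one MR analysis run.

    Defaults mirror the screening settings of the reference analysis:
    p < 5e-6, clump r2 = 0.001 within 10,000 kb, F > 10, at least one SNP
    (Wald-ratio fallback). ``strict_min_snps`` of 3 enforces the stricter
    three-instrument rule when wanted.
    """

    p_threshold: float = 5e-6
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    f_threshold: float = 10.0
    min_snps: int = 1
    palindrome_maf_band: float = 0.08
    effects_model: str = "auto"
    phi: float = 1.0
    n_boot: int = 1000
    seed: int = 0
    apply_steiger_filter: bool = True
    significance_alpha: float = 0.05

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)
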