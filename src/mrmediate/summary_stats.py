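"""GWAS summary-statistics tables: reading, validation, writing, harmonisation.

The on-disk format is tab-separated text with a header. Canonical columns:

    snp_id chrom pos effect_allele other_allele eaf beta se pval n

``eaf`` and ``n`` are optional; all other columns are required. A *dialect*
mapping translates nonstandard header names onto the canonical ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.errors import DomainError, FormatError, NoOverlapError

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]
REQUIRED_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]
OPTIONAL_COLUMNS = ["eaf", "n"]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: dropped_reason codes used by :func:`harmonise` and the instrument filters
DROP_PALINDROMIC = "palindromic_ambiguous"
DROP_MISMATCH = "allele_mismatch"
DROP_STEIGER = "steiger_failed"


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's marginal association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_BASES:
            raise DomainError(
                f"{self.snp_id}: effect_allele {self.effect_allele!r} is not a single base"
            )
        if self.other_allele not in _VALID_BASES:
            raise DomainError(
                f"{self.snp_id}: other_allele {self.other_allele!r} is not a single base"
            )
        if self.effect_allele == self.other_allele:
            raise DomainError(f"{self.snp_id}: alleles must be distinct")
        if not self.se > 0:
            raise DomainError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise DomainError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not np.isnan(self.eaf):
            if not (0 <= self.eaf <= 1):
                raise DomainError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.n is not None and not np.isnan(self.n) and not self.n > 0:
            raise DomainError(f"{self.snp_id}: n must be > 0, got {self.n}")

    @property
    def palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC_PAIRS


@dataclass
class SummaryStatsTable:
    """Ordered collection of per-variant associations for one trait.

    Rows are held in a :class:`pandas.DataFrame` with canonical columns;
    ``snp_id`` is unique and row order is stable under read/write.
    """

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "continuous"  # continuous | binary
    ancestry_label: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise DomainError(f"trait_type must be continuous or binary, got {self.trait_type}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"table {self.trait_id}: missing required column(s) {missing}")
        for col in OPTIONAL_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = np.nan
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)
        dup = self.df["snp_id"][self.df["snp_id"].duplicated()]
        if len(dup):
            raise FormatError(
                f"table {self.trait_id}: duplicate snp_id values: {sorted(set(dup))}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[VariantAssociation]:
        for row in self.df.itertuples(index=False):
            yield VariantAssociation(
                snp_id=row.snp_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            )

    def validate(self, z_consistency_tol: float = 1.0) -> None:
        """Check row-level invariants; warn on p/z inconsistency, never edit.

        A row is flagged when the supplied p-value and the two-sided normal
        p implied by |beta/se| disagree by more than ``z_consistency_tol``
        units in -log10 space (default: a factor of 10).
        """
        for rec in self.records():
            pass  # constructor enforces the per-row invariants
        with np.errstate(divide="ignore"):
            z = np.abs(self.df["beta"].to_numpy() / self.df["se"].to_numpy())
            # log-space survival function survives arbitrarily large z
            implied_log10 = (np.log(2.0) + stats.norm.logsf(z)) / np.log(10.0)
            stated = self.df["pval"].to_numpy(dtype=float)
            ok = stated > 0
            gap = np.abs(np.log10(stated[ok]) - implied_log10[ok])
        bad = self.df.loc[np.flatnonzero(ok)[gap > z_consistency_tol], "snp_id"]
        if len(bad):
            warnings.warn(
                f"table {self.trait_id}: p-value inconsistent with beta/se for "
                f"{len(bad)} variant(s), e.g. {list(bad[:5])}",
                stacklevel=2,
            )


HARMONIZED_COLUMNS = [
    "snp_id",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_exposure",
    "eaf_outcome",
    "pval_exposure",
    "pval_outcome",
    "flipped",
    "palindromic",
    "dropped_reason",
]


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs expressed on a common effect-allele frame.

    Rows with ``dropped_reason`` set are excluded from estimation but kept
    for audit; :attr:`retained` is the view every estimator consumes.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame
    n_exposure: Optional[float] = None
    n_outcome: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.rows.columns]
        if missing:
            raise FormatError(f"harmonized set: missing column(s) {missing}")
        self.rows = self.rows.reset_index(drop=True)
        kept = self.retained
        if len(kept) and not ((kept["se_exposure"] > 0) & (kept["se_outcome"] > 0)).all():
            raise DomainError("retained rows must have positive standard errors")

    @property
    def retained(self) -> pd.DataFrame:
        return self.rows[self.rows["dropped_reason"].isna()]

    @property
    def nsnp(self) -> int:
        return int(len(self.retained))

    def drop(self, snp_ids, reason: str) -> "HarmonizedSet":
        """Return a copy with ``reason`` recorded on the given variants."""
        rows = self.rows.copy()
        mask = rows["snp_id"].isin(set(snp_ids)) & rows["dropped_reason"].isna()
        rows.loc[mask, "dropped_reason"] = reason
        return HarmonizedSet(
            self.exposure_id, self.outcome_id, rows, self.n_exposure, self.n_outcome
        )


def _normalise_dialect(dialect: Optional[Mapping[str, str]]) -> Mapping[str, str]:
    if dialect is None:
        return {c: c for c in CANONICAL_COLUMNS}
    return {canon: dialect.get(canon, canon) for canon in CANONICAL_COLUMNS}


def read_summary_stats(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    trait_id: Optional[str] = None,
    trait_type: str = "continuous",
    ancestry_label: str = "",
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics table.

    ``dialect`` maps canonical column names to the file's header names; map
    an optional column (``eaf``/``n``) to ``None`` to mark it absent.
    Rows failing numeric coercion raise with their 1-based data line numbers.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    colmap = _normalise_dialect(dialect)
    frame = {}
    for canon in CANONICAL_COLUMNS:
        src = colmap.get(canon)
        if src is None or src not in raw.columns:
            if canon in OPTIONAL_COLUMNS:
                frame[canon] = pd.Series([np.nan] * len(raw))
                continue
            raise FormatError(f"{path}: missing required column {canon!r} (header {src!r})")
        frame[canon] = raw[src]
    df = pd.DataFrame(frame)

    numeric = ["pos", "eaf", "beta", "se", "pval", "n"]
    bad_lines: list[int] = []
    for col in numeric:
        ser = df[col].replace({"": np.nan, "NA": np.nan, "nan": np.nan})
        # builtin float() is correctly rounded; pandas' fast parser is not
        values = np.empty(len(ser))
        for i, raw in enumerate(ser.to_numpy()):
            if raw is np.nan or (isinstance(raw, float) and np.isnan(raw)):
                values[i] = np.nan
                continue
            try:
                values[i] = float(raw)
            except (TypeError, ValueError):
                values[i] = np.nan
                bad_lines.append(i + 2)
        df[col] = values
    if bad_lines:
        raise FormatError(
            f"{path}: non-numeric values on line(s) {sorted(set(bad_lines))[:20]}"
        )
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("effect_allele", "other_allele"):
        bad = ~df[col].isin(_VALID_BASES)
        if bad.any():
            raise FormatError(
                f"{path}: non-SNP alleles (indel/multi-base) at snp_id "
                f"{df.loc[bad, 'snp_id'].tolist()[:10]}"
            )
    df["pos"] = df["pos"].astype(np.int64)
    table = SummaryStatsTable(
        trait_id=trait_id if trait_id is not None else str(path),
        df=df,
        trait_type=trait_type,
        ancestry_label=ancestry_label,
    )
    table.validate()
    return table


def write_summary_stats(table: SummaryStatsTable, path, sep: str = "\t") -> None:
    """Write a table in canonical column order, lossless for float64."""
    out = table.df.copy()
    for col in ("eaf", "beta", "se", "pval", "n"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else format(float(v), ".17g"))
    out.to_csv(path, sep=sep, index=False)


def _classify_pair(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str:
    """How do the outcome alleles relate to the exposure frame?"""
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    cea, coa = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "comp"
    if (cea, coa) == (oa_x, ea_x):
        return "comp_swap"
    return "mismatch"


def harmonise(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_maf_band: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure effect-allele frame.

    Allele swaps negate the outcome beta and reflect its EAF; strand
    complements relabel only. Palindromic pairs (A/T, G/C) cannot be
    resolved from alleles alone: they are dropped when either table's EAF
    lies inside ``0.5 +/- palindrome_maf_band`` (or is missing), otherwise
    strand is resolved by EAF concordance. Irreconcilable pairs are dropped
    as allele mismatches.
    """
    if not 0 <= palindrome_maf_band <= 0.5:
        raise DomainError("palindrome_maf_band must lie in [0, 0.5]")
    x = exposure.df.set_index("snp_id")
    y = outcome.df.set_index("snp_id")
    shared = [s for s in exposure.df["snp_id"] if s in y.index]
    if not shared:
        raise NoOverlapError(
            f"no overlapping variants between {exposure.trait_id} and {outcome.trait_id}"
        )

    lo, hi = 0.5 - palindrome_maf_band, 0.5 + palindrome_maf_band

    def _ambiguous(eaf) -> bool:
        return pd.isna(eaf) or (lo < float(eaf) < hi)

    out_rows = []
    for snp in shared:
        rx, ry = x.loc[snp], y.loc[snp]
        b_y, eaf_y = float(ry["beta"]), ry["eaf"]
        flipped = False
        dropped = None
        kind = _classify_pair(
            rx["effect_allele"], rx["other_allele"], ry["effect_allele"], ry["other_allele"]
        )
        pal = frozenset((rx["effect_allele"], rx["other_allele"])) in _PALINDROMIC_PAIRS
        if kind == "mismatch":
            dropped = DROP_MISMATCH
        elif pal:
            # alleles alone cannot distinguish strand; use EAF or drop
            if _ambiguous(rx["eaf"]) or _ambiguous(eaf_y):
                dropped = DROP_PALINDROMIC
            else:
                concordant = (float(rx["eaf"]) - 0.5) * (float(eaf_y) - 0.5) > 0
                if not concordant:
                    b_y = -b_y
                    eaf_y = 1.0 - float(eaf_y)
                    flipped = True
        elif kind in ("swap", "comp_swap"):
            b_y = -b_y
            if not pd.isna(eaf_y):
                eaf_y = 1.0 - float(eaf_y)
            flipped = True
        out_rows.append(
            {
                "snp_id": snp,
                "beta_exposure": float(rx["beta"]),
                "se_exposure": float(rx["se"]),
                "beta_outcome": b_y,
                "se_outcome": float(ry["se"]),
                "eaf_exposure": rx["eaf"],
                "eaf_outcome": eaf_y,
                "pval_exposure": float(rx["pval"]),
                "pval_outcome": float(ry["pval"]),
                "flipped": flipped,
                "palindromic": pal,
                "dropped_reason": dropped,
            }
        )
    rows = pd.DataFrame(out_rows, columns=HARMONIZED_COLUMNS)

    def _n_of(t: SummaryStatsTable):
        n = t.df["n"]
        return None if n.isna().all() else float(n.max())

    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        rows=rows,
        n_exposure=_n_of(exposure),
        n_outcome=_n_of(outcome),
    )


def write_harmonized(h: HarmonizedSet, path, sep: str = "\t") -> None:
    out = h.rows.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else format(float(v), ".17g"))
    out.to_csv(path, sep=sep, index=False)


def read_harmonized(
    path, exposure_id="exposure", outcome_id="outcome", n_exposure=None, n_outcome=None
) -> HarmonizedSet:
    rows = pd.read_csv(path, sep="\t")
    if "dropped_reason" in rows.columns:
        rows["dropped_reason"] = rows["dropped_reason"].astype("object")
        rows.loc[rows["dropped_reason"].isna(), "dropped_reason"] = None
    return HarmonizedSet(exposure_id, outcome_id, rows, n_exposure, n_outcome)
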