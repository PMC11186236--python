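"""GWAS summary-statistics data model, file I/O, and allele harmonization.

Summary statistics are marginal per-variant association estimates (beta, SE,
p, N) for one trait.  Everything downstream — instrument selection, two-sample
MR, SMR, colocalization — consumes these tables, so this module owns the
validation rules (positive SEs, biallelic SNPs, p consistent with beta/se) and
the effect-allele bookkeeping that makes two cohorts comparable.

Conventions
-----------
* Coordinates are 1-based and windows are inclusive at both ends.
* ``beta`` is the effect per copy of ``effect_allele``: log-odds for binary
  traits, SD units for quantitative traits.
* Only biallelic SNPs with alleles in {A, C, G, T} are retained; indels and
  multi-allelic records are dropped with a distinct reason code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
#: strand-ambiguous allele pairs: reverse complement equals the allele swap
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "ncase", "nctrl",
]
MANDATORY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "n",
]

#: actions after which exposure and outcome share the same effect allele
KEPT_ACTIONS = frozenset({"kept", "sign_flipped", "freq_inferred"})


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float
    ncase: float | None = None
    nctrl: float | None = None

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS

    def flipped(self) -> "VariantAssociation":
        """Same association under the opposite allele coding."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None or math.isnan(self.eaf) else 1.0 - self.eaf,
        )


@dataclass
class SumStatsTable:
    """A validated, position-sorted table of variant associations for a trait.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; rows failing
    validation at construction are dropped and tallied in ``drop_reasons``.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_dropped(self) -> int:
        return sum(self.drop_reasons.values())

    def subset(self, mask_or_df) -> "SumStatsTable":
        sub = self.df[mask_or_df] if not isinstance(mask_or_df, pd.DataFrame) else mask_or_df
        return SumStatsTable(self.trait_id, self.trait_type, sub.reset_index(drop=True))

    def records(self) -> Iterable[VariantAssociation]:
        for row in self.df.itertuples(index=False):
            yield _row_to_assoc(row)

    def get(self, variant_id: str) -> VariantAssociation:
        hit = self.df[self.df["variant_id"] == variant_id]
        if hit.empty:
            raise KeyError(variant_id)
        return _row_to_assoc(next(hit.itertuples(index=False)))


def _row_to_assoc(row) -> VariantAssociation:
    def _opt(v):
        return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return VariantAssociation(
        variant_id=str(row.variant_id), chrom=str(row.chrom), pos=int(row.pos),
        effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
        eaf=_opt(row.eaf), beta=float(row.beta), se=float(row.se),
        pval=float(row.pval), n=float(row.n),
        ncase=_opt(getattr(row, "ncase", None)), nctrl=_opt(getattr(row, "nctrl", None)),
    )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene body coordinates (1-based, inclusive) for cis-window lookups."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class HarmonizedPair:
    """One variant's exposure and outcome associations on a shared effect allele."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    p_exp: float
    n_exp: float
    eaf_exp: float
    beta_out: float
    se_out: float
    p_out: float
    n_out: float
    eaf_out: float
    action_taken: str

    @property
    def kept(self) -> bool:
        return self.action_taken in KEPT_ACTIONS


# ---------------------------------------------------------------------------
# validation & I/O
# ---------------------------------------------------------------------------

def two_sided_p(z) -> np.ndarray | float:
    """Two-sided normal-tail p-value of a z statistic."""
    return 2.0 * norm.sf(np.abs(z))


def validate_records(df: pd.DataFrame, p_tolerance_oom: float = 2.0
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating the record invariants; return (clean, drop tally).

    A supplied p-value disagreeing with |beta/se| by more than
    ``p_tolerance_oom`` orders of magnitude triggers a warning only — many
    sources round or truncate p.  Missing p-values are reconstructed from the
    two-sided normal tail of beta/se.
    """
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    drops: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            drops[reason] = drops.get(reason, 0) + k
            df = df[~mask]

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    valid = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(VALID_ALLELES)
    _drop(~valid, "indel_or_multiallelic")
    _drop(df["effect_allele"] == df["other_allele"], "identical_alleles")

    num = df[["beta", "se", "pos", "n"]].apply(pd.to_numeric, errors="coerce")
    _drop(num.isna().any(axis=1), "missing_required_value")
    for col in ("pos", "eaf", "beta", "se", "pval", "n", "ncase", "nctrl"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    _drop(~(df["se"] > 0), "nonpositive_se")

    missing_p = df["pval"].isna()
    if missing_p.any():
        df.loc[missing_p, "pval"] = two_sided_p(df.loc[missing_p, "beta"] / df.loc[missing_p, "se"])
    _drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    _drop(df["eaf"].notna() & ~df["eaf"].between(0, 1), "eaf_out_of_range")
    _drop(df["variant_id"].duplicated(keep="first"), "duplicate_variant_id")

    expected = two_sided_p(df["beta"] / df["se"]).clip(min=1e-300)
    with np.errstate(divide="ignore"):
        oom = np.abs(np.log10(df["pval"].clip(lower=1e-300) / expected))
    n_bad = int((oom > p_tolerance_oom).sum())
    if n_bad:
        logger.warning("%d p-values deviate from |beta/se| by > %g orders of magnitude",
                       n_bad, p_tolerance_oom)

    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("eaf", "beta", "se", "pval", "n", "ncase", "nctrl"):
        df[col] = df[col].astype(float)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df, drops


def read_column_map(path) -> dict[str, str]:
    """Read a ``canonical=foreign`` key=value text file mapping column names."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        mapping[key.strip()] = val.strip()
    return mapping


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait_type: str = "quantitative", trait_id: str | None = None,
                  sep: str = "\t") -> SumStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    ``column_map`` maps canonical names to the file's header names
    (e.g. ``{"variant_id": "SNP", "beta": "Effect"}``); a missing mandatory
    column is a hard error naming the column.  Rows violating the record
    invariants are dropped and tallied.
    """
    raw = pd.read_csv(path, sep=sep)
    if column_map:
        rename = {foreign: canon for canon, foreign in column_map.items()}
        missing_src = [f for f in rename if f not in raw.columns]
        if missing_src:
            raise ValueError(f"column map refers to absent column(s): {missing_src}")
        raw = raw.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"mandatory column {col!r} not found in {path}")
    clean, drops = validate_records(raw)
    if clean.empty:
        raise ValueError(f"no valid records remain after validation of {path}")
    if drops:
        logger.info("read_sumstats(%s): dropped %s", path, drops)
    return SumStatsTable(trait_id or str(path), trait_type, clean, drops)


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write the canonical TSV; floats at 10 significant digits."""
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_annotations(path, zero_based_half_open: bool = False) -> list[GeneAnnotation]:
    """Read a BED-like TSV (chrom, start, end, gene_id[, symbol]).

    Pass ``zero_based_half_open=True`` for true BED coordinates; they are
    converted to the internal 1-based inclusive convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene annotation file needs >= 4 columns: chrom start end gene_id")
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row[1]), int(row[2])
        if zero_based_half_open:
            start += 1
        symbol = str(row[4]) if df.shape[1] > 4 else str(row[3])
        genes.append(GeneAnnotation(str(row[3]), symbol, str(row[0]), start, end))
    return genes


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize_frames(exp_df: pd.DataFrame, out_df: pd.DataFrame,
                     palindrome_window: float = 0.08) -> pd.DataFrame:
    """Vectorized allele harmonization of two canonical frames.

    Returns one row per shared variant with columns
    ``beta_exp .. eaf_out`` and ``action_taken``; rows with a dropped action
    keep their statistics for reporting but must not be used downstream.
    """
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n"]
    merged = exp_df[cols].merge(
        out_df[["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]],
        on="variant_id", suffixes=("_exp", "_out"))
    if merged.empty:
        return _empty_harmonized()

    ea_e = merged["effect_allele_exp"].to_numpy()
    oa_e = merged["other_allele_exp"].to_numpy()
    ea_o = merged["effect_allele_out"].to_numpy()
    oa_o = merged["other_allele_out"].to_numpy()

    same = (ea_e == ea_o) & (oa_e == oa_o)
    swapped = (ea_e == oa_o) & (oa_e == ea_o)
    pal = np.array([(a, b) in PALINDROMIC_PAIRS for a, b in zip(ea_e, oa_e)])
    compatible = same | swapped

    eaf_e = merged["eaf_exp"].to_numpy(float)
    eaf_o = merged["eaf_out"].to_numpy(float)
    lo, hi = 0.5 - palindrome_window, 0.5 + palindrome_window
    ambiguous = (np.isnan(eaf_e) | np.isnan(eaf_o)
                 | ((eaf_e >= lo) & (eaf_e <= hi))
                 | ((eaf_o >= lo) & (eaf_o <= hi)))

    action = np.full(len(merged), "dropped_mismatch", dtype=object)
    action[same & ~pal] = "kept"
    action[swapped & ~pal] = "sign_flipped"
    action[pal & compatible & ambiguous] = "dropped_palindromic"
    action[pal & compatible & ~ambiguous] = "freq_inferred"

    # outcome flips: plain allele swap, or palindromic frequency disagreement
    flip = (action == "sign_flipped").copy()
    freq_rows = action == "freq_inferred"
    flip |= freq_rows & ((eaf_e - 0.5) * (eaf_o - 0.5) < 0)

    beta_out = merged["beta_out"].to_numpy(float).copy()
    beta_out[flip] = -beta_out[flip]
    eaf_out = eaf_o.copy()
    eaf_out[flip] = 1.0 - eaf_out[flip]

    result = pd.DataFrame({
        "variant_id": merged["variant_id"],
        "chrom": merged["chrom"].astype(str),
        "pos": merged["pos"],
        "effect_allele": ea_e,
        "other_allele": oa_e,
        "beta_exp": merged["beta_exp"].astype(float),
        "se_exp": merged["se_exp"].astype(float),
        "p_exp": merged["pval_exp"].astype(float),
        "n_exp": merged["n_exp"].astype(float),
        "eaf_exp": eaf_e,
        "beta_out": beta_out,
        "se_out": merged["se_out"].astype(float),
        "p_out": merged["pval_out"].astype(float),
        "n_out": merged["n_out"].astype(float),
        "eaf_out": eaf_out,
        "action_taken": action,
    })
    if not result["action_taken"].isin(KEPT_ACTIONS).any():
        logger.warning("harmonization dropped every shared variant")
    return result


def _empty_harmonized() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "beta_exp", "se_exp", "p_exp", "n_exp", "eaf_exp",
        "beta_out", "se_out", "p_out", "n_out", "eaf_out", "action_taken"])


def harmonize(exposure: SumStatsTable, outcome: SumStatsTable,
              palindrome_window: float = 0.08) -> list[HarmonizedPair]:
    """Align outcome records to the exposure's effect-allele orientation.

    Per shared variant: identical allele order is kept; swapped alleles flip
    the outcome beta and EAF; palindromic (A/T, C/G) variants are resolved by
    allele frequency when both EAFs lie outside the ambiguous band
    (0.5 ± ``palindrome_window``) and dropped otherwise; irreconcilable allele
    sets are dropped as mismatches.
    """
    frame = harmonize_frames(exposure.df, outcome.df, palindrome_window)
    return frame_to_pairs(frame)


def frame_to_pairs(frame: pd.DataFrame) -> list[HarmonizedPair]:
    return [HarmonizedPair(
        variant_id=str(r.variant_id), chrom=str(r.chrom), pos=int(r.pos),
        effect_allele=str(r.effect_allele), other_allele=str(r.other_allele),
        beta_exp=float(r.beta_exp), se_exp=float(r.se_exp), p_exp=float(r.p_exp),
        n_exp=float(r.n_exp), eaf_exp=float(r.eaf_exp),
        beta_out=float(r.beta_out), se_out=float(r.se_out), p_out=float(r.p_out),
        n_out=float(r.n_out), eaf_out=float(r.eaf_out),
        action_taken=str(r.action_taken)) for r in frame.itertuples(index=False)]


def kept_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.kept]


def cis_window(gene: GeneAnnotation, table: SumStatsTable,
               flank: int = 1_000_000) -> SumStatsTable:
    """Records on the gene's chromosome within ``flank`` bp of the gene body.

    The window [start - flank, end + flank] is inclusive at both ends.  An
    unknown chromosome yields an empty subset with a warning.
    """
    on_chrom = table.df["chrom"] == gene.chrom
    if not on_chrom.any():
        logger.warning("cis_window(%s): chromosome %s absent from %s",
                       gene.gene_id, gene.chrom, table.trait_id)
        return table.subset(on_chrom)
    mask = on_chrom & table.df["pos"].between(gene.start - flank, gene.end + flank)
    return table.subset(mask)
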