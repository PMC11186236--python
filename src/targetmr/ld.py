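"""Instrument selection: LD matrices, clumping, strength, and directionality.

Cis-QTL instruments for a protein (or gene) are the variants near the encoding
gene that pass the source study's significance threshold.  This module turns a
cis region into an instrument set: optional greedy LD clumping, per-variant
F-statistics for weak-instrument screening, and the Steiger filter that drops
variants explaining more variance in the outcome than in the exposure
(a reverse-causation guard).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sumstats import HarmonizedPair, SumStatsTable

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


@dataclass
class LDMatrix:
    """Pairwise variant correlations (r, not r^2) over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {m} variants")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.linalg.eigvalsh(self.r).min() < -1e-8:
            raise ValueError("LD matrix is not positive semi-definite (tol 1e-8)")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def submatrix(self, variant_ids: list[str]) -> "LDMatrix":
        idx = [self.index(v) for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])


def read_ld(path) -> LDMatrix:
    """Read the text LD format: line 1 = variant ids, then one matrix row per line."""
    lines = Path(path).read_text().splitlines()
    ids = lines[0].split()
    rows = [np.fromstring(line, sep=" ") for line in lines[1:1 + len(ids)]]
    return LDMatrix(ids, np.vstack(rows))


def write_ld(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.variant_ids) + "\n")
        for row in ld.r:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class InstrumentSet:
    """Harmonized instruments for one protein/gene with their regional LD."""

    protein_id: str
    pairs: list[HarmonizedPair]
    ld: LDMatrix | None = None
    source_label: str = ""
    f_stats: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ld is not None:
            missing = [p.variant_id for p in self.pairs if p.variant_id not in self.ld]
            if missing:
                raise ValueError(f"instrument variants absent from LD matrix: {missing}")
        if any(f < 0 for f in self.f_stats.values()):
            raise ValueError("negative F-statistic")
        if not self.f_stats:
            self.f_stats = {p.variant_id: f_statistic_xy(p.beta_exp, p.se_exp)
                            for p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def select_instruments(cis_table: SumStatsTable, p_threshold: float) -> SumStatsTable:
    """Retain cis records with p below the source study's threshold."""
    if not p_threshold > 0:
        raise ValueError("p_threshold must be > 0")
    return cis_table.subset(cis_table.df["pval"] < p_threshold)


def clump(candidates: SumStatsTable, ld: LDMatrix, r2_max: float = 0.01,
          window_kb: int = 10_000) -> SumStatsTable:
    """Greedy LD clumping: repeatedly keep the lowest-p remaining variant and
    discard variants within ``window_kb`` of it with r^2 above ``r2_max``.

    Ties on p break by (chrom, pos).  Every candidate must appear in ``ld``.
    """
    df = candidates.df
    missing = [v for v in df["variant_id"] if v not in ld]
    if missing:
        raise KeyError(f"variant(s) missing from LD matrix: {missing}")
    order = df.sort_values(["pval", "chrom", "pos"], kind="mergesort").index.to_numpy()
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    ld_idx = np.array([ld.index(v) for v in df["variant_id"]])
    window_bp = int(window_kb) * 1000

    alive = np.ones(len(df), dtype=bool)
    keep: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        keep.append(i)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        r2 = ld.r[ld_idx[i], ld_idx[near]] ** 2
        kill = np.flatnonzero(near)[r2 > r2_max]
        alive[kill] = False
    kept = df.loc[sorted(keep)]
    return candidates.subset(kept)


def f_statistic(beta: float, se: float) -> float:
    """Approximate per-instrument F-statistic, (beta/se)^2.

    The conventional weak-instrument rule of thumb flags F <= 10; see
    :func:`is_weak_instrument`.
    """
    if not se > 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


# alias used internally where the arguments come from harmonized pairs
f_statistic_xy = f_statistic


def is_weak_instrument(f: float, threshold: float = WEAK_F_THRESHOLD) -> bool:
    return f <= threshold


@dataclass(frozen=True)
class SteigerRecord:
    variant_id: str
    r2_exposure: float
    r2_outcome: float
    retained: bool
    reason: str


def steiger_pseudo_r2(beta: float, se: float, n: float) -> float:
    """Variance explained approximated from the t statistic: t^2/(t^2 + n - 2)."""
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2.0)


def steiger_filter(pairs: list[HarmonizedPair]
                   ) -> tuple[list[HarmonizedPair], list[SteigerRecord]]:
    """Drop instruments explaining no more variance in the exposure than in
    the outcome (strict inequality required for retention; ties drop).

    The pseudo-r^2 uses the t-statistic approximation on both sides, which is
    exact for a quantitative trait and an approximation on the log-odds scale
    for binary traits.  Variants with n <= 2 on either side are dropped with a
    reason code.
    """
    kept: list[HarmonizedPair] = []
    report: list[SteigerRecord] = []
    for p in pairs:
        if p.n_exp <= 2 or p.n_out <= 2:
            report.append(SteigerRecord(p.variant_id, float("nan"), float("nan"),
                                        False, "insufficient_n"))
            continue
        r2_exp = steiger_pseudo_r2(p.beta_exp, p.se_exp, p.n_exp)
        r2_out = steiger_pseudo_r2(p.beta_out, p.se_out, p.n_out)
        ok = r2_exp > r2_out
        report.append(SteigerRecord(p.variant_id, r2_exp, r2_out, ok,
                                    "retained" if ok else "outcome_variance_not_smaller"))
        if ok:
            kept.append(p)
    return kept, report
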