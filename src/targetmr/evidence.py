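"""Evidence synthesis: FDR gating, meta-analysis, replication, and tiering.

A protein becomes a candidate drug target when its MR signal survives
per-source false-discovery-rate control; the per-source estimates are then
combined by fixed-effect inverse-variance meta-analysis, corroborated at the
expression level (SMR + HEIDI) and the locus level (colocalization), probed
across a panel of related outcomes for replication, and graded:

* tier 1 — MR-significant and passed both SMR and colocalization;
* tier 2 — MR-significant and passed exactly one of the two;
* tier 3 — MR-significant only.

Replication counts respect each outcome's polarity: for outcomes where a
negative beta means increased risk (e.g. eGFR and its annualized slope), the
sign is mapped onto the risk direction before comparison with the principal
estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .mr import MRResult, Z975

FAMILIES = ("ckd_binary", "egfr_continuous", "decline_binary",
            "slope_continuous", "clinical_binary")


@dataclass(frozen=True)
class OutcomeSpec:
    """One replication-panel outcome and how its beta maps to risk direction."""

    outcome_id: str
    family: str
    polarity: int  # +1: positive beta = higher risk; -1: negative beta = higher risk

    def __post_init__(self) -> None:
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown outcome family {self.family!r}")


@dataclass
class EvidenceRow:
    protein_id: str
    combined_beta: float = float("nan")
    combined_se: float = float("nan")
    combined_p: float = float("nan")
    combined_or: float = float("nan")
    combined_or_low: float = float("nan")
    combined_or_high: float = float("nan")
    q_value: float = float("nan")
    n_sig_sources: int = 0
    replication_count: int = 0
    passed_smr: bool = False
    passed_coloc: bool = False
    pph4: float = float("nan")
    coloc_level: str = "none"
    direction_consistent_gene: str = "no_gene_estimate"
    tier: int | None = None
    per_source: dict = field(default_factory=dict)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fixed_effect_meta(estimates: list[tuple[float, float]]
                      ) -> tuple[float, float, float, float, tuple[float, float]]:
    """Inverse-variance fixed-effect combination of (beta, se) estimates.

    Returns (beta, se, p, OR, (OR low, OR high)); a single estimate passes
    through unchanged.
    """
    if not estimates:
        raise ValueError("no estimates to combine")
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("standard errors must be finite and > 0")
    w = 1.0 / se ** 2
    beta = float(np.sum(w * b) / np.sum(w))
    se_c = float(1.0 / math.sqrt(np.sum(w)))
    p = 2.0 * float(norm.sf(abs(beta / se_c)))
    or_ci = (math.exp(beta - Z975 * se_c), math.exp(beta + Z975 * se_c))
    return beta, se_c, p, math.exp(beta), or_ci


def count_replications(principal_beta: float,
                       panel_results: dict[str, MRResult | None],
                       outcome_specs: dict[str, OutcomeSpec],
                       alpha: float = 0.05) -> int:
    """Panel outcomes significant at ``alpha`` whose risk direction matches
    the principal estimate's.  Missing results are skipped, never counted."""
    principal_sign = int(np.sign(principal_beta))
    count = 0
    for outcome_id, spec in outcome_specs.items():
        res = panel_results.get(outcome_id)
        if res is None or not np.isfinite(res.pval):
            continue
        risk_sign = int(np.sign(res.beta)) * spec.polarity
        if res.pval < alpha and risk_sign == principal_sign:
            count += 1
    return count


def assign_tier(mr_sig: bool, passed_smr: bool, passed_coloc: bool) -> int | None:
    """Evidence grade: 1 = MR+SMR+coloc, 2 = MR plus one, 3 = MR only."""
    if not mr_sig:
        return None
    n_extra = int(passed_smr) + int(passed_coloc)
    return {2: 1, 1: 2, 0: 3}[n_extra]


def direction_consistency(protein_beta: float,
                          gene_smr_betas: dict[str, float]
                          ) -> tuple[dict[str, bool], str]:
    """Sign agreement of per-tissue expression effects with the protein effect.

    Summary: ``consistent`` if every tissue agrees, ``opposite`` if none does,
    ``mixed`` (the '-/+' pattern) otherwise.
    """
    if not gene_smr_betas:
        return {}, "no_gene_estimate"
    sign_p = np.sign(protein_beta)
    flags = {tissue: bool(np.sign(b) == sign_p) for tissue, b in gene_smr_betas.items()}
    n_agree = sum(flags.values())
    if n_agree == len(flags):
        summary = "consistent"
    elif n_agree == 0:
        summary = "opposite"
    else:
        summary = "mixed"
    return flags, summary


_TABLE_COLUMNS = [
    "protein_id", "tier", "q_value", "combined_beta", "combined_se", "combined_p",
    "combined_or", "combined_or_low", "combined_or_high", "n_sig_sources",
    "replication_count", "passed_smr", "passed_coloc", "pph4", "coloc_level",
    "direction_consistent_gene",
]


def build_evidence_table(rows: list[EvidenceRow]) -> pd.DataFrame:
    """Materialize evidence rows as a deterministic table (tier, then q).

    Duplicate protein ids are a hard error: upstream results must be keyed
    consistently.
    """
    ids = [r.protein_id for r in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein id(s) in evidence rows: {dup}")
    df = pd.DataFrame([{c: getattr(r, c) for c in _TABLE_COLUMNS} for r in rows],
                      columns=_TABLE_COLUMNS)
    sort_tier = np.array([99 if t is None or (isinstance(t, float) and math.isnan(t))
                          else int(t) for t in df["tier"]])
    df = df.iloc[np.lexsort((df["protein_id"], df["q_value"].fillna(2.0), sort_tier))]
    return df.reset_index(drop=True)


def write_evidence(df: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=str)


def read_outcome_specs(path) -> dict[str, OutcomeSpec]:
    """Read the outcome-panel spec TSV (outcome_id, family, polarity)."""
    df = pd.read_csv(path, sep="\t")
    return {r.outcome_id: OutcomeSpec(str(r.outcome_id), str(r.family), int(r.polarity))
            for r in df.itertuples(index=False)}
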