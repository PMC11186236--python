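"""Bayesian colocalization of two regional association signals (ABF method).

For each variant j and trait, the evidence of association is summarized by a
Wakefield approximate Bayes factor computed from (beta, se) alone: with
V = se^2, z = beta/se and r = w^2/(w^2 + V) for a prior effect-size SD w,

    log ABF = 0.5 * (log(1 - r) + r z^2).

Assuming at most one causal variant per trait in the region, the five
hypotheses are H0 (no association), H1/H2 (one trait only), H3 (two distinct
causal variants) and H4 (one shared causal variant).  Per-variant prior
probabilities p1, p2 (single-trait) and p12 (shared) weight sums of ABFs over
single variants (H1, H2, H4) or ordered distinct pairs (H3).  All mass
arithmetic is in log space; H3 is an explicit pairwise i != j log-sum-exp
rather than a subtraction, avoiding catastrophic cancellation.

Because the ABF depends on z only through z^2, colocalization needs the two
regions to share a variant list but not an allele orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import SumStatsTable

logger = logging.getLogger(__name__)


@dataclass
class ColocConfig:
    """Per-variant priors and prior effect-size SDs.

    Defaults follow common single-causal-variant colocalization practice:
    p1 = p2 = 1e-4, p12 = 1e-5; prior SD 0.15 for quantitative traits and
    0.2 (log-odds) for case-control traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = 0.15
    w_cc: float = 0.2

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be > 0")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")

    def prior_sd(self, trait_type: str) -> float:
        return self.w_cc if trait_type == "binary" else self.w_quant


@dataclass
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_variants: int
    call: str  # "colocalized" | "moderate" | "none"
    status: str = "ok"

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])


def labf(beta: float | np.ndarray, se: float | np.ndarray, w: float) -> np.ndarray | float:
    """Log Wakefield approximate Bayes factor for one association estimate."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or w <= 0:
        raise ValueError("se and w must be > 0")
    v = se ** 2
    z = np.asarray(beta, dtype=float) / se
    r = w ** 2 / (w ** 2 + v)
    out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return float(out) if out.ndim == 0 else out


def _pairwise_lse_offdiag(l1: np.ndarray, l2: np.ndarray) -> float:
    """log sum over ordered pairs i != j of exp(l1[i] + l2[j]), stabilized."""
    mat = l1[:, None] + l2[None, :]
    np.fill_diagonal(mat, -np.inf)
    return float(logsumexp(mat))


def colocalize(trait1_region: SumStatsTable, trait2_region: SumStatsTable,
               cfg: ColocConfig = ColocConfig(),
               pph4_full: float = 0.8, pph4_moderate: float = 0.5) -> ColocResult:
    """Posterior probabilities of H0-H4 for two traits over one region.

    The variant lists are intersected (and the reduction logged); with fewer
    than 2 shared variants H3 is undefined and posteriors are computed over
    the remaining hypotheses with a status note.
    """
    df1, df2 = trait1_region.df, trait2_region.df
    shared = df1[df1["variant_id"].isin(set(df2["variant_id"]))]
    if len(shared) < len(df1) or len(shared) < len(df2):
        logger.info("colocalize: intersected to %d shared variants (%d vs %d)",
                    len(shared), len(df1), len(df2))
    if shared.empty:
        raise ValueError("no shared variants between the two regions")
    d2 = df2.set_index("variant_id").loc[shared["variant_id"]]

    l1 = np.asarray(labf(shared["beta"].to_numpy(), shared["se"].to_numpy(),
                         cfg.prior_sd(trait1_region.trait_type)))
    l2 = np.asarray(labf(d2["beta"].to_numpy(), d2["se"].to_numpy(),
                         cfg.prior_sd(trait2_region.trait_type)))
    m = len(shared)

    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))

    logm = {
        "h0": 0.0,
        "h1": math.log(cfg.p1) + s1,
        "h2": math.log(cfg.p2) + s2,
        "h4": math.log(cfg.p12) + s12,
    }
    status = "ok"
    if m >= 2:
        logm["h3"] = math.log(cfg.p1) + math.log(cfg.p2) + _pairwise_lse_offdiag(l1, l2)
    else:
        status = "h3_undefined_single_variant"

    keys = ["h0", "h1", "h2", "h3", "h4"]
    vals = np.array([logm.get(k, -np.inf) for k in keys])
    post = np.exp(vals - logsumexp(vals))
    pph = dict(zip(keys, post))

    if pph["h4"] > pph4_full:
        call = "colocalized"
    elif pph["h4"] > pph4_moderate:
        call = "moderate"
    else:
        call = "none"
    return ColocResult(pph["h0"], pph["h1"], pph["h2"], pph["h3"], pph["h4"],
                       m, call, status)
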