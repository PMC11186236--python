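"""Two-sample Mendelian-randomization estimators and diagnostics.

Given harmonized per-variant effects on an exposure (bx, SD units of the
protein) and an outcome (by, log-odds for a binary outcome), the causal effect
of a 1-SD increase in the exposure is estimated by:

* the Wald ratio by/bx with a delta-method SE for a single instrument;
* fixed-effect inverse-variance weighting (equivalently, weighted least
  squares of by on bx through the origin) for two or more instruments, with
  Cochran's Q as the heterogeneity diagnostic;
* MR-Egger weighted regression with an intercept, whose intercept tests for
  directional horizontal pleiotropy (slope and intercept inference on a
  t reference with k - 2 df).

Both IVW and Egger assume (approximately) independent instruments; correlated
instruments leave the point estimate consistent but understate its SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, t as t_dist

from .ld import InstrumentSet
from .sumstats import HarmonizedPair

Z975 = norm.ppf(0.975)


@dataclass
class MRResult:
    """A causal-effect estimate for one protein on one outcome."""

    protein_id: str
    outcome_id: str
    method: str  # "wald" | "ivw" | "egger"
    beta: float
    se: float
    pval: float
    n_instruments: int
    or_point: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    status: str = "ok"

    def attach_or(self) -> "MRResult":
        self.or_point = math.exp(self.beta)
        self.or_low = math.exp(self.beta - Z975 * self.se)
        self.or_high = math.exp(self.beta + Z975 * self.se)
        return self


@dataclass
class ProteinMRReport:
    """Primary estimate plus diagnostics and filter provenance for one protein."""

    protein_id: str
    outcome_id: str
    primary: MRResult | None
    egger: MRResult | None
    status: str
    provenance: dict


def _two_sided_normal_p(z: float) -> float:
    return 2.0 * norm.sf(abs(z))


def wald_ratio(pair: HarmonizedPair, protein_id: str = "", outcome_id: str = "",
               second_order: bool = False, binary_outcome: bool = True) -> MRResult:
    """Single-instrument Wald ratio by/bx with a delta-method SE.

    The default first-order SE is se_out/|bx|; ``second_order=True`` adds the
    by^2 * se_exp^2 / bx^4 term, accounting for sampling error in bx.
    """
    bx, by = pair.beta_exp, pair.beta_out
    if bx == 0:
        raise ValueError("Wald ratio undefined: exposure beta is 0")
    beta = by / bx
    var = pair.se_out ** 2 / bx ** 2
    if second_order:
        var += by ** 2 * pair.se_exp ** 2 / bx ** 4
    se = math.sqrt(var)
    res = MRResult(protein_id, outcome_id, "wald", beta, se,
                   _two_sided_normal_p(beta / se), 1)
    return res.attach_or() if binary_outcome else res


def _extract_arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(instruments, InstrumentSet):
        pairs = instruments.pairs
    else:
        pairs = list(instruments)
    bx = np.array([p.beta_exp for p in pairs], dtype=float)
    by = np.array([p.beta_out for p in pairs], dtype=float)
    se = np.array([p.se_out for p in pairs], dtype=float)
    return bx, by, se


def ivw_arrays(bx: np.ndarray, by: np.ndarray, se_out: np.ndarray
               ) -> tuple[float, float, float, int, float]:
    """Fixed-effect IVW on raw arrays: (beta, se, Q, q_df, q_pval)."""
    w = 1.0 / se_out ** 2
    denom = float(np.sum(w * bx ** 2))
    if denom == 0:
        raise ValueError("IVW undefined: all exposure betas are 0")
    beta = float(np.sum(w * bx * by)) / denom
    se = 1.0 / math.sqrt(denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_df = len(bx) - 1
    q_p = float(chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    return beta, se, q, q_df, q_p


def ivw(instruments, protein_id: str = "", outcome_id: str = "",
        binary_outcome: bool = True) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate over >= 2 instruments.

    beta = sum(w bx by) / sum(w bx^2) with w = 1/se_out^2; equivalently the
    origin-constrained WLS slope of by on bx.  Cochran's Q with k - 1 df
    measures heterogeneity of the per-instrument ratios.  A single instrument
    dispatches to :func:`wald_ratio`.
    """
    bx, by, se_out = _extract_arrays(instruments)
    pairs = instruments.pairs if isinstance(instruments, InstrumentSet) else list(instruments)
    if len(bx) == 0:
        raise ValueError("no instruments")
    if len(bx) == 1:
        return wald_ratio(pairs[0], protein_id, outcome_id, binary_outcome=binary_outcome)
    beta, se, q, q_df, q_p = ivw_arrays(bx, by, se_out)
    res = MRResult(protein_id, outcome_id, "ivw", beta, se,
                   _two_sided_normal_p(beta / se), len(bx),
                   q_stat=q, q_df=q_df, q_pval=q_p)
    return res.attach_or() if binary_outcome else res


def egger(instruments, protein_id: str = "", outcome_id: str = "",
          binary_outcome: bool = True) -> MRResult:
    """MR-Egger: WLS of by on bx with an intercept, weights 1/se_out^2.

    Instruments are first oriented so every bx >= 0 (joint sign flips, the
    standard bookkeeping under the InSIDE assumption).  Slope and intercept
    use a t reference with k - 2 df; an intercept p < 0.05 flags directional
    pleiotropy.  Fewer than 3 instruments yields a not-computable result.
    """
    bx, by, se_out = _extract_arrays(instruments)
    k = len(bx)
    if k < 3:
        return MRResult(protein_id, outcome_id, "egger", float("nan"), float("nan"),
                        float("nan"), k, status="not_computable")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / se_out ** 2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ by)
    resid = by - X @ coef
    dof = k - 2
    sigma2 = float(np.sum(w * resid ** 2)) / dof
    cov = sigma2 * np.linalg.inv(xtwx)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])

    def _t_p(est: float, se: float) -> float:
        if se == 0:
            return 0.0 if est != 0 else 1.0
        return 2.0 * float(t_dist.sf(abs(est / se), dof))

    res = MRResult(protein_id, outcome_id, "egger",
                   float(coef[1]), se_slope, _t_p(coef[1], se_slope), k,
                   egger_intercept=float(coef[0]),
                   egger_intercept_p=_t_p(coef[0], se_int))
    return res.attach_or() if binary_outcome else res


def run_protein_mr(protein_id: str, instruments: InstrumentSet,
                   outcome_id: str = "", binary_outcome: bool = True,
                   second_order_wald: bool = False,
                   provenance: dict | None = None) -> ProteinMRReport:
    """Primary MR estimate with diagnostics for one protein.

    One instrument -> Wald ratio; two or more -> fixed-effect IVW with
    Cochran's Q; Egger attached as a pleiotropy diagnostic when k >= 3.
    Zero instruments degrade to status ``no_instruments``.
    """
    prov = dict(provenance or {})
    prov.setdefault("source", instruments.source_label)
    prov["n_instruments"] = len(instruments)
    if len(instruments) == 0:
        return ProteinMRReport(protein_id, outcome_id, None, None, "no_instruments", prov)
    if len(instruments) == 1:
        primary = wald_ratio(instruments.pairs[0], protein_id, outcome_id,
                             second_order=second_order_wald, binary_outcome=binary_outcome)
    else:
        primary = ivw(instruments, protein_id, outcome_id, binary_outcome=binary_outcome)
    egger_res = egger(instruments, protein_id, outcome_id, binary_outcome=binary_outcome)
    if egger_res.status != "ok":
        egger_res = None
    return ProteinMRReport(protein_id, outcome_id, primary, egger_res, "ok", prov)
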