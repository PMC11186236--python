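"""Summary-data-based MR (SMR) and the HEIDI linkage test.

SMR instruments gene expression with its single top cis-eQTL: with z_zx the
eQTL z-statistic and z_zy the outcome z-statistic at that SNP,

    b_smr = b_zy / b_zx,
    T_smr = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2)  ~  chi^2_1 under the null.

A significant T_smr is compatible with both a shared causal variant and mere
linkage of two distinct causal variants.  HEIDI discriminates: under a single
shared causal variant the ratio b_xy(i) = b_zy(i)/b_zx(i) is the same constant
at every SNP in LD with the top SNP, so the differences
d_i = b_xy(i) - b_xy(top) are jointly zero-mean.  HEIDI standardizes the d_i
by first-order delta-method (co)variances (eQTL and outcome cohorts are
independent, so each trait contributes its own LD-proportional covariance) and
sums the squared z_d.  The null distribution of that sum is a weighted sum of
independent chi^2_1 with weights the eigenvalues of the z_d correlation
matrix; the tail probability is evaluated by Imhof's numerical inversion of
the characteristic function.  A small HEIDI p (< 0.01 by convention) rejects
the single-shared-variant model, i.e. flags linkage.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.stats import chi2

from .ld import LDMatrix
from .sumstats import SumStatsTable, VariantAssociation, harmonize_frames

logger = logging.getLogger(__name__)


@dataclass
class HeidiConfig:
    """HEIDI SNP-inclusion rules (conventions of the reference SMR tooling)."""

    p_eqtl_inclusion: float = 1.57e-3   # eQTL p required for a test SNP
    r2_min: float = 0.05                # LD bounds against the top SNP
    r2_max: float = 0.9
    max_snps: int = 20
    min_snps: int = 3                   # minimum non-top test SNPs
    linkage_threshold: float = 0.01


@dataclass
class SMRResult:
    gene_id: str
    tissue_label: str
    top_variant: str | None
    b_zx: float = float("nan")
    se_zx: float = float("nan")
    b_zy: float = float("nan")
    se_zy: float = float("nan")
    b_smr: float = float("nan")
    se_smr: float = float("nan")
    p_smr: float = float("nan")
    heidi_p: float | None = None
    heidi_n_snps: int = 0
    status: str = "ok"


def weighted_chisq_sf(q: float, weights: np.ndarray) -> float:
    """P(sum_k w_k chi^2_1 > q) by Imhof's inversion of the CF.

    Exact up to quadrature error; weights must be nonnegative (tiny negative
    eigenvalues from finite precision are clipped).
    """
    lam = np.asarray(weights, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0 or q <= 0:
        return 1.0
    if lam.size == 1:
        return float(chi2.sf(q / lam[0], 1))

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return math.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=2000)
    return float(min(max(0.5 + val / math.pi, 0.0), 1.0))


def top_eqtl(cis_eqtl: SumStatsTable, p_top: float = 5e-8) -> VariantAssociation | None:
    """The most significant cis-eQTL if it clears ``p_top``, else None.

    Ties on p break by larger |z|, then (chrom, pos).
    """
    df = cis_eqtl.df
    if df.empty:
        return None
    absz = (df["beta"] / df["se"]).abs()
    order = df.assign(_absz=-absz).sort_values(
        ["pval", "_absz", "chrom", "pos"], kind="mergesort")
    best = next(order.itertuples(index=False))
    if best.pval >= p_top:
        return None
    return cis_eqtl.get(best.variant_id)


def smr_test(eqtl: VariantAssociation, outcome: VariantAssociation) -> dict:
    """Core SMR statistic at an allele-harmonized top SNP.

    Returns b_smr, se_smr, p_smr and the two z statistics; the caller is
    responsible for having aligned the effect alleles.
    """
    if eqtl.beta == 0:
        raise ValueError("SMR undefined: eQTL beta is 0")
    z_zx, z_zy = eqtl.z, outcome.z
    b_smr = outcome.beta / eqtl.beta
    t_smr = (z_zx ** 2 * z_zy ** 2) / (z_zx ** 2 + z_zy ** 2)
    p_smr = float(chi2.sf(t_smr, 1)) if t_smr > 0 else 1.0
    se_smr = abs(b_smr) / math.sqrt(t_smr) if t_smr > 0 else float("inf")
    return {"b_smr": b_smr, "se_smr": se_smr, "p_smr": p_smr,
            "t_smr": t_smr, "z_zx": z_zx, "z_zy": z_zy}


def heidi_test(region: "np.ndarray | object", ld: LDMatrix, top_variant: str,
               cfg: HeidiConfig = HeidiConfig()) -> tuple[float | None, int]:
    """HEIDI on a harmonized region frame; returns (heidi_p, n_snps_used).

    ``region`` is the harmonized eQTL-vs-outcome frame (columns beta_exp,
    se_exp, p_exp, beta_out, se_out per variant) including the top SNP.
    Test SNPs are region variants with eQTL p < ``p_eqtl_inclusion`` and LD
    r^2 against the top SNP within [r2_min, r2_max], ranked by eQTL p and
    capped at ``max_snps``; variants absent from the LD matrix are excluded
    and logged.  Fewer than ``min_snps`` test SNPs -> (None, count).
    """
    frame = region[region["action_taken"].isin(("kept", "sign_flipped", "freq_inferred"))] \
        if "action_taken" in region.columns else region
    frame = frame.set_index("variant_id") if frame.index.name != "variant_id" else frame
    if top_variant not in frame.index or top_variant not in ld:
        return None, 0
    t = ld.index(top_variant)

    cands: list[str] = []
    for vid, p_e in frame["p_exp"].items():
        if vid == top_variant or not (p_e < cfg.p_eqtl_inclusion):
            continue
        if vid not in ld:
            logger.info("heidi: %s absent from LD matrix, excluded", vid)
            continue
        r2 = ld.r[ld.index(vid), t] ** 2
        if cfg.r2_min <= r2 <= cfg.r2_max:
            cands.append(vid)
    cands.sort(key=lambda v: frame.at[v, "p_exp"])
    cands = cands[:cfg.max_snps]
    if len(cands) < cfg.min_snps:
        return None, len(cands)

    ids = [top_variant] + cands
    sub = frame.loc[ids]
    bzx = sub["beta_exp"].to_numpy(float)
    sezx = sub["se_exp"].to_numpy(float)
    bzy = sub["beta_out"].to_numpy(float)
    sezy = sub["se_out"].to_numpy(float)
    R = ld.submatrix(ids).r

    bxy = bzy / bzx
    gy = 1.0 / bzx                      # d b_xy / d b_zy
    gx = -bzy / bzx ** 2                # d b_xy / d b_zx
    # cohorts are independent: each trait contributes r_ij * se_i * se_j
    cov_bxy = R * (np.outer(gy * sezy, gy * sezy) + np.outer(gx * sezx, gx * sezx))

    d = bxy[1:] - bxy[0]
    cov_d = (cov_bxy[1:, 1:] - cov_bxy[1:, [0]] - cov_bxy[[0], 1:] + cov_bxy[0, 0])
    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    corr = cov_d / np.outer(sd, sd)
    q_h = float(np.sum(z_d ** 2))
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    return weighted_chisq_sf(q_h, lam), len(cands)


def run_gene_smr(gene_id: str, cis_eqtl: SumStatsTable, outcome: SumStatsTable,
                 ld: LDMatrix, tissue_label: str = "",
                 p_top: float = 5e-8, cfg: HeidiConfig = HeidiConfig()) -> SMRResult:
    """Compose top-eQTL selection, harmonization, SMR, and HEIDI for one gene.

    A gene passes the expression-level test iff p_smr is below the caller's
    significance threshold AND heidi_p >= the linkage threshold (the observed
    association is not attributed to linkage).
    """
    top = top_eqtl(cis_eqtl, p_top)
    if top is None:
        return SMRResult(gene_id, tissue_label, None, status="no_top_eqtl")

    region = harmonize_frames(cis_eqtl.df, outcome.df)
    region = region[region["action_taken"].isin(("kept", "sign_flipped", "freq_inferred"))]
    hit = region[region["variant_id"] == top.variant_id]
    if hit.empty:
        return SMRResult(gene_id, tissue_label, top.variant_id, status="no_top_eqtl")
    row = next(hit.itertuples(index=False))

    eq = VariantAssociation(top.variant_id, str(row.chrom), int(row.pos),
                            str(row.effect_allele), str(row.other_allele),
                            None, row.beta_exp, row.se_exp, row.p_exp, row.n_exp)
    out = VariantAssociation(top.variant_id, str(row.chrom), int(row.pos),
                             str(row.effect_allele), str(row.other_allele),
                             None, row.beta_out, row.se_out, row.p_out, row.n_out)
    core = smr_test(eq, out)

    heidi_p, n_used = heidi_test(region, ld, top.variant_id, cfg)
    if heidi_p is None:
        status = "heidi_insufficient_snps"
    elif heidi_p < cfg.linkage_threshold:
        status = "heidi_linkage"
    else:
        status = "ok"
    return SMRResult(gene_id, tissue_label, top.variant_id,
                     b_zx=row.beta_exp, se_zx=row.se_exp,
                     b_zy=row.beta_out, se_zy=row.se_out,
                     b_smr=core["b_smr"], se_smr=core["se_smr"], p_smr=core["p_smr"],
                     heidi_p=heidi_p, heidi_n_snps=n_used, status=status)


def smr_passes(result: SMRResult, p_threshold: float = 0.05,
               linkage_threshold: float = 0.01) -> bool:
    """Expression-level support: significant SMR signal not explained by linkage."""
    if result.status in ("no_top_eqtl", "heidi_insufficient_snps", "heidi_linkage"):
        return False
    return (result.p_smr < p_threshold
            and result.heidi_p is not None
            and result.heidi_p >= linkage_threshold)
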