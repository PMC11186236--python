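"""Seeded simulation of regional GWAS summary statistics under LD.

The generator produces, for one locus, marginal summary statistics for three
traits — a plasma protein, the expression of its coding gene, and a binary
outcome — under controlled causal architectures, together with the regional
LD matrix and the generative ground truth.  It exists so that every pipeline
stage (harmonization, instrument selection, MR, SMR+HEIDI, colocalization,
tiering) can be exercised and calibrated offline.

Generative model (summary-level)
--------------------------------
Variants have AR(1) LD, R_ij = rho^|i-j|.  On the standardized scale a trait
with joint (direct) per-variant effects beta has marginal effects b = R beta,
and the sampled estimates follow

    b_hat ~ MVN(b, R / n_eff),   se_j = 1 / sqrt(n_eff),

with n_eff the sample size for quantitative traits and the effective sample
size 4/(1/ncase + 1/nctrl) on the log-odds scale for binary traits.  This is
the standard regression-with-summary-statistics approximation; it is fast and
exact in distribution for large n, but carries no MAF-dependent information
(allele frequencies are attached only to exercise harmonization).

Architectures (``SimScenario.name``)
------------------------------------
* ``null``       — no effects anywhere.
* ``causal`` / ``mediated`` — one variant drives the protein (effect ``a``)
  and expression (``e``); the outcome effect ``theta * a`` flows through the
  protein (per-SD protein effect ``theta``).
* ``linkage``    — the protein variant and a second outcome-only variant
  (direct effect ``c``) are distinct but in LD.
* ``pleiotropy`` — the protein variant also affects the outcome directly
  (``c`` on top of any ``theta * a``).
* ``reverse``    — the variant drives the outcome (effect ``a``) and the
  protein only via a back-effect ``theta * a``; the Steiger filter should
  remove such instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import OutcomeSpec
from .ld import LDMatrix
from .sumstats import GeneAnnotation, SumStatsTable, two_sided_p

SCENARIOS = ("null", "causal", "linkage", "pleiotropy", "reverse", "mediated")

REGION_START = 1_000_000
SPACING_BP = 10_000

#: emulated pQTL discovery sources: (sample size, genome-wide p threshold)
PQTL_SOURCES: dict[str, tuple[float, float]] = {
    "deCODE": (35_000, 1.8e-9),
    "Fenland": (10_700, 1.004e-11),
    "UKB-PPP": (54_000, 1.7e-11),
}

#: replication panel: (family, polarity, effective sample size)
PANEL_OUTCOMES: dict[str, tuple[str, int, float]] = {
    "CKD2": ("ckd_binary", +1, 60_000),
    "CKD3": ("ckd_binary", +1, 30_000),
    "CKD4": ("ckd_binary", +1, 20_000),
    "eGFRcrea": ("egfr_continuous", -1, 1_000_000),
    "eGFRcys": ("egfr_continuous", -1, 460_000),
    "Rapid3": ("decline_binary", +1, 40_000),
    "CKDi25": ("decline_binary", +1, 55_000),
    "slope_pop1": ("slope_continuous", -1, 100_000),
    "slope_pop2": ("slope_continuous", -1, 60_000),
    "slope_pop3": ("slope_continuous", -1, 40_000),
    "slope_pop4": ("slope_continuous", -1, 25_000),
    "IgA_nephropathy": ("clinical_binary", +1, 8_000),
    "chronic_glomerulonephritis": ("clinical_binary", +1, 6_000),
    "tubulointerstitial_nephritis": ("clinical_binary", +1, 3_000),
    "membranous_nephropathy": ("clinical_binary", +1, 4_000),
    "nephrotic_syndrome": ("clinical_binary", +1, 5_000),
    "diabetic_nephropathy": ("clinical_binary", +1, 10_000),
}

PRINCIPAL_OUTCOME = "CKD1"
PRINCIPAL_OUTCOME_N_EFF = 150_000.0


@dataclass
class SimScenario:
    """Generative parameters for one synthetic locus."""

    name: str
    m: int = 200
    rho: float = 0.9
    n_prot: float = 35_000
    n_eqtl: float = 30_000
    n_out: float = PRINCIPAL_OUTCOME_N_EFF
    theta: float = 0.2       # protein -> outcome, log-OR per SD protein
    a: float = 0.3           # variant -> protein, SD per allele (standardized)
    e: float = 0.3           # variant -> expression
    c: float = 0.05          # direct variant -> outcome (linkage/pleiotropy)
    causal_idx: int | None = None   # default: m // 3
    second_idx: int | None = None   # default: causal_idx + 3 (r^2 ~ 0.5 at rho 0.9)
    seed: int = 0
    chrom: str = "1"
    palindromic_fraction: float = 0.1
    flip_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        for n in (self.n_prot, self.n_eqtl, self.n_out):
            if n < 100:
                raise ValueError("sample sizes must be >= 100")
        if self.causal_idx is None:
            self.causal_idx = self.m // 3
        if self.second_idx is None:
            self.second_idx = min(self.causal_idx + 3, self.m - 1)
        for idx in (self.causal_idx, self.second_idx):
            if not 0 <= idx < self.m:
                raise ValueError("variant index out of range")
        if self.name in ("linkage",) and self.causal_idx == self.second_idx:
            raise ValueError("linkage requires distinct causal_idx and second_idx")


@dataclass
class SimTruth:
    scenario: SimScenario
    joint: dict[str, np.ndarray]      # direct effect vectors per trait
    marginal: dict[str, np.ndarray]   # R @ joint


@dataclass
class SimulatedRegion:
    prot: SumStatsTable
    eqtl: SumStatsTable
    outcome: SumStatsTable
    ld: LDMatrix
    truth: SimTruth


_CHOL_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _ar1(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _chol(m: int, rho: float) -> np.ndarray:
    key = (m, round(rho, 12))
    if key not in _CHOL_CACHE:
        _CHOL_CACHE[key] = np.linalg.cholesky(_ar1(m, rho))
    return _CHOL_CACHE[key]


def variant_ids(m: int, chrom: str = "1") -> list[str]:
    return [f"snp_c{chrom}_{j + 1}" for j in range(m)]


def positions(m: int) -> np.ndarray:
    return REGION_START + SPACING_BP * np.arange(m, dtype=np.int64)


def make_ld(m: int, rho: float, chrom: str = "1") -> LDMatrix:
    """AR(1) LD matrix R_ij = rho^|i-j| over m variants spaced 10 kb apart."""
    if m < 1 or not abs(rho) < 1:
        raise ValueError("need m >= 1 and |rho| < 1")
    return LDMatrix(variant_ids(m, chrom), _ar1(m, rho))


def joint_effects(scn: SimScenario) -> dict[str, np.ndarray]:
    """Direct (pre-LD) effect vectors per trait for one architecture."""
    prot = np.zeros(scn.m)
    expr = np.zeros(scn.m)
    out = np.zeros(scn.m)
    if scn.name in ("causal", "mediated"):
        prot[scn.causal_idx] = scn.a
        expr[scn.causal_idx] = scn.e
        out[scn.causal_idx] = scn.theta * scn.a
    elif scn.name == "linkage":
        prot[scn.causal_idx] = scn.a
        expr[scn.second_idx] = scn.e
        out[scn.second_idx] = scn.c
    elif scn.name == "pleiotropy":
        prot[scn.causal_idx] = scn.a
        expr[scn.causal_idx] = scn.e
        out[scn.causal_idx] = scn.theta * scn.a + scn.c
    elif scn.name == "reverse":
        out[scn.causal_idx] = scn.a
        prot[scn.causal_idx] = scn.theta * scn.a
    return {"prot": prot, "eqtl": expr, "out": out}


def _draw_alleles(rng: np.random.Generator, m: int, pal_fraction: float,
                  protect: tuple[int, ...] = ()) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Allele pairs and frequencies; designated signal variants are kept
    non-palindromic so a designed effect is never lost to frequency ambiguity."""
    nonpal = np.array([("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")])
    pal = np.array([("A", "T"), ("C", "G")])
    is_pal = rng.random(m) < pal_fraction
    is_pal[list(protect)] = False
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    pick_np = rng.integers(0, len(nonpal), size=m)
    pick_p = rng.integers(0, len(pal), size=m)
    for j in range(m):
        ea[j], oa[j] = pal[pick_p[j]] if is_pal[j] else nonpal[pick_np[j]]
    eaf = rng.uniform(0.05, 0.5, size=m)
    return ea, oa, eaf


def _trait_table(trait_id: str, trait_type: str, chrom: str, ids: list[str],
                 pos: np.ndarray, ea: np.ndarray, oa: np.ndarray, eaf: np.ndarray,
                 marginal: np.ndarray, n_eff: float, L: np.ndarray,
                 rng: np.random.Generator, flip_fraction: float) -> SumStatsTable:
    m = len(ids)
    se = 1.0 / np.sqrt(n_eff)
    bhat = marginal + (L @ rng.standard_normal(m)) * se
    flip = rng.random(m) < flip_fraction
    ea_t, oa_t, eaf_t = ea.copy(), oa.copy(), eaf.copy()
    ea_t[flip], oa_t[flip] = oa[flip], ea[flip]
    eaf_t[flip] = 1.0 - eaf[flip]
    bhat = np.where(flip, -bhat, bhat)
    df = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea_t, "other_allele": oa_t, "eaf": eaf_t,
        # floor keeps extreme signals strictly positive through text round-trips
        "beta": bhat, "se": se,
        "pval": np.clip(two_sided_p(bhat / se), 1e-300, 1.0),
        "n": float(n_eff),
        "ncase": n_eff / 2.0 if trait_type == "binary" else np.nan,
        "nctrl": n_eff / 2.0 if trait_type == "binary" else np.nan,
    })
    return SumStatsTable(trait_id, trait_type, df)


def simulate_region(scn: SimScenario) -> SimulatedRegion:
    """Simulate one locus: protein, expression, and outcome tables + LD + truth.

    The same seed yields byte-identical output; sub-streams for alleles and
    for each trait's noise are derived from the scenario seed, so adding a
    trait draw does not disturb the others.
    """
    ss = np.random.SeedSequence(scn.seed)
    rng_alleles, rng_prot, rng_eqtl, rng_out = (
        np.random.default_rng(child) for child in ss.spawn(4))
    ld = make_ld(scn.m, scn.rho, scn.chrom)
    L = _chol(scn.m, scn.rho)
    R = _ar1(scn.m, scn.rho)
    joint = joint_effects(scn)
    marginal = {k: R @ v for k, v in joint.items()}

    ids = variant_ids(scn.m, scn.chrom)
    pos = positions(scn.m)
    ea, oa, eaf = _draw_alleles(rng_alleles, scn.m, scn.palindromic_fraction,
                                protect=(scn.causal_idx, scn.second_idx))
    prot = _trait_table("prot", "quantitative", scn.chrom, ids, pos, ea, oa, eaf,
                        marginal["prot"], scn.n_prot, L, rng_prot, 0.0)
    eqtl = _trait_table("eqtl", "quantitative", scn.chrom, ids, pos, ea, oa, eaf,
                        marginal["eqtl"], scn.n_eqtl, L, rng_eqtl, scn.flip_fraction)
    outcome = _trait_table("outcome", "binary", scn.chrom, ids, pos, ea, oa, eaf,
                           marginal["out"], scn.n_out, L, rng_out, scn.flip_fraction)
    return SimulatedRegion(prot, eqtl, outcome, ld,
                           SimTruth(scn, joint, marginal))


# ---------------------------------------------------------------------------
# multi-locus panels
# ---------------------------------------------------------------------------

@dataclass
class PanelDataset:
    """An end-to-end synthetic study: multi-source pQTLs, blood eQTLs, an
    outcome panel with declared polarities, gene annotations, LD, and truth."""

    genes: list[GeneAnnotation]
    protein_gene: dict[str, str]
    pqtl_sources: dict[str, SumStatsTable]
    pqtl_thresholds: dict[str, float]
    eqtl_sources: dict[str, SumStatsTable]
    outcomes: dict[str, SumStatsTable]
    outcome_specs: dict[str, OutcomeSpec]
    principal_outcome: str
    ld_by_chrom: dict[str, LDMatrix]
    truth: pd.DataFrame
    seed: int = 0
    extra: dict = field(default_factory=dict)


def _scenario_counts(k: int, mix: dict[str, float]) -> list[str]:
    """Largest-remainder apportionment of k loci across scenario proportions."""
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("scenario proportions must sum to 1")
    quotas = {name: k * p for name, p in mix.items()}
    counts = {name: int(q) for name, q in quotas.items()}
    short = k - sum(counts.values())
    for name in sorted(mix, key=lambda s: quotas[s] - counts[s], reverse=True)[:short]:
        counts[name] += 1
    labels: list[str] = []
    for name in mix:
        labels.extend([name] * counts[name])
    return labels


def simulate_panel(k_proteins: int, mix: dict[str, float], seed: int,
                   m: int = 200, rho: float = 0.9,
                   **scenario_kwargs) -> PanelDataset:
    """Independent loci (one per protein) across the full study design:
    three pQTL discovery sources with their own sample sizes and thresholds,
    a blood eQTL source, and a principal outcome plus a 17-outcome
    replication panel with declared polarities.

    Same (k, mix, seed) yields an identical dataset and truth table.
    """
    labels = _scenario_counts(k_proteins, mix)
    ss = np.random.SeedSequence(seed)
    locus_seeds = ss.spawn(k_proteins)

    genes: list[GeneAnnotation] = []
    protein_gene: dict[str, str] = {}
    ld_by_chrom: dict[str, LDMatrix] = {}
    per_source_frames: dict[str, list[pd.DataFrame]] = {s: [] for s in PQTL_SOURCES}
    eqtl_frames: list[pd.DataFrame] = []
    outcome_frames: dict[str, list[pd.DataFrame]] = {PRINCIPAL_OUTCOME: []}
    outcome_frames.update({o: [] for o in PANEL_OUTCOMES})
    truth_rows = []

    for i, (label, lseed) in enumerate(zip(labels, locus_seeds)):
        chrom = str(i + 1)
        scn = SimScenario(name=label, m=m, rho=rho, seed=0, chrom=chrom,
                          **scenario_kwargs)
        # sub-streams: alleles + pQTL sources + eQTL + principal + panel
        n_tables = 3 + len(PQTL_SOURCES) + len(PANEL_OUTCOMES)
        children = lseed.spawn(n_tables)
        rngs = [np.random.default_rng(c) for c in children]
        rng_alleles = rngs[0]

        ld = make_ld(m, rho, chrom)
        ld_by_chrom[chrom] = ld
        L = _chol(m, rho)
        R = _ar1(m, rho)
        joint = joint_effects(scn)
        ids = variant_ids(m, chrom)
        pos = positions(m)
        ea, oa, eaf = _draw_alleles(rng_alleles, m, scn.palindromic_fraction,
                                    protect=(scn.causal_idx, scn.second_idx))

        protein_id, gene_id = f"PROT{i + 1}", f"GENE{i + 1}"
        center = int(pos[scn.causal_idx])
        genes.append(GeneAnnotation(gene_id, gene_id, chrom,
                                    center - 5_000, center + 5_000))
        protein_gene[protein_id] = gene_id

        marg_prot = R @ joint["prot"]
        marg_eqtl = R @ joint["eqtl"]
        marg_risk = R @ joint["out"]

        k_rng = 1
        for source, (n_s, _thr) in PQTL_SOURCES.items():
            tab = _trait_table(protein_id, "quantitative", chrom, ids, pos,
                               ea, oa, eaf, marg_prot, n_s, L, rngs[k_rng], 0.0)
            per_source_frames[source].append(tab.df)
            k_rng += 1

        eqtl_frames.append(_trait_table(gene_id, "quantitative", chrom, ids, pos,
                                        ea, oa, eaf, marg_eqtl, scn.n_eqtl, L,
                                        rngs[k_rng], scn.flip_fraction).df)
        k_rng += 1

        outcome_frames[PRINCIPAL_OUTCOME].append(
            _trait_table(PRINCIPAL_OUTCOME, "binary", chrom, ids, pos, ea, oa, eaf,
                         marg_risk, scn.n_out, L, rngs[k_rng], scn.flip_fraction).df)
        k_rng += 1
        for outcome_id, (family, polarity, n_eff) in PANEL_OUTCOMES.items():
            ttype = "binary" if family.endswith("binary") else "quantitative"
            outcome_frames[outcome_id].append(
                _trait_table(outcome_id, ttype, chrom, ids, pos, ea, oa, eaf,
                             polarity * marg_risk, n_eff, L, rngs[k_rng],
                             scn.flip_fraction).df)
            k_rng += 1

        truth_rows.append({
            "protein_id": protein_id, "gene_id": gene_id, "chrom": chrom,
            "scenario": label, "theta": scn.theta, "a": scn.a, "e": scn.e,
            "c": scn.c, "causal_variant": ids[scn.causal_idx],
            "second_variant": ids[scn.second_idx],
        })

    def _concat(frames: list[pd.DataFrame], trait_id: str, ttype: str) -> SumStatsTable:
        return SumStatsTable(trait_id, ttype,
                             pd.concat(frames, ignore_index=True))

    pqtl_sources = {s: _concat(per_source_frames[s], s, "quantitative")
                    for s in PQTL_SOURCES}
    eqtl_sources = {"blood": _concat(eqtl_frames, "blood", "quantitative")}
    outcomes = {}
    specs = {}
    outcomes[PRINCIPAL_OUTCOME] = _concat(outcome_frames[PRINCIPAL_OUTCOME],
                                          PRINCIPAL_OUTCOME, "binary")
    specs[PRINCIPAL_OUTCOME] = OutcomeSpec(PRINCIPAL_OUTCOME, "ckd_binary", +1)
    for outcome_id, (family, polarity, _n) in PANEL_OUTCOMES.items():
        ttype = "binary" if family.endswith("binary") else "quantitative"
        outcomes[outcome_id] = _concat(outcome_frames[outcome_id], outcome_id, ttype)
        specs[outcome_id] = OutcomeSpec(outcome_id, family, polarity)

    return PanelDataset(genes, protein_gene, pqtl_sources,
                        {s: thr for s, (_n, thr) in PQTL_SOURCES.items()},
                        eqtl_sources, outcomes, specs, PRINCIPAL_OUTCOME,
                        ld_by_chrom, pd.DataFrame(truth_rows), seed)
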