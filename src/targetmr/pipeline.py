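"""End-to-end discovery pipeline: instruments -> MR -> FDR -> meta -> SMR ->
colocalization -> replication -> evidence tiers.

The pipeline mirrors a proteome-wide drug-target screen: for every protein it
selects cis-pQTL instruments per discovery source, estimates the causal effect
on the principal outcome, controls the FDR within each source, meta-analyzes
proteins significant in at least one source, then corroborates the survivors
at the expression level (SMR + HEIDI in each eQTL tissue), at the locus level
(ABF colocalization of the protein and outcome signals), and across a
replication panel of related outcomes, finally assigning evidence tiers.

`analyze_panel` is the in-memory engine; `run_pipeline` wraps it with file
I/O, a declarative TOML config, stage TSV outputs, and provenance.
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import ColocConfig, colocalize
from .evidence import (EvidenceRow, OutcomeSpec, assign_tier, bh_fdr,
                       build_evidence_table, count_replications,
                       direction_consistency, fixed_effect_meta, write_evidence)
from .ld import InstrumentSet, LDMatrix, clump, read_ld, select_instruments, steiger_filter
from .mr import MRResult, ProteinMRReport, run_protein_mr
from .simulate import PanelDataset
from .smr import HeidiConfig, SMRResult, run_gene_smr, smr_passes
from .sumstats import (GeneAnnotation, SumStatsTable, cis_window, frame_to_pairs,
                       harmonize_frames, read_gene_annotations, read_sumstats)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds and mode switches of the discovery pipeline."""

    fdr_q: float = 0.05
    smr_p: float = 0.05
    heidi_p: float = 0.01
    pph4_full: float = 0.8
    pph4_moderate: float = 0.5
    p_top_eqtl: float = 5e-8
    cis_flank: int = 1_000_000
    clump_instruments: bool = False     # principal analysis uses all cis-QTLs
    clump_r2: float = 0.01
    clump_kb: int = 10_000
    sentinel_only: bool = False
    steiger: bool = True
    second_order_wald: bool = False
    palindrome_window: float = 0.08
    replication_alpha: float = 0.05
    heidi: HeidiConfig = field(default_factory=HeidiConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)

    def __post_init__(self) -> None:
        for name in ("fdr_q", "smr_p", "heidi_p", "pph4_full", "pph4_moderate"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def _protein_instruments(protein_id: str, gene: GeneAnnotation,
                         source_table: SumStatsTable, p_threshold: float,
                         outcome: SumStatsTable, ld: LDMatrix,
                         cfg: AnalysisConfig, source_label: str
                         ) -> tuple[InstrumentSet, dict]:
    """Cis window -> threshold -> (optional clump/sentinel) -> harmonize ->
    Steiger.  Returns the instrument set and filter provenance."""
    prov: dict = {"source": source_label, "p_threshold": p_threshold}
    cis = cis_window(gene, source_table, cfg.cis_flank)
    hits = select_instruments(cis, p_threshold)
    prov["n_cis_significant"] = len(hits)
    if len(hits) and cfg.sentinel_only:
        hits = hits.subset(hits.df["pval"] == hits.df["pval"].min()).subset(slice(0, 1))
    elif len(hits) and cfg.clump_instruments:
        hits = clump(hits, ld, cfg.clump_r2, cfg.clump_kb)
    prov["n_after_clump"] = len(hits)

    frame = harmonize_frames(hits.df, outcome.df, cfg.palindrome_window)
    pairs = [p for p in frame_to_pairs(frame) if p.kept]
    prov["n_harmonized"] = len(pairs)
    if cfg.steiger and pairs:
        pairs, report = steiger_filter(pairs)
        prov["n_steiger_removed"] = sum(not r.retained for r in report)
    prov["steiger_estimator"] = "t2/(t2+n-2) pseudo-r2"
    sub_ld = ld.submatrix([p.variant_id for p in pairs]) if pairs else None
    return InstrumentSet(protein_id, pairs, sub_ld, source_label), prov


def mr_stage(panel: PanelDataset, cfg: AnalysisConfig
             ) -> dict[str, dict[str, ProteinMRReport]]:
    """Per-source, per-protein MR against the principal outcome."""
    outcome = panel.outcomes[panel.principal_outcome]
    binary = outcome.trait_type == "binary"
    gene_by_id = {g.gene_id: g for g in panel.genes}
    results: dict[str, dict[str, ProteinMRReport]] = {}
    for source, table in panel.pqtl_sources.items():
        thr = panel.pqtl_thresholds[source]
        per_protein = {}
        for protein_id, gene_id in panel.protein_gene.items():
            gene = gene_by_id[gene_id]
            ld = panel.ld_by_chrom[gene.chrom]
            iv, prov = _protein_instruments(protein_id, gene, table, thr,
                                            outcome, ld, cfg, source)
            per_protein[protein_id] = run_protein_mr(
                protein_id, iv, panel.principal_outcome, binary_outcome=binary,
                second_order_wald=cfg.second_order_wald, provenance=prov)
        results[source] = per_protein
    return results


def fdr_stage(mr_results: dict[str, dict[str, ProteinMRReport]], fdr_q: float
              ) -> dict[str, pd.DataFrame]:
    """BH FDR within each source over proteins with a computable estimate."""
    out = {}
    for source, per_protein in mr_results.items():
        rows = [(pid, rep.primary.pval) for pid, rep in per_protein.items()
                if rep.primary is not None]
        df = pd.DataFrame(rows, columns=["protein_id", "pval"])
        if not df.empty:
            # strong signals underflow to p = 0; floor them for the BH step
            df["q"] = bh_fdr(np.clip(df["pval"].to_numpy(), 1e-300, 1.0))
            df["significant"] = df["q"] < fdr_q
        else:
            df["q"] = []
            df["significant"] = []
        out[source] = df.set_index("protein_id")
    return out


def meta_stage(mr_results, fdr_tables, fdr_q: float) -> dict[str, dict]:
    """Fixed-effect meta-combination per the discovery rule: combine when the
    protein is significant (q < fdr_q) in >= 1 source and has estimates from
    >= 2 sources; otherwise report the best single-source estimate."""
    proteins = sorted({pid for per in mr_results.values() for pid in per})
    combined = {}
    for pid in proteins:
        ests, qs, n_sig = [], [], 0
        for source, per in mr_results.items():
            rep = per.get(pid)
            if rep is None or rep.primary is None:
                continue
            ests.append((rep.primary.beta, rep.primary.se))
            qrow = fdr_tables[source]
            if pid in qrow.index:
                qs.append(float(qrow.at[pid, "q"]))
                if qrow.at[pid, "significant"]:
                    n_sig += 1
        if not ests:
            combined[pid] = {"status": "no_instruments", "n_sig_sources": 0,
                             "q_min": float("nan")}
            continue
        if n_sig >= 1 and len(ests) >= 2:
            beta, se, p, or_, ci = fixed_effect_meta(ests)
        else:
            # single available estimate, or nothing significant: most precise source
            beta, se, p, or_, ci = fixed_effect_meta([min(ests, key=lambda t: t[1])])
        combined[pid] = {"status": "ok", "beta": beta, "se": se, "p": p,
                         "or": or_, "ci": ci, "n_sources": len(ests),
                         "n_sig_sources": n_sig,
                         "q_min": min(qs) if qs else float("nan")}
    return combined


def smr_stage(panel: PanelDataset, protein_ids: list[str], cfg: AnalysisConfig
              ) -> dict[str, dict[str, SMRResult]]:
    """SMR + HEIDI per eQTL tissue for the MR-significant proteins."""
    outcome = panel.outcomes[panel.principal_outcome]
    gene_by_id = {g.gene_id: g for g in panel.genes}
    results: dict[str, dict[str, SMRResult]] = {pid: {} for pid in protein_ids}
    for tissue, eqtl_table in panel.eqtl_sources.items():
        for pid in protein_ids:
            gene = gene_by_id[panel.protein_gene[pid]]
            cis = cis_window(gene, eqtl_table, cfg.cis_flank)
            cis.trait_id = gene.gene_id
            res = run_gene_smr(gene.gene_id, cis, outcome,
                               panel.ld_by_chrom[gene.chrom], tissue,
                               cfg.p_top_eqtl, cfg.heidi)
            results[pid][tissue] = res
    return results


def coloc_stage(panel: PanelDataset, protein_ids: list[str],
                source_for: dict[str, str], cfg: AnalysisConfig) -> dict[str, object]:
    """Colocalize each significant protein's cis region with the outcome."""
    outcome = panel.outcomes[panel.principal_outcome]
    gene_by_id = {g.gene_id: g for g in panel.genes}
    out = {}
    for pid in protein_ids:
        gene = gene_by_id[panel.protein_gene[pid]]
        prot_region = cis_window(gene, panel.pqtl_sources[source_for[pid]], cfg.cis_flank)
        out_region = cis_window(gene, outcome, cfg.cis_flank)
        out[pid] = colocalize(prot_region, out_region, cfg.coloc,
                              cfg.pph4_full, cfg.pph4_moderate)
    return out


def replication_stage(panel: PanelDataset, protein_ids: list[str],
                      cfg: AnalysisConfig) -> dict[str, dict[str, MRResult | None]]:
    """Principal-design MR of each significant protein on every panel outcome."""
    gene_by_id = {g.gene_id: g for g in panel.genes}
    results: dict[str, dict[str, MRResult | None]] = {pid: {} for pid in protein_ids}
    panel_ids = [o for o in panel.outcomes if o != panel.principal_outcome]
    for outcome_id in panel_ids:
        outcome = panel.outcomes[outcome_id]
        binary = outcome.trait_type == "binary"
        for pid in protein_ids:
            gene = gene_by_id[panel.protein_gene[pid]]
            ld = panel.ld_by_chrom[gene.chrom]
            best: MRResult | None = None
            for source, table in panel.pqtl_sources.items():
                iv, _ = _protein_instruments(pid, gene, table,
                                             panel.pqtl_thresholds[source],
                                             outcome, ld, cfg, source)
                rep = run_protein_mr(pid, iv, outcome_id, binary_outcome=binary)
                if rep.primary is not None and (best is None or rep.primary.se < best.se):
                    best = rep.primary
            results[pid][outcome_id] = best
    return results


def analyze_panel(panel: PanelDataset, cfg: AnalysisConfig | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline on an in-memory dataset.

    Returns the evidence table (one row per protein, ordered by tier then q)
    and a report bundle with the per-stage results.
    """
    cfg = cfg or AnalysisConfig()
    t0 = time.time()
    mr_results = mr_stage(panel, cfg)
    fdr_tables = fdr_stage(mr_results, cfg.fdr_q)
    combined = meta_stage(mr_results, fdr_tables, cfg.fdr_q)

    significant = sorted(pid for pid, c in combined.items()
                         if c["status"] == "ok" and c["n_sig_sources"] >= 1)
    # protein region for colocalization: the source with the smallest q
    source_for = {}
    for pid in significant:
        best_q, best_source = np.inf, next(iter(panel.pqtl_sources))
        for source, table in fdr_tables.items():
            if pid in table.index and table.at[pid, "q"] < best_q:
                best_q, best_source = float(table.at[pid, "q"]), source
        source_for[pid] = best_source

    smr_results = smr_stage(panel, significant, cfg)
    coloc_results = coloc_stage(panel, significant, source_for, cfg)
    replication = replication_stage(panel, significant, cfg)

    panel_specs = {o: s for o, s in panel.outcome_specs.items()
                   if o != panel.principal_outcome}
    rows = []
    for pid, comb in combined.items():
        row = EvidenceRow(protein_id=pid)
        if comb["status"] != "ok":
            rows.append(row)
            continue
        row.combined_beta, row.combined_se, row.combined_p = (
            comb["beta"], comb["se"], comb["p"])
        row.combined_or = comb["or"]
        row.combined_or_low, row.combined_or_high = comb["ci"]
        row.q_value = comb["q_min"]
        row.n_sig_sources = comb["n_sig_sources"]
        mr_sig = pid in significant
        if mr_sig:
            per_tissue = smr_results[pid]
            row.passed_smr = any(
                smr_passes(r, cfg.smr_p, cfg.heidi_p) for r in per_tissue.values())
            gene_betas = {t: r.b_smr for t, r in per_tissue.items()
                          if r.status not in ("no_top_eqtl",) and np.isfinite(r.b_smr)}
            _, row.direction_consistent_gene = direction_consistency(
                row.combined_beta, gene_betas)
            cres = coloc_results[pid]
            row.pph4 = cres.pph4
            row.coloc_level = cres.call
            row.passed_coloc = cres.pph4 > cfg.pph4_moderate
            row.replication_count = count_replications(
                row.combined_beta, replication[pid], panel_specs,
                cfg.replication_alpha)
        row.tier = assign_tier(mr_sig, row.passed_smr, row.passed_coloc)
        row.per_source = {
            s: {"beta": r.primary.beta, "se": r.primary.se, "p": r.primary.pval,
                "method": r.primary.method, "n_instruments": r.primary.n_instruments}
            for s, per in mr_results.items()
            if (r := per.get(pid)) is not None and r.primary is not None}
        rows.append(row)

    table = build_evidence_table(rows)
    report = {"mr": mr_results, "fdr": fdr_tables, "combined": combined,
              "smr": smr_results, "coloc": coloc_results,
              "replication": replication, "elapsed_s": time.time() - t0}
    return table, report


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative run description loaded from a TOML file."""

    pqtl_sources: dict[str, dict]       # label -> {path, p_threshold, [column_map]}
    eqtl_sources: dict[str, dict]       # tissue -> {path}
    outcomes: dict[str, dict]           # outcome_id -> {path, family, polarity, trait_type}
    principal_outcome: str
    genes_path: str
    ld_paths: dict[str, str]            # chrom -> LD matrix file
    protein_gene: dict[str, str]
    out_dir: str
    seed: int = 0
    genes_zero_based: bool = False
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        analysis_kwargs = raw.get("analysis", {})
        heidi = HeidiConfig(**analysis_kwargs.pop("heidi", {}))
        coloc_cfg = ColocConfig(**analysis_kwargs.pop("coloc", {}))
        cfg = cls(
            pqtl_sources=raw["pqtl_sources"],
            eqtl_sources=raw["eqtl_sources"],
            outcomes=raw["outcomes"],
            principal_outcome=raw["principal_outcome"],
            genes_path=raw["genes_path"],
            ld_paths=raw["ld_paths"],
            protein_gene=raw["protein_gene"],
            out_dir=raw["out_dir"],
            seed=int(raw.get("seed", 0)),
            genes_zero_based=bool(raw.get("genes_zero_based", False)),
            analysis=AnalysisConfig(heidi=heidi, coloc=coloc_cfg, **analysis_kwargs),
        )
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        paths = ([self.genes_path]
                 + [s["path"] for s in self.pqtl_sources.values()]
                 + [s["path"] for s in self.eqtl_sources.values()]
                 + [s["path"] for s in self.outcomes.values()]
                 + list(self.ld_paths.values()))
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def _load_panel(cfg: PipelineConfig) -> PanelDataset:
    genes = read_gene_annotations(cfg.genes_path, cfg.genes_zero_based)
    pqtl, thresholds = {}, {}
    for label, spec in cfg.pqtl_sources.items():
        pqtl[label] = read_sumstats(spec["path"], spec.get("column_map"),
                                    "quantitative", label)
        thresholds[label] = float(spec["p_threshold"])
    eqtl = {tissue: read_sumstats(spec["path"], spec.get("column_map"),
                                  "quantitative", tissue)
            for tissue, spec in cfg.eqtl_sources.items()}
    outcomes, specs = {}, {}
    for oid, spec in cfg.outcomes.items():
        outcomes[oid] = read_sumstats(spec["path"], spec.get("column_map"),
                                      spec.get("trait_type", "binary"), oid)
        specs[oid] = OutcomeSpec(oid, spec["family"], int(spec["polarity"]))
    ld = {chrom: read_ld(path) for chrom, path in cfg.ld_paths.items()}
    return PanelDataset(genes, dict(cfg.protein_gene), pqtl, thresholds, eqtl,
                        outcomes, specs, cfg.principal_outcome, ld,
                        pd.DataFrame(), cfg.seed)


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Execute the pipeline from a validated config; write stage outputs,
    the evidence table, a run log, and provenance.  Deterministic given
    fixed inputs.  Hard errors abort with the stage name."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("targetmr")
    root.addHandler(handler)
    try:
        stage = "load"
        panel = _load_panel(config)
        stage = "analyze"
        table, report = analyze_panel(panel, config.analysis)
        stage = "write"
        _write_stage_outputs(out_dir, table, report)
        provenance = {
            "version": __version__,
            "seed": config.seed,
            "inputs": {
                "pqtl_sources": {k: v["path"] for k, v in config.pqtl_sources.items()},
                "eqtl_sources": {k: v["path"] for k, v in config.eqtl_sources.items()},
                "outcomes": {k: v["path"] for k, v in config.outcomes.items()},
                "genes": config.genes_path,
                "ld": config.ld_paths,
            },
            "thresholds": {
                "fdr_q": config.analysis.fdr_q, "smr_p": config.analysis.smr_p,
                "heidi_p": config.analysis.heidi_p,
                "pph4": [config.analysis.pph4_full, config.analysis.pph4_moderate],
                "pqtl_p": {k: v["p_threshold"] for k, v in config.pqtl_sources.items()},
            },
        }
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                            sort_keys=True))
        return table
    except Exception as exc:
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline aborted in stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_stage_outputs(out_dir: Path, table: pd.DataFrame, report: dict) -> None:
    write_evidence(table, out_dir / "evidence.tsv", out_dir / "evidence.json")
    mr_rows = []
    for source, per in report["mr"].items():
        for pid, rep in per.items():
            if rep.primary is None:
                mr_rows.append({"source": source, "protein_id": pid,
                                "method": "", "status": rep.status})
                continue
            r = rep.primary
            mr_rows.append({"source": source, "protein_id": pid, "method": r.method,
                            "beta": r.beta, "se": r.se, "pval": r.pval,
                            "n_instruments": r.n_instruments, "q_stat": r.q_stat,
                            "q_pval": r.q_pval, "status": rep.status})
    pd.DataFrame(mr_rows).to_csv(out_dir / "mr_per_source.tsv", sep="\t",
                                 index=False, float_format="%.10g")
    smr_rows = []
    for pid, per_tissue in report["smr"].items():
        for tissue, r in per_tissue.items():
            smr_rows.append({"protein_id": pid, "tissue": tissue,
                             "top_variant": r.top_variant, "b_smr": r.b_smr,
                             "se_smr": r.se_smr, "p_smr": r.p_smr,
                             "heidi_p": r.heidi_p, "heidi_n_snps": r.heidi_n_snps,
                             "status": r.status})
    pd.DataFrame(smr_rows).to_csv(out_dir / "smr.tsv", sep="\t", index=False,
                                  float_format="%.10g")
    coloc_rows = [{"protein_id": pid, "pph0": c.pph0, "pph1": c.pph1,
                   "pph2": c.pph2, "pph3": c.pph3, "pph4": c.pph4,
                   "n_variants": c.n_variants, "call": c.call}
                  for pid, c in report["coloc"].items()]
    pd.DataFrame(coloc_rows).to_csv(out_dir / "coloc.tsv", sep="\t", index=False,
                                    float_format="%.10g")
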