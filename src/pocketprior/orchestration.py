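"""End-to-end pipeline runner.

``run_all`` executes pocket annotation -> mutation mapping -> enrichment
screen -> CePIN -> drug response -> survival in order, skipping any stage
whose inputs are not configured, and assembles a machine-readable report
with per-stage record counts and conservation checks.  Every threshold the
analysis uses (FDR 0.1, PCC 0.5, alpha 0.05, follow-up horizon) is a
config key defaulting to the published value.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cepin as cepin_mod
from . import drug_response as drug_mod
from . import enrichment_stats as enrich_mod
from . import mutation_mapping as mut_mod
from . import survival as surv_mod
from .pocket_annotation import (
    DEFAULT_EXCLUDED,
    load_pocket_annotations,
    read_accession_list,
    write_pocket_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run (YAML-serialisable)."""

    outdir: str
    # inputs (None -> stage skipped)
    pdb_dir: str | None = None
    sifts: str | None = None
    allowed_proteins: str | None = None
    mutations: str | None = None
    gene_sets: str | None = None
    ppi: str | None = None
    expression: str | None = None
    cl_mutations: str | None = None
    pharmacology: str | None = None
    survival_cohort: str | None = None
    # thresholds / choices
    excluded_proteins: list[str] = field(default_factory=lambda: sorted(DEFAULT_EXCLUDED))
    fdr_threshold: float = 0.1
    pcc_threshold: float = 0.5
    alpha: float = 0.05
    survival_horizon_days: float | None = None
    alternative: str = "greater"
    drug_alternative: str = "two-sided"
    top_k_cancer_types: int = 10
    drug_gene: str | None = None  # default: gene with most pocket cell-line mutations
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold <= 1 and 0 < self.alpha <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if not (-1 <= self.pcc_threshold <= 1):
            raise ValueError("pcc_threshold must lie in [-1, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def _report_hash(report: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(report, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config_hash": _config_hash(config), "stages": {}, "skipped": []}
    stages = report["stages"]

    # --- pocket annotation -------------------------------------------------
    annotations = None
    if config.pdb_dir and config.sifts:
        try:
            allowed = read_accession_list(config.allowed_proteins) if config.allowed_proteins else None
            annotations, trans_report = load_pocket_annotations(
                config.pdb_dir, config.sifts, allowed=allowed, excluded=set(config.excluded_proteins)
            )
            write_pocket_table(annotations, outdir / "pockets.tsv")
            stages["pocket_annotation"] = {
                "n_pocket_residues": len(annotations),
                "n_proteins": len(annotations.proteins),
                "n_unmapped": trans_report.unmapped,
                "n_mismatched": trans_report.mismatched,
            }
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise PipelineError("pocket_annotation", str(exc)) from exc
    else:
        report["skipped"].append("pocket_annotation")

    # --- mutation mapping --------------------------------------------------
    mapped = None
    if annotations is not None and config.mutations:
        try:
            catalog = mut_mod.read_mutation_catalog(config.mutations)
            mapped = mut_mod.map_mutations(catalog, annotations)
            mut_mod.write_mapped_set(mapped, outdir / "mapped_mutations.tsv")
            class_summary = mut_mod.summarize_by_class(mapped)
            class_summary.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
            n_pocket = int(mapped.records["in_pocket"].sum())
            stage: dict[str, Any] = {
                "n_catalog": len(catalog),
                "n_on_annotated_proteins": len(mapped),
                "n_pocket": n_pocket,
                "n_non_pocket": len(mapped) - n_pocket,
                "class_summary": class_summary.to_dict("records"),
                "top_genes": mut_mod.top_genes_by_pocket_missense(mapped, 10) if n_pocket else [],
            }
            if n_pocket:
                mean_all, mean_mis = mut_mod.per_protein_averages(mapped)
                stage["mean_pocket_mutations_per_protein"] = mean_all
                stage["mean_pocket_missense_per_protein"] = mean_mis
                mut_mod.amino_acid_spectrum(mapped, "cancer_type").to_csv(
                    outdir / "aa_spectrum_by_cancer_type.tsv", sep="\t"
                )
            stages["mutation_mapping"] = stage
        except Exception as exc:
            raise PipelineError("mutation_mapping", str(exc)) from exc
    elif "pocket_annotation" not in report["skipped"] or config.mutations:
        report["skipped"].append("mutation_mapping")

    # --- enrichment screen -------------------------------------------------
    pocket_genes: set[str] = set()
    background_genes: set[str] = set()
    if mapped is not None and len(mapped):
        try:
            screens = [enrich_mod.run_per_gene_screen(
                mapped, None, config.fdr_threshold, config.alternative
            )]
            for ctype in enrich_mod.select_top_cancer_types(mapped, config.top_k_cancer_types):
                screens.append(enrich_mod.run_per_gene_screen(
                    mapped, ctype, config.fdr_threshold, config.alternative
                ))
            non_empty = [s for s in screens if len(s)]
            results = pd.concat(non_empty, ignore_index=True) if non_empty else screens[0]
            enrich_mod.write_screen_results(results, outdir / "enrichment.tsv")
            pan = results[results["scope"] == enrich_mod.PAN_CANCER]
            stages["enrichment"] = {
                "n_tests": len(results),
                "n_significant_pan_cancer": int(pan["significant"].sum()),
                "significant_genes_pan_cancer": sorted(pan[pan["significant"]]["gene"]),
                "scopes": sorted(results["scope"].unique()),
            }
            missense = mapped.records[mapped.records["mclass"] == "missense"]
            pocket_genes = set(missense[missense["in_pocket"]]["gene"])
            background_genes = set(missense["gene"]) - pocket_genes
            if config.gene_sets and pocket_genes and background_genes:
                gs_rows = []
                for gs in enrich_mod.read_gmt(config.gene_sets):
                    table, p, orat = enrich_mod.gene_set_enrichment(pocket_genes, background_genes, gs)
                    gs_rows.append({"gene_set": gs.name, "a": table.a, "b": table.b,
                                    "c": table.c, "d": table.d, "odds_ratio": orat, "p": p})
                pd.DataFrame(gs_rows).to_csv(outdir / "gene_set_enrichment.tsv", sep="\t", index=False)
                stages["gene_set_enrichment"] = gs_rows
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("enrichment", str(exc)) from exc

    # --- CePIN ---------------------------------------------------------------
    if config.ppi and config.expression and mapped is not None:
        try:
            edges, clean_report = cepin_mod.clean_ppi(cepin_mod.read_ppi_edges(config.ppi))
            expr = cepin_mod.quantile_normalize(cepin_mod.read_expression_matrix(config.expression))
            net, build_report = cepin_mod.build_cepin(edges, expr, pocket_genes, config.pcc_threshold)
            cepin_mod.write_cepin(net, outdir / "cepin.tsv")
            table, p, orat = cepin_mod.pocket_pair_enrichment(net)
            stages["cepin"] = {
                "n_edges_clean": clean_report.n_kept,
                "n_self_loops_removed": clean_report.n_self_loops,
                "n_duplicates_removed": clean_report.n_duplicates,
                "n_edges_scored": build_report.n_edges_out,
                "n_dropped_missing_expression": build_report.n_dropped_missing_expression,
                "pocket_pair_table": list(table.as_tuple()),
                "odds_ratio": orat,
                "p_value": p,
            }
        except Exception as exc:
            raise PipelineError("cepin", str(exc)) from exc
    elif config.ppi or config.expression:
        report["skipped"].append("cepin")

    # --- drug response -------------------------------------------------------
    if config.cl_mutations and config.pharmacology and annotations is not None:
        try:
            profiles = mut_mod.read_mutation_catalog(config.cl_mutations)
            pharm = drug_mod.read_pharmacology(config.pharmacology)
            gene = config.drug_gene
            if gene is None:
                cl_mapped = mut_mod.map_mutations(profiles, annotations)
                pocket_cl = cl_mapped.pocket_records()
                if pocket_cl.empty:
                    raise ValueError("no cell line carries a pocket mutation; configure drug_gene")
                gene = pocket_cl.groupby("gene").size().sort_values(ascending=False).index[0]
            comparisons = []
            for drug in sorted(pharm["drug"].unique()):
                for mode in drug_mod.MODES:
                    comparisons.append(drug_mod.compare_response(
                        gene, drug, profiles, pharm, annotations,
                        mode=mode, alternative=config.drug_alternative, alpha=config.alpha,
                    ))
            table = drug_mod.comparison_table(comparisons)
            table.to_csv(outdir / "drug_response.tsv", sep="\t", index=False)
            stages["drug_response"] = {"gene": gene, "comparisons": table.to_dict("records")}
        except Exception as exc:
            raise PipelineError("drug_response", str(exc)) from exc
    elif config.cl_mutations or config.pharmacology:
        report["skipped"].append("drug_response")

    # --- survival ------------------------------------------------------------
    if config.survival_cohort:
        try:
            cohort = surv_mod.read_cohort(config.survival_cohort)
            if config.survival_horizon_days is not None:
                cohort = surv_mod.truncate(cohort, config.survival_horizon_days)
            low, high = surv_mod.dichotomize_by_median(cohort)
            for name, group in (("low", low), ("high", high)):
                curve = surv_mod.km_estimate(group["time_days"], group["event"])
                surv_mod.km_curve_table(curve).to_csv(outdir / f"km_{name}.tsv", sep="\t", index=False)
            chi2, p = surv_mod.logrank_test(
                low["time_days"], low["event"], high["time_days"], high["event"]
            )
            stages["survival"] = {
                "n_low": len(low), "n_high": len(high),
                "n_events": int(cohort["event"].sum()),
                "horizon_days": config.survival_horizon_days,
                "chi_square": chi2, "p_value": p,
            }
        except Exception as exc:
            raise PipelineError("survival", str(exc)) from exc

    report["report_hash"] = _report_hash(report["stages"])
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
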