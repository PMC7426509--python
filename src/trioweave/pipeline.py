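"""End-to-end pipeline orchestration.

Runs simulate -> differential expression -> trio QC + integrative set test
-> variant screening -> enrichment -> minimal network as one reproducible
run driven by a YAML config and a master seed, writing every intermediate
artifact and a machine-readable run report.  Identical configs produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counts import de_gene_lists, filter_low_counts, nb_de_test, size_factors
from .enrich import AnnotationMap, hypergeom_enrich
from .genes import write_bed
from .io import (
    write_catalog_tsv,
    write_counts_tsv,
    write_interactome_tsv,
    write_network_graphml,
    write_network_json,
    write_trio_panel,
    write_variants_vcf,
)
from .network import common_tf_report, condense_minimal, select_interconnected_seeds
from .synthetic import CohortConfig, gen_annotation, gen_cohort
from .trio import QcThresholds, integrate, qc_filter, tdt_all
from .variants import count_novel_by_gene, run_cascade

STAGE_ORDER = ("simulate", "de", "integrate", "variants", "enrich", "network")

#: Every analysis threshold with its default value; mirrored into YAML.
STAGE_DEFAULTS = {
    "de": {"quantile": 0.4, "alpha_bh": 0.1, "alpha_raw": 0.05, "dispersion_mode": "blind"},
    "integrate": {
        "window": 20_000,
        "n_perm": 10_000,
        "max_reps": 5,
        "prune_r2": 0.5,
        "snp_p_enter": 0.05,
        "set_alpha": 0.05,
    },
    "variants": {"af_min": 0.4, "an_min": 10, "effect_keep": ["MODERATE", "HIGH"]},
    "enrich": {"alpha": 0.05},
    "network": {"max_intermediates": 1},
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "trioweave_run"
    cohort: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        unknown = set(self.params) - set(STAGE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter blocks: {sorted(unknown)}")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def stage_params(self, stage: str) -> dict:
        merged = dict(STAGE_DEFAULTS[stage])
        merged.update(self.params.get(stage, {}))
        return merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        doc = {
            "seed": self.seed,
            "outdir": self.outdir,
            "cohort": self.cohort,
            "stages": {s: self.enabled(s) for s in STAGE_ORDER},
            "params": {s: self.stage_params(s) for s in STAGE_DEFAULTS},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # ---- simulate -------------------------------------------------------
    try:
        cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
        cohort = gen_cohort(cohort_cfg)
        write_bed(cohort.gene_models, out / "genes.bed")
        write_counts_tsv(cohort.counts.matrix, out / "counts.tsv", out / "groups.tsv")
        write_trio_panel(cohort.trios.panel, out / "trios.ped.tsv", out / "sites.tsv")
        write_variants_vcf(cohort.variants.table, out / "variants.vcf")
        write_catalog_tsv(cohort.variants.catalog, out / "catalog.tsv")
        write_interactome_tsv(cohort.interactome.graph, out / "interactome.tsv")
        report["stages"]["simulate"] = {
            "n_genes": len(cohort.gene_models),
            "n_trios": cohort.trios.panel.n_families,
            "n_snps": cohort.trios.panel.n_snps,
            "n_variants": len(cohort.variants.table),
            "n_planted_de": len(cohort.counts.de_gene_ids),
            "n_distorted_snps": len(cohort.trios.distorted_snp_ids),
        }
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("simulate", str(exc)) from exc

    de_results = None
    significant: list = []
    candidates: list = []
    if config.enabled("de"):
        try:
            p = config.stage_params("de")
            filtered = filter_low_counts(cohort.counts.matrix, quantile=p["quantile"])
            factors = size_factors(filtered)
            de_results = nb_de_test(filtered, factors, dispersion_mode=p["dispersion_mode"])
            significant, candidates = de_gene_lists(
                de_results, alpha_bh=p["alpha_bh"], alpha_raw=p["alpha_raw"]
            )
            de_results.to_csv(out / "de_results.tsv", sep="\t", index=False)
            report["stages"]["de"] = {
                "input_genes": len(cohort.counts.matrix.gene_ids),
                "low_count_removed": len(filtered.low_count_filtered),
                "tested": len(filtered.gene_ids),
                "significant_bh": len(significant),
                "candidates_raw": len(candidates),
            }
        except Exception as exc:
            raise PipelineError("de", str(exc)) from exc

    integrative = pd.DataFrame(
        columns=["gene_id", "empirical_p", "observed_stat", "representative_snp_ids"]
    )
    if config.enabled("integrate") and de_results is not None:
        try:
            p = config.stage_params("integrate")
            clean_panel, qc_report = qc_filter(cohort.trios.panel, QcThresholds())
            qc_report.snps_dropped.to_csv(out / "qc_snps_dropped.tsv", sep="\t", index=False)
            qc_report.families_dropped.to_csv(out / "qc_families_dropped.tsv", sep="\t", index=False)
            tdt_all(clean_panel).to_csv(out / "tdt_results.tsv", sep="\t", index=False)
            integrative = integrate(
                de_results,
                clean_panel,
                cohort.gene_models,
                window=p["window"],
                de_p=config.stage_params("de")["alpha_raw"],
                set_alpha=p["set_alpha"],
                max_reps=p["max_reps"],
                prune_r2=p["prune_r2"],
                snp_p_enter=p["snp_p_enter"],
                n_perm=p["n_perm"],
                seed=config.seed,
            )
            integrative.to_csv(out / "integrative_results.tsv", sep="\t", index=False)
            report["stages"]["integrate"] = {
                "families_in": cohort.trios.panel.n_families,
                "families_dropped": len(qc_report.families_dropped),
                "snps_in": cohort.trios.panel.n_snps,
                "snps_dropped": len(qc_report.snps_dropped),
                "genotypes_masked": qc_report.genotypes_masked,
                "genes_reported": len(integrative),
            }
        except Exception as exc:
            raise PipelineError("integrate", str(exc)) from exc

    retained_variants = pd.DataFrame()
    if config.enabled("variants"):
        try:
            p = config.stage_params("variants")
            retained_variants, ledger = run_cascade(
                cohort.variants.table,
                cohort.variants.catalog,
                af_min=p["af_min"],
                an_min=p["an_min"],
                effect_keep=tuple(p["effect_keep"]),
            )
            retained_variants.to_csv(out / "variants_retained.tsv", sep="\t", index=False)
            ledger.to_csv(out / "variants_ledger.tsv", sep="\t", index=False)
            per_gene = count_novel_by_gene(retained_variants, cohort.gene_models)
            per_gene[per_gene["n_novel_common"] > 0].to_csv(
                out / "novel_by_gene.tsv", sep="\t", index=False
            )
            report["stages"]["variants"] = {
                "input": len(cohort.variants.table),
                "retained": len(retained_variants),
                "removed": {
                    str(r.stage): int(r.removed) for r in ledger.itertuples(index=False)
                },
            }
        except Exception as exc:
            raise PipelineError("variants", str(exc)) from exc

    if config.enabled("enrich") and de_results is not None:
        try:
            p = config.stage_params("enrich")
            gene_ids = [g.gene_id for g in cohort.gene_models]
            terms = gen_annotation(cohort_cfg, gene_ids, enriched_in=cohort.counts.de_gene_ids)
            annot = AnnotationMap(terms=terms, universe=set(gene_ids))
            query = significant if significant else candidates
            enr = hypergeom_enrich(query, annot)
            enr.to_csv(out / "enrichment_go.tsv", sep="\t", index=False)
            report["stages"]["enrich"] = {
                "query_genes": len(query),
                "terms_tested": len(enr),
                "terms_significant": int((enr["q_value"] < p["alpha"]).sum()) if len(enr) else 0,
            }
        except Exception as exc:
            raise PipelineError("enrich", str(exc)) from exc

    if config.enabled("network"):
        try:
            p = config.stage_params("network")
            seed_sources: dict = {}
            for gid in significant:
                seed_sources.setdefault(gid, set()).add("RNASEQ")
            for gid in integrative["gene_id"]:
                seed_sources.setdefault(gid, set()).add("INTEGRATIVE")
            if len(retained_variants):
                for gid in retained_variants["gene_id"].dropna():
                    seed_sources.setdefault(gid, set()).add("EXOME_NOVEL")
            graph = cohort.interactome.graph
            seeds = sorted(set(seed_sources) & set(graph.nodes))
            if not seeds:
                raise ValueError("no seed genes present in the interactome")
            retained, dropped_report = select_interconnected_seeds(graph, seeds)
            dropped_report.to_csv(out / "network_dropped_seeds.tsv", sep="\t", index=False)
            if not retained:
                report["stages"]["network"] = {
                    "seeds_in": len(seeds),
                    "seeds_retained": 0,
                    "seeds_dropped": len(dropped_report),
                    "connectors": 0,
                    "edges": 0,
                }
                with open(out / "report.json", "w") as fh:
                    json.dump(report, fh, indent=2, sort_keys=True)
                return report
            snp_decor = {}
            for row in integrative.itertuples(index=False):
                snp_decor[row.gene_id] = row.representative_snp_ids
            decorations = {
                g: {
                    "sources": ",".join(sorted(seed_sources.get(g, set()))),
                    "snp_ids": snp_decor.get(g, ""),
                    "de": g in set(significant),
                }
                for g in retained
            }
            minimal = condense_minimal(
                graph, retained, max_intermediates=p["max_intermediates"], decorations=decorations
            )
            write_network_json(minimal, out / "network.json")
            write_network_graphml(minimal, out / "network.graphml")
            tf_terms = _tf_targets(graph)
            if tf_terms and minimal.nodes:
                tf_annot = AnnotationMap(terms=tf_terms, universe=set(graph.nodes))
                tf_report = common_tf_report(minimal, tf_annot)
                tf_report.to_csv(out / "network_tf_enrichment.tsv", sep="\t", index=False)
            report["stages"]["network"] = {
                "seeds_in": len(seeds),
                "seeds_retained": len(retained),
                "seeds_dropped": len(dropped_report),
                "connectors": len(minimal.connectors),
                "edges": minimal.graph.number_of_edges(),
            }
        except Exception as exc:
            raise PipelineError("network", str(exc)) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _tf_targets(graph) -> dict:
    """TF-target annotation induced by the interactome's TF edges."""
    terms: dict = {}
    for u, v, data in graph.edges(data=True):
        if "TF" in data.get("provenance", set()):
            terms.setdefault(u, set()).add(v)
            terms.setdefault(v, set()).add(u)
    return {t: g for t, g in terms.items() if g}
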