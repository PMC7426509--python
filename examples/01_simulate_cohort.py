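"""Generate a synthetic multi-omics trio cohort with known ground truth.

The generator plants differentially expressed genes, places transmission-
distorted SNPs inside those genes' 20 kb windows, and builds variant
tables and an interactome over the same gene namespace — everything the
analysis stages consume, reproducible from one master seed.
"""

from trioweave import CohortConfig, gen_cohort

config = CohortConfig(seed=1, n_trios=36, n_snps=2000, n_genes=400)
cohort = gen_cohort(config)

print(f"trios:          {cohort.trios.panel.n_families} families x {cohort.trios.panel.n_snps} SNPs")
print(f"planted DE:     {len(cohort.counts.de_gene_ids)} of {config.n_genes} genes")
print(f"distorted SNPs: {len(cohort.trios.distorted_snp_ids)} (tau = {config.distortion_tau})")
print(f"variants:       {len(cohort.variants.table)} records, "
      f"{len(cohort.variants.catalog)} in the known catalog")
print(f"interactome:    {cohort.interactome.graph.number_of_nodes()} nodes, "
      f"{cohort.interactome.graph.number_of_edges()} edges, "
      f"{len(cohort.interactome.seeds)} planted seeds")
# The distorted SNPs sit inside planted-DE gene windows, so the
# integrative stage downstream has a recoverable gene-SNP signal.
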