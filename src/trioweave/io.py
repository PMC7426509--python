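"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: counts as gene x sample TSV plus a sample->group TSV; trio panels
as a PED/FAM-like dosage TSV plus a VCF-style sites file; variant tables
as VCF 4.2 with the quality annotations in INFO (read back via pysam);
interactomes as 3-column edge TSVs; gene models as BED6; condensed
networks as JSON and GraphML.

VCF INFO floats are written with shortest round-trip formatting; the
synthetic generator quantizes them to binary fractions, so the trip
through htslib's float32 INFO storage is lossless.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pysam

from .counts import CountMatrix
from .network import MinimalNetwork, assemble_interactome
from .trio import TrioPanel

_INFO_FLOAT_KEYS = {
    "QD": "qd",
    "FS": "fs",
    "MQ": "mq",
    "HaplotypeScore": "haplotype_score",
    "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum",
    "AF": "af",
}


# ---------------------------------------------------------------------------
# Counts


def write_counts_tsv(matrix: CountMatrix, counts_path, groups_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.groups.rename_axis("sample_id").to_csv(groups_path, sep="\t")


def read_counts_tsv(counts_path, groups_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return CountMatrix(counts=counts, groups=groups)


# ---------------------------------------------------------------------------
# Trio panel: PED/FAM-like dosage TSV + sites file


def write_trio_panel(panel: TrioPanel, ped_path, sites_path) -> None:
    rows = []
    for role, geno in (("father", panel.father), ("mother", panel.mother), ("child", panel.child)):
        for i, fam in enumerate(panel.family_ids):
            rows.append([fam, f"{fam}_{role}", role, *geno[i]])
    ped = pd.DataFrame(rows, columns=["family_id", "individual_id", "role", *panel.snp_ids])
    ped.to_csv(ped_path, sep="\t", index=False)
    sites = pd.DataFrame(
        {"snp_id": panel.snp_ids, "chrom": panel.chrom, "pos": panel.pos}
    )
    sites.to_csv(sites_path, sep="\t", index=False)


def read_trio_panel(ped_path, sites_path) -> TrioPanel:
    ped = pd.read_csv(ped_path, sep="\t", dtype={"family_id": str})
    sites = pd.read_csv(sites_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    snp_ids = sites["snp_id"].to_numpy(dtype=object)
    fams = ped.loc[ped["role"] == "father", "family_id"].to_numpy(dtype=object)

    def _block(role: str) -> np.ndarray:
        block = ped[ped["role"] == role].set_index("family_id").loc[fams, snp_ids]
        return block.to_numpy(dtype=np.int8)

    return TrioPanel(
        family_ids=fams,
        snp_ids=snp_ids,
        chrom=sites["chrom"].to_numpy(dtype=object),
        pos=sites["pos"].to_numpy(dtype=np.int64),
        father=_block("father"),
        mother=_block("mother"),
        child=_block("child"),
    )


# ---------------------------------------------------------------------------
# Variants: VCF 4.2 dialect


_VCF_HEADER_INFO = """##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias Fisher p">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype consistency score">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank-sum Z">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank-sum Z">
##INFO=<ID=AF,Number=1,Type=Float,Description="Cohort alternate allele frequency">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total number of called alleles">
##INFO=<ID=EFF,Number=1,Type=String,Description="Effect annotation: term|class|gene">
"""


def write_variants_vcf(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(table["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(_VCF_HEADER_INFO)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in table.itertuples(index=False):
            info = []
            for key, col in _INFO_FLOAT_KEYS.items():
                val = getattr(row, col)
                if val is not None and not (isinstance(val, float) and np.isnan(val)):
                    info.append(f"{key}={repr(float(val))}")
            info.append(f"AN={int(row.an)}")
            info.append(f"EFF={row.effect_term}|{row.effect_class}|{row.gene_id}")
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.variant_id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t{';'.join(info)}\n"
            )


def read_variants_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            eff = info.get("EFF", "||")
            term, cls, gene = (eff.split("|") + ["", "", ""])[:3]
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "variant_id": rec.id,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "",
            }
            for key, col in _INFO_FLOAT_KEYS.items():
                if key == "AF":
                    val = info.get("AF")
                    if isinstance(val, tuple):
                        val = val[0]
                else:
                    val = info.get(key)
                row[col] = float(val) if val is not None else np.nan
            row["an"] = int(info.get("AN", 0))
            row["effect_term"] = term
            row["effect_class"] = cls
            row["gene_id"] = gene
            rows.append(row)
    return pd.DataFrame(rows)


def write_catalog_tsv(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "id": str})


# ---------------------------------------------------------------------------
# Interactome edge lists


def write_interactome_tsv(graph, path) -> None:
    rows = []
    for u, v, data in sorted(graph.edges(data=True)):
        for prov in sorted(data.get("provenance", set())):
            rows.append((u, v, prov))
    pd.DataFrame(rows, columns=["node_a", "node_b", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_interactome_tsv(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    by_prov = {"PPI": [], "TF": [], "PATHWAY": []}
    for row in df.itertuples(index=False):
        by_prov[row.provenance].append((row.node_a, row.node_b))
    return assemble_interactome(by_prov["PPI"], by_prov["TF"], by_prov["PATHWAY"])


# ---------------------------------------------------------------------------
# Minimal network


def write_network_json(minimal: MinimalNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(minimal.to_json_dict(), fh, indent=2, sort_keys=True)


def write_network_graphml(minimal: MinimalNetwork, path) -> None:
    import networkx as nx

    g = minimal.graph.copy()
    for u, v, data in g.edges(data=True):
        data["provenance"] = ",".join(sorted(data.get("provenance", set())))
    for n, data in g.nodes(data=True):
        data["role"] = "seed" if n in minimal.seeds else "connector"
    nx.write_graphml(g, path)
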