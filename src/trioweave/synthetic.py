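"""Synthetic cohort generator: every input the pipeline consumes.

The generator emulates the statistical structure the analysis assumes —
affected-child trios with a configurable fraction of SNPs under
transmission distortion, negative-binomial counts with planted
differentially expressed genes, annotated variant tables with a
known-variant catalog, and a scale-free interactome with planted seed
modules — all derived deterministically from one master seed.  Each stage
draws from an independent named substream (the stage name is hashed into
the seed sequence) so stages can be regenerated independently.

Ground truth (distorted SNP ids, DE gene ids, planted connectors) is
returned alongside every artifact, which is what makes recovery and
calibration tests possible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import networkx as nx
import numpy as np
import pandas as pd

from .counts import CountMatrix
from .genes import GeneModel
from .network import assemble_interactome
from .trio import MISSING, TrioPanel

_EFFECT_TERMS = {
    "LOW": ["synonymous_variant", "stop_retained_variant"],
    "MODERATE": ["missense_variant", "inframe_insertion", "inframe_deletion"],
    "HIGH": ["frameshift_variant", "splice_acceptor_variant", "stop_gained"],
}


class CohortConfigError(ValueError):
    """Raised when a cohort configuration is invalid."""


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: 36 affected-child trios, 6 vs 6
    expression samples, a 20 kb gene-window SNP layout, planted
    transmission distortion at tau = 0.75 inside DE-gene windows.
    """

    n_trios: int = 36
    n_snps: int = 5_000
    distorted_fraction: float = 0.05
    distortion_tau: float = 0.75
    maf_range: tuple = (0.1, 0.5)
    missing_rate: float = 0.02
    n_genes: int = 1_000
    n_samples_per_group: int = 6
    de_fraction: float = 0.05
    log2fc: float = 2.0
    nb_dispersion: float = 0.2
    base_mean: float = 100.0
    mean_log2_sd: float = 0.0
    n_variants: int = 500
    catalog_fraction: float = 0.5
    hard_filter_violation: float = 0.1
    missing_annotation_rate: float = 0.0
    interactome_nodes: int = 300
    attachment_m: int = 2
    n_seeds: int = 20
    n_connectors: int = 10
    planted_pair_fraction: float = 1.0
    window: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_trios": self.n_trios,
            "n_snps": self.n_snps,
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_variants": self.n_variants,
            "interactome_nodes": self.interactome_nodes,
            "attachment_m": self.attachment_m,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise CohortConfigError(f"{name} must be a positive integer, got {value!r}")
        proportions = {
            "distorted_fraction": self.distorted_fraction,
            "missing_rate": self.missing_rate,
            "de_fraction": self.de_fraction,
            "catalog_fraction": self.catalog_fraction,
            "hard_filter_violation": self.hard_filter_violation,
            "missing_annotation_rate": self.missing_annotation_rate,
            "planted_pair_fraction": self.planted_pair_fraction,
        }
        for name, value in proportions.items():
            if not np.isfinite(value) or not 0 <= value <= 1:
                raise CohortConfigError(f"{name} must be a proportion in [0, 1], got {value!r}")
        if not np.isfinite(self.distortion_tau) or not 0.5 <= self.distortion_tau <= 1:
            raise CohortConfigError("distortion_tau must lie in [0.5, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise CohortConfigError("maf_range must be an interval within (0, 0.5]")
        if not np.isfinite(self.nb_dispersion) or self.nb_dispersion < 0:
            raise CohortConfigError("nb_dispersion must be a non-negative real")
        if not np.isfinite(self.log2fc):
            raise CohortConfigError("log2fc must be finite")
        if self.interactome_nodes < self.attachment_m + 1:
            raise CohortConfigError("interactome_nodes must exceed attachment_m")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic substream for a named stage."""
        key = zlib.crc32(stage.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), key]))

    def replace(self, **kwargs) -> "CohortConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return CohortConfig(**current)


@dataclass
class TrioPanelSim:
    panel: TrioPanel
    distorted_snp_ids: list


@dataclass
class CountSim:
    matrix: CountMatrix
    de_gene_ids: list
    size_factors: pd.Series


@dataclass
class VariantSim:
    table: pd.DataFrame
    catalog: pd.DataFrame
    violation_truth: dict


@dataclass
class InteractomeSim:
    graph: nx.Graph
    seeds: list
    connectors: list


@dataclass
class SyntheticCohort:
    config: CohortConfig
    gene_models: list
    counts: CountSim
    trios: TrioPanelSim
    variants: VariantSim
    interactome: InteractomeSim


# ---------------------------------------------------------------------------


def gen_gene_models(config: CohortConfig) -> list[GeneModel]:
    """Deterministic gene layout: 10 kb genes spaced 100 kb apart on chr1.

    The spacing exceeds twice the SNP window, so gene windows never
    overlap and every SNP belongs to at most one gene.
    """
    width = max(4 * config.window + 20_000, 100_000)
    return [
        GeneModel(
            gene_id=f"GENE{i + 1:05d}",
            chrom="chr1",
            start=config.window + 30_000 + i * width,
            end=config.window + 40_000 + i * width,
        )
        for i in range(config.n_genes)
    ]


def _pick_de_genes(config: CohortConfig, gene_ids) -> list:
    n_de = int(np.ceil(config.de_fraction * len(gene_ids)))
    rng = config.rng("de_genes")
    return sorted(rng.choice(np.asarray(gene_ids, dtype=object), size=n_de, replace=False))


def gen_counts(config: CohortConfig, de_gene_ids=None) -> CountSim:
    """NB counts with planted DE genes and log-uniform size factors.

    counts_ij ~ NB(mean = s_j * mu_i, variance = mu + alpha mu^2); planted
    genes have the group-B mean multiplied by 2**log2fc.
    """
    rng = config.rng("counts")
    gene_ids = [g.gene_id for g in gen_gene_models(config)]
    if de_gene_ids is None:
        de_gene_ids = _pick_de_genes(config, gene_ids)
    de_set = set(de_gene_ids)
    n = config.n_samples_per_group
    sample_ids = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    groups = pd.Series(["A"] * n + ["B"] * n, index=sample_ids, name="group")
    s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=2 * n))
    if config.mean_log2_sd > 0:
        mu = config.base_mean * 2 ** rng.normal(0.0, config.mean_log2_sd, size=len(gene_ids))
    else:
        mu = np.full(len(gene_ids), config.base_mean)
    is_de = np.array([g in de_set for g in gene_ids])
    mean = np.outer(mu, s)
    mean[is_de, n:] *= 2.0**config.log2fc
    alpha = config.nb_dispersion
    if alpha < 1e-12:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, r / (r + mean))
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        groups=groups,
    )
    return CountSim(
        matrix=matrix,
        de_gene_ids=list(de_gene_ids),
        size_factors=pd.Series(s, index=sample_ids, name="size_factor"),
    )


def gen_trio_panel(
    config: CohortConfig,
    gene_models: list[GeneModel] | None = None,
    distort_in_windows_of=None,
) -> TrioPanelSim:
    """Trio genotypes under Hardy-Weinberg parents and Mendelian children.

    Parental genotypes are drawn per SNP at HW proportions with MAF
    uniform in ``maf_range``; each child allele is a fair draw from its
    parent, except at the designated distorted SNPs where a heterozygous
    parent transmits the minor allele with probability ``distortion_tau``.
    When ``distort_in_windows_of`` names genes, distorted SNPs are placed
    inside those genes' windows (the planted gene-SNP alignment the
    integrative stage is meant to recover).
    """
    rng = config.rng("trios")
    T, S = config.n_trios, config.n_snps
    if gene_models is None:
        gene_models = gen_gene_models(config)
    # round-robin SNP placement over gene windows keeps per-gene SNP counts even
    gene_idx = np.arange(S) % len(gene_models)
    pos = np.empty(S, dtype=np.int64)
    for i, g in enumerate(gene_models):
        mask = gene_idx == i
        lo, hi = g.window(config.window)
        pos[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    snp_ids = np.array([f"rs{i + 1:06d}" for i in range(S)], dtype=object)
    chrom = np.array([gene_models[i].chrom for i in gene_idx], dtype=object)

    n_dist = int(np.ceil(config.distorted_fraction * S))
    if distort_in_windows_of:
        # spread distortion evenly over the target genes' windows (each
        # target gene carries an associated block), topping up from the
        # background only if the windows run out of SNPs
        wanted = {g for g in distort_in_windows_of}
        per_gene = [
            list(rng.permutation(np.flatnonzero((gene_idx == i))))
            for i, g in enumerate(gene_models)
            if g.gene_id in wanted
        ]
        picked: list = []
        layer = 0
        while len(picked) < n_dist and any(len(p) > layer for p in per_gene):
            for p in per_gene:
                if layer < len(p) and len(picked) < n_dist:
                    picked.append(p[layer])
            layer += 1
        if len(picked) < n_dist:
            rest = np.setdiff1d(np.arange(S), np.array(picked, dtype=int))
            picked.extend(rng.choice(rest, size=n_dist - len(picked), replace=False))
        distorted_idx = np.array(sorted(picked), dtype=int)
    else:
        distorted_idx = np.sort(rng.choice(np.arange(S), size=n_dist, replace=False))
    tau = np.full(S, 0.5)
    tau[distorted_idx] = config.distortion_tau

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=S)
    father = (rng.random((T, S)) < maf).astype(np.int8) + (rng.random((T, S)) < maf).astype(np.int8)
    mother = (rng.random((T, S)) < maf).astype(np.int8) + (rng.random((T, S)) < maf).astype(np.int8)

    def _transmit(parent: np.ndarray) -> np.ndarray:
        het_draw = (rng.random((T, S)) < tau[None, :]).astype(np.int8)
        return np.where(parent == 1, het_draw, (parent // 2).astype(np.int8))

    child = _transmit(father) + _transmit(mother)

    if config.missing_rate > 0:
        for arr in (father, mother, child):
            arr[rng.random((T, S)) < config.missing_rate] = MISSING

    panel = TrioPanel(
        family_ids=np.array([f"FAM{i + 1:04d}" for i in range(T)], dtype=object),
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        father=father,
        mother=mother,
        child=child,
    )
    return TrioPanelSim(panel=panel, distorted_snp_ids=list(snp_ids[distorted_idx]))


def _quantize(x: np.ndarray, step: float) -> np.ndarray:
    # binary-fraction grid => lossless through float32 VCF INFO storage
    return np.round(x / step) * step


def gen_variant_table(
    config: CohortConfig, gene_models: list[GeneModel] | None = None
) -> VariantSim:
    """Annotated variant records plus a known-variant catalog.

    Quality annotations are drawn from pass/fail mixtures so that a
    ``hard_filter_violation`` fraction of records violates each hard
    filter, with a safety margin around every threshold so quantization
    never flips a pass/fail.  Values are quantized to binary fractions
    (1/32 for qualities, 1/1024 for AF) so the VCF round-trip through
    float32 INFO storage is exact.
    """
    rng = config.rng("variants")
    if gene_models is None:
        gene_models = gen_gene_models(config)
    V = config.n_variants
    gene_idx = rng.integers(0, len(gene_models), size=V)
    pos0 = np.empty(V, dtype=np.int64)
    for i, g in enumerate(gene_models):
        mask = gene_idx == i
        if mask.any():
            lo, hi = g.window(config.window)
            pos0[mask] = rng.integers(lo, hi, size=int(mask.sum()))
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = rng.choice(bases, size=V)
    alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref], dtype=object)

    frac = config.hard_filter_violation
    ranges = {  # (good_lo, good_hi, bad_lo, bad_hi); margins clear the 1/32 grid
        "qd": (2.1, 40.0, 0.0, 1.9),
        "fs": (0.0, 59.9, 60.1, 200.0),
        "mq": (40.1, 60.0, 0.0, 39.9),
        "haplotype_score": (0.0, 12.9, 13.1, 50.0),
        "mq_rank_sum": (-12.4, 12.5, -30.0, -12.6),
        "read_pos_rank_sum": (-7.9, 8.0, -20.0, -8.1),
    }
    quals = {}
    violation_truth = {}
    for key, (glo, ghi, blo, bhi) in ranges.items():
        bad = rng.random(V) < frac
        vals = np.where(bad, rng.uniform(blo, bhi, size=V), rng.uniform(glo, ghi, size=V))
        vals = _quantize(vals, 1 / 32)
        if config.missing_annotation_rate > 0:
            vals = np.where(rng.random(V) < config.missing_annotation_rate, np.nan, vals)
        quals[key] = vals
        violation_truth[key] = int(bad.sum())

    af = np.clip(_quantize(rng.uniform(0, 1, size=V), 1 / 1024), 0.0, 1.0)
    an = 2 * rng.integers(1, config.n_trios + 1, size=V)
    cls = rng.choice(["LOW", "MODERATE", "HIGH"], size=V, p=[0.4, 0.4, 0.2])
    term = np.array([_EFFECT_TERMS[c][rng.integers(0, len(_EFFECT_TERMS[c]))] for c in cls], dtype=object)

    table = pd.DataFrame(
        {
            "chrom": [gene_models[i].chrom for i in gene_idx],
            "pos": pos0 + 1,  # 1-based in the VCF dialect
            "variant_id": [f"var{i + 1:06d}" for i in range(V)],
            "ref": ref,
            "alt": alt,
            **quals,
            "af": af,
            "an": an,
            "effect_term": term,
            "effect_class": cls,
            "gene_id": [gene_models[i].gene_id for i in gene_idx],
        }
    )
    n_cat = int(round(config.catalog_fraction * V))
    cat_idx = np.sort(rng.choice(V, size=n_cat, replace=False))
    catalog = table.iloc[cat_idx][["chrom", "pos", "ref", "alt"]].copy()
    catalog["id"] = [f"rsdb{i + 1:06d}" for i in range(n_cat)]
    return VariantSim(table=table, catalog=catalog.reset_index(drop=True), violation_truth=violation_truth)


def gen_interactome(
    config: CohortConfig, node_ids=None, seed_candidates=None
) -> InteractomeSim:
    """Scale-free background graph with a planted seed-connector module.

    The preferential-attachment background spans the non-seed nodes only;
    seed genes attach exclusively through the module structure, so the
    planted ground truth is exact: ``n_seeds`` seeds are split round-robin
    over ``n_connectors`` designated connector nodes and a
    ``planted_pair_fraction`` of them gets an edge to its connector
    (seeds sharing a connector sit at distance 2 through it).  Unplanted
    seeds hang off a private background node instead, so every distance-2
    seed pair passes through a designated connector.
    """
    rng = config.rng("interactome")
    if node_ids is None:
        node_ids = [g.gene_id for g in gen_gene_models(config)][: config.interactome_nodes]
        if len(node_ids) < config.interactome_nodes:
            node_ids += [f"NODE{i:05d}" for i in range(config.interactome_nodes - len(node_ids))]
    pool = list(seed_candidates) if seed_candidates is not None else list(node_ids)
    n_seeds = min(config.n_seeds, len(pool), len(node_ids) - config.attachment_m - 1)
    seeds = sorted(rng.choice(np.asarray(pool, dtype=object), size=n_seeds, replace=False))
    bg_nodes = [v for v in node_ids if v not in set(seeds)]
    bg = nx.barabasi_albert_graph(
        len(bg_nodes), config.attachment_m, seed=int(rng.integers(0, 2**31 - 1))
    )
    order = list(rng.permutation(len(bg_nodes)))
    bg = nx.relabel_nodes(bg, {i: bg_nodes[order[i]] for i in range(len(bg_nodes))})

    n_conn = max(1, min(config.n_connectors, n_seeds // 2, len(bg_nodes)))
    connectors = sorted(rng.choice(np.asarray(bg_nodes, dtype=object), size=n_conn, replace=False))

    n_attached = int(np.ceil(config.planted_pair_fraction * n_seeds))
    planted_edges = [(s, connectors[j % n_conn]) for j, s in enumerate(seeds[:n_attached])]
    # unplanted seeds get one private anchor each so they stay connected
    # without creating seed-seed distance-2 paths outside the module
    anchors = [v for v in bg_nodes if v not in set(connectors)]
    anchor_pick = rng.choice(
        np.asarray(anchors, dtype=object), size=len(seeds[n_attached:]), replace=False
    )
    planted_edges += [(s, a) for s, a in zip(seeds[n_attached:], anchor_pick)]

    prov_names = ["PPI", "TF", "PATHWAY"]
    provs = rng.choice(prov_names, size=bg.number_of_edges(), p=[0.6, 0.2, 0.2])
    by_prov: dict = {p: [] for p in prov_names}
    for (u, v), p in zip(sorted(bg.edges()), provs):
        by_prov[p].append((u, v))
    by_prov["PPI"].extend(planted_edges)
    graph = assemble_interactome(by_prov["PPI"], by_prov["TF"], by_prov["PATHWAY"])
    return InteractomeSim(graph=graph, seeds=list(seeds), connectors=list(connectors))


def gen_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full, mutually consistent synthetic cohort.

    DE genes are planted first; distorted SNPs are placed inside those
    genes' windows; the interactome is built over the gene namespace with
    seeds drawn from the planted DE genes, so every downstream stage has a
    recoverable signal.
    """
    gene_models = gen_gene_models(config)
    gene_ids = [g.gene_id for g in gene_models]
    de_ids = _pick_de_genes(config, gene_ids)
    counts = gen_counts(config, de_gene_ids=de_ids)
    trios = gen_trio_panel(config, gene_models=gene_models, distort_in_windows_of=de_ids)
    variants = gen_variant_table(config, gene_models=gene_models)
    interactome = gen_interactome(config, node_ids=gene_ids, seed_candidates=de_ids)
    return SyntheticCohort(
        config=config,
        gene_models=gene_models,
        counts=counts,
        trios=trios,
        variants=variants,
        interactome=interactome,
    )


def gen_annotation(
    config: CohortConfig,
    gene_ids=None,
    enriched_in=None,
    n_terms: int = 50,
    term_size_range: tuple = (10, 50),
):
    """Synthetic term->gene annotation with one planted enriched term.

    Random terms draw genes uniformly; if ``enriched_in`` names a gene set
    (e.g. the planted DE genes), a dedicated term containing that set is
    added so over-representation tests have a recoverable positive.
    Returns {term_id: gene set} suitable for ``AnnotationMap``.
    """
    rng = config.rng("annotation")
    if gene_ids is None:
        gene_ids = [g.gene_id for g in gen_gene_models(config)]
    gene_arr = np.asarray(gene_ids, dtype=object)
    lo, hi = term_size_range
    terms = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"TERM{t + 1:04d}"] = set(rng.choice(gene_arr, size=min(size, len(gene_arr)), replace=False))
    if enriched_in:
        terms["TERM_PLANTED"] = set(enriched_in)
    return terms


def duplicate_snp(panel: TrioPanel, snp_id: str, new_id: str) -> TrioPanel:
    """Append an exact copy of a SNP column under a new id (r^2 = 1 helper
    for LD-pruning tests)."""
    i = panel.snp_index(snp_id)
    return TrioPanel(
        family_ids=panel.family_ids,
        snp_ids=np.append(panel.snp_ids, new_id),
        chrom=np.append(panel.chrom, panel.chrom[i]),
        pos=np.append(panel.pos, panel.pos[i]),
        father=np.hstack([panel.father, panel.father[:, i : i + 1]]),
        mother=np.hstack([panel.mother, panel.mother[:, i : i + 1]]),
        child=np.hstack([panel.child, panel.child[:, i : i + 1]]),
    )
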