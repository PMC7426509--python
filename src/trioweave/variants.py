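"""Variant screening cascades for targeted and exome sequencing.

Variant tables are pandas DataFrames with one row per variant and the
columns ``chrom, pos (1-based), variant_id, ref, alt, qd, fs, mq,
haplotype_score, mq_rank_sum, read_pos_rank_sum, af, an, effect_term,
effect_class, gene_id``; annotation columns may hold NaN for absent values.

The cascade mirrors a GATK-style hard-filter stage followed by
catalog-based novelty classification, a cohort commonness filter
(AF > 0.4 and AN > 10), and a predicted-effect-class filter.  All
thresholds are strict inequalities and every removal is recorded with its
reason so the ledger balances: |input| = |retained| + sum(removals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import GeneModel

QUALITY_KEYS = ("qd", "fs", "mq", "haplotype_score", "mq_rank_sum", "read_pos_rank_sum")

#: Mapping from annotation effect terms to coarse effect classes.  Editable:
#: pass a custom mapping to :func:`classify_effect`.
EFFECT_CLASS_MAP = {
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "frameshift_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "synonymous_variant": "LOW",
    "stop_retained_variant": "LOW",
    "intron_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
}


@dataclass
class HardFilterThresholds:
    """GATK-style hard-filter cutoffs; a record fails on any violation."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    haplotype_score_max: float = 13.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0


def apply_hard_filters(
    variants: pd.DataFrame, thresholds: HardFilterThresholds | None = None
) -> pd.DataFrame:
    """Annotate each variant with hard-filter pass/fail and failure reasons.

    A record fails iff any *present* annotation violates its threshold
    (QD < min, FS > max, MQ < min, HaplotypeScore > max, rank sums < min);
    absent (NaN) annotations never fail a record.  Adds boolean column
    ``hard_filter_pass`` and string column ``hard_filter_reasons``.
    """
    t = thresholds or HardFilterThresholds()
    out = variants.copy()
    checks = {
        "QD": out["qd"] < t.qd_min,
        "FS": out["fs"] > t.fs_max,
        "MQ": out["mq"] < t.mq_min,
        "HaplotypeScore": out["haplotype_score"] > t.haplotype_score_max,
        "MQRankSum": out["mq_rank_sum"] < t.mq_rank_sum_min,
        "ReadPosRankSum": out["read_pos_rank_sum"] < t.read_pos_rank_sum_min,
    }
    reasons = []
    for i in range(len(out)):
        why = [name for name, mask in checks.items() if bool(mask.iloc[i])]
        reasons.append(",".join(why))
    out["hard_filter_reasons"] = reasons
    out["hard_filter_pass"] = out["hard_filter_reasons"] == ""
    return out


def classify_novelty(variants: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Flag variants as known/novel against a known-variant catalog.

    Membership is allele-specific: known iff the exact
    (chrom, pos, ref, alt) tuple appears in the catalog.
    """
    out = variants.copy()
    if len(catalog):
        keys = set(zip(catalog["chrom"], catalog["pos"], catalog["ref"], catalog["alt"]))
    else:
        keys = set()
    out["novel"] = [
        (c, p, r, a) not in keys
        for c, p, r, a in zip(out["chrom"], out["pos"], out["ref"], out["alt"])
    ]
    return out


def commonness_filter(
    variants: pd.DataFrame, af_min: float = 0.4, an_min: int = 10
) -> pd.DataFrame:
    """Retain highly common variants: AF > af_min AND AN > an_min, strict."""
    keep = (variants["af"] > af_min) & (variants["an"] > an_min)
    return variants[keep].copy()


def classify_effect(terms, mapping: dict | None = None) -> list[str]:
    """Map annotation effect terms to {LOW, MODERATE, HIGH, MODIFIER}."""
    mapping = mapping if mapping is not None else EFFECT_CLASS_MAP
    out = []
    for term in terms:
        cls = mapping.get(term)
        if cls is None:
            warnings.warn(f"unmapped effect term {term!r}; classified MODIFIER", stacklevel=2)
            cls = "MODIFIER"
        out.append(cls)
    return out


def effect_class_filter(variants: pd.DataFrame, keep=("MODERATE", "HIGH")) -> pd.DataFrame:
    """Retain variants whose effect class is in ``keep``.

    If ``effect_class`` is absent it is derived from ``effect_term`` via
    the shipped mapping table.
    """
    out = variants.copy()
    if "effect_class" not in out.columns or out["effect_class"].isna().any():
        out["effect_class"] = classify_effect(out["effect_term"])
    return out[out["effect_class"].isin(set(keep))].copy()


def intersect_known_associated(variants: pd.DataFrame, assoc_ids) -> pd.DataFrame:
    """Retain variants whose id appears in a known-associated SNP list."""
    ids = set(assoc_ids)
    return variants[variants["variant_id"].isin(ids)].copy()


def count_novel_by_gene(
    variants: pd.DataFrame, genes: list[GeneModel], window: int = 20_000
) -> pd.DataFrame:
    """Per-gene counts of novel, highly common variants near each gene.

    A variant counts toward every gene whose windowed interval
    [start - window, end + window] contains its position (overlapping
    windows are legal and flagged in the ``multi_gene`` column of the
    returned per-variant assignment).  Gene intervals are 0-based
    half-open; variant positions are 1-based, so position p corresponds to
    0-based coordinate p - 1.
    """
    novel = variants[variants.get("novel", pd.Series(True, index=variants.index))].copy()
    counts = {g.gene_id: 0 for g in genes}
    hits_per_variant = np.zeros(len(novel), dtype=int)
    for g in genes:
        lo, hi = g.start - window, g.end + window
        pos0 = novel["pos"].to_numpy() - 1
        mask = (novel["chrom"].to_numpy() == g.chrom) & (pos0 >= lo) & (pos0 <= hi)
        counts[g.gene_id] = int(mask.sum())
        hits_per_variant += mask.astype(int)
    table = pd.DataFrame(
        {"gene_id": list(counts), "n_novel_common": list(counts.values())}
    )
    table.attrs["n_multi_gene_variants"] = int((hits_per_variant > 1).sum())
    return table


def run_cascade(
    variants: pd.DataFrame,
    catalog: pd.DataFrame,
    thresholds: HardFilterThresholds | None = None,
    af_min: float = 0.4,
    an_min: int = 10,
    effect_keep=("MODERATE", "HIGH"),
    require_novel: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full screening cascade with a conservation ledger.

    Stages: hard filters -> novelty (optional removal of known variants) ->
    commonness (AF/AN) -> effect class.  Returns (retained, ledger) where
    the ledger rows count removals per stage and satisfy
    |input| = |retained| + sum(removed).
    """
    ledger_rows = []
    current = apply_hard_filters(variants, thresholds)
    n0 = len(current)
    passed = current[current["hard_filter_pass"]].copy()
    ledger_rows.append({"stage": "hard_filter", "removed": n0 - len(passed)})

    passed = classify_novelty(passed, catalog)
    if require_novel:
        n_before = len(passed)
        passed = passed[passed["novel"]].copy()
        ledger_rows.append({"stage": "known_in_catalog", "removed": n_before - len(passed)})

    n_before = len(passed)
    passed = commonness_filter(passed, af_min=af_min, an_min=an_min)
    ledger_rows.append({"stage": "commonness", "removed": n_before - len(passed)})

    n_before = len(passed)
    passed = effect_class_filter(passed, keep=effect_keep)
    ledger_rows.append({"stage": "effect_class", "removed": n_before - len(passed)})

    ledger = pd.DataFrame(ledger_rows)
    assert len(variants) == len(passed) + ledger["removed"].sum()
    return passed.reset_index(drop=True), ledger
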