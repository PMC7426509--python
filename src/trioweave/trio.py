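"""Trio genetics: QC, transmission disequilibrium testing, and the
permutation set-based gene test.

Genotypes are coded as minor-allele dosage {0, 1, 2}; missing is -1.  All
per-SNP operations are vectorised over a (families x SNPs) layout.

The gene-level test follows the classic set-based recipe: run the TDT at
every SNP in a gene's window, greedily keep up to ``max_reps``
LD-independent representatives (decreasing chi-square, per-SNP entry
p-value threshold, pairwise r-squared pruning), average their chi-square
statistics, and calibrate that average by permutation.  Each permutation
draws one Rademacher sign per family and flips that family's
transmitted/untransmitted contributions at all SNPs simultaneously, which
preserves inter-SNP LD within the set; representatives are re-selected
inside every permutation so the selection optimism is part of the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genes import GeneModel

MISSING = -1


class TrioPanelError(ValueError):
    """Raised on invalid trio-panel construction or operations."""


@dataclass
class TrioPanel:
    """Father/mother/affected-child genotype dosages over a SNP map.

    ``father``, ``mother``, ``child`` are (n_families, n_snps) int8 arrays
    of minor-allele dosages with -1 for missing.
    """

    family_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    father: np.ndarray
    mother: np.ndarray
    child: np.ndarray

    def __post_init__(self) -> None:
        self.family_ids = np.asarray(self.family_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        shape = (len(self.family_ids), len(self.snp_ids))
        for name in ("father", "mother", "child"):
            arr = np.asarray(getattr(self, name), dtype=np.int8)
            if arr.shape != shape:
                raise TrioPanelError(f"{name} genotypes have shape {arr.shape}, expected {shape}")
            bad = (arr < MISSING) | (arr > 2)
            if bad.any():
                raise TrioPanelError(f"{name} contains dosages outside {{-1, 0, 1, 2}}")
            setattr(self, name, arr)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise TrioPanelError("snp ids must be unique")
        if (self.pos < 0).any():
            raise TrioPanelError("positions must be non-negative")

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise TrioPanelError(f"unknown SNP id {snp_id!r}")
        return int(idx[0])

    def founders(self) -> np.ndarray:
        """Founder (parental) dosages stacked as (2 * n_families, n_snps)."""
        return np.vstack([self.father, self.mother])

    def subset_snps(self, mask: np.ndarray) -> "TrioPanel":
        return TrioPanel(
            family_ids=self.family_ids,
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            father=self.father[:, mask],
            mother=self.mother[:, mask],
            child=self.child[:, mask],
        )

    def subset_families(self, mask: np.ndarray) -> "TrioPanel":
        return TrioPanel(
            family_ids=self.family_ids[mask],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            father=self.father[mask],
            mother=self.mother[mask],
            child=self.child[mask],
        )


@dataclass
class QcThresholds:
    max_missing: float = 0.10
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    max_snp_mendel: float = 0.10
    max_family_mendel: float = 0.05


@dataclass
class QcReport:
    families_dropped: pd.DataFrame
    snps_dropped: pd.DataFrame
    genotypes_masked: int


@dataclass
class TdtResult:
    snp_id: str
    b: int
    c: int
    chi2: float
    p_value: float
    n_informative: int
    uninformative: bool = False


@dataclass
class SetTestResult:
    gene_id: str
    representative_snp_ids: list[str]
    observed_stat: float
    empirical_p: float
    n_perm: int
    empty_selection: bool = False


# ---------------------------------------------------------------------------
# Mendelian consistency


def _consistency_masks(panel: TrioPanel):
    """Complete-trio and Mendel-consistent masks, (families x SNPs)."""
    f, m, c = panel.father, panel.mother, panel.child
    complete = (f != MISSING) & (m != MISSING) & (c != MISSING)
    # A parent with dosage 0 can only transmit the major allele, dosage 2
    # only the minor, dosage 1 either: the child dosage must fall in
    # [#(parents hom minor), #(parents carrying a minor allele)].
    lo = (f == 2).astype(np.int8) + (m == 2).astype(np.int8)
    hi = (f >= 1).astype(np.int8) + (m >= 1).astype(np.int8)
    consistent = complete & (c >= lo) & (c <= hi)
    return complete, consistent


def mendel_errors(panel: TrioPanel) -> tuple[pd.Series, pd.Series]:
    """Per-SNP and per-family Mendelian error rates.

    A trio genotype at a SNP is an error iff the child's alleles cannot be
    drawn one from each parent; trios with any missing member at that SNP
    are excluded from the denominator.
    """
    complete, consistent = _consistency_masks(panel)
    errors = complete & ~consistent
    with np.errstate(invalid="ignore"):
        snp_rate = np.where(
            complete.sum(axis=0) > 0, errors.sum(axis=0) / np.maximum(complete.sum(axis=0), 1), 0.0
        )
        fam_rate = np.where(
            complete.sum(axis=1) > 0, errors.sum(axis=1) / np.maximum(complete.sum(axis=1), 1), 0.0
        )
    return (
        pd.Series(snp_rate, index=panel.snp_ids, name="mendel_rate"),
        pd.Series(fam_rate, index=panel.family_ids, name="mendel_rate"),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities of outcomes no more probable than the
    observed one.  Monomorphic samples give p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise TrioPanelError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise TrioPanelError("at least one genotyped individual required")
    n_a = 2 * n_aa + n_Aa  # minor allele count
    n_A = 2 * n_AA + n_Aa
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = (2 * n - rare - hets) // 2
    # P(het = h | allele counts) via the standard conditional distribution
    logp = (
        gammaln(n + 1)
        - gammaln(homs_rare + 1)
        - gammaln(hets + 1)
        - gammaln(homs_common + 1)
        + hets * np.log(2)
        - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC cascade


def founder_genotype_counts(panel: TrioPanel) -> np.ndarray:
    """(n_snps, 3) counts of founder dosages 0/1/2, missing excluded."""
    founders = panel.founders()
    out = np.empty((panel.n_snps, 3), dtype=np.int64)
    for dose in (0, 1, 2):
        out[:, dose] = (founders == dose).sum(axis=0)
    return out


def founder_maf(panel: TrioPanel) -> np.ndarray:
    counts = founder_genotype_counts(panel)
    called = counts.sum(axis=1)
    minor = counts[:, 1] + 2 * counts[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, minor / (2 * np.maximum(called, 1)), 0.0)
    return np.minimum(freq, 1 - freq)


def qc_filter(panel: TrioPanel, thresholds: QcThresholds | None = None) -> tuple[TrioPanel, QcReport]:
    """Standard trio QC cascade.

    Order: (1) drop families whose Mendelian error rate exceeds
    ``max_family_mendel``; (2) on the remaining families drop SNPs failing
    missingness, founder MAF, founder HWE, or per-SNP Mendel-rate checks;
    (3) mask any remaining Mendel-inconsistent trio genotypes to missing
    (all three members, since the error cannot be attributed).  Every
    exclusion is listed with its reason(s).
    """
    thresholds = thresholds or QcThresholds()
    _, fam_rates = mendel_errors(panel)
    fam_keep = fam_rates.to_numpy() <= thresholds.max_family_mendel
    families_dropped = pd.DataFrame(
        {
            "family_id": panel.family_ids[~fam_keep],
            "mendel_rate": fam_rates.to_numpy()[~fam_keep],
            "reason": "family_mendel",
        }
    )
    if not fam_keep.any():
        raise TrioPanelError("QC excluded every family")
    panel = panel.subset_families(fam_keep)

    n_ind = 3 * panel.n_families
    missing = (
        (panel.father == MISSING).sum(axis=0)
        + (panel.mother == MISSING).sum(axis=0)
        + (panel.child == MISSING).sum(axis=0)
    ) / n_ind
    maf = founder_maf(panel)
    geno = founder_genotype_counts(panel)
    hwe_p = np.array(
        [hwe_exact_p(int(a), int(h), int(b)) if (a + h + b) > 0 else 1.0 for a, h, b in geno]
    )
    snp_rates, _ = mendel_errors(panel)
    snp_rates = snp_rates.to_numpy()

    reasons = []
    for i in range(panel.n_snps):
        why = []
        if missing[i] > thresholds.max_missing:
            why.append("missingness")
        if maf[i] < thresholds.min_maf:
            why.append("maf")
        if hwe_p[i] < thresholds.hwe_alpha:
            why.append("hwe")
        if snp_rates[i] > thresholds.max_snp_mendel:
            why.append("snp_mendel")
        reasons.append(",".join(why))
    reasons = np.array(reasons, dtype=object)
    snp_keep = reasons == ""
    snps_dropped = pd.DataFrame(
        {"snp_id": panel.snp_ids[~snp_keep], "reason": reasons[~snp_keep]}
    )
    panel = panel.subset_snps(snp_keep)

    complete, consistent = _consistency_masks(panel)
    bad = complete & ~consistent
    n_masked = int(bad.sum())
    if n_masked:
        father = panel.father.copy()
        mother = panel.mother.copy()
        child = panel.child.copy()
        father[bad] = MISSING
        mother[bad] = MISSING
        child[bad] = MISSING
        panel = TrioPanel(
            family_ids=panel.family_ids,
            snp_ids=panel.snp_ids,
            chrom=panel.chrom,
            pos=panel.pos,
            father=father,
            mother=mother,
            child=child,
        )
    return panel, QcReport(families_dropped, snps_dropped, n_masked)


# ---------------------------------------------------------------------------
# TDT


def transmission_counts(panel: TrioPanel) -> tuple[np.ndarray, np.ndarray]:
    """Per-family transmitted (b) / untransmitted (c) minor-allele counts.

    Returns (B, C), each (n_families, n_snps).  Only complete,
    Mendel-consistent trios with at least one heterozygous parent
    contribute; a hom x hom mating is uninformative.
    """
    f, m, c = panel.father, panel.mother, panel.child
    _, consistent = _consistency_masks(panel)
    B = np.zeros(f.shape, dtype=np.int16)
    C = np.zeros(f.shape, dtype=np.int16)

    # One heterozygous parent, one homozygous: the hom parent's contribution
    # is fixed (0 or 1 minor alleles), so the het parent transmitted
    # child_dosage - hom_contribution.
    for het, hom in ((f, m), (m, f)):
        mask = consistent & (het == 1) & ((hom == 0) | (hom == 2))
        t = c - (hom // 2)  # 1 = minor transmitted, 0 = major
        B += (mask & (t == 1)).astype(np.int16)
        C += (mask & (t == 0)).astype(np.int16)

    both = consistent & (f == 1) & (m == 1)
    B += np.where(both, np.where(c == 2, 2, np.where(c == 1, 1, 0)), 0).astype(np.int16)
    C += np.where(both, np.where(c == 0, 2, np.where(c == 1, 1, 0)), 0).astype(np.int16)
    return B, C


def _chi2_p(b: np.ndarray, c: np.ndarray):
    denom = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, (b - c) ** 2 / np.maximum(denom, 1), 0.0)
    p = np.where(denom > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def tdt(panel: TrioPanel, snp_id: str) -> TdtResult:
    """Transmission disequilibrium test at one SNP.

    b counts heterozygous-parent transmissions of the minor allele, c the
    non-transmissions; chi2 = (b - c)^2 / (b + c) with a chi-square(1)
    p-value.  No informative transmissions gives chi2 = 0, p = 1.
    """
    i = panel.snp_index(snp_id)
    B, C = transmission_counts(panel)
    b = int(B[:, i].sum())
    c = int(C[:, i].sum())
    n_informative = int(((B[:, i] + C[:, i]) > 0).sum())
    chi2, p = _chi2_p(np.array([b], dtype=float), np.array([c], dtype=float))
    return TdtResult(
        snp_id=snp_id,
        b=b,
        c=c,
        chi2=float(chi2[0]),
        p_value=float(p[0]),
        n_informative=n_informative,
        uninformative=(b + c) == 0,
    )


def tdt_all(panel: TrioPanel) -> pd.DataFrame:
    """TDT at every SNP, vectorised; columns snp_id, b, c, chi2, p_value."""
    B, C = transmission_counts(panel)
    b = B.sum(axis=0).astype(float)
    c = C.sum(axis=0).astype(float)
    chi2, p = _chi2_p(b, c)
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "b": b.astype(int),
            "c": c.astype(int),
            "chi2": chi2,
            "p_value": p,
            "n_informative": ((B + C) > 0).sum(axis=0),
        }
    )


# ---------------------------------------------------------------------------
# LD


def _pairwise_r2(founders: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Founder-dosage r^2 matrix over the SNP indices ``idx``.

    Pairwise-complete; monomorphic or <2 complete pairs yield 0.
    """
    k = len(idx)
    out = np.zeros((k, k))
    cols = [founders[:, j].astype(float) for j in idx]
    masks = [col != MISSING for col in cols]
    for a in range(k):
        for b_i in range(a + 1, k):
            ok = masks[a] & masks[b_i]
            if ok.sum() < 2:
                continue
            x, y = cols[a][ok], cols[b_i][ok]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            out[a, b_i] = out[b_i, a] = r * r
    np.fill_diagonal(out, 1.0)
    return out


def ld_r2(panel: TrioPanel, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of founder dosages at two SNPs.

    Pairwise-complete over founders; a monomorphic SNP gives 0 by
    convention (with a warning).
    """
    ia, ib = panel.snp_index(snp_a), panel.snp_index(snp_b)
    founders = panel.founders()
    x = founders[:, ia].astype(float)
    y = founders[:, ib].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise TrioPanelError("fewer than 2 complete founder pairs")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        warnings.warn(f"monomorphic SNP in r^2({snp_a}, {snp_b}); returning 0", stacklevel=2)
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Gene windows


def snps_near_gene(gene: GeneModel, panel: TrioPanel, window: int = 20_000) -> list[str]:
    """SNP ids within ``window`` bases of the gene body, bounds inclusive."""
    lo = gene.start - window
    hi = gene.end + window
    mask = (panel.chrom == gene.chrom) & (panel.pos >= lo) & (panel.pos <= hi)
    return list(panel.snp_ids[mask])


# ---------------------------------------------------------------------------
# Set-based test


def _greedy_select(
    chi2_row: np.ndarray,
    informative: np.ndarray,
    r2: np.ndarray,
    chi2_enter: float,
    prune_r2: float,
    max_reps: int,
) -> list[int]:
    order = np.argsort(-chi2_row, kind="stable")
    selected: list[int] = []
    for j in order:
        if len(selected) >= max_reps:
            break
        if not informative[j] or chi2_row[j] <= chi2_enter:
            continue
        if any(r2[j, s] >= prune_r2 for s in selected):
            continue
        selected.append(int(j))
    return selected


def set_based_test(
    panel: TrioPanel,
    snp_ids,
    gene_id: str = "",
    max_reps: int = 5,
    prune_r2: float = 0.5,
    snp_p_enter: float = 0.05,
    n_perm: int = 10_000,
    seed=0,
    reselect_per_perm: bool = True,
) -> SetTestResult:
    """Permutation-calibrated gene-level statistic over a SNP set.

    The observed statistic is the mean chi-square of the greedily selected
    representatives.  Each permutation flips, per family, the
    transmitted/untransmitted roles at all SNPs jointly (one Rademacher
    sign per family), then re-runs selection and averaging.  The empirical
    p-value uses the add-one estimator and can therefore never be exactly
    zero.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise TrioPanelError("empty SNP set")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for an empirical p-value", stacklevel=2)
    idx = np.array([panel.snp_index(s) for s in snp_ids])
    B, C = transmission_counts(panel)
    B, C = B[:, idx].astype(np.int64), C[:, idx].astype(np.int64)
    tot_b, tot_c = B.sum(axis=0), C.sum(axis=0)
    denom = (tot_b + tot_c).astype(float)
    informative = denom > 0
    diff0 = (tot_b - tot_c).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2_obs = np.where(informative, diff0**2 / np.maximum(denom, 1.0), 0.0)
    r2 = _pairwise_r2(panel.founders(), idx)
    chi2_enter = float(stats.chi2.isf(snp_p_enter, df=1))

    sel = _greedy_select(chi2_obs, informative, r2, chi2_enter, prune_r2, max_reps)
    observed_stat = float(np.mean(chi2_obs[sel])) if sel else 0.0

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, panel.n_families))
    D = (B - C).astype(float)
    diffs = diff0[None, :] - 2.0 * (flips @ D)  # (n_perm, S); b+c is flip-invariant
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2_perm = np.where(informative[None, :], diffs**2 / np.maximum(denom, 1.0)[None, :], 0.0)

    if reselect_per_perm:
        perm_stats = np.empty(n_perm)
        for t in range(n_perm):
            s = _greedy_select(chi2_perm[t], informative, r2, chi2_enter, prune_r2, max_reps)
            perm_stats[t] = np.mean(chi2_perm[t, s]) if s else 0.0
    else:
        perm_stats = chi2_perm[:, sel].mean(axis=1) if sel else np.zeros(n_perm)

    if not sel:
        empirical_p = 1.0
    else:
        empirical_p = (1 + int((perm_stats >= observed_stat).sum())) / (1 + n_perm)
    return SetTestResult(
        gene_id=gene_id,
        representative_snp_ids=[snp_ids[j] for j in sel],
        observed_stat=observed_stat,
        empirical_p=float(empirical_p),
        n_perm=n_perm,
        empty_selection=not sel,
    )


# ---------------------------------------------------------------------------
# Integration with differential expression


def integrate(
    de_results: pd.DataFrame,
    panel: TrioPanel,
    genes: list[GeneModel],
    window: int = 20_000,
    de_p: float = 0.05,
    set_alpha: float = 0.05,
    max_reps: int = 5,
    prune_r2: float = 0.5,
    snp_p_enter: float = 0.05,
    n_perm: int = 10_000,
    seed=0,
) -> pd.DataFrame:
    """Pair differentially expressed genes with nearby trio-associated SNPs.

    Genes with a raw DE p-value below ``de_p`` are windowed for SNPs, each
    window is run through the set-based test, and genes with an empirical
    p-value strictly below ``set_alpha`` are reported sorted by that
    p-value — the "gene + associated SNPs" table of the integrative stage.
    """
    candidates = set(de_results.loc[de_results["p_value"] < de_p, "gene_id"])
    if not candidates:
        warnings.warn("no DE candidate genes at the raw-p threshold", stacklevel=2)
    gene_by_id = {g.gene_id: g for g in genes}
    cand_genes = sorted(candidates & set(gene_by_id))
    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(len(cand_genes))
    rows = []
    for gid, sub_seed in zip(cand_genes, child_seeds):
        snps = snps_near_gene(gene_by_id[gid], panel, window=window)
        if not snps:
            continue
        res = set_based_test(
            panel,
            snps,
            gene_id=gid,
            max_reps=max_reps,
            prune_r2=prune_r2,
            snp_p_enter=snp_p_enter,
            n_perm=n_perm,
            seed=sub_seed,
        )
        rows.append(
            {
                "gene_id": gid,
                "empirical_p": res.empirical_p,
                "observed_stat": res.observed_stat,
                "representative_snp_ids": ",".join(res.representative_snp_ids),
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "empirical_p", "observed_stat", "representative_snp_ids"])
    table = table[table["empirical_p"] < set_alpha]
    return table.sort_values(["empirical_p", "gene_id"], kind="stable").reset_index(drop=True)
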