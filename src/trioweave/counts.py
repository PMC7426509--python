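"""Differential expression on bulk RNA count matrices.

The stage mirrors a classic bulk workflow: drop the lowest-total genes,
normalise with median-of-ratios size factors, test each gene with a
method-of-moments negative-binomial Wald statistic, and control FDR with
Benjamini-Hochberg.  This is a deliberately simplified, fully specified
substitute for DESeq's dispersion-shrinkage machinery: dispersions are
method-of-moments estimates, not fitted, so users should treat it as a
transparent screening test rather than a drop-in DESeq replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class CountMatrixError(ValueError):
    """Raised on invalid count-matrix construction or operations."""


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with a two-group design.

    ``counts`` is indexed by gene id with sample ids as columns; ``groups``
    maps every sample id to a label in {"A", "B"}.
    """

    counts: pd.DataFrame
    groups: pd.Series
    low_count_filtered: pd.Index = field(default_factory=lambda: pd.Index([], name="gene_id"))

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise CountMatrixError("empty count matrix")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise CountMatrixError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CountMatrixError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise CountMatrixError("gene ids must be unique")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise CountMatrixError("every sample needs a group label")
        labels = set(self.groups.unique())
        if not labels <= {"A", "B"} or len(labels) < 2:
            raise CountMatrixError("groups must contain both labels A and B")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, label: str) -> pd.Index:
        return self.groups.index[self.groups == label]


def filter_low_counts(matrix: CountMatrix, quantile: float = 0.4) -> CountMatrix:
    """Remove the ``floor(quantile * G)`` genes with the smallest count totals.

    Ties are broken by gene id ascending (removed first).  Removed ids are
    kept on the returned matrix (``low_count_filtered``) so reports can list
    them rather than silently dropping genes.
    """
    if not 0 <= quantile < 1:
        raise CountMatrixError(f"quantile must be in [0, 1), got {quantile}")
    totals = matrix.counts.sum(axis=1)
    n_remove = int(np.floor(quantile * len(totals)))
    order = totals.reset_index()
    order.columns = ["gene_id", "total"]
    order = order.sort_values(["total", "gene_id"], kind="stable")
    removed = pd.Index(order["gene_id"].iloc[:n_remove], name="gene_id")
    kept = matrix.counts.drop(index=removed)
    return CountMatrix(counts=kept, groups=matrix.groups, low_count_filtered=removed)


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios normalisation factors.

    s_j = median over genes i (with positive counts in every sample) of
    k_ij / geometric_mean_i.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise CountMatrixError(
            "no gene has all-positive counts; consider adding a pseudocount "
            "before computing size factors"
        )
    sub = counts[all_positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise CountMatrixError("NaN p-value passed to BH adjustment")
    if (p < 0).any() or (p > 1).any():
        raise CountMatrixError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def nb_de_test(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    dispersion_mode: str = "blind",
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald-style test between groups A and B.

    Normalised counts q_ij = k_ij / s_j.  The per-gene dispersion is the
    method-of-moments estimate alpha_i = max(0, (var - mean) / mean^2).
    In ``blind`` mode it is pooled across all samples regardless of group
    (appropriate when a design has no replicates; conservative when a real
    group effect exists, since the effect inflates the pooled variance).
    In ``per_group`` mode gene-wise df-weighted within-group estimates are
    floored at their across-gene median — sharing dispersion information
    across genes keeps null genes calibrated while leaving true effects
    detectable.  The statistic is

        T_i = (mu_B - mu_A) / sqrt(V_A / n_A + V_B / n_B),
        V_g = mu_g + alpha_i * mu_g^2,

    with a two-sided p-value from the standard normal.  The fold change uses
    a 0.5 pseudocount (fold change only — never the statistic):
    log2((mu_B + 0.5) / (mu_A + 0.5)).

    Returns a DataFrame with columns gene_id, log2_fold_change, statistic,
    p_value, q_value, filtered_low_count, all_zero.
    """
    if dispersion_mode not in ("blind", "per_group"):
        raise CountMatrixError(f"unknown dispersion_mode {dispersion_mode!r}")
    if factors is None:
        factors = size_factors(matrix)
    factors = factors.reindex(matrix.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise CountMatrixError("size factors must be positive for every sample")
    in_a = (matrix.groups == "A").to_numpy()
    in_b = (matrix.groups == "B").to_numpy()
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    if n_a < 2 or n_b < 2:
        raise CountMatrixError("need at least 2 samples per group for a variance estimate")

    q = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()
    mu_a = q[:, in_a].mean(axis=1)
    mu_b = q[:, in_b].mean(axis=1)

    def _mom_alpha(block: np.ndarray) -> np.ndarray:
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        return np.where(m > 0, np.maximum(a, 0.0), 0.0)

    if dispersion_mode == "blind":
        alpha = _mom_alpha(q)
    else:
        gene_wise = ((n_a - 1) * _mom_alpha(q[:, in_a]) + (n_b - 1) * _mom_alpha(q[:, in_b])) / (
            n_a + n_b - 2
        )
        alpha = np.maximum(gene_wise, np.median(gene_wise))

    var_a = mu_a + alpha * mu_a**2
    var_b = mu_b + alpha * mu_b**2
    se = np.sqrt(var_a / n_a + var_b / n_b)
    all_zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mu_b - mu_a) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.where(all_zero, 1.0, p)
    t = np.where(all_zero, 0.0, t)
    lfc = np.log2((mu_b + 0.5) / (mu_a + 0.5))

    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "log2_fold_change": lfc,
            "statistic": t,
            "p_value": p,
            "q_value": adjust_bh(p),
            "filtered_low_count": False,
            "all_zero": all_zero,
        }
    ).reset_index(drop=True)


def de_gene_lists(results: pd.DataFrame, alpha_bh: float = 0.1, alpha_raw: float = 0.05):
    """Split DE results into the two threshold tiers used downstream.

    ``significant``: BH q < alpha_bh.  ``candidate``: raw p < alpha_raw —
    the looser list that feeds the integrative trio stage.
    """
    significant = results.loc[results["q_value"] < alpha_bh, "gene_id"].tolist()
    candidate = results.loc[results["p_value"] < alpha_raw, "gene_id"].tolist()
    return significant, candidate
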