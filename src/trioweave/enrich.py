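"""Over-representation statistics for gene sets.

Two flavours are provided: the plain upper-tail hypergeometric test with
Benjamini-Hochberg correction (the usual GO over-representation test),
and the EASE score — a conservative, jackknifed variant of the one-sided
Fisher exact test in which one gene is removed from the overlap cell
before computing the tail.  With N genes in the universe, K annotated to
the term, n in the query and k in the overlap:

    hypergeometric  p = P(X >= k),            X ~ Hypergeom(N, K, n)
    EASE            p = Fisher one-sided p of the 2x2 table with the
                        overlap cell replaced by max(k - 1, 0)

so EASE p >= Fisher p always, and k <= 1 gives p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .counts import adjust_bh


class EnrichmentError(ValueError):
    """Raised on invalid annotation maps or queries."""


@dataclass
class AnnotationMap:
    """term id -> annotated gene set, over a gene universe.

    By default the universe is the union of all annotated genes; pass an
    explicit ``universe`` to widen it (e.g. to all assayed genes).
    """

    terms: dict
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.terms = {t: set(g) for t, g in self.terms.items()}
        if any(not g for g in self.terms.values()):
            raise EnrichmentError("terms must annotate at least one gene")
        annotated = set().union(*self.terms.values()) if self.terms else set()
        if not self.universe:
            self.universe = annotated
        elif not annotated <= self.universe:
            raise EnrichmentError("every annotated gene must belong to the universe")
        if not self.universe:
            raise EnrichmentError("empty universe")

    @classmethod
    def from_table(cls, df: pd.DataFrame, universe=None) -> "AnnotationMap":
        terms: dict = {}
        for term, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
            terms.setdefault(term, set()).add(gene)
        return cls(terms=terms, universe=set(universe) if universe is not None else set())


def _clean_query(query, annot: AnnotationMap) -> set:
    query = set(query)
    outside = query - annot.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped", stacklevel=3
        )
    return query & annot.universe


def _result_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "expected", "p_value"])
    if len(df):
        df["q_value"] = adjust_bh(df["p_value"].to_numpy())
    else:
        df["q_value"] = []
    return df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)


def hypergeom_enrich(query, annot: AnnotationMap) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term, BH-corrected.

    Terms with zero overlap are skipped.  Results are deterministic in
    term order (sorted by p, then term id).
    """
    query = _clean_query(query, annot)
    N = len(annot.universe)
    n = len(query)
    rows = []
    for term in sorted(annot.terms):
        genes = annot.terms[term]
        k = len(query & genes)
        if k == 0:
            continue
        K = len(genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, n * K / N, min(p, 1.0)))
    return _result_frame(rows)


def ease_enrich(query, annot: AnnotationMap) -> pd.DataFrame:
    """EASE-score enrichment per term, BH-corrected.

    One-sided Fisher exact p on the 2x2 table (query vs rest x in-term vs
    not) with the overlap cell jackknifed to max(k - 1, 0); overlaps of 0
    or 1 give p = 1.
    """
    query = _clean_query(query, annot)
    N = len(annot.universe)
    n = len(query)
    rows = []
    for term in sorted(annot.terms):
        genes = annot.terms[term]
        k = len(query & genes)
        if k == 0:
            continue
        K = len(genes)
        if k <= 1:
            p = 1.0
        else:
            table = [[k - 1, K - k], [n - k, N - K - n + k]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append((term, k, K, n, N, n * K / N, min(p, 1.0)))
    return _result_frame(rows)
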