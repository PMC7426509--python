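"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (enumeration, exact
combinatorics) and deliberately shares no code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, factorial

MISSING = -1


def tdt_oracle_trio(f: int, m: int, c: int) -> tuple[int, int] | None:
    """Brute-force transmission counts for one trio at one SNP.

    Enumerates every assignment of one transmitted allele per parent that
    is consistent with the child's dosage; counts minor-allele
    transmissions (b) and non-transmissions (c) from heterozygous parents.
    Returns None for incomplete, Mendel-inconsistent, or uninformative
    (no het parent) trios.
    """
    if MISSING in (f, m, c):
        return None
    alleles = {0: [0], 1: [0, 1], 2: [1]}
    outcomes = set()
    for af in alleles[f]:
        for am in alleles[m]:
            if af + am != c:
                continue
            b = ct = 0
            if f == 1:
                b += af
                ct += 1 - af
            if m == 1:
                b += am
                ct += 1 - am
            outcomes.add((b, ct))
    if not outcomes:
        return None  # Mendel error
    assert len(outcomes) == 1, "transmission counts must be assignment-invariant"
    b, ct = outcomes.pop()
    if b + ct == 0:
        return None  # no heterozygous parent
    return b, ct


def tdt_oracle_snp(fathers, mothers, children) -> tuple[int, int]:
    """Total (b, c) at one SNP by independent per-trio enumeration."""
    b_tot = c_tot = 0
    for f, m, c in zip(fathers, mothers, children):
        out = tdt_oracle_trio(int(f), int(m), int(c))
        if out is not None:
            b_tot += out[0]
            c_tot += out[1]
    return b_tot, c_tot


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration with rational arithmetic.

    P(h heterozygotes | allele counts) = n! / (n_rr! h! n_cc!) * 2^h /
    (2n)! * n_rare! * n_common!, summed over all h with the observed
    probability or less.
    """
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    common = 2 * n - rare

    def prob(h: int) -> Fraction:
        n_rr = (rare - h) // 2
        n_cc = (common - h) // 2
        return (
            Fraction(factorial(n), factorial(n_rr) * factorial(h) * factorial(n_cc))
            * Fraction(2**h)
            * Fraction(factorial(rare) * factorial(common), factorial(2 * n))
        )

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    assert sum(probs.values()) == 1
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hypergeom_upper_tail_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws."""
    universe = range(N)
    in_term = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(in_term.intersection(draw)) >= k:
            hits += 1
    return hits / total


def ease_oracle(N: int, K: int, n: int, k: int) -> float:
    """EASE p by enumeration on the jackknifed table.

    Removing one overlap gene reduces every margin by one: draw n-1 from
    N-1 with K-1 in the term and require overlap >= k-1.
    """
    if k <= 1:
        return 1.0
    return hypergeom_upper_tail_oracle(N - 1, K - 1, n - 1, k - 1)


def min_set_cover_size(pairs: list, candidates: dict) -> int | None:
    """Exhaustive minimum number of connectors covering all pairs.

    ``candidates`` maps connector -> set of seeds it touches; a connector
    covers a pair when it touches both endpoints.  Returns None when no
    cover exists.
    """
    names = sorted(candidates)
    coverable = [
        p for p in pairs if any(p[0] in candidates[c] and p[1] in candidates[c] for c in names)
    ]
    if not coverable:
        return 0
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            covered = {
                p
                for p in coverable
                for c in combo
                if p[0] in candidates[c] and p[1] in candidates[c]
            }
            if len(covered) == len(coverable):
                return size
    return None


def bh_oracle(pvals):
    """Hand step-up BH: q_(i) = min_{j >= i} min(1, p_(j) * m / j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [min(1.0, pvals[order[i]] * m / (i + 1)) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out


def size_factor_oracle(counts):
    """Median-of-ratios by direct loops (genes x samples list of lists)."""
    import math
    import statistics

    usable = [row for row in counts if all(v > 0 for v in row)]
    n_samp = len(counts[0])
    factors = []
    for j in range(n_samp):
        ratios = []
        for row in usable:
            geo = math.exp(sum(math.log(v) for v in row) / n_samp)
            ratios.append(row[j] / geo)
        factors.append(statistics.median(ratios))
    return factors


def comb_exact(n: int, k: int) -> int:
    return comb(n, k)
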