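"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: hexamer counting by
slicing every 6-mer, Fisher p-values by exhaustive hypergeometric
enumeration over all tables with fixed margins, and rank-sum p-values by
enumerating every assignment of ranks to groups.
"""

from __future__ import annotations

import itertools
from math import comb

HEXAMERS = ("AATAAA", "ATTAAA")


def brute_count_awtaaa(sequence: str) -> int:
    return sum(
        1 for i in range(len(sequence) - 5) if sequence[i : i + 6] in HEXAMERS
    )


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities.

    Enumerates every 2x2 table with the observed margins; the p-value is
    the total probability of tables no more probable than the observed
    one (with the customary 1e-7 relative tolerance for float ties).
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def ranksum_exact_enumeration(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Tie-free inputs only.  Computes the null distribution of the
    Mann-Whitney U statistic over all C(n+m, n) assignments and returns
    2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    all_ranks = list(range(1, n + m + 1))
    for combo in itertools.combinations(all_ranks, n):
        us.append(sum(combo) - n * (n + 1) / 2)
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def brute_map_variants(variant_positions, site_positions, flank):
    """All (variant, site) index pairs with |pos - cs| <= flank, per chrom."""
    pairs = []
    for vi, (vchrom, vpos) in enumerate(variant_positions):
        for si, (schrom, spos) in enumerate(site_positions):
            if vchrom == schrom and abs(vpos - spos) <= flank:
                pairs.append((vi, si))
    return sorted(pairs)
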