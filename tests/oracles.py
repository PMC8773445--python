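"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through a different route than the
package (exact rational arithmetic, per-site python loops) so that agreement
is informative.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact two-sided Hardy-Weinberg p by full rational enumeration.

    Conditional on the allele counts, P(het = h) is proportional to
    ``2**h * n! / (n_rr! h! n_aa!)``; the p-value sums the probabilities of
    every heterozygote configuration no more probable than the observed one.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_alt + n_het  # alt-allele count
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return Fraction(1)

    def weight(h: int) -> Fraction:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        return Fraction(2**h) * Fraction(
            comb(n, h) * comb(n - h, rare_hom)
        )  # multinomial n! / (h! rare_hom! common_hom!) times 2^h

    hs = list(range(n_rare % 2, n_rare + 1, 2))
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    p_obs = weights[n_het]
    return sum(w for w in weights.values() if w <= p_obs) / total


def site_agreement_oracle(
    h: np.ndarray, strict_missing: bool
) -> tuple[list[bool], list[bool]]:
    """Per-site agreement flags via python set logic (independent route)."""
    k, m = h.shape
    agree, full = [], []
    for j in range(m):
        observed = [int(x) for x in h[:, j] if x != MISSING]
        values = set(observed)
        is_full = len(observed) == k and len(values) == 1
        if strict_missing:
            agree.append(is_full)
        else:
            agree.append(len(values) <= 1)
        full.append(is_full)
    return agree, full


def scan_oracle(
    hm, member_rows, strict_missing: bool = False
) -> list[tuple[str, int, int, int]]:
    """All distinct maximal shared segments as (chrom, start_bp, end_bp, n_snps).

    Walks every site, grows the surrounding run by per-site rechecking, and
    trims each run to its outermost fully matching SNPs.
    """
    rows = np.asarray(member_rows)
    out = []
    chroms = hm.variants["chrom"].to_numpy()
    pos_all = hm.variants["pos"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        h = hm.haplotypes[np.ix_(rows, idx)]
        agree, full = site_agreement_oracle(h, strict_missing)
        pos = pos_all[idx]
        j = 0
        m = len(idx)
        while j < m:
            if not agree[j]:
                j += 1
                continue
            end = j
            while end + 1 < m and agree[end + 1]:
                end += 1
            full_sites = [x for x in range(j, end + 1) if full[x]]
            if full_sites:
                out.append(
                    (
                        chrom,
                        int(pos[full_sites[0]]),
                        int(pos[full_sites[-1]]),
                        len(full_sites),
                    )
                )
            j = end + 1
    return out


def focal_oracle(
    hm, member_rows, focal_global_idx: int, strict_missing: bool = False
) -> tuple[str, int, int, int] | None:
    """The oracle segment containing a focal variant index, if any."""
    chrom = hm.variants["chrom"].iloc[focal_global_idx]
    focal_pos = int(hm.variants["pos"].iloc[focal_global_idx])
    for seg in scan_oracle(hm, member_rows, strict_missing):
        if seg[0] == chrom and seg[1] <= focal_pos <= seg[2]:
            return seg
    return None
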