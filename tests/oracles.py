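"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a verdict from first principles (exact rational
arithmetic, exhaustive enumeration, O(n^2) distance scans) without touching
the implementation path it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np

TIE_NUM = 10**7  # tie tolerance 1e-7, as exact rational (1 + 1/TIE_NUM)


def fisher_two_sided_rational(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational: sum of hypergeometric point
    probabilities at most the observed one (ties within rel. 1e-7 included,
    evaluated in exact integer arithmetic)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    a_min, a_max = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(a_min, a_max + 1)]
    obs = nums[a - a_min]
    total = sum(num for num in nums if num * TIE_NUM <= obs * (TIE_NUM + 1))
    return Fraction(total, comb(n, c1))


def fisher_one_sided_rational(a: int, b: int, c: int, d: int) -> Fraction:
    """Upper-tail exact p: P(A >= a) at fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    a_max = min(r1, c1)
    total = sum(comb(r1, k) * comb(r2, c1 - k) for k in range(a, a_max + 1))
    return Fraction(total, comb(n, c1))


def quality_verdict_bruteforce(dp, gq, ad, min_depth=20, min_gq=30, min_vaf=0.2) -> bool:
    """One-line re-statement of the three-clause quality rule."""
    vaf = None if (ad is None or dp is None or dp <= 0) else ad[1] / dp
    return not (
        (dp is not None and dp < min_depth)
        or (gq is not None and gq < min_gq)
        or (vaf is not None and vaf < min_vaf)
    )


def recessive_candidates_bruteforce(variant_genes, genotype_matrix, affected):
    """Exhaustive recessive classification over all (gene, variant-subset)
    combinations.

    ``variant_genes``: {vk: gene}; ``genotype_matrix``: {vk: {sample:
    (a0, a1) or None}}.  Returns (hom_keys: set, comphet: {gene:
    frozenset_of_keys}).  A subset of >= 2 variants in one gene is a
    compound-het support set iff each member is heterozygous in every
    affected; the candidate's variant set is the union of all such subsets.
    """
    hom = set()
    for vk in variant_genes:
        gts = [genotype_matrix[vk].get(s) for s in affected]
        if any(g is None for g in gts):
            continue
        if all(sorted(g) == [1, 1] for g in gts):
            hom.add(vk)
    comphet = {}
    genes = set(variant_genes.values())
    for gene in genes:
        keys = [k for k, g in variant_genes.items() if g == gene]
        support = set()
        for r in range(2, len(keys) + 1):
            for subset in itertools.combinations(keys, r):
                ok = all(
                    genotype_matrix[vk].get(s) is not None
                    and sorted(genotype_matrix[vk][s]) == [0, 1]
                    for vk in subset
                    for s in affected
                )
                if ok:
                    support.update(subset)
        if support:
            comphet[gene] = frozenset(support)
    return hom, comphet


def cosegregation_bruteforce(model, variant_keys, genotypes, affected, unaffected, parents):
    """Direct truth-table evaluation of cosegregation over all members.

    ``genotypes``: {sample: {vk: (a0, a1) or absent}}.  Homozygous model:
    every typed affected hom-alt and no typed unaffected hom-alt.
    Compound-het: some variant pair carried by all typed affecteds, by no
    unaffected typed at both sites, with a cross-parent assignment when both
    parents are typed at both sites.
    """

    def carries(sid, vk):
        g = genotypes.get(sid, {}).get(vk)
        return None if g is None else (sum(g) >= 1)

    def hom_alt(sid, vk):
        g = genotypes.get(sid, {}).get(vk)
        return None if g is None else (sorted(g) == [1, 1])

    if model == "homozygous":
        (vk,) = variant_keys
        for s in affected:
            if hom_alt(s, vk) is False:
                return False
        for s in unaffected:
            if hom_alt(s, vk) is True:
                return False
        return True

    for v1, v2 in itertools.combinations(variant_keys, 2):
        ok = True
        for s in affected:
            if carries(s, v1) is False or carries(s, v2) is False:
                ok = False
                break
        if not ok:
            continue
        for s in unaffected:
            if carries(s, v1) is True and carries(s, v2) is True:
                ok = False
                break
        if not ok:
            continue
        typed = [p for p in parents if carries(p, v1) is not None and carries(p, v2) is not None]
        if len(typed) >= 2:
            p1, p2 = typed[:2]
            if not (
                (carries(p1, v1) and carries(p2, v2))
                or (carries(p1, v2) and carries(p2, v1))
            ):
                continue
        return True
    return False


def count_cross_chain_polar_bruteforce(chains, cutoff=3.5):
    """O(n^2) scan: cross-chain N/O atom pairs within cutoff.

    ``chains``: list of (elements, coords) pairs.
    """
    total = 0
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            ei, ci = chains[i]
            ej, cj = chains[j]
            for e1, x1 in zip(ei, ci):
                if str(e1).upper() not in ("N", "O"):
                    continue
                for e2, x2 in zip(ej, cj):
                    if str(e2).upper() not in ("N", "O"):
                        continue
                    if np.linalg.norm(np.asarray(x1) - np.asarray(x2)) <= cutoff:
                        total += 1
    return total


def burial_bruteforce(chains, ca_positions, radius=10.0, max_neighbors=10):
    """All-pairs distance count of foreign heavy atoms around each C-term CA.

    ``chains``: list of (elements, coords); ``ca_positions``: list of the
    C-terminal CA coordinate per chain.  Returns per-chain exposure booleans.
    """
    out = []
    for i, ca in enumerate(ca_positions):
        count = 0
        for j, (elems, coords) in enumerate(chains):
            if j == i:
                continue
            for e, x in zip(elems, coords):
                if str(e).upper() == "H":
                    continue
                if np.linalg.norm(np.asarray(x) - np.asarray(ca)) <= radius:
                    count += 1
        out.append(count <= max_neighbors)
    return out
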