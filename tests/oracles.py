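"""Independent brute-force oracles for cross-checking the library.

Every function here is written directly from the published definition of
the statistic, using plain loops and fractions of counts — deliberately
sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter


def oracle_gene_diversity(copies: list[int]) -> float:
    """Nei unbiased gene diversity from a flat list of gene copies."""
    N = len(copies)
    counts = Counter(copies)
    sum_p2 = 0.0
    for allele in counts:
        sum_p2 += (counts[allele] / N) ** 2
    return (N / (N - 1)) * (1 - sum_p2)


def oracle_allelic_richness_exhaustive(copies: list[int], g: int) -> float:
    """Expected distinct alleles in a g-subsample, by full enumeration."""
    total = 0
    n_subsets = 0
    for subset in itertools.combinations(range(len(copies)), g):
        total += len({copies[i] for i in subset})
        n_subsets += 1
    return total / n_subsets


def oracle_haplotype_diversity(seqs: list[str]) -> float:
    n = len(seqs)
    counts = Counter(seqs)
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    return (n / (n - 1)) * (1 - sum_p2)


def oracle_nucleotide_diversity(seqs: list[str]) -> float:
    """Mean pairwise proportion of differing sites (pairwise deletion)."""
    props = []
    for s1, s2 in itertools.combinations(seqs, 2):
        diffs = valid = 0
        for c1, c2 in zip(s1, s2):
            if c1 in "ACGT" and c2 in "ACGT":
                valid += 1
                if c1 != c2:
                    diffs += 1
        if valid:
            props.append(diffs / valid)
    return sum(props) / len(props)


def oracle_weir_cockerham(
    pops: list[list[tuple[int, int]]]
) -> tuple[float | None, float | None]:
    """(f, theta) from the 1984 per-allele variance components.

    *pops*: female genotypes per population.  Components a, b, c are
    computed for every allele at the locus and summed; f = 1 − Σc/Σ(b+c),
    θ = Σa/Σ(a+b+c) (θ None for a single population).
    """
    pops = [p for p in pops if p]
    r = len(pops)
    if r == 0:
        return None, None
    alleles = sorted({a for pop in pops for geno in pop for a in geno})
    n_i = [len(pop) for pop in pops]
    nbar = sum(n_i) / r
    if nbar <= 1:
        return None, None
    if r > 1:
        nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
    SA = SB = SC = 0.0
    for allele in alleles:
        p_i = []
        h_i = []
        for pop in pops:
            n = len(pop)
            count = sum(geno.count(allele) for geno in pop)
            het = sum(1 for geno in pop if geno.count(allele) == 1)
            p_i.append(count / (2 * n))
            h_i.append(het / n)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        if r > 1:
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
            a = (nbar / nc) * (
                s2
                - 1.0
                / (nbar - 1)
                * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        else:
            a = 0.0
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        c = hbar / 2
        SA += a
        SB += b
        SC += c
    f = 1 - SC / (SB + SC) if (SB + SC) != 0 else None
    theta = SA / (SA + SB + SC) if r > 1 and (SA + SB + SC) != 0 else None
    return f, theta


def oracle_allele_tally(
    genotypes: dict[str, list[tuple[int, ...]]]
) -> dict[str, Counter]:
    """Group -> allele Counter, from explicit per-group genotype lists."""
    out: dict[str, Counter] = {}
    for group, genos in genotypes.items():
        c: Counter = Counter()
        for geno in genos:
            for allele in geno:
                c[allele] += 1
        out[group] = c
    return out
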