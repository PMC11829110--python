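"""Microsatellite and mtDNA diversity and differentiation statistics.

Haplodiploid sample filtering is built into every contract: statistics that
depend on heterozygote frequencies (H_O, F_IS, F_ST, the Hardy–Weinberg
deficit test) use only diploid females, while allele-frequency indices
(allele counts, Nei gene diversity, rarefied allelic richness) use all gene
copies — two per female, one per haploid male — unless told otherwise.

F-statistics follow the Weir & Cockerham (1984) variance-component
estimators: per allele and per locus the components are

    a  — among populations,
    b  — among individuals within populations,
    c  — within individuals (heterozygosity),

and multi-locus estimates are ratios of summed components
(f = 1 − Σc/Σ(b+c), θ = Σa/Σ(a+b+c)), never means of per-locus ratios.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import HaplotypeAlignment, MicrosatDataset, SampleMeta

_UNAMBIGUOUS = frozenset("ACGT")


class StatsError(ValueError):
    pass


class UndefinedStatistic(StatsError):
    """A statistic whose preconditions are not met (flagged, never zero)."""


# ---------------------------------------------------------------------------
# unit selection helpers
# ---------------------------------------------------------------------------


def _unit_samples(dataset: MicrosatDataset, unit: str) -> list[SampleMeta]:
    """Samples of a named unit (a population label or a group label)."""
    samples = dataset.select(population=unit)
    if not samples:
        samples = dataset.select(group=unit)
    if not samples:
        raise StatsError(f"no samples in unit {unit!r}")
    return samples


def _female_genotypes(
    dataset: MicrosatDataset, unit: str, locus: str
) -> list[tuple[int, int]]:
    out = []
    for s in _unit_samples(dataset, unit):
        if s.sex != "female":
            continue
        call = dataset.get_call(s.sample_id, locus)
        if call is not None:
            out.append((call[0], call[1]))
    return out


# ---------------------------------------------------------------------------
# microsatellite diversity
# ---------------------------------------------------------------------------


def heterozygosity(
    dataset: MicrosatDataset, population: str, locus: str
) -> tuple[float, float]:
    """(H_O, H_E) for females of one unit at one locus.

    H_O is the fraction of heterozygous females; H_E is the unbiased
    expected heterozygosity (2n/(2n−1))(1 − Σp_i²) over female gene copies.
    """
    genos = _female_genotypes(dataset, population, locus)
    n = len(genos)
    if n == 0:
        raise UndefinedStatistic(
            f"H_O/H_E undefined: no females with data at {locus!r} in {population!r}"
        )
    h_o = sum(1 for a, b in genos if a != b) / n
    copies = Counter()
    for a, b in genos:
        copies.update((a, b))
    total = 2 * n
    sum_p2 = sum((c / total) ** 2 for c in copies.values())
    h_e = 0.0 if total < 2 else (total / (total - 1)) * (1.0 - sum_p2)
    return h_o, h_e


def gene_diversity(dataset: MicrosatDataset, unit: str, locus: str) -> float:
    """Nei unbiased gene diversity (N/(N−1))(1 − Σp²) on all gene copies."""
    copies = dataset.gene_copies(_unit_samples(dataset, unit), locus)
    N = len(copies)
    if N < 2:
        raise UndefinedStatistic(
            f"gene diversity undefined: {N} gene copies at {locus!r} in {unit!r}"
        )
    counts = Counter(copies)
    sum_p2 = sum((c / N) ** 2 for c in counts.values())
    return (N / (N - 1)) * (1.0 - sum_p2)


def allele_count(dataset: MicrosatDataset, unit: str, locus: str) -> int:
    copies = dataset.gene_copies(_unit_samples(dataset, unit), locus)
    return len(set(copies))


def allelic_richness(
    dataset: MicrosatDataset, unit: str, locus: str, g: int
) -> float:
    """Rarefied allelic richness at subsample size *g* gene copies.

    R_g = Σ_a [1 − C(N−N_a, g) / C(N, g)]: the expected number of distinct
    alleles in a random draw of g of the unit's N gene copies.
    """
    copies = dataset.gene_copies(_unit_samples(dataset, unit), locus)
    N = len(copies)
    if g < 1:
        raise StatsError("rarefaction size g must be >= 1")
    if g > N:
        raise StatsError(f"rarefaction size g={g} exceeds gene copies N={N}")
    counts = Counter(copies)
    denom = math.comb(N, g)
    return float(
        sum(1.0 - math.comb(N - na, g) / denom for na in counts.values())
    )


def default_rarefaction_size(
    dataset: MicrosatDataset, units: Sequence[str], locus: str
) -> int:
    """Smallest per-unit gene-copy count among compared units (FSTAT convention)."""
    sizes = [
        len(dataset.gene_copies(_unit_samples(dataset, unit), locus))
        for unit in units
    ]
    g = min(sizes)
    if g < 1:
        raise StatsError(f"a compared unit has no gene copies at {locus!r}")
    return g


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics
# ---------------------------------------------------------------------------


@dataclass
class FStatResult:
    populations: list[str]
    loci: list[str]
    f_per_locus: dict[str, float | None]
    theta_per_locus: dict[str, float | None]
    f_overall: float | None
    theta_overall: float | None
    components: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def _wc_components(
    genos_by_pop: list[list[tuple[int, int]]]
) -> tuple[float, float, float] | None:
    """Summed (a, b, c) variance components over alleles for one locus.

    *genos_by_pop* holds female genotypes per population (populations with
    no data already dropped).  Returns None when undefined (fewer than two
    gene copies, or every population a single individual with r == 1).
    """
    r = len(genos_by_pop)
    ns = np.array([len(g) for g in genos_by_pop], dtype=float)
    if r == 0 or ns.sum() == 0:
        return None
    alleles = sorted({x for pop in genos_by_pop for g in pop for x in g})
    if len(alleles) < 2:
        return (0.0, 0.0, 0.0)  # monomorphic: contributes nothing to the sums

    nbar = ns.mean()
    if r > 1:
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    else:
        nc = nbar
    if nbar <= 1:
        return None

    A = B = C = 0.0
    for allele in alleles:
        p_i = np.array(
            [
                sum((a == allele) + (b == allele) for a, b in pop) / (2 * len(pop))
                for pop in genos_by_pop
            ]
        )
        h_i = np.array(
            [
                sum(1 for a, b in pop if (a == allele) != (b == allele)) / len(pop)
                for pop in genos_by_pop
            ]
        )
        pbar = float((ns * p_i).sum() / (r * nbar))
        hbar = float((ns * h_i).sum() / (r * nbar))
        if r > 1:
            s2 = float((ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar))
        else:
            s2 = 0.0
        rr = (r - 1) / r if r > 1 else 0.0
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - rr * s2 - hbar / 4.0)
        ) if r > 1 else 0.0
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - rr * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        A += a
        B += b
        C += c
    return (A, B, C)


def weir_cockerham(
    dataset: MicrosatDataset,
    populations: Sequence[str] | None = None,
    loci: Sequence[str] | None = None,
) -> FStatResult:
    """Weir–Cockerham f (F_IS) and θ (F_ST) per locus and overall.

    Uses females only.  With a single population only f is estimated
    (θ is None).  Multi-locus estimates combine summed components.
    """
    pops = list(populations) if populations is not None else dataset.populations()
    loci = list(loci) if loci is not None else list(dataset.loci)
    single_pop = len(pops) == 1

    f_per: dict[str, float | None] = {}
    t_per: dict[str, float | None] = {}
    comps: dict[str, tuple[float, float, float]] = {}
    SA = SB = SC = 0.0
    any_defined = False
    for locus in loci:
        genos_by_pop = [
            g for g in (_female_genotypes(dataset, p, locus) for p in pops) if g
        ]
        result = _wc_components(genos_by_pop)
        if result is None:
            f_per[locus] = None
            t_per[locus] = None
            continue
        a, b, c = result
        comps[locus] = result
        SA += a
        SB += b
        SC += c
        any_defined = True
        f_per[locus] = 1.0 - c / (b + c) if (b + c) != 0 else None
        t_per[locus] = (
            a / (a + b + c) if (not single_pop and (a + b + c) != 0) else None
        )
    if not any_defined:
        raise UndefinedStatistic("no locus with enough female data for F-statistics")
    f_overall = 1.0 - SC / (SB + SC) if (SB + SC) != 0 else None
    theta_overall = (
        SA / (SA + SB + SC) if (not single_pop and (SA + SB + SC) != 0) else None
    )
    return FStatResult(
        populations=pops,
        loci=loci,
        f_per_locus=f_per,
        theta_per_locus=t_per,
        f_overall=f_overall,
        theta_overall=theta_overall,
        components=comps,
    )


# ---------------------------------------------------------------------------
# Hardy–Weinberg heterozygote-deficit permutation test
# ---------------------------------------------------------------------------


def _f_from_het(H: np.ndarray, n: int, sum_p2: float) -> np.ndarray:
    """Single-population W&C f as a function of observed heterozygote
    proportion H, at fixed allele frequencies (sum_p2 = Σ p(1−p))."""
    denom = (n / (n - 1)) * sum_p2 - H / (2 * (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, 1.0 - H / denom, np.nan)


def hwe_deficit_test(
    dataset: MicrosatDataset,
    population: str,
    locus: str,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided Monte-Carlo test for heterozygote deficiency.

    Statistic: the population's single-locus W&C f.  Null distribution:
    the population's female gene copies are shuffled into random diploids.
    p = (1 + #{f_null >= f_obs}) / (n_perm + 1).  Monomorphic loci return
    p = 1 by convention.
    """
    if n_perm < 1:
        raise StatsError("n_perm must be >= 1")
    genos = _female_genotypes(dataset, population, locus)
    n = len(genos)
    if n < 2:
        raise UndefinedStatistic(
            f"HWE test needs >= 2 females with data at {locus!r}"
        )
    copies = np.array([x for g in genos for x in g])
    if len(set(copies.tolist())) < 2:
        return 1.0
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    freqs = np.array(list(Counter(copies.tolist()).values())) / (2 * n)
    sum_p1p = float((freqs * (1 - freqs)).sum())

    h_obs = np.array([float(sum(1 for a, b in genos if a != b)) / n])
    f_obs = _f_from_het(h_obs, n, sum_p1p)[0]

    # vectorised permutations: each row is a shuffle of the 2n gene copies,
    # consecutive pairs form diploids
    order = np.argsort(rng.random((n_perm, 2 * n)), axis=1)
    shuffled = copies[order]
    h_null = (shuffled[:, 0::2] != shuffled[:, 1::2]).mean(axis=1)
    f_null = _f_from_het(h_null, n, sum_p1p)
    exceed = int(np.sum(f_null >= f_obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# mtDNA statistics
# ---------------------------------------------------------------------------


@dataclass
class MtDnaSummary:
    n_individuals: int
    n_haplotypes: int
    haplotype_counts: list[int]
    haplotype_of: dict[str, int]  # sample id -> haplotype index
    n_segregating_sites: int
    haplotype_diversity: float | None = None
    nucleotide_diversity: float | None = None


def collapse_haplotypes(alignment: HaplotypeAlignment) -> MtDnaSummary:
    """Collapse identical sequences to haplotypes; count segregating sites.

    Haplotype identity is exact string equality of the aligned sequence.
    Segregating sites are positions carrying >= 2 distinct unambiguous
    bases (N and gaps ignored at that position).
    """
    hap_index: dict[str, int] = {}
    hap_of: dict[str, int] = {}
    counts: list[int] = []
    for sid, seq in zip(alignment.ids, alignment.seqs):
        if seq not in hap_index:
            hap_index[seq] = len(hap_index)
            counts.append(0)
        idx = hap_index[seq]
        hap_of[sid] = idx
        counts[idx] += 1
    n_seg = 0
    for pos in range(alignment.length):
        states = {s[pos] for s in alignment.seqs} & _UNAMBIGUOUS
        if len(states) >= 2:
            n_seg += 1
    summary = MtDnaSummary(
        n_individuals=alignment.n,
        n_haplotypes=len(hap_index),
        haplotype_counts=counts,
        haplotype_of=hap_of,
        n_segregating_sites=n_seg,
    )
    if alignment.n >= 2:
        summary.haplotype_diversity = haplotype_diversity(summary)
        summary.nucleotide_diversity = nucleotide_diversity(alignment)
    return summary


def haplotype_diversity(summary: MtDnaSummary) -> float:
    """Hd = (n/(n−1))(1 − Σ p_i²) over haplotype frequencies."""
    n = summary.n_individuals
    if n < 2:
        raise UndefinedStatistic("haplotype diversity undefined for n < 2")
    sum_p2 = sum((c / n) ** 2 for c in summary.haplotype_counts)
    return (n / (n - 1)) * (1.0 - sum_p2)


def _pair_diff(s1: str, s2: str) -> tuple[int, int]:
    """(differences, comparable sites) with pairwise deletion of ambiguity."""
    diffs = valid = 0
    for c1, c2 in zip(s1, s2):
        if c1 in _UNAMBIGUOUS and c2 in _UNAMBIGUOUS:
            valid += 1
            if c1 != c2:
                diffs += 1
    return diffs, valid


def nucleotide_diversity(alignment: HaplotypeAlignment) -> float:
    """π: mean pairwise proportion of differing sites over unordered pairs.

    Sites where either member of a pair is ambiguous (N or gap) are excluded
    for that pair only.
    """
    n = alignment.n
    if n < 2:
        raise UndefinedStatistic("nucleotide diversity undefined for n < 2")
    if alignment.length == 0:
        raise UndefinedStatistic("nucleotide diversity undefined for empty alignment")
    total = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs, valid = _pair_diff(alignment.seqs[i], alignment.seqs[j])
            if valid == 0:
                continue
            total += diffs / valid
            n_pairs += 1
    if n_pairs == 0:
        raise UndefinedStatistic("no comparable site in any pair")
    return total / n_pairs


def pairwise_differences(alignment: HaplotypeAlignment) -> np.ndarray:
    """Symmetric matrix of raw site differences (pairwise deletion)."""
    n = alignment.n
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            diffs, _ = _pair_diff(alignment.seqs[i], alignment.seqs[j])
            mat[i, j] = mat[j, i] = diffs
    return mat


def min_between_clusters(
    alignment: HaplotypeAlignment,
    ids_a: Iterable[str],
    ids_b: Iterable[str],
) -> int:
    """Smallest raw pairwise difference between two clusters of sequences."""
    index = {sid: k for k, sid in enumerate(alignment.ids)}
    mat = pairwise_differences(alignment)
    best: int | None = None
    for ia in ids_a:
        for ib in ids_b:
            d = int(mat[index[ia], index[ib]])
            if best is None or d < best:
                best = d
    if best is None:
        raise StatsError("empty cluster")
    return best
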