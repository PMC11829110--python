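"""Shared/private allele accounting between two population groups.

A *private allele* is an allele observed (>= 1 gene copy, no frequency
floor) in exactly one of the two groups at a locus.  Two aggregate bases are
first-class because they answer different questions and must not be
conflated:

``amplified`` (locus basis)
    Over all loci with data in both groups: the proportion of loci at which
    a focal group carries at least one private allele.  This is the quantity
    that feeds the divergence-time estimator.

``analyzed`` (allele basis)
    Over a designated panel of analysis loci (typically the polymorphic
    panel): the unweighted per-locus mean of the fractions of distinct
    alleles that are shared / private to each group.

Males contribute their single gene copy to all inventories.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genotype_io import MicrosatDataset


class AccountingError(ValueError):
    pass


@dataclass
class AlleleInventory:
    """Per locus x per group: allele code -> gene-copy count."""

    loci: list[str]
    groups: list[str]
    counts: dict[str, dict[str, Counter]]  # locus -> group -> Counter
    amplified_loci: list[str]  # data in BOTH groups
    amplified_either: list[str]  # data in at least one group

    def alleles(self, locus: str, group: str) -> set[int]:
        return set(self.counts[locus][group])


@dataclass
class LocusClassification:
    shared: frozenset[int]
    private: dict[str, frozenset[int]]  # group -> private alleles

    @property
    def union_size(self) -> int:
        return len(self.shared) + sum(len(v) for v in self.private.values())

    def fractions(self, group_order: Sequence[str]) -> tuple[float, ...]:
        """(shared, private_A, private_B, ...) fractions of distinct alleles."""
        u = self.union_size
        return (len(self.shared) / u,) + tuple(
            len(self.private[g]) / u for g in group_order
        )


@dataclass
class PrivateAlleleSummary:
    """Per-locus shared/private classification for one group pair."""

    focal_pair: tuple[str, str]
    per_locus: dict[str, LocusClassification]
    amplified_loci: list[str]
    analysis_loci: list[str] = field(default_factory=list)


def allele_inventory(
    dataset: MicrosatDataset,
    grouping: Mapping[str, str] | None = None,
) -> AlleleInventory:
    """Tally gene copies per locus per group (females 2, males 1).

    *grouping* maps population -> group; by default each sample's own group
    label is used.  A grouping that names an unknown population is an error.
    """
    if not dataset.samples:
        raise AccountingError("empty dataset")
    if grouping is not None:
        known = set(dataset.populations())
        unknown = set(grouping) - known
        if unknown:
            raise AccountingError(
                f"grouping references unknown populations: {sorted(unknown)}"
            )

    def group_of(sample) -> str:
        if grouping is None:
            return sample.group
        return grouping[sample.population]

    groups: list[str] = []
    for s in dataset.samples:
        g = group_of(s)
        if g not in groups:
            groups.append(g)

    counts: dict[str, dict[str, Counter]] = {
        locus: {g: Counter() for g in groups} for locus in dataset.loci
    }
    for s in dataset.samples:
        g = group_of(s)
        for locus in dataset.loci:
            call = dataset.get_call(s.sample_id, locus)
            if call is not None:
                counts[locus][g].update(call)

    amplified_both = [
        locus
        for locus in dataset.loci
        if all(counts[locus][g] for g in groups)
    ]
    amplified_either = [
        locus
        for locus in dataset.loci
        if any(counts[locus][g] for g in groups)
    ]
    return AlleleInventory(
        loci=list(dataset.loci),
        groups=groups,
        counts=counts,
        amplified_loci=amplified_both,
        amplified_either=amplified_either,
    )


def classify_alleles(
    inventory: AlleleInventory,
    focal_pair: tuple[str, str] | None = None,
    analysis_loci: Iterable[str] | None = None,
    *,
    basis_requires_both: bool = True,
) -> PrivateAlleleSummary:
    """Classify every allele at every amplified locus as shared or private.

    An allele is shared iff present (count >= 1) in both groups of
    *focal_pair*, otherwise private to the group carrying it.  With
    ``basis_requires_both=False`` the locus basis relaxes to loci amplified
    in either group.
    """
    if focal_pair is None:
        if len(inventory.groups) != 2:
            raise AccountingError(
                "focal_pair required when inventory has != 2 groups"
            )
        focal_pair = (inventory.groups[0], inventory.groups[1])
    a, b = focal_pair
    for g in focal_pair:
        if g not in inventory.groups:
            raise AccountingError(f"unknown group {g!r}")

    basis = inventory.amplified_loci if basis_requires_both else inventory.amplified_either
    if not basis:
        raise AccountingError("zero amplified loci for this group pair")

    per_locus: dict[str, LocusClassification] = {}
    for locus in basis:
        set_a = inventory.alleles(locus, a)
        set_b = inventory.alleles(locus, b)
        per_locus[locus] = LocusClassification(
            shared=frozenset(set_a & set_b),
            private={a: frozenset(set_a - set_b), b: frozenset(set_b - set_a)},
        )

    if analysis_loci is None:
        analysis = list(basis)
    else:
        analysis = list(analysis_loci)
        extra = set(analysis) - set(basis)
        if extra:
            raise AccountingError(
                f"analysis loci outside the amplified basis: {sorted(extra)}"
            )
    return PrivateAlleleSummary(
        focal_pair=focal_pair,
        per_locus=per_locus,
        amplified_loci=list(basis),
        analysis_loci=analysis,
    )


def locus_private_proportion(
    summary: PrivateAlleleSummary,
    focal_group: str,
    basis: str = "amplified",
) -> tuple[float, int, int]:
    """Proportion of loci at which *focal_group* has >= 1 private allele.

    Returns ``(k/n, k, n)`` where n is the number of loci on the chosen
    basis (``"amplified"`` or ``"analyzed"``); the raw (k, n) support
    binomial confidence intervals downstream.
    """
    if basis not in ("amplified", "analyzed"):
        raise AccountingError(f"unknown basis {basis!r}")
    if focal_group not in summary.focal_pair:
        raise AccountingError(f"group {focal_group!r} not in focal pair")
    loci = summary.amplified_loci if basis == "amplified" else summary.analysis_loci
    n = len(loci)
    if n == 0:
        raise AccountingError(f"no loci on basis {basis!r}")
    k = sum(1 for locus in loci if summary.per_locus[locus].private[focal_group])
    return k / n, k, n


def mean_allele_class_proportions(
    summary: PrivateAlleleSummary,
    analysis_loci: Iterable[str] | None = None,
) -> tuple[float, float, float]:
    """Unweighted per-locus mean of (shared, private_A, private_B) fractions.

    Averaged over the summary's analysis loci (or an explicit subset).  The
    three means sum to 1 exactly up to floating point.
    """
    loci = list(analysis_loci) if analysis_loci is not None else summary.analysis_loci
    if not loci:
        raise AccountingError("empty analysis locus set")
    missing = [l for l in loci if l not in summary.per_locus]
    if missing:
        raise AccountingError(f"loci outside the classified basis: {missing}")
    order = summary.focal_pair
    sums = [0.0, 0.0, 0.0]
    for locus in loci:
        fr = summary.per_locus[locus].fractions(order)
        for i in range(3):
            sums[i] += fr[i]
    n = len(loci)
    return (sums[0] / n, sums[1] / n, sums[2] / n)
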