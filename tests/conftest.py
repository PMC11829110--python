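from __future__ import annotations

import numpy as np
import pytest

from msprivtime.genotype_io import (
    HaplotypeAlignment,
    MicrosatDataset,
    SampleMeta,
)


def female(sid: str, pop: str = "Ishigaki", group: str = "native") -> SampleMeta:
    return SampleMeta(sid, pop, group, "female")


def male(sid: str, pop: str = "Okinawa", group: str = "native") -> SampleMeta:
    return SampleMeta(sid, pop, group, "male")


def build_dataset(rows, loci=None) -> MicrosatDataset:
    """rows: list of (SampleMeta, {locus: call-tuple-or-None})."""
    loci = loci or sorted({l for _, calls in rows for l in calls})
    samples = [meta for meta, _ in rows]
    call_map = {}
    for meta, calls in rows:
        for locus in loci:
            call_map[(meta.sample_id, locus)] = calls.get(locus)
    return MicrosatDataset(loci=list(loci), samples=samples, calls=call_map)


def random_female_dataset(
    rng: np.random.Generator,
    n_pops: int = 2,
    n_females: int = 6,
    n_loci: int = 3,
    n_alleles: int = 4,
) -> MicrosatDataset:
    """Small random all-female multi-population fixture for oracle checks."""
    rows = []
    for p in range(n_pops):
        for i in range(n_females):
            meta = SampleMeta(f"p{p}s{i}", f"pop{p}", "native", "female")
            calls = {
                f"L{k}": tuple(
                    int(a) for a in rng.integers(100, 100 + n_alleles, size=2)
                )
                for k in range(n_loci)
            }
            rows.append((meta, calls))
    return build_dataset(rows)


@pytest.fixture
def two_pop_dataset() -> MicrosatDataset:
    """Two populations, two groups, mixed sexes, one missing call."""
    rows = [
        (female("ir1", "Iriomote"), {"LocA": (100, 103), "LocB": (200, 200)}),
        (female("ir2", "Iriomote"), {"LocA": (100, 100), "LocB": (200, 203)}),
        (male("ok1", "Okinawa"), {"LocA": (103,), "LocB": (206,)}),
        (
            female("kn1", "Kanagawa", "invasive"),
            {"LocA": (106, 106), "LocB": None},
        ),
        (
            female("kn2", "Kanagawa", "invasive"),
            {"LocA": (106, 109), "LocB": (203, 209)},
        ),
    ]
    return build_dataset(rows)


@pytest.fixture
def small_alignment() -> HaplotypeAlignment:
    return HaplotypeAlignment(
        ids=["a", "b", "c", "d"],
        seqs=["ACGTACGT", "ACGTACGT", "ACGTACCT", "ACGTTCCT"],
    )
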