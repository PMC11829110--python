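"""Reading, validating and writing microsatellite genotype data and aligned mtDNA.

The package's canonical in-memory containers are defined here:

``MicrosatDataset``
    Per-sample, per-locus allele calls with ploidy-aware storage.  Diploid
    females carry two allele codes per locus, haploid males one.  Allele
    codes are positive integers (fragment lengths / repeat counts taken at
    face value; trinucleotide panels need no stutter binning).  Missing data
    is an explicit ``None`` call, never a 0-as-data sentinel.

``HaplotypeAlignment``
    A pre-aligned set of equal-length nucleotide sequences (mtDNA COI in the
    motivating study), case-normalised, with gaps and Ns preserved.

Supported on-disk formats: the GenePop exchange dialect (2- or 3-digit
coding, ``00``/``000`` missing), a TSV genotype table with two columns per
locus, and aligned FASTA (via Biopython).  GenePop has no haploid encoding,
so males are written as duplicated-allele homozygotes and their sex travels
in sample metadata (a sidecar TSV written next to the GenePop file).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

NATIVE = "native"
INVASIVE = "invasive"

#: Population -> group mapping of the motivating study (Ryukyu natives,
#: Japanese-mainland invasives).  Callers with other designs pass their own.
DEFAULT_GROUP_MAP: dict[str, str] = {
    "Iriomote": NATIVE,
    "Ishigaki": NATIVE,
    "Okinawa": NATIVE,
    "Shizuoka": INVASIVE,
    "Kanagawa": INVASIVE,
}

VALID_SEXES = ("female", "male")
ALIGNMENT_ALPHABET = frozenset("ACGTN-")


class GenotypeIOError(ValueError):
    """Raised for malformed genotype/alignment inputs."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity and grouping metadata for one sampled individual."""

    sample_id: str
    population: str
    group: str
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise GenotypeIOError(
                f"sample {self.sample_id!r}: unknown sex {self.sex!r} "
                f"(expected one of {VALID_SEXES})"
            )


Call = tuple[int, ...] | None


@dataclass
class MicrosatDataset:
    """Ploidy-aware microsatellite calls for a set of samples.

    ``calls[(sample_id, locus)]`` is a tuple of allele codes — length 2 for
    females, 1 for males — or ``None`` for missing.
    """

    loci: list[str]
    samples: list[SampleMeta]
    calls: dict[tuple[str, str], Call] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenotypeIOError(f"duplicate sample ids: {dup}")
        if len(set(self.loci)) != len(self.loci):
            raise GenotypeIOError("duplicate locus names")
        by_id = {s.sample_id: s for s in self.samples}
        for (sid, locus), call in self.calls.items():
            if sid not in by_id:
                raise GenotypeIOError(f"call for unknown sample {sid!r}")
            if locus not in self.loci:
                raise GenotypeIOError(f"call for unknown locus {locus!r}")
            if call is None:
                continue
            expected = 2 if by_id[sid].sex == "female" else 1
            if len(call) != expected:
                raise GenotypeIOError(
                    f"sample {sid!r} ({by_id[sid].sex}) at locus {locus!r}: "
                    f"got {len(call)} allele codes, expected {expected}"
                )
            if any(a <= 0 for a in call):
                raise GenotypeIOError(
                    f"sample {sid!r} at locus {locus!r}: non-positive allele "
                    f"code in {call} (missing data must be None, not 0)"
                )

    # -- accessors --------------------------------------------------------

    def get_call(self, sample_id: str, locus: str) -> Call:
        return self.calls.get((sample_id, locus))

    def select(
        self,
        *,
        population: str | None = None,
        group: str | None = None,
        sex: str | None = None,
    ) -> list[SampleMeta]:
        out = []
        for s in self.samples:
            if population is not None and s.population != population:
                continue
            if group is not None and s.group != group:
                continue
            if sex is not None and s.sex != sex:
                continue
            out.append(s)
        return out

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    def gene_copies(self, samples: Iterable[SampleMeta], locus: str) -> list[int]:
        """All allele codes carried by *samples* at *locus* (2 per female
        with data, 1 per male), missing calls skipped."""
        copies: list[int] = []
        for s in samples:
            call = self.get_call(s.sample_id, locus)
            if call is not None:
                copies.extend(call)
        return copies


@dataclass
class HaplotypeAlignment:
    """Equal-length aligned nucleotide sequences keyed by sample id."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise GenotypeIOError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise GenotypeIOError("duplicate sequence ids")
        self.seqs = [s.upper() for s in self.seqs]
        if self.seqs:
            ref = len(self.seqs[0])
            bad = [i for i, s in zip(self.ids, self.seqs) if len(s) != ref]
            if bad:
                raise GenotypeIOError(
                    f"sequences not all of equal length; offending ids: {bad}"
                )
        for i, s in zip(self.ids, self.seqs):
            extra = set(s) - ALIGNMENT_ALPHABET
            if extra:
                raise GenotypeIOError(
                    f"sequence {i!r}: characters outside A/C/G/T/N/-: {sorted(extra)}"
                )

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n(self) -> int:
        return len(self.seqs)

    def subset(self, ids: Sequence[str]) -> "HaplotypeAlignment":
        wanted = set(ids)
        pairs = [(i, s) for i, s in zip(self.ids, self.seqs) if i in wanted]
        return HaplotypeAlignment([p[0] for p in pairs], [p[1] for p in pairs])


# ---------------------------------------------------------------------------
# GenePop dialect
# ---------------------------------------------------------------------------


def _parse_genepop_token(token: str, line_no: int) -> tuple[int, ...] | None:
    """Parse one GenePop genotype token into (a1, a2) or None (missing).

    Digit width is inferred from the token length: 4 characters = 2-digit
    coding, 6 = 3-digit.  Widths 2/3 (single-coded haploids) are accepted
    and returned as 1-tuples.
    """
    if not token.isdigit():
        raise GenotypeIOError(f"line {line_no}: non-numeric genotype token {token!r}")
    if len(token) in (2, 3):
        a = int(token)
        return None if a == 0 else (a,)
    if len(token) in (4, 6):
        w = len(token) // 2
        a1, a2 = int(token[:w]), int(token[w:])
        if a1 == 0 or a2 == 0:
            # partially-missing genotypes are treated as missing calls
            return None
        return (a1, a2)
    raise GenotypeIOError(
        f"line {line_no}: genotype token {token!r} has ambiguous digit width "
        "(expected 2/3 digits per allele)"
    )


def read_genepop(
    path: str | Path,
    metadata: Mapping[str, SampleMeta] | Iterable[SampleMeta],
) -> MicrosatDataset:
    """Read a GenePop file, resolving ploidy from per-sample metadata.

    Every sample id in the file must be present in *metadata*.  Samples whose
    metadata says ``male`` may be coded either single (``145``) or as a
    duplicated-allele homozygote (``145145``); both collapse to one stored
    allele code.  A male coded as a heterozygote is an error.
    """
    meta = _as_meta_map(metadata)
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeIOError(f"{path}: empty file")

    loci: list[str] = []
    samples: list[SampleMeta] = []
    calls: dict[tuple[str, str], Call] = {}
    pop_index = -1  # -1 = still in locus header
    n_loci = 0
    for line_no, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            if not loci:
                raise GenotypeIOError(f"line {line_no}: POP before any locus names")
            pop_index += 1
            n_loci = len(loci)
            continue
        if pop_index < 0:
            # locus header: one per line, or comma-separated
            loci.extend(name.strip() for name in line.split(",") if name.strip())
            continue
        if "," not in line:
            raise GenotypeIOError(
                f"line {line_no}: sample line without ',' separator: {raw!r}"
            )
        sid_part, geno_part = line.split(",", 1)
        sid = sid_part.strip()
        if sid not in meta:
            raise GenotypeIOError(
                f"line {line_no}: sample {sid!r} absent from metadata"
            )
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise GenotypeIOError(
                f"line {line_no}: sample {sid!r} has {len(tokens)} genotypes "
                f"for {n_loci} declared loci"
            )
        widths = {len(t) for t in tokens if len(t) > 3}
        if len(widths) > 1:
            raise GenotypeIOError(
                f"line {line_no}: mixed allele digit widths {sorted(widths)}"
            )
        sm = meta[sid]
        samples.append(sm)
        for locus, token in zip(loci, tokens):
            call = _parse_genepop_token(token, line_no)
            if call is not None and sm.sex == "male":
                if len(call) == 2:
                    if call[0] != call[1]:
                        raise GenotypeIOError(
                            f"line {line_no}: male {sid!r} coded as heterozygote "
                            f"{call} at locus {locus!r}"
                        )
                    call = (call[0],)
            elif call is not None and sm.sex == "female" and len(call) == 1:
                raise GenotypeIOError(
                    f"line {line_no}: female {sid!r} single-coded at locus {locus!r}"
                )
            calls[(sid, locus)] = call
    if pop_index < 0:
        raise GenotypeIOError(f"{path}: no POP block found")
    if not samples:
        raise GenotypeIOError(f"{path}: no samples in data section")
    return MicrosatDataset(loci=loci, samples=samples, calls=calls)


def write_genepop(
    dataset: MicrosatDataset,
    path: str | Path,
    *,
    title: str = "msprivtime export",
    digits: int = 3,
    sidecar: bool = True,
) -> None:
    """Write *dataset* in canonical GenePop form.

    Canonical form: title line, one locus name per line, one POP block per
    population in dataset order, 3-digit coding, samples in dataset order.
    Males are emitted as duplicated-allele homozygotes; their sex (and the
    population/group labels) go to a ``<path>.meta.tsv`` sidecar so a round
    trip through :func:`read_genepop` is lossless.
    """
    if digits not in (2, 3):
        raise GenotypeIOError("digits must be 2 or 3")
    width = digits
    missing = "0" * (2 * width)
    out = [title]
    out.extend(dataset.loci)
    for pop in dataset.populations():
        out.append("POP")
        for s in dataset.select(population=pop):
            fields = []
            for locus in dataset.loci:
                call = dataset.get_call(s.sample_id, locus)
                if call is None:
                    fields.append(missing)
                else:
                    a1 = call[0]
                    a2 = call[1] if len(call) == 2 else call[0]
                    if max(a1, a2) >= 10**width:
                        raise GenotypeIOError(
                            f"allele code {max(a1, a2)} does not fit {width}-digit coding"
                        )
                    fields.append(f"{a1:0{width}d}{a2:0{width}d}")
            out.append(f"{s.sample_id} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")
    if sidecar:
        write_metadata(dataset.samples, str(path) + ".meta.tsv")


def write_metadata(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = ["sample_id\tpopulation\tgroup\tsex"]
    rows += [f"{s.sample_id}\t{s.population}\t{s.group}\t{s.sex}" for s in samples]
    Path(path).write_text("\n".join(rows) + "\n")


def read_metadata(path: str | Path) -> dict[str, SampleMeta]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    expected = ["sample_id", "population", "group", "sex"]
    if header != expected:
        raise GenotypeIOError(f"{path}: metadata header must be {expected}")
    out: dict[str, SampleMeta] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        sid, pop, group, sex = line.split("\t")
        out[sid] = SampleMeta(sid, pop, group, sex)
    return out


def _as_meta_map(
    metadata: Mapping[str, SampleMeta] | Iterable[SampleMeta],
) -> Mapping[str, SampleMeta]:
    if isinstance(metadata, Mapping):
        return metadata
    return {s.sample_id: s for s in metadata}


# ---------------------------------------------------------------------------
# TSV genotype table
# ---------------------------------------------------------------------------


def read_genotype_table(
    path: str | Path,
    group_map: Mapping[str, str] | None = None,
) -> MicrosatDataset:
    """Read the TSV genotype dialect.

    Header: ``sample_id  population  sex  <locus>.1  <locus>.2  ...`` (two
    columns per locus, suffixes ``.1``/``.2``).  Missing alleles are empty
    cells or ``0``; males fill only the ``.1`` column.  Group labels come
    from *group_map* (population -> group), defaulting to the study's
    Ryukyu/mainland mapping.
    """
    group_map = dict(group_map or DEFAULT_GROUP_MAP)
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeIOError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:3] != ["sample_id", "population", "sex"]:
        raise GenotypeIOError(
            f"{path}: header must start with sample_id, population, sex"
        )
    locus_cols = header[3:]
    loci: list[str] = []
    for col in locus_cols:
        if "." not in col:
            raise GenotypeIOError(
                f"{path}: locus column {col!r} lacks a .1/.2 suffix"
            )
        name, suffix = col.rsplit(".", 1)
        if suffix == "1":
            loci.append(name)
        elif suffix != "2":
            raise GenotypeIOError(f"{path}: unexpected locus column {col!r}")
    expected_cols = [f"{n}.{s}" for n in loci for s in ("1", "2")]
    if locus_cols != expected_cols:
        raise GenotypeIOError(
            f"{path}: locus columns must be paired as <locus>.1 <locus>.2 in order"
        )
    if len(lines) == 1:
        raise GenotypeIOError(f"{path}: empty data section")

    samples: list[SampleMeta] = []
    calls: dict[tuple[str, str], Call] = {}
    for line_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise GenotypeIOError(
                f"{path} line {line_no}: {len(cells)} cells for {len(header)} columns"
            )
        sid, pop, sex = cells[0], cells[1], cells[2]
        if sex not in VALID_SEXES:
            raise GenotypeIOError(
                f"{path} line {line_no}: unknown sex label {sex!r}"
            )
        if pop not in group_map:
            raise GenotypeIOError(
                f"{path} line {line_no}: population {pop!r} not in group mapping"
            )
        sm = SampleMeta(sid, pop, group_map[pop], sex)
        samples.append(sm)
        for k, locus in enumerate(loci):
            c1, c2 = cells[3 + 2 * k], cells[4 + 2 * k]
            a1 = int(c1) if c1.strip() not in ("", "0", ".") else 0
            a2 = int(c2) if c2.strip() not in ("", "0", ".") else 0
            if sex == "male":
                if a2 and a2 != a1:
                    raise GenotypeIOError(
                        f"{path} line {line_no}: male {sid!r} with two distinct "
                        f"alleles at {locus!r}"
                    )
                calls[(sid, locus)] = (a1,) if a1 else None
            else:
                if bool(a1) != bool(a2):
                    raise GenotypeIOError(
                        f"{path} line {line_no}: female {sid!r} with only one "
                        f"allele column filled at {locus!r}"
                    )
                calls[(sid, locus)] = (a1, a2) if a1 else None
    return MicrosatDataset(loci=loci, samples=samples, calls=calls)


def write_genotype_table(dataset: MicrosatDataset, path: str | Path) -> None:
    header = ["sample_id", "population", "sex"]
    for locus in dataset.loci:
        header += [f"{locus}.1", f"{locus}.2"]
    rows = ["\t".join(header)]
    for s in dataset.samples:
        cells = [s.sample_id, s.population, s.sex]
        for locus in dataset.loci:
            call = dataset.get_call(s.sample_id, locus)
            if call is None:
                cells += ["0", "0"]
            elif len(call) == 1:
                cells += [str(call[0]), "0"]
            else:
                cells += [str(call[0]), str(call[1])]
        rows.append("\t".join(cells))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignment
# ---------------------------------------------------------------------------


def read_fasta_alignment(path: str | Path) -> HaplotypeAlignment:
    """Read a pre-aligned FASTA file (all records must be equal length)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenotypeIOError(f"{path}: no FASTA records")
    return HaplotypeAlignment(
        ids=[r.id for r in records],
        seqs=[str(r.seq).upper() for r in records],
    )


def write_fasta_alignment(alignment: HaplotypeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.ids, alignment.seqs):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(tables: Mapping[str, object], path: str | Path) -> None:
    """Serialise report *tables* to ``<path>.json`` plus one TSV per table.

    A table is either a pandas DataFrame or any JSON-serialisable object;
    DataFrames become TSVs next to the JSON.
    """
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload: dict[str, object] = {}
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(path.with_name(f"{path.stem}.{name}.tsv"), sep="\t", index=False)
            payload[name] = json.loads(table.to_json(orient="records"))
        else:
            payload[name] = table
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj: object) -> object:
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
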