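"""Typing scheme, allele database, ST registry and profile-table I/O.

The packaged default scheme types *Leuconostoc mesenteroides* by eight
housekeeping-gene fragments in the canonical profile order ``pyrG, rpoB,
groEL, recA, uvrC, carB, murC, pheS``.  Allele calling is by exact
sequence identity against a numbered per-locus database, and a sequence
type (ST) is the integer label of a unique allelic profile — the ordered
tuple of allele numbers, one per locus.

The module also reads and writes the PubMLST-style plain-text formats
used throughout the pipeline: a scheme TSV, per-locus multi-FASTA allele
databases with ``<locus>_<allele>`` headers, and a profile TSV with one
row per isolate.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DNA_ALPHABET",
    "LocusDef",
    "SchemeDef",
    "AlleleDatabase",
    "STRegistry",
    "IsolateRecord",
    "load_scheme",
    "default_scheme",
    "read_profile_table",
    "write_profile_table",
    "registry_from_records",
]

DNA_ALPHABET = frozenset("ACGT")

#: Source categories seen in the study collection (crops, a Tibetan
#: fermented yak-milk dairy, and culture-collection reference strains).
SOURCE_TYPES = ("potato", "oat", "wheat", "Qula", "standard")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("mlstpop").joinpath("data", name)))


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if not seq or bad:
        raise ValueError(f"{what} must be nonempty over A/C/G/T, got {sorted(bad) or 'empty'}")
    return seq


@dataclass(frozen=True)
class LocusDef:
    """One locus of a typing scheme: a gene fragment with its primer pair."""

    name: str
    fragment_length: int
    primer_forward: str
    primer_reverse: str
    genome_position: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be nonempty")
        if self.fragment_length <= 0:
            raise ValueError(f"fragment_length must be positive, got {self.fragment_length}")
        object.__setattr__(self, "primer_forward", _check_dna(self.primer_forward, "primer_forward"))
        object.__setattr__(self, "primer_reverse", _check_dna(self.primer_reverse, "primer_reverse"))


@dataclass(frozen=True)
class SchemeDef:
    """An ordered collection of loci; the order fixes profile column order."""

    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate locus names in scheme: {names}")
        if not names:
            raise ValueError("scheme must define at least one locus")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"locus {name!r} not in scheme {self.locus_names}")


def load_scheme(path: str | Path) -> SchemeDef:
    """Parse a scheme TSV with columns name, fragment_length, primer_f, primer_r."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"empty scheme file {path}")
    header = lines[0].split("\t")
    required = ["name", "fragment_length", "primer_f", "primer_r"]
    for col in required:
        if col not in header:
            raise ValueError(f"scheme file missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    loci = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        pos = None
        if "genome_position" in idx and len(parts) > idx["genome_position"] and parts[idx["genome_position"]]:
            pos = int(parts[idx["genome_position"]])
        loci.append(
            LocusDef(
                name=parts[idx["name"]],
                fragment_length=int(parts[idx["fragment_length"]]),
                primer_forward=parts[idx["primer_f"]],
                primer_reverse=parts[idx["primer_r"]],
                genome_position=pos,
            )
        )
    return SchemeDef(tuple(loci))


def default_scheme() -> SchemeDef:
    """The packaged eight-locus L. mesenteroides scheme."""
    return load_scheme(_data_path("scheme.tsv"))


class AlleleDatabase:
    """Numbered allele sequences per locus (exact-match, alignment-free).

    Within a locus all alleles have equal length, so novel-allele
    detection and nearest-allele distances reduce to Hamming comparisons.
    Numbers are dense from 1 in first-seen order.
    """

    def __init__(self) -> None:
        self._alleles: dict[str, dict[int, str]] = {}
        self._index: dict[str, dict[str, int]] = {}

    def loci(self) -> tuple[str, ...]:
        return tuple(self._alleles)

    def alleles(self, locus: str) -> dict[int, str]:
        return dict(self._alleles.get(locus, {}))

    def n_alleles(self, locus: str) -> int:
        return len(self._alleles.get(locus, {}))

    def allele_length(self, locus: str) -> Optional[int]:
        table = self._alleles.get(locus)
        if not table:
            return None
        return len(next(iter(table.values())))

    def sequence(self, locus: str, number: int) -> str:
        return self._alleles[locus][number]

    def lookup(self, locus: str, seq: str) -> Optional[int]:
        """Allele number of an exact (case-insensitive) match, else None."""
        return self._index.get(locus, {}).get(seq.upper())

    def register(self, locus: str, seq: str) -> int:
        """Return the allele number of ``seq``, assigning max+1 if novel.

        Idempotent: re-registering a known sequence returns its existing
        number.  A sequence whose length disagrees with the locus is
        rejected (indels cannot be represented in an exact-match scheme).
        """
        seq = _check_dna(seq, f"allele sequence for {locus}")
        existing = self.lookup(locus, seq)
        if existing is not None:
            return existing
        length = self.allele_length(locus)
        if length is not None and len(seq) != length:
            raise ValueError(
                f"allele length {len(seq)} for locus {locus} does not match database length {length}"
            )
        table = self._alleles.setdefault(locus, {})
        number = max(table, default=0) + 1
        table[number] = seq
        self._index.setdefault(locus, {})[seq] = number
        return number

    # --- PubMLST-style FASTA serialisation -------------------------------

    def to_fasta_dir(self, directory: str | Path) -> None:
        """Write one ``<locus>.fasta`` per locus with ``<locus>_<n>`` headers."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for locus, table in self._alleles.items():
            records = [
                SeqRecord(Seq(seq), id=f"{locus}_{num}", description="")
                for num, seq in sorted(table.items())
            ]
            SeqIO.write(records, directory / f"{locus}.fasta", "fasta")

    @classmethod
    def from_fasta_dir(cls, directory: str | Path) -> "AlleleDatabase":
        db = cls()
        for path in sorted(Path(directory).glob("*.fasta")):
            for rec in SeqIO.parse(str(path), "fasta"):
                locus, _, num = rec.id.rpartition("_")
                if not locus or not num.isdigit():
                    raise ValueError(f"allele header {rec.id!r} not of the form <locus>_<number>")
                number = int(num)
                seq = _check_dna(str(rec.seq), f"allele {rec.id}")
                length = db.allele_length(locus)
                if length is not None and len(seq) != length:
                    raise ValueError(f"allele {rec.id} length {len(seq)} != locus length {length}")
                db._alleles.setdefault(locus, {})[number] = seq
                db._index.setdefault(locus, {})[seq] = number
        for locus, table in db._alleles.items():
            if sorted(table) != list(range(1, len(table) + 1)):
                raise ValueError(f"allele numbers for {locus} not dense from 1: {sorted(table)}")
        return db


def _check_profile(profile: Sequence[int], n_loci: int) -> tuple[int, ...]:
    profile = tuple(int(a) for a in profile)
    if len(profile) != n_loci:
        raise ValueError(f"profile has {len(profile)} entries, scheme has {n_loci} loci")
    if any(a < 1 for a in profile):
        raise ValueError(f"allele numbers must be >= 1, got {profile}")
    return profile


class STRegistry:
    """Bijective map between allelic profiles and ST numbers."""

    def __init__(self, n_loci: int = 8) -> None:
        self.n_loci = n_loci
        self._by_profile: dict[tuple[int, ...], int] = {}
        self._by_st: dict[int, tuple[int, ...]] = {}

    def __len__(self) -> int:
        return len(self._by_st)

    def sts(self) -> tuple[int, ...]:
        return tuple(sorted(self._by_st))

    def profile_of(self, st: int) -> tuple[int, ...]:
        return self._by_st[st]

    def st_of(self, profile: Sequence[int]) -> Optional[int]:
        return self._by_profile.get(_check_profile(profile, self.n_loci))

    def add(self, profile: Sequence[int], st: int) -> None:
        """Register a profile under an explicit ST label (fixture seeding)."""
        profile = _check_profile(profile, self.n_loci)
        if st < 1:
            raise ValueError(f"ST must be >= 1, got {st}")
        if profile in self._by_profile and self._by_profile[profile] != st:
            raise ValueError(f"profile {profile} already mapped to ST{self._by_profile[profile]}")
        if st in self._by_st and self._by_st[st] != profile:
            raise ValueError(f"ST{st} already mapped to a different profile")
        self._by_profile[profile] = st
        self._by_st[st] = profile

    def assign(self, profile: Sequence[int]) -> int:
        """ST of a seen profile, or max+1 for an unseen one (stored)."""
        profile = _check_profile(profile, self.n_loci)
        st = self._by_profile.get(profile)
        if st is None:
            st = max(self._by_st, default=0) + 1
            self._by_profile[profile] = st
            self._by_st[st] = profile
        return st


@dataclass
class IsolateRecord:
    """One typed (or untypable) isolate with optional sampling metadata."""

    isolate_id: str
    st: Optional[int] = None
    profile: Optional[tuple[int, ...]] = None
    source_type: Optional[str] = None
    region: Optional[str] = None
    year: Optional[int] = None
    novel_loci: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.st is None) != (self.profile is None):
            raise ValueError("st is assigned iff the profile is fully resolved")


def read_profile_table(path: str | Path, scheme: Optional[SchemeDef] = None) -> list[IsolateRecord]:
    """Parse a profile TSV (isolate, ST, then one column per locus)."""
    scheme = scheme or default_scheme()
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty profile table {path}")
    header = lines[0].split("\t")
    expected = ["isolate", "ST", *scheme.locus_names]
    if header != expected:
        missing = [c for c in expected if c not in header]
        raise ValueError(f"profile table header {header} != {expected} (missing {missing})")
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(expected):
            raise ValueError(f"row has {len(parts)} fields, expected {len(expected)}: {line!r}")
        try:
            st = int(parts[1])
            profile = tuple(int(x) for x in parts[2:])
        except ValueError as exc:
            raise ValueError(f"non-integer ST/allele entry in row {line!r}") from exc
        records.append(IsolateRecord(isolate_id=parts[0], st=st, profile=profile))
    return records


def write_profile_table(records: Iterable[IsolateRecord], path: str | Path,
                        scheme: Optional[SchemeDef] = None) -> None:
    """Write records in the canonical TSV layout (byte-stable round trip)."""
    scheme = scheme or default_scheme()
    out = ["\t".join(["isolate", "ST", *scheme.locus_names])]
    for rec in records:
        if rec.st is None or rec.profile is None:
            continue  # untypable isolates carry no profile row
        out.append("\t".join([rec.isolate_id, str(rec.st), *map(str, rec.profile)]))
    Path(path).write_text("\n".join(out) + "\n")


def registry_from_records(records: Iterable[IsolateRecord], n_loci: int = 8) -> STRegistry:
    """Seed a registry with the explicit ST labels carried by the records."""
    reg = STRegistry(n_loci=n_loci)
    for rec in records:
        if rec.st is not None and rec.profile is not None:
            reg.add(rec.profile, rec.st)
    return reg
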