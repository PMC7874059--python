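"""Allele calling: from raw locus sequences to allelic profiles.

Calls are exact-match against the allele database.  An oriented,
length-matched sequence with no database hit is a NOVEL allele (reported
with its Hamming distance to the nearest known allele); a sequence of
the wrong length or containing ambiguity codes FAILs and leaves the
isolate untyped at that locus.  Primer matching for fragment extraction
is exact-string only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Seq import Seq

from .scheme import (
    DNA_ALPHABET,
    AlleleDatabase,
    IsolateRecord,
    LocusDef,
    SchemeDef,
    STRegistry,
)

__all__ = [
    "LocusSequence",
    "AlleleCall",
    "PrimerNotFoundError",
    "orient_sequence",
    "extract_fragment",
    "call_allele",
    "type_isolate",
]


class PrimerNotFoundError(ValueError):
    """A primer has no exact match in the read."""


@dataclass(frozen=True)
class LocusSequence:
    isolate_id: str
    locus: str
    seq: str
    strand: str  # "forward" | "reverse-complement-detected"

    def __post_init__(self) -> None:
        bad = set(self.seq.upper()) - (DNA_ALPHABET | {"N"})
        if bad:
            raise ValueError(f"locus sequence contains non-DNA characters {sorted(bad)}")


@dataclass(frozen=True)
class AlleleCall:
    locus: str
    status: str  # "OK" | "NOVEL" | "FAIL"
    allele: Optional[int] = None
    mismatch_count: Optional[int] = None
    novel_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.status == "OK") != (self.allele is not None and self.mismatch_count == 0):
            raise ValueError("allele number is set iff the call is an exact match")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _identities(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def orient_sequence(seq: str, db: AlleleDatabase, locus: str,
                    isolate_id: str = "") -> LocusSequence:
    """Return the input or its reverse complement, whichever better matches
    the known alleles of the locus.  Ties keep the forward presentation.
    """
    if db.n_alleles(locus) == 0:
        raise ValueError(f"no alleles registered for locus {locus}; cannot orient")
    seq = seq.upper()
    rc = revcomp(seq)
    alleles = db.alleles(locus).values()
    fwd = max(_identities(seq, a) for a in alleles)
    rev = max(_identities(rc, a) for a in alleles)
    if rev > fwd:
        return LocusSequence(isolate_id, locus, rc, "reverse-complement-detected")
    return LocusSequence(isolate_id, locus, seq, "forward")


def extract_fragment(read: str, locus: LocusDef) -> str:
    """Trim the amplicon down to the region strictly between the primers.

    The leftmost forward-primer hit and the nearest subsequent
    reverse-complemented reverse-primer hit delimit the fragment; both
    primers are trimmed off.  A fragment whose length deviates more than
    10% from the scheme's expected length triggers a warning only.
    """
    read = read.upper()
    fwd = locus.primer_forward
    rev_rc = revcomp(locus.primer_reverse)
    i = read.find(fwd)
    if i < 0:
        raise PrimerNotFoundError(f"forward primer for {locus.name} not found")
    start = i + len(fwd)
    j = read.find(rev_rc, start)
    if j < 0:
        raise PrimerNotFoundError(f"reverse primer for {locus.name} not found downstream of forward")
    fragment = read[start:j]
    expected = locus.fragment_length
    if abs(len(fragment) - expected) > 0.1 * expected:
        warnings.warn(
            f"{locus.name}: extracted {len(fragment)} bp, expected ~{expected} bp",
            stacklevel=2,
        )
    return fragment


def call_allele(seq: str, db: AlleleDatabase, locus: str) -> AlleleCall:
    """Exact match -> allele number; equal-length mismatch -> NOVEL with
    Hamming distance to the nearest allele; wrong length or any N -> FAIL.
    """
    seq = seq.upper()
    if "N" in seq or set(seq) - DNA_ALPHABET:
        return AlleleCall(locus, "FAIL")
    number = db.lookup(locus, seq)
    if number is not None:
        return AlleleCall(locus, "OK", allele=number, mismatch_count=0)
    length = db.allele_length(locus)
    if length is None or len(seq) != length:
        return AlleleCall(locus, "FAIL")
    nearest = min(sum(x != y for x, y in zip(seq, a)) for a in db.alleles(locus).values())
    return AlleleCall(locus, "NOVEL", mismatch_count=nearest, novel_seq=seq)


def type_isolate(isolate_id: str, calls: Sequence[AlleleCall], db: AlleleDatabase,
                 registry: STRegistry, scheme: SchemeDef) -> IsolateRecord:
    """Assemble one call per locus into a profile and an ST.

    NOVEL calls register their sequences first (new max+1 allele numbers,
    flagged on the record); any FAIL leaves the isolate unassigned.
    """
    by_locus = {c.locus: c for c in calls}
    missing = [n for n in scheme.locus_names if n not in by_locus]
    if missing or len(calls) != len(scheme):
        raise ValueError(f"need exactly one call per scheme locus; missing {missing}")
    if any(by_locus[n].status == "FAIL" for n in scheme.locus_names):
        return IsolateRecord(isolate_id=isolate_id)
    profile = []
    novel = []
    for name in scheme.locus_names:
        call = by_locus[name]
        if call.status == "OK":
            profile.append(call.allele)
        else:  # NOVEL
            profile.append(db.register(name, call.novel_seq))
            novel.append(name)
    st = registry.assign(tuple(profile))
    return IsolateRecord(isolate_id=isolate_id, st=st, profile=tuple(profile),
                         novel_loci=tuple(novel))
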