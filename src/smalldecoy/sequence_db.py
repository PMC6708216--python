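"""Protein sequence databases in FASTA.

A :class:`ProteinDatabase` is an ordered collection of accessioned amino-acid
sequences with a whole-database target/decoy role.  Decoy records are marked
purely by an accession prefix (default ``DECOY_``), so target/decoy
classification downstream is plain string matching and never requires the
FASTA files themselves.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO

DEFAULT_DECOY_PREFIX = "DECOY_"

#: The 20 standard residues plus ambiguity letters tolerated on ingest.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")
TOLERATED_ALPHABET = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES

PathLike = Union[str, Path]


@dataclass(frozen=True, slots=True)
class ProteinRecord:
    """One FASTA entry: accession, free-text description, residue string."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.accession!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinDatabase:
    """Ordered protein records plus the database's target/decoy role."""

    records: list[ProteinRecord] = field(default_factory=list)
    is_decoy: bool = False
    decoy_prefix: str = DEFAULT_DECOY_PREFIX

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
        if self.is_decoy:
            bad = [r.accession for r in self.records
                   if not r.accession.startswith(self.decoy_prefix)]
            if bad:
                raise ValueError(
                    f"decoy database has {len(bad)} accession(s) without the "
                    f"{self.decoy_prefix!r} prefix, e.g. {bad[0]!r}")

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def entry_count(self) -> int:
        return len(self.records)

    @property
    def residue_count(self) -> int:
        return sum(len(r.sequence) for r in self.records)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]


def _open_text(path: PathLike, mode: str) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode + "t" if "b" not in mode else mode)


def read_fasta(path: PathLike, *, is_decoy: bool = False,
               decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> ProteinDatabase:
    """Read a plain or gzipped FASTA file into a :class:`ProteinDatabase`.

    The accession is the first whitespace-delimited token of the header and
    the description is the remainder (possibly empty).  Sequences are
    upper-cased; residues outside the tolerated alphabet (20 standard letters
    plus B/J/O/U/X/Z) raise a ``ValueError`` identifying the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    with _open_text(path, "r") as handle:
        for idx, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            accession = rec.id
            description = rec.description[len(rec.id):].strip()
            sequence = str(rec.seq).upper()
            bad = set(sequence) - TOLERATED_ALPHABET
            if bad:
                raise ValueError(
                    f"record {idx} ({accession!r}) in {path} contains "
                    f"invalid residue(s) {sorted(bad)}")
            records.append(ProteinRecord(accession, description, sequence))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return ProteinDatabase(records, is_decoy=is_decoy, decoy_prefix=decoy_prefix)


def write_fasta(db: ProteinDatabase | Iterable[ProteinRecord], path: PathLike,
                line_width: int = 60) -> None:
    """Write records as ``>accession description`` headers with wrapped lines."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    records = list(db)
    if not records:
        raise ValueError("refusing to write an empty database")
    with _open_text(path, "w") as out:
        for rec in records:
            header = rec.accession
            if rec.description:
                header += " " + rec.description
            out.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), line_width):
                out.write(seq[i:i + line_width] + "\n")


def merge_databases(target: ProteinDatabase,
                    decoy: ProteinDatabase) -> ProteinDatabase:
    """Concatenate target and decoy databases (target first) for a combined search.

    Contaminant entries are expected to already live in ``target``.  Raises if
    the decoy role flags are wrong or any accession collides after prefixing.
    """
    if target.is_decoy:
        raise ValueError("first argument must be the target database")
    if decoy.records and not decoy.is_decoy:
        raise ValueError("second argument must be a decoy database")
    merged = ProteinDatabase(list(target.records) + list(decoy.records),
                             is_decoy=False, decoy_prefix=decoy.decoy_prefix)
    return merged
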