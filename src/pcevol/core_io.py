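"""Sequence and alignment data model plus FASTA input/output.

All sequences are held internally in the RNA alphabet (``T`` is normalised
to ``U`` on input and the DNA origin is remembered so output can restore
it).  Coordinates throughout the package are 0-based, half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: residues permitted after normalisation
ALPHABET = frozenset("ACGUN-")

_COMPLEMENT = str.maketrans("ACGUN-", "UGCAN-")


class FastaFormatError(ValueError):
    """Raised when a FASTA file is malformed or violates an invariant."""


class AlignmentError(ValueError):
    """Raised when records cannot form a valid alignment."""


def normalize_residues(raw: str) -> tuple[str, str]:
    """Fold case, map T->U and validate the alphabet.

    Returns ``(residues, molecule)`` where *molecule* is ``"DNA"`` if any
    ``T`` was seen and ``"RNA"`` otherwise.  Ambiguity codes other than
    ``N`` are rejected.
    """
    upper = raw.upper().replace(" ", "")
    molecule = "DNA" if "T" in upper else "RNA"
    residues = upper.replace("T", "U")
    bad = set(residues) - ALPHABET
    if bad:
        raise FastaFormatError(
            f"disallowed symbol(s) {sorted(bad)}; only A/C/G/T/U/N/- are accepted"
        )
    return residues, molecule


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence in the internal RNA alphabet."""

    id: str
    residues: str
    description: str = ""
    molecule: str = "RNA"  # "DNA" or "RNA": alphabet of the source file

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FastaFormatError(f"record {self.id!r}: disallowed symbols {sorted(bad)}")
        if self.molecule not in ("DNA", "RNA"):
            raise ValueError(f"molecule must be 'DNA' or 'RNA', got {self.molecule!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, residues=self.residues.translate(_COMPLEMENT)[::-1])

    @classmethod
    def from_raw(cls, id: str, raw: str, description: str = "") -> "SequenceRecord":
        residues, molecule = normalize_residues(raw)
        return cls(id=id, residues=residues, description=description, molecule=molecule)


def revcomp(seq: str) -> str:
    """Reverse complement in the internal RNA alphabet (gaps/N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Alignment:
    """An ordered collection of equal-length gapped records."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"records have unequal lengths {sorted(lengths)}; not an alignment"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record id(s) {dup}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def columns(self, interval: tuple[int, int]) -> "Alignment":
        """Restrict to a [start, end) column window."""
        s, e = interval
        if not (0 <= s <= e <= self.n_columns):
            raise AlignmentError(f"interval {interval} outside 0..{self.n_columns}")
        return Alignment([replace(r, residues=r.residues[s:e]) for r in self.records])


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gapped) FASTA file into normalised records.

    ``T`` is folded to ``U`` and the DNA origin recorded per record.
    """
    path = Path(path)
    _precheck_fasta(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord.from_raw(rec.id, str(rec.seq), rec.description))
        except FastaFormatError as exc:
            raise FastaFormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def _precheck_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            return
    raise FastaFormatError(f"{path}: empty file")


def read_alignment(path: str | Path) -> Alignment:
    """Read FASTA as an alignment; unequal lengths raise :class:`AlignmentError`."""
    return Alignment(read_fasta(path))


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records to FASTA, restoring T for DNA-origin records."""
    records = list(records)
    if not records:
        warnings.warn(f"writing empty FASTA to {path}", stacklevel=2)
        Path(path).write_text("")
        return
    out = []
    for r in records:
        seq = r.residues.replace("U", "T") if r.molecule == "DNA" else r.residues
        desc = r.description if r.description and r.description != r.id else ""
        out.append(SeqRecord(Seq(seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(out)


def as_alignment(seqs: Sequence[str], ids: Sequence[str] | None = None) -> Alignment:
    """Convenience constructor from raw strings (tests, simulations)."""
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    return Alignment(
        [SequenceRecord.from_raw(i, s) for i, s in zip(ids, seqs, strict=True)]
    )
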