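"""FASTA input/output, header label parsing and dataset curation.

The classifier consumes labeled protein datasets in FASTA format.  A record's
subtype label (one of the eleven P-type ATPase subtypes 1A..5B) travels in the
header as the last ``|``-separated field of the first whitespace-delimited
token, e.g. ``>Q9XES1|2B calcium pump``.  Curation follows two rules applied
in order: records containing characters outside the configured amino-acid
alphabet are dropped, then records whose residue string exactly duplicates an
earlier-kept record are dropped (first occurrence wins).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

from Bio import SeqIO

from .errors import DuplicateIdError, EmptyDatasetError, FastaFormatError

#: The eleven P-type ATPase subtypes, named for the transported substrate
#: taxonomy (1A..5B).
SUBTYPES: tuple[str, ...] = (
    "1A", "1B", "2A", "2B", "2C", "2D", "3A", "3B", "4", "5A", "5B",
)

#: The twenty standard amino-acid letters; ambiguity codes (B, J, O, U, X, Z)
#: are deliberately absent and count as invalid characters during curation.
STANDARD_ALPHABET: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Width at which write_fasta wraps sequence lines.
FASTA_WIDTH = 60

# A label parser maps the full header line (without '>') to (id, label).
HeaderParser = Callable[[str], tuple[str, Optional[str]]]


def pipe_label_parser(
    allowed: Optional[Iterable[str]] = SUBTYPES, delimiter: str = "|"
) -> HeaderParser:
    """Build the default header dialect parser.

    The first whitespace-delimited token of the header is split on
    ``delimiter``; if the last field is a member of ``allowed`` it is taken as
    the label and the id is the remainder.  ``allowed=None`` accepts any
    non-empty last field as a label (useful for synthetic class names).
    """
    allowed_set = None if allowed is None else frozenset(allowed)

    def parse(header: str) -> tuple[str, Optional[str]]:
        token = header.split()[0] if header.split() else header
        parts = token.split(delimiter)
        if len(parts) >= 2 and parts[-1]:
            if allowed_set is None or parts[-1] in allowed_set:
                return delimiter.join(parts[:-1]), parts[-1]
        return token, None

    return parse


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with an optional subtype label."""

    id: str
    residues: str
    label: Optional[str] = None
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


class Dataset:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        self._by_id: dict[str, SequenceRecord] = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise DuplicateIdError(f"duplicate record id {rec.id!r}")
            self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key) -> SequenceRecord:
        if isinstance(key, str):
            return self._by_id[key]
        return self.records[key]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def __eq__(self, other) -> bool:
        return isinstance(other, Dataset) and self.records == other.records

    @property
    def labeled(self) -> bool:
        """True when every record carries a label."""
        return all(r.label is not None for r in self.records)

    @property
    def labels(self) -> list[str]:
        """Sorted distinct labels present in the dataset."""
        return sorted({r.label for r in self.records if r.label is not None})

    def subset(self, ids: Iterable[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset(r for r in self.records if r.id in wanted)


@dataclass
class CurationLog:
    """Record of curation removals: (id, reason) with reason in
    {invalid_character, duplicate}."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.removed)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\treason\n")
            for rec_id, reason in self.removed:
                fh.write(f"{rec_id}\t{reason}\n")


def read_fasta(path, label_parser: Optional[HeaderParser] = None) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    Residues are uppercased, whitespace stripped, and a single trailing stop
    character ``*`` removed.  Labels are extracted with ``label_parser``
    (default: :func:`pipe_label_parser` restricted to the eleven subtypes).

    Raises
    ------
    FastaFormatError
        If sequence data precedes the first header (with the line number).
    EmptyDatasetError
        If the file contains no records.
    DuplicateIdError
        If two records resolve to the same id.
    """
    parser = label_parser or pipe_label_parser()
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaFormatError(
                f"sequence data before the first '>' header in {path.name}",
                line=lineno,
            )
        break
    records = []
    for seqrec in SeqIO.parse(io.StringIO(text), "fasta"):
        header = seqrec.description
        rec_id, label = parser(header)
        residues = str(seqrec.seq).upper().replace(" ", "")
        residues = residues.rstrip("*")
        if not residues:
            raise FastaFormatError(f"record {rec_id!r} has an empty sequence")
        token = header.split()[0] if header.split() else header
        description = header[len(token):].strip()
        records.append(
            SequenceRecord(id=rec_id, residues=residues, label=label,
                           description=description)
        )
    if not records:
        raise EmptyDatasetError(f"no FASTA records in {path}")
    return Dataset(records)


def curate(
    ds: Dataset, alphabet: frozenset[str] | set[str] = STANDARD_ALPHABET
) -> tuple[Dataset, CurationLog]:
    """Apply the curation rules: drop invalid-character records, then exact
    duplicate sequences (first occurrence kept).  Order is otherwise
    preserved.  Idempotent.
    """
    if len(ds) == 0:
        raise EmptyDatasetError("cannot curate an empty dataset")
    alphabet = frozenset(alphabet)
    log = CurationLog()
    kept: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in ds:
        if not set(rec.residues) <= alphabet:
            log.removed.append((rec.id, "invalid_character"))
            continue
        if rec.residues in seen:
            log.removed.append((rec.id, "duplicate"))
            continue
        seen.add(rec.residues)
        kept.append(rec)
    if not kept:
        raise EmptyDatasetError("curation removed every record")
    return Dataset(kept), log


def write_fasta(ds: Dataset, path, width: int = FASTA_WIDTH) -> None:
    """Write a dataset as FASTA, encoding labels as ``id|label`` headers.

    ``read_fasta(write_fasta(ds))`` reproduces ids, labels and residues
    exactly (descriptions are carried along after the id token).
    """
    if len(ds) == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    with open(path, "w") as fh:
        for rec in ds:
            token = rec.id if rec.label is None else f"{rec.id}|{rec.label}"
            header = f">{token} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def relabel(rec: SequenceRecord, label: Optional[str]) -> SequenceRecord:
    """Return a copy of ``rec`` with a different label."""
    return replace(rec, label=label)
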