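"""PROSITE pattern parsing and scanning.

Implements the pattern mini-language used by PROSITE entries: ``-``-separated
elements that are a fixed residue, a choice set ``[..]``, an exclusion set
``{..}``, or the wildcard ``x``, each optionally repeated ``(n)`` or ranged
``(n,m)``; ``<`` and ``>`` anchor to the termini.  The shipped default is
PS00154, ``D-K-T-G-T-[LIVM]-[TI]`` — the phosphorylation-site motif
characteristic of P-type ATPases — used here as the gate that nominates
candidate sequences for subtype classification.

Matches are reported at every start position (overlaps allowed); for
variable-length patterns one match per start is reported, taking the shortest
extent.  Positions are 1-based inclusive, following PROSITE/UniProt
convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import PatternSyntaxError
from .seqio import Dataset, SequenceRecord

#: PROSITE PS00154, the P-type ATPase phosphorylation-site signature.
PS00154 = "D-K-T-G-T-[LIVM]-[TI]"

_AA = "ACDEFGHIKLMNPQRSTVWY"
_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


@dataclass(frozen=True)
class PatternElement:
    """One position spec: kind in {fixed, choice, exclusion, wildcard}."""

    kind: str
    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def to_regex(self) -> str:
        if self.kind == "fixed":
            body = next(iter(self.residues))
        elif self.kind == "choice":
            body = "[" + "".join(sorted(self.residues)) + "]"
        elif self.kind == "exclusion":
            body = "[^" + "".join(sorted(self.residues)) + "]"
        else:  # wildcard
            body = "."
        if (self.min_repeat, self.max_repeat) == (1, 1):
            return body
        if self.min_repeat == self.max_repeat:
            return f"{body}{{{self.min_repeat}}}"
        # non-greedy: shortest extent per start position
        return f"{body}{{{self.min_repeat},{self.max_repeat}}}?"


@dataclass(frozen=True)
class PrositePattern:
    """A parsed PROSITE pattern."""

    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False
    source: str = ""

    def to_regex(self) -> str:
        body = "".join(e.to_regex() for e in self.elements)
        if self.anchored_start:
            body = "^" + body
        if self.anchored_end:
            body += "$"
        return body


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence; start/end are 1-based inclusive."""

    record_id: str
    start: int
    end: int
    matched: str


def parse_prosite(pattern: str) -> PrositePattern:
    """Parse a PROSITE-syntax pattern string.

    Raises :class:`PatternSyntaxError` with the 1-based token position on any
    malformed token.
    """
    text = pattern.strip().rstrip(".")
    if not text:
        raise PatternSyntaxError("empty pattern", 0)
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    tokens = text.split("-")
    elements: list[PatternElement] = []
    for pos, token in enumerate(tokens, start=1):
        token = token.strip()
        if not token:
            raise PatternSyntaxError("empty token", pos)
        lo, hi = 1, 1
        m = _REPEAT_RE.search(token)
        if m:
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if lo > hi or lo < 0 or hi == 0:
                raise PatternSyntaxError(f"bad repeat count in {token!r}", pos)
            token = token[: m.start()]
        if token.startswith("[") and token.endswith("]"):
            body = token[1:-1]
            kind = "choice"
        elif token.startswith("{") and token.endswith("}"):
            body = token[1:-1]
            kind = "exclusion"
        elif token in ("x", "X"):
            body = _AA
            kind = "wildcard"
        elif len(token) == 1 and token.upper() in _AA:
            body = token.upper()
            kind = "fixed"
        else:
            raise PatternSyntaxError(f"unknown token {token!r}", pos)
        body = body.upper()
        if not body or not set(body) <= set(_AA):
            raise PatternSyntaxError(
                f"empty or non-amino-acid set in {token!r}", pos
            )
        elements.append(
            PatternElement(kind=kind, residues=frozenset(body),
                           min_repeat=lo, max_repeat=hi)
        )
    return PrositePattern(
        elements=tuple(elements),
        anchored_start=anchored_start,
        anchored_end=anchored_end,
        source=pattern,
    )


def scan(record: SequenceRecord, pattern: PrositePattern) -> list[MotifMatch]:
    """Find all motif occurrences in a record (one per matching start)."""
    regex = re.compile(f"(?=({pattern.to_regex()}))")
    matches = []
    for m in regex.finditer(record.residues):
        sub = m.group(1)
        start = m.start() + 1
        matches.append(
            MotifMatch(record_id=record.id, start=start,
                       end=start + len(sub) - 1, matched=sub)
        )
    return matches


def screen(ds: Dataset, pattern: PrositePattern) -> Dataset:
    """Subset of ``ds`` whose records contain at least one motif match;
    record order preserved.  An empty result is legal."""
    return Dataset(r for r in ds if scan(r, pattern))
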