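"""Homology search used as the classifier's distance function.

The k-NN classifier measures "distance" between a query and the training
sequences the way a protein BLAST search does: an affine-gap local alignment
score converted to a bit score and E-value with Karlin-Altschul statistics,

    bits = (lambda * S - ln kappa) / ln 2,      E = m * n * 2**(-bits),

where ``S`` is the raw alignment score, ``m`` the query length and ``n`` the
summed database length.  Two interchangeable backends satisfy one ``Hit``
contract: an internal k-mer-seeded searcher whose candidates are scored with
an exact Smith-Waterman engine (Bio.Align.PairwiseAligner), and an adapter
for externally produced 12-column tabular hit files (BLAST ``-outfmt 6``),
so genuine BLAST output can drive the classifier unchanged.

Deviations from BLAST proper are deliberate and documented: no two-hit
triggering or X-drop extension (candidates get exact local alignment), and no
composition-based or length-corrected statistics.  Classification depends on
E-value *ordering*, which these simplifications preserve.

Defaults mirror common protein-BLAST practice: BLOSUM62, gap open 11 /
extend 1, word size 3, E-value cutoff 10, gapped constants lambda=0.267,
kappa=0.041.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import EmptyDatasetError, ParameterError, TabularFormatError
from .seqio import Dataset, SequenceRecord

_LN2 = math.log(2.0)


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul
    constants.

    ``gap_open`` and ``gap_extend`` follow the BLAST convention: a gap of
    length L costs ``gap_open + L * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    kappa: float = 0.041
    word_size: int = 3
    max_evalue: float = 10.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ParameterError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ParameterError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.kappa <= 0:
            raise ParameterError("lambda and kappa must be positive")
        self.matrix = substitution_matrices.load(self.matrix_name)
        self._aligner: Optional[Align.PairwiseAligner] = None

    def make_aligner(self) -> Align.PairwiseAligner:
        # the configured aligner is stateless across calls; cache it
        if self._aligner is not None:
            return self._aligner
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # PairwiseAligner charges open_gap_score on the first gapped column,
        # so BLAST's open+extend for a length-1 gap maps to -(open+extend).
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        self._aligner = aligner
        return aligner


@dataclass(frozen=True)
class Hit:
    """One search result against a single subject sequence."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0


@dataclass
class LocalAlignment:
    """Result of an exact local alignment."""

    raw_score: int
    identity: float
    #: 1-based inclusive spans; all zero when the optimum is the empty
    #: alignment (no positive-scoring residue pair).
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0
    #: matching columns and total alignment columns backing ``identity``.
    n_identical: int = 0
    n_columns: int = 0


def smith_waterman(a: str, b: str, scheme: Optional[ScoringScheme] = None
                   ) -> LocalAlignment:
    """Optimal affine-gap local alignment of two residue strings.

    Identity is matching columns divided by alignment columns (gapped columns
    included).  A pair with no positive-scoring alignment returns score 0
    with empty spans.
    """
    if not a or not b:
        raise ParameterError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.make_aligner()
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return LocalAlignment(raw_score=0, identity=0.0)
    aln = alignments[0]
    score = alignments.score
    counts = aln.counts()
    n_cols = aln.length
    n_id = counts.identities
    qa, sa = aln.aligned  # lists of (start, end) blocks, 0-based half-open
    return LocalAlignment(
        raw_score=int(round(score)),
        identity=n_id / n_cols if n_cols else 0.0,
        q_start=int(qa[0][0]) + 1,
        q_end=int(qa[-1][1]),
        s_start=int(sa[0][0]) + 1,
        s_end=int(sa[-1][1]),
        n_identical=int(n_id),
        n_columns=int(n_cols),
    )


def evalue_from_score(raw_score: int, m: int, n: int,
                      scheme: Optional[ScoringScheme] = None
                      ) -> tuple[float, float]:
    """Karlin-Altschul bit score and E-value for a raw alignment score.

    ``m`` is the query length and ``n`` the total database length.
    """
    if m <= 0 or n <= 0:
        raise ParameterError("search-space dimensions must be positive")
    if raw_score < 0:
        raise ParameterError("raw_score must be non-negative")
    scheme = scheme or ScoringScheme()
    bits = (scheme.lam * raw_score - math.log(scheme.kappa)) / _LN2
    evalue = m * n * 2.0 ** (-bits)
    return bits, evalue


class SearchIndex:
    """Exact k-mer postings over a subject dataset.

    Stands in for a formatted BLAST database: candidate subjects for a query
    are those sharing at least one word.
    """

    def __init__(self, records: Dataset, word_size: int):
        if word_size < 2:
            raise ParameterError("word_size must be at least 2")
        if len(records) == 0:
            raise EmptyDatasetError("cannot index an empty dataset")
        self.records = records
        self.word_size = word_size
        self.kmer_table: dict[str, list[tuple[str, int]]] = {}
        for rec in records:
            seq = rec.residues
            for off in range(len(seq) - word_size + 1):
                word = seq[off : off + word_size]
                self.kmer_table.setdefault(word, []).append((rec.id, off))
        self.total_length = sum(len(r) for r in records)


def build_index(db: Dataset, word_size: int = 3) -> SearchIndex:
    """Index a curated subject dataset for seeded searching."""
    return SearchIndex(db, word_size)


def seeded_search(
    query: SequenceRecord,
    index: SearchIndex,
    scheme: Optional[ScoringScheme] = None,
    max_evalue: Optional[float] = None,
    self_exclude: bool = False,
    with_alignment: bool = True,
) -> list[Hit]:
    """Search a query against an indexed database.

    Candidate subjects are those sharing at least one word with the query;
    each candidate is scored with the exact local aligner, converted to bit
    score / E-value against the whole database length, filtered at
    ``max_evalue`` and returned sorted by (E-value asc, bit score desc,
    subject id asc).  With ``self_exclude`` the subject whose id equals the
    query's is dropped (database-screening use; irrelevant in
    cross-validation where the query is never indexed).
    ``with_alignment=False`` skips traceback, leaving identity and
    coordinates zeroed — scores, bit scores and E-values are unaffected;
    classification only consumes those.
    """
    scheme = scheme or ScoringScheme()
    if max_evalue is None:
        max_evalue = scheme.max_evalue
    w = index.word_size
    seq = query.residues
    candidates: set[str] = set()
    for off in range(len(seq) - w + 1):
        for subject_id, _ in index.kmer_table.get(seq[off : off + w], ()):
            candidates.add(subject_id)
    if self_exclude:
        candidates.discard(query.id)
    aligner = scheme.make_aligner()
    m, n = len(seq), index.total_length
    hits: list[Hit] = []
    for subject_id in candidates:
        subject = index.records[subject_id]
        score = max(aligner.score(seq, subject.residues), 0.0)
        bits, evalue = evalue_from_score(int(round(score)), m, n, scheme)
        if evalue > max_evalue:
            continue
        if with_alignment and score > 0:
            aln = smith_waterman(seq, subject.residues, scheme)
        else:
            aln = LocalAlignment(raw_score=int(round(score)), identity=0.0)
        hits.append(
            Hit(
                query_id=query.id,
                subject_id=subject_id,
                raw_score=aln.raw_score,
                bit_score=bits,
                evalue=evalue,
                identity=aln.identity,
                q_start=aln.q_start,
                q_end=aln.q_end,
                s_start=aln.s_start,
                s_end=aln.s_end,
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.bit_score, h.subject_id))
    return hits


def local_identity(a: str, b: str, scheme: Optional[ScoringScheme] = None,
                   denominator: str = "shorter") -> float:
    """Sequence identity on the optimal local alignment.

    ``denominator`` selects the convention: ``"shorter"`` (CD-HIT style,
    matches over the shorter sequence length — used by the clustering module)
    or ``"columns"`` (matches over alignment columns).
    """
    aln = smith_waterman(a, b, scheme)
    if denominator == "shorter":
        return aln.n_identical / min(len(a), len(b))
    if denominator == "columns":
        return aln.identity
    raise ParameterError(f"unknown identity denominator {denominator!r}")


def read_tabular_hits(path) -> dict[str, list[Hit]]:
    """Read a standard 12-column tabular hit file (BLAST ``-outfmt 6``).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore.  Hits are grouped by query in file order; percent
    identity is converted to a fraction.  An empty file yields an empty map.
    """
    result: dict[str, list[Hit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise TabularFormatError(
                    f"expected 12 tab-separated columns, got {len(fields)}",
                    lineno,
                )
            try:
                hit = Hit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    raw_score=0,  # raw score is not part of outfmt 6
                    bit_score=float(fields[11]),
                    evalue=float(fields[10]),
                    identity=float(fields[2]) / 100.0,
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                )
            except ValueError as exc:
                raise TabularFormatError(str(exc), lineno) from exc
            result.setdefault(hit.query_id, []).append(hit)
    return result
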