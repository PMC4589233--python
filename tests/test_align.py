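"""Alignment engine, Karlin-Altschul statistics, seeded search and the
tabular-hit adapter, each checked against independent oracles."""

import math
import random

import pytest
from Bio.Align import substitution_matrices

import homotype as ht
from homotype.errors import (
    EmptyDatasetError,
    ParameterError,
    TabularFormatError,
)
from oracles import brute_force_local_affine, karlin_altschul

AA = "ACDEFGHIKLMNPQRSTVWY"
B62 = substitution_matrices.load("BLOSUM62")


def _rec(rec_id, residues, label="1A"):
    return ht.SequenceRecord(id=rec_id, residues=residues, label=label)


# ---------------------------------------------------------------- alignment

def test_self_alignment_scores_the_diagonal(scoring):
    seq = "MDKTGTLTQNKM"
    aln = ht.smith_waterman(seq, seq, scoring)
    assert aln.raw_score == sum(B62[c, c] for c in seq)
    assert aln.identity == 1.0
    assert (aln.q_start, aln.q_end) == (1, len(seq))


def test_no_positive_pair_scores_zero(scoring):
    # G-W scores negatively in BLOSUM62, so no local alignment survives
    aln = ht.smith_waterman("GGGG", "WWWW", scoring)
    assert aln.raw_score == 0
    assert (aln.q_start, aln.q_end, aln.s_start, aln.s_end) == (0, 0, 0, 0)


def test_alignment_matches_brute_force_on_random_50mers(scoring):
    rng = random.Random(123)
    for _ in range(12):
        a = "".join(rng.choice(AA) for _ in range(50))
        b = "".join(rng.choice(AA) for _ in range(50))
        expected = brute_force_local_affine(a, b, scoring.gap_open,
                                            scoring.gap_extend)
        assert ht.smith_waterman(a, b, scoring).raw_score == expected


def test_alignment_matches_brute_force_on_related_pairs(scoring):
    """Gapped cases: mutated + indel-bearing copies exercise the affine
    path."""
    rng = random.Random(5)
    base = "".join(rng.choice(AA) for _ in range(60))
    for _ in range(6):
        b = list(base)
        for _ in range(6):
            b[rng.randrange(len(b))] = rng.choice(AA)
        cut = rng.randrange(10, 40)
        b = b[:cut] + b[cut + rng.randrange(1, 5):]  # deletion
        b = "".join(b)
        expected = brute_force_local_affine(base, b, scoring.gap_open,
                                            scoring.gap_extend)
        assert ht.smith_waterman(base, b, scoring).raw_score == expected


def test_empty_sequence_rejected(scoring):
    with pytest.raises(ParameterError):
        ht.smith_waterman("", "MKV", scoring)


# ------------------------------------------------------------- KA statistics

def test_evalue_at_score_zero_is_kappa_mn(scoring):
    _, evalue = ht.evalue_from_score(0, 100, 2000, scoring)
    assert evalue == pytest.approx(scoring.kappa * 100 * 2000)


def test_evalue_linear_in_database_length(scoring):
    _, e1 = ht.evalue_from_score(80, 100, 1000, scoring)
    _, e2 = ht.evalue_from_score(80, 100, 2000, scoring)
    assert e2 == pytest.approx(2 * e1)


@pytest.mark.parametrize("score,m,n", [(0, 10, 10), (40, 250, 10000),
                                       (120, 500, 500000), (300, 80, 1200)])
def test_evalue_matches_independent_formula(scoring, score, m, n):
    bits, evalue = ht.evalue_from_score(score, m, n, scoring)
    exp_bits, exp_e = karlin_altschul(score, m, n, scoring.lam, scoring.kappa)
    assert bits == pytest.approx(exp_bits)
    assert evalue == pytest.approx(exp_e, rel=1e-9)


def test_evalue_monotone_decreasing_in_score(scoring):
    evalues = [ht.evalue_from_score(s, 100, 10000, scoring)[1]
               for s in range(0, 200, 10)]
    assert all(a > b for a, b in zip(evalues, evalues[1:]))


def test_evalue_rejects_bad_search_space(scoring):
    with pytest.raises(ParameterError):
        ht.evalue_from_score(10, 0, 100, scoring)


# ------------------------------------------------------------------- index

def test_index_postings_enumerated():
    ds = ht.Dataset([_rec("a", "MKVM")])
    idx = ht.build_index(ds, word_size=2)
    assert set(idx.kmer_table) == {"MK", "KV", "VM"}
    assert idx.kmer_table["MK"] == [("a", 0)]
    assert idx.total_length == 4


def test_index_rejects_bad_input():
    with pytest.raises(EmptyDatasetError):
        ht.build_index(ht.Dataset([]), 3)
    with pytest.raises(ParameterError):
        ht.build_index(ht.Dataset([_rec("a", "MKVM")]), 1)


def test_index_total_length_sums_members(family4):
    ds, _ = family4
    idx = ht.build_index(ds, 3)
    assert idx.total_length == sum(len(r) for r in ds)


# ------------------------------------------------------------ seeded search

def test_identical_subject_ranks_first(scoring, family4):
    ds, _ = family4
    idx = ht.build_index(ds, scoring.word_size)
    query = ht.SequenceRecord(id="q", residues=ds[0].residues)
    hits = ht.seeded_search(query, idx, scoring)
    assert hits[0].subject_id == ds[0].id
    assert hits[0].evalue == min(h.evalue for h in hits)


def test_no_shared_word_means_no_hits(scoring):
    idx = ht.build_index(ht.Dataset([_rec("a", "MKVMKV")]), 3)
    query = ht.SequenceRecord(id="q", residues="GGAGGA")
    assert ht.seeded_search(query, idx, scoring) == []


def test_self_exclusion_flag(scoring, family4):
    ds, _ = family4
    idx = ht.build_index(ds, scoring.word_size)
    hits = ht.seeded_search(ds[0], idx, scoring, self_exclude=True)
    assert all(h.subject_id != ds[0].id for h in hits)


def test_search_is_deterministic(scoring, family4):
    ds, _ = family4
    idx = ht.build_index(ds, scoring.word_size)
    h1 = ht.seeded_search(ds[3], idx, scoring)
    h2 = ht.seeded_search(ds[3], idx, scoring)
    assert h1 == h2


def test_search_agrees_with_exhaustive_oracle(scoring):
    """On a small instance the seeded search must rank subjects exactly as
    brute-force optimal alignment scores do."""
    rng = random.Random(77)
    base = "".join(rng.choice(AA) for _ in range(80))
    subjects = []
    for i in range(12):
        s = list(base)
        for _ in range(rng.randrange(4, 40)):
            s[rng.randrange(len(s))] = rng.choice(AA)
        subjects.append(_rec(f"s{i:02d}", "".join(s)))
    ds = ht.Dataset(subjects)
    idx = ht.build_index(ds, scoring.word_size)
    query = ht.SequenceRecord(id="q", residues=base)
    hits = ht.seeded_search(query, idx, scoring, max_evalue=float("inf"))
    oracle = {
        r.id: brute_force_local_affine(base, r.residues, scoring.gap_open,
                                       scoring.gap_extend)
        for r in subjects
    }
    assert len(hits) == len(subjects)
    for h in hits:
        assert h.raw_score == oracle[h.subject_id]
    ranked = [h.raw_score for h in hits]
    assert ranked == sorted(ranked, reverse=True)


# ---------------------------------------------------------- tabular adapter

TABULAR = (
    "q1\ts1\t98.50\t200\t3\t0\t1\t200\t1\t200\t1e-180\t520.1\n"
    "q1\ts2\t45.00\t180\t90\t4\t5\t184\t3\t178\t2.5e-30\t120.4\n"
)


def test_read_tabular_hits(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(TABULAR)
    hits = ht.read_tabular_hits(p)
    assert list(hits) == ["q1"]
    assert len(hits["q1"]) == 2
    first = hits["q1"][0]
    assert first.evalue == 1e-180
    assert first.identity == pytest.approx(0.985)
    assert first.bit_score == pytest.approx(520.1)
    assert (first.q_start, first.q_end) == (1, 200)


def test_read_tabular_empty_file(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    assert ht.read_tabular_hits(p) == {}


def test_read_tabular_wrong_column_count(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("q1\ts1\t98.5\n")
    with pytest.raises(TabularFormatError) as exc:
        ht.read_tabular_hits(p)
    assert exc.value.line == 1
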