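"""k-NN voting: majority and E-value-weighted schemes, tie handling, and
batch prediction."""

import pytest

import homotype as ht
from homotype.classify import vote_from_hits
from homotype.errors import ConfigurationError, ParameterError


def _hit(subject, evalue, query="q"):
    return ht.Hit(query_id=query, subject_id=subject, raw_score=100,
                  bit_score=50.0, evalue=evalue, identity=0.9)


LABELS = {"n1": "2B", "n2": "2B", "n3": "1A", "n4": "1A", "n5": "3A"}


def test_unweighted_majority():
    hits = [_hit("n1", 1e-30), _hit("n2", 1e-20), _hit("n3", 1e-10)]
    pred = vote_from_hits("q", hits, LABELS, k=3, scheme="unweighted")
    assert pred.label == "2B"
    assert pred.tallies == {"2B": 2.0, "1A": 1.0}
    assert pred.status == "classified" and not pred.tie_break


def test_weighted_vote_arithmetic():
    # class A: {1e-10, 1e-8} -> mean 5.05e-9; class B: {1e-20} -> B wins
    labels = {"a1": "A", "a2": "A", "b1": "B"}
    hits = [_hit("b1", 1e-20), _hit("a1", 1e-10), _hit("a2", 1e-8)]
    pred = vote_from_hits("q", hits, labels, k=3, scheme="weighted")
    assert pred.label == "B"
    assert pred.tallies["A"] == pytest.approx(5.05e-9)
    assert pred.tallies["B"] == pytest.approx(1e-20)


def test_k1_returns_top_hit_label_under_both_schemes():
    hits = [_hit("n3", 1e-40), _hit("n1", 1e-30)]
    for scheme in ht.SCHEMES:
        pred = vote_from_hits("q", hits, LABELS, k=1, scheme=scheme)
        assert pred.label == "1A"
        assert len(pred.neighbors) == 1


def test_zero_hits_is_unclassified_never_a_default():
    for scheme in ht.SCHEMES:
        pred = vote_from_hits("q", [], LABELS, k=5, scheme=scheme)
        assert pred.status == "unclassified"
        assert pred.label is None and pred.neighbors == []


def test_fewer_hits_than_k_votes_over_available():
    hits = [_hit("n1", 1e-30), _hit("n3", 1e-20)]
    pred = vote_from_hits("q", hits, LABELS, k=10, scheme="unweighted")
    assert len(pred.neighbors) == 2
    assert sum(pred.tallies.values()) == 2


def test_unweighted_tie_broken_by_smaller_mean_evalue():
    hits = [_hit("n1", 1e-30), _hit("n3", 1e-40)]  # 2B vs 1A, one vote each
    pred = vote_from_hits("q", hits, LABELS, k=2, scheme="unweighted")
    assert pred.label == "1A"  # smaller E-value
    assert pred.tie_break


def test_zero_evalue_class_dominates_weighted_vote():
    labels = {"a1": "A", "b1": "B"}
    hits = [_hit("a1", 0.0), _hit("b1", 1e-300)]
    pred = vote_from_hits("q", hits, labels, k=2, scheme="weighted")
    assert pred.label == "A"


def test_duplicate_subject_hits_collapse_to_one_vote():
    hits = [_hit("n1", 1e-30), _hit("n1", 1e-10), _hit("n3", 1e-20)]
    pred = vote_from_hits("q", hits, LABELS, k=3, scheme="unweighted")
    assert sum(pred.tallies.values()) == 2  # n1 votes once


def test_weighted_argmin_invariant_under_evalue_scaling():
    labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    hits = [_hit("a1", 1e-12), _hit("b1", 3e-12), _hit("a2", 5e-11),
            _hit("b2", 2e-10)]
    base = vote_from_hits("q", hits, labels, k=4, scheme="weighted")
    for c in (1e-5, 1.0, 1e7):
        scaled = [ht.Hit(**{**h.__dict__, "evalue": h.evalue * c})
                  for h in hits]
        pred = vote_from_hits("q", scaled, labels, k=4, scheme="weighted")
        assert pred.label == base.label


def test_invalid_k_and_scheme_rejected():
    with pytest.raises(ParameterError):
        vote_from_hits("q", [], LABELS, k=0, scheme="weighted")
    with pytest.raises(ParameterError):
        vote_from_hits("q", [], LABELS, k=1, scheme="plurality")


def test_unlabeled_training_set_rejected(family4, scoring):
    ds, _ = family4
    unlabeled = ht.Dataset(
        ht.SequenceRecord(id=r.id, residues=r.residues) for r in ds
    )
    with pytest.raises(ConfigurationError):
        ht.knn_predict(ds[0], unlabeled, k=1, scoring=scoring)


def test_batch_preserves_order_and_recovers_own_labels(family4, scoring):
    ds, _ = family4
    queries = ht.Dataset(list(ds)[:6])
    preds = ht.predict_batch(queries, ds, k=1, scheme="weighted",
                             scoring=scoring)
    assert [p.query_id for p in preds] == [q.id for q in queries]
    # self-exclusion off: the identity hit dominates
    assert all(p.label == q.label for p, q in zip(preds, queries))


def test_prediction_invariant_to_training_order(family4, scoring):
    ds, _ = family4
    reversed_ds = ht.Dataset(list(ds)[::-1])
    q = ht.SequenceRecord(id="q", residues=ds[5].residues)
    p1 = ht.knn_predict(q, ds, k=3, scheme="unweighted", scoring=scoring)
    p2 = ht.knn_predict(q, reversed_ds, k=3, scheme="unweighted",
                        scoring=scoring)
    assert p1.label == p2.label
    assert [h.subject_id for h, _ in p1.neighbors] == [
        h.subject_id for h, _ in p2.neighbors
    ]


def test_held_out_queries_recover_class_labels(family4, scoring):
    """Leave-members-out: each class's held-out member is recovered from the
    remaining training sequences."""
    ds, _ = family4
    held_ids = {r.id for r in ds if r.id.endswith("m00")}
    train = ht.Dataset(r for r in ds if r.id not in held_ids)
    queries = ht.Dataset(r for r in ds if r.id in held_ids)
    preds = ht.predict_batch(queries, train, k=1, scoring=scoring)
    assert all(p.label == q.label for p, q in zip(preds, queries))
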