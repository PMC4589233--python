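"""k-nearest-neighbor subtype prediction over ranked homology hits.

The neighbors of a query are the top ``k`` training sequences returned by
the homology search, ranked by E-value.  Two voting schemes are supported:

* **unweighted** — plain majority over neighbor labels; ties broken by the
  smaller mean E-value among tied classes, then lexicographic label order.
* **weighted** — each class receives weight
  ``sum(E-values of its neighbors) / count(its neighbors)`` and the
  *minimum*-weight class wins (small E-values mean close homology).

At ``k = 1`` both schemes reduce to a plain homology search: the top hit's
label is returned, so their predictions coincide per query.  A query with no
hits at all is reported ``unclassified`` rather than assigned a default
class; evaluation counts it as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .align import Hit, ScoringScheme, SearchIndex, build_index, seeded_search
from .errors import ConfigurationError, ParameterError
from .seqio import Dataset, SequenceRecord

SCHEMES = ("unweighted", "weighted")


@dataclass
class Prediction:
    """Outcome of classifying one query."""

    query_id: str
    label: Optional[str]
    scheme: str
    k: int
    neighbors: list[tuple[Hit, str]] = field(default_factory=list)
    tallies: dict[str, float] = field(default_factory=dict)
    status: str = "classified"
    tie_break: bool = False


def _vote(neighbors: list[tuple[Hit, str]], scheme: str
          ) -> tuple[str, dict[str, float], bool]:
    """Apply a voting scheme to (hit, label) neighbors; returns (winner,
    tallies, tie_break_used)."""
    by_class: dict[str, list[Hit]] = {}
    for hit, label in neighbors:
        by_class.setdefault(label, []).append(hit)
    if scheme == "unweighted":
        tallies = {c: float(len(hits)) for c, hits in by_class.items()}
        best = max(tallies.values())
        tied = sorted(c for c, v in tallies.items() if v == best)
        if len(tied) == 1:
            return tied[0], tallies, False
        # tie: smaller mean E-value among tied classes, then label order
        mean_e = {c: sum(h.evalue for h in by_class[c]) / len(by_class[c])
                  for c in tied}
        winner = min(tied, key=lambda c: (mean_e[c], c))
        return winner, tallies, True
    if scheme == "weighted":
        tallies = {c: sum(h.evalue for h in hits) / len(hits)
                   for c, hits in by_class.items()}
        best = min(tallies.values())
        tied = sorted(c for c, v in tallies.items() if v == best)
        return tied[0], tallies, len(tied) > 1
    raise ParameterError(f"unknown vote scheme {scheme!r}")


def _dedupe_best_per_subject(hits: Sequence[Hit]) -> list[Hit]:
    """One vote per training sequence: keep only the best-ranked hit for each
    subject (hits arrive already sorted by rank)."""
    seen: set[str] = set()
    out = []
    for h in hits:
        if h.subject_id not in seen:
            seen.add(h.subject_id)
            out.append(h)
    return out


def vote_from_hits(query_id: str, hits: Sequence[Hit],
                   labels: dict[str, str], k: int, scheme: str) -> Prediction:
    """Build a :class:`Prediction` from an already-ranked hit list.

    Backend-agnostic core: the hits may come from the internal seeded search
    or from an external tabular file.  ``labels`` maps subject id to class.
    """
    if k < 1:
        raise ParameterError("k must be a positive integer")
    if scheme not in SCHEMES:
        raise ParameterError(f"unknown vote scheme {scheme!r}")
    hits = _dedupe_best_per_subject(hits)
    neighbors = [(h, labels[h.subject_id]) for h in hits[:k]]
    if not neighbors:
        return Prediction(query_id=query_id, label=None, scheme=scheme, k=k,
                          status="unclassified")
    winner, tallies, tie = _vote(neighbors, scheme)
    return Prediction(query_id=query_id, label=winner, scheme=scheme, k=k,
                      neighbors=neighbors, tallies=tallies,
                      status="classified", tie_break=tie)


def _labels_of(training: Dataset) -> dict[str, str]:
    labels: dict[str, str] = {}
    for rec in training:
        if rec.label is None:
            raise ConfigurationError(
                f"training record {rec.id!r} has no subtype label"
            )
        labels[rec.id] = rec.label
    return labels


def knn_predict(
    query: SequenceRecord,
    training: Union[Dataset, SearchIndex],
    k: int = 1,
    scheme: str = "weighted",
    scoring: Optional[ScoringScheme] = None,
    self_exclude: bool = False,
) -> Prediction:
    """Classify one query against a labeled training set (or prebuilt
    index)."""
    scoring = scoring or ScoringScheme()
    if isinstance(training, SearchIndex):
        index = training
    else:
        index = build_index(training, scoring.word_size)
    labels = _labels_of(index.records)
    hits = seeded_search(query, index, scoring, self_exclude=self_exclude,
                         with_alignment=False)
    return vote_from_hits(query.id, hits, labels, k, scheme)


def predict_batch(
    queries: Dataset,
    training: Union[Dataset, SearchIndex],
    k: int = 1,
    scheme: str = "weighted",
    scoring: Optional[ScoringScheme] = None,
    self_exclude: bool = False,
) -> list[Prediction]:
    """Classify every query, preserving query order; the training index is
    built once."""
    scoring = scoring or ScoringScheme()
    if isinstance(training, SearchIndex):
        index = training
    else:
        index = build_index(training, scoring.word_size)
    _labels_of(index.records)  # validate up front
    return [knn_predict(q, index, k, scheme, scoring, self_exclude)
            for q in queries]


def predictions_to_rows(predictions: Sequence[Prediction]) -> list[dict]:
    """Flatten predictions for CSV output: query, label, status, k, scheme,
    tallies, and the top neighbor's id and E-value."""
    rows = []
    for p in predictions:
        top = p.neighbors[0][0] if p.neighbors else None
        rows.append({
            "query_id": p.query_id,
            "predicted_label": p.label if p.label is not None else "",
            "status": p.status,
            "k": p.k,
            "scheme": p.scheme,
            "tallies": ";".join(
                f"{c}={v:.6g}" for c, v in sorted(p.tallies.items())
            ),
            "top_neighbor": top.subject_id if top else "",
            "top_evalue": f"{top.evalue:.6g}" if top else "",
        })
    return rows
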