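"""Repeated, shuffled, non-stratified k-fold cross-validation.

The evaluation protocol: shuffle the labeled dataset, split it into
``n_folds`` near-equal contiguous parts (no label balancing), train the
classifier on all-but-one part and predict the held-out part, once per part;
pooling the predictions over the parts gives one *run* accuracy.  The run is
repeated ``n_runs`` times with fresh shuffles and the mean and standard
deviation of the run accuracies are reported per (k, vote scheme).
Unclassified predictions count as errors.

Reproducibility: a single master seed spawns one RNG substream per run, so
adding runs never perturbs earlier ones, and (dataset, config) determine the
report exactly.  Each query is searched once per fold; votes for every k and
scheme are derived from that single ranked hit list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .align import ScoringScheme, build_index, seeded_search
from .classify import SCHEMES, vote_from_hits
from .cluster import cluster_greedy, representatives
from .errors import ConfigurationError, ParameterError
from .seqio import Dataset


@dataclass
class CVConfig:
    """Cross-validation protocol parameters."""

    n_folds: int = 5
    n_runs: int = 20
    k_values: Sequence[int] = (1,)
    schemes: Union[str, Sequence[str]] = SCHEMES
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ParameterError("n_folds must be at least 2")
        if self.n_runs < 1:
            raise ParameterError("n_runs must be at least 1")
        if isinstance(self.schemes, str):
            self.schemes = (self.schemes,)
        self.schemes = tuple(self.schemes)
        self.k_values = tuple(int(k) for k in self.k_values)
        if any(k < 1 for k in self.k_values):
            raise ParameterError("all k values must be positive")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ParameterError(f"unknown vote scheme {s!r}")


@dataclass
class CVReport:
    """Per-(k, scheme) run accuracies with summary statistics."""

    n_folds: int
    n_records: int
    #: (k, scheme) -> list of per-run pooled accuracies
    run_accuracies: dict[tuple[int, str], list[float]] = field(
        default_factory=dict
    )

    def mean_accuracy(self, k: int, scheme: str) -> float:
        return float(np.mean(self.run_accuracies[(k, scheme)]))

    def sd_accuracy(self, k: int, scheme: str) -> float:
        accs = self.run_accuracies[(k, scheme)]
        if len(accs) < 2:
            return 0.0
        return float(np.std(accs, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-run table: k, scheme, run, accuracy."""
        rows = [
            {"k": k, "scheme": s, "run": i, "accuracy": a}
            for (k, s), accs in sorted(self.run_accuracies.items())
            for i, a in enumerate(accs)
        ]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        """Summary table: k, scheme, mean accuracy, sd."""
        rows = [
            {"k": k, "scheme": s, "mean_accuracy": self.mean_accuracy(k, s),
             "sd_accuracy": self.sd_accuracy(k, s)}
            for (k, s) in sorted(self.run_accuracies)
        ]
        return pd.DataFrame(rows)


def make_folds(ds: Dataset, n_folds: int,
               rng: np.random.Generator) -> list[tuple[Dataset, Dataset]]:
    """Shuffle and split into ``n_folds`` (train, test) partitions.

    Test parts are disjoint, cover the dataset, and differ in size by at
    most one; no stratification by label is applied.
    """
    if n_folds > len(ds):
        raise ParameterError(
            f"n_folds={n_folds} exceeds dataset size {len(ds)}"
        )
    order = rng.permutation(len(ds))
    parts = np.array_split(order, n_folds)
    folds = []
    for i, test_idx in enumerate(parts):
        test_set = set(int(j) for j in test_idx)
        train = Dataset(ds[int(j)] for j in order if int(j) not in test_set)
        test = Dataset(ds[int(j)] for j in test_idx)
        folds.append((train, test))
    return folds


def run_cv(ds: Dataset, cfg: CVConfig,
           scoring: Optional[ScoringScheme] = None) -> CVReport:
    """Run the full repeated cross-validation protocol."""
    if not ds.labeled:
        raise ConfigurationError("cross-validation requires a labeled dataset")
    scoring = scoring or ScoringScheme()
    report = CVReport(n_folds=cfg.n_folds, n_records=len(ds))
    combos = [(k, s) for k in cfg.k_values for s in cfg.schemes]
    for k, s in combos:
        report.run_accuracies[(k, s)] = []
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    for run_stream in streams:
        rng = np.random.default_rng(run_stream)
        correct = {combo: 0 for combo in combos}
        for train, test in make_folds(ds, cfg.n_folds, rng):
            index = build_index(train, scoring.word_size)
            labels = {r.id: r.label for r in train}
            for query in test:
                hits = seeded_search(query, index, scoring,
                                     with_alignment=False)
                for k, s in combos:
                    pred = vote_from_hits(query.id, hits, labels, k, s)
                    if pred.status == "classified" and pred.label == query.label:
                        correct[(k, s)] += 1
        for combo in combos:
            report.run_accuracies[combo].append(correct[combo] / len(ds))
    return report


def reduced_dataset_cv(
    ds: Dataset,
    thresholds: Sequence[float],
    cfg: CVConfig,
    scoring: Optional[ScoringScheme] = None,
) -> dict[float, Union[CVReport, Exception]]:
    """Cluster at each identity threshold, keep the representatives, and
    cross-validate the reduced dataset.

    A threshold whose reduced dataset is smaller than ``n_folds`` maps to the
    error instead of aborting the other thresholds.
    """
    scoring = scoring or ScoringScheme()
    out: dict[float, Union[CVReport, Exception]] = {}
    for t in thresholds:
        reduced = representatives(cluster_greedy(ds, t, scoring))
        if len(reduced) < cfg.n_folds:
            out[t] = ParameterError(
                f"reduced dataset at threshold {t} has {len(reduced)} "
                f"records, fewer than n_folds={cfg.n_folds}"
            )
            continue
        out[t] = run_cv(reduced, cfg, scoring)
    return out
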