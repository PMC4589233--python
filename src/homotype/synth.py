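"""Synthetic labeled protein-family generator.

Emulates the statistical structure of a curated subtype dataset: each class
descends from its own random ancestor, classes are mutually dissimilar
(rejection-sampled below ``inter_identity_max``), and members are ancestor
copies with i.i.d. point substitutions at rate ``1 - intra_identity``
(uniform over the 19 alternative residues — the simplest model sufficient to
create identity-controlled classes).  Optionally each class ancestor carries
a planted PS00154-satisfying motif (``DKTGT`` plus one residue from LIVM and
one from TI); the motif window is excluded from mutation so every member
retains an exact copy and motif screening keeps the whole dataset.

Real subtype classes are not star phylogenies: they contain several
homologous subfamilies whose members are much closer to each other than to
the rest of the class.  ``n_subfamilies > 1`` reproduces this with a
two-level hierarchy — subfamily ancestors derived from the class ancestor at
``subfamily_identity``, members derived from their subfamily ancestor at
``intra_identity``.  This hierarchical shape is what makes
identity-reduction experiments meaningful: clustering collapses subfamilies,
not whole classes.

Not modelled: indels, rate heterogeneity across sites, realistic
substitution biases, guide trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import ScoringScheme, local_identity
from .errors import GenerationError, ParameterError
from .seqio import SUBTYPES, Dataset, SequenceRecord

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_MOTIF_LEN = 7

#: rejection-sampling iteration cap per ancestor
_MAX_REJECT = 200


@dataclass
class SynthConfig:
    """Parameters of the synthetic family generator."""

    n_classes: int = 4
    per_class: int = 10
    seq_length: int = 300
    intra_identity: float = 0.9
    inter_identity_max: float = 0.5
    plant_motif: bool = True
    seed: int = 0
    #: >1 gives each class a two-level subfamily hierarchy
    n_subfamilies: int = 1
    #: identity of subfamily ancestors to the class ancestor (only used when
    #: n_subfamilies > 1)
    subfamily_identity: float = 0.6
    #: class labels; default: the eleven subtype names, then C12, C13, ...
    labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise ParameterError("need at least 2 classes")
        if self.per_class < 1:
            raise ParameterError("need at least 1 member per class")
        if not 0.0 < self.inter_identity_max < self.intra_identity <= 1.0:
            raise ParameterError(
                "require 0 < inter_identity_max < intra_identity <= 1"
            )
        if self.seq_length < 2 * _MOTIF_LEN:
            raise ParameterError("seq_length too short")
        if self.n_subfamilies < 1:
            raise ParameterError("n_subfamilies must be at least 1")
        if self.labels is None:
            base = list(SUBTYPES[: self.n_classes])
            base += [f"C{i}" for i in range(len(base) + 1,
                                            self.n_classes + 1)]
            self.labels = base
        self.labels = list(self.labels)
        if len(self.labels) != self.n_classes:
            raise ParameterError("labels must match n_classes")


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return _AA[rng.integers(0, len(_AA), size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            protected: Optional[range] = None) -> np.ndarray:
    """Substitute each position with probability ``rate``, uniformly over the
    19 alternative residues; positions in ``protected`` are left intact."""
    out = seq.copy()
    if rate <= 0.0:
        return out
    hit = rng.random(len(seq)) < rate
    if protected is not None:
        hit[protected.start : protected.stop] = False
    for i in np.flatnonzero(hit):
        choices = _AA[_AA != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def _plant_motif(seq: np.ndarray, offset: int,
                 rng: np.random.Generator) -> None:
    motif = list("DKTGT")
    motif.append(rng.choice(list("LIVM")))
    motif.append(rng.choice(list("TI")))
    seq[offset : offset + _MOTIF_LEN] = motif


def generate(cfg: SynthConfig,
             scoring: Optional[ScoringScheme] = None
             ) -> tuple[Dataset, pd.DataFrame]:
    """Generate a labeled dataset plus a ground-truth manifest.

    The manifest has one row per record: id, class, subfamily, and the
    realized (Hamming) identity of the member to its immediate ancestor.
    Deterministic given the seed.
    """
    scoring = scoring or ScoringScheme()
    rng = np.random.default_rng(cfg.seed)
    ancestors: list[np.ndarray] = []
    motif_windows: list[Optional[range]] = []
    for _ in range(cfg.n_classes):
        for _attempt in range(_MAX_REJECT):
            cand = _random_sequence(cfg.seq_length, rng)
            window = None
            if cfg.plant_motif:
                offset = int(rng.integers(_MOTIF_LEN,
                                          cfg.seq_length - 2 * _MOTIF_LEN))
                _plant_motif(cand, offset, rng)
                window = range(offset, offset + _MOTIF_LEN)
            cand_str = "".join(cand)
            if all(
                local_identity(cand_str, "".join(a), scoring)
                < cfg.inter_identity_max
                for a in ancestors
            ):
                ancestors.append(cand)
                motif_windows.append(window)
                break
        else:
            raise GenerationError(
                "could not sample mutually dissimilar ancestors; "
                "lower inter_identity_max or raise seq_length"
            )
    records: list[SequenceRecord] = []
    manifest_rows: list[dict] = []
    for c, (label, ancestor) in enumerate(zip(cfg.labels, ancestors)):
        window = motif_windows[c]
        if cfg.n_subfamilies > 1:
            sub_ancestors = [
                _mutate(ancestor, 1.0 - cfg.subfamily_identity, rng, window)
                for _ in range(cfg.n_subfamilies)
            ]
        else:
            sub_ancestors = [ancestor]
        for j in range(cfg.per_class):
            sf = j % len(sub_ancestors)
            parent = sub_ancestors[sf]
            member = _mutate(parent, 1.0 - cfg.intra_identity, rng, window)
            realized = float(np.mean(member == parent))
            rec_id = f"syn{c:02d}m{j:02d}"
            records.append(
                SequenceRecord(id=rec_id, residues="".join(member),
                               label=label)
            )
            manifest_rows.append({
                "id": rec_id,
                "class": label,
                "subfamily": sf,
                "identity_to_ancestor": realized,
            })
    return Dataset(records), pd.DataFrame(manifest_rows)
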