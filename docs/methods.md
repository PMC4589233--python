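# Methods

## Model

A protein's subtype is predicted from its nearest homologs. The "distance"
between a query and a reference sequence is that of a protein BLAST search:
the optimal affine-gap local alignment score *S* is converted to a bit score
and E-value with Karlin–Altschul statistics,

    bits = (λ·S − ln κ) / ln 2,        E = m · n · 2^(−bits),

where *m* is the query length and *n* the summed length of the reference
set. Hits are ranked by (E-value ascending, bit score descending, subject id
ascending) — the explicit tie-break makes every run byte-reproducible. The
top *k* hits vote: unweighted majority, or weighted with class weight
*w(c)* = mean E-value of class-*c* hits and the minimum-weight class
winning. At *k* = 1 the two schemes coincide per query, which the tests
assert as an exact per-query property, not just an equality of accuracies.

The underlying assumption is that subtype membership is congruent with
sequence similarity — classes form homology clusters separated from one
another. Both the cross-validation results and the identity-reduction
experiment probe exactly this assumption.

## Search engine

Candidates are found by shared fixed-length words (default word size 3) in
an exact k-mer index, then scored with an exact Smith–Waterman affine-gap
local alignment (Bio.Align.PairwiseAligner's C kernel configured from the
package's `ScoringScheme`). We deliberately do not reproduce BLAST's
two-hit trigger or X-drop gapped extension: exact candidate scoring is
affordable at the package's dataset scales, is deterministic, and makes the
seeded search provably agree with exhaustive Smith–Waterman ranking (a
property the test suite checks against an independently written dynamic
program). Composition-based statistics and length corrections to E-values
are likewise omitted; classification depends on E-value *ordering* and
class-relative magnitude, both of which survive this simplification. For
byte-parity with genuine BLAST runs, a 12-column tabular (`-outfmt 6`)
adapter feeds external hits into the identical voting code path.

Gap penalties follow the BLAST convention (a gap of length L costs
open + L·extend); PairwiseAligner charges its open score on the first
gapped column, so open 11 / extend 1 maps to −12 / −1 internally.

## Defaults and parameters

| parameter | default | rationale |
|---|---|---|
| substitution matrix | BLOSUM62 | standard protein-search default |
| gap open / extend | 11 / 1 | standard protein-search default |
| λ, κ (gapped) | 0.267, 0.041 | published gapped constants for BLOSUM62 11/1 |
| word size | 3 | protein-BLAST default |
| E-value cutoff | 10 | protein-BLAST default; hits above it never vote |
| k | 1 | empirically optimal; larger k only dilutes the vote |
| vote scheme | weighted | degrades more gracefully at large k |

All are configurable on `ScoringScheme` and via CLI flags.

## Curation and gating

Curation removes records with characters outside the 20-letter amino-acid
alphabet (ambiguity codes B, J, O, U, X, Z count as invalid), then exact
duplicate sequences, first occurrence kept — two order-stable rules that
make curation idempotent and give |kept| + |removed| = |input|. The PROSITE
gate accepts the full pattern mini-grammar (fixed residues, `[..]`, `{..}`,
`x`, repeats `(n)`/`(n,m)`, anchors `<`/`>`); PS00154 is the shipped
default. A match anywhere in the sequence suffices. For variable-length
elements one match per start position is reported, at the shortest extent;
PS00154 itself is fixed-length.

## Clustering

Greedy incremental clustering in CD-HIT's style: sequences sorted by
decreasing length (id as tie-break), each joining the first representative
it matches at ≥ threshold identity, where identity is matching columns of
the optimal local alignment divided by the shorter sequence's length.
CD-HIT's word-count pre-filters and banded alignment are speed heuristics,
not semantics, and are not reproduced; exact alignment against
representatives preserves the greedy semantics at these scales.
Cluster-level agreement with CD-HIT is not promised — what matters
downstream is classification accuracy on the representative sets.

## Cross-validation protocol

Non-stratified, shuffled k-fold (default 5 folds): each run shuffles the
dataset, splits it into near-equal contiguous parts, trains on all-but-one
part and predicts the held-out part, and pools the predictions into one run
accuracy (pooling and fold-averaging coincide when folds are equal-sized;
pooling handles unequal folds coherently). Runs are repeated (default 20)
with fresh shuffles; the mean and sample standard deviation (ddof 1, zero
for a single run) are reported per (k, scheme). A master seed spawns one
RNG substream per run, so adding runs never perturbs earlier ones.
Unclassified predictions count as errors. Each test query is searched once
per fold; votes for every k and scheme are derived from that single ranked
hit list.

## Synthetic data generator

The generator emulates the statistical structure of a curated subtype
collection: each class descends from a random ancestor (i.i.d. uniform
residues), ancestors are rejection-sampled to pairwise local identity below
`inter_identity_max`, and members are ancestor copies with i.i.d.
substitutions at rate 1 − `intra_identity`, uniform over the 19 alternative
residues. With `n_subfamilies > 1` each class gains a two-level hierarchy —
subfamily ancestors at `subfamily_identity` to the class ancestor, members
at `intra_identity` to their subfamily ancestor. The hierarchy is essential
for the identity-reduction experiment: real subtype classes contain several
homologous subfamilies, so clustering at 75% or 50% identity collapses
subfamilies but keeps multiple representatives per class. A flat
one-ancestor model would collapse each class to a near-singleton, and with
non-stratified folds a class whose few representatives all land in one test
fold is unclassifiable at k = 1 for structural reasons unrelated to the
method. When motif planting is on, a PS00154-satisfying heptamer is written
into each ancestor and its window is excluded from mutation, so every
member carries an exact copy and motif screening retains the whole dataset.

Not modelled: indels, site-rate heterogeneity, substitution-matrix-biased
mutation, realistic background composition (uniform by default), and
phylogenetic tree structure within subfamilies. Passing tests on this
generator therefore demonstrate the machinery and the
similarity-implies-subtype mechanism, not performance on real sequences
with indels and biased composition.

## Experiment scales

The packaged experiments run on generated datasets of 11 classes × 12
members (6 subfamilies per class, length 240, ~90% intra-subfamily and
<50% inter-class identity) for the curation, cross-validation and
identity-reduction results, and 6 classes × 12 members for the
accuracy-versus-k trend — sizes chosen so the full suite and the
acceptance script each complete in minutes on a single CPU while keeping
every structural feature of the larger setting (eleven classes, per-class
subfamily redundancy, near-even fold splits). Cross-validation repeats are
correspondingly reduced (2–3 runs in tests, versus 20 in the protocol's
default configuration); with separable classes the run-to-run spread is
exactly zero, so additional repeats only confirm the zero standard
deviation.

## Numerical and degenerate-input choices

* Raw scores are integers; a pair with no positive-scoring alignment gets
  score 0, empty spans, and survives only if κ·m·n ≤ the E-value cutoff.
* E-values of exactly 0 (possible in external BLAST output) are kept as 0
  in class-weight sums; a zero-weight class can be beaten only by another
  zero-weight class, then the lexicographic tie-break applies.
* Unweighted class ties break by smaller mean E-value, then label order;
  the prediction records that a tie-break fired.
* Multiple hits on one subject collapse to the best-ranked hit — one vote
  per training sequence.
* Fewer than k hits: the available hits vote; zero hits: `unclassified`.
* Curating away every record, clustering thresholds outside (0, 1], folds
  exceeding the dataset size, and word sizes below 2 are hard errors, not
  silent degradations.

## Known limitations

* E-values lack BLAST's length and composition corrections, so their
  absolute magnitudes differ from BLAST's; parity with external searches is
  at the level of classification outcomes (the tabular adapter exists for
  exact-parity workflows).
* The greedy clusterer is quadratic in the number of clusters per record
  and intended for datasets up to a few thousand sequences.
* Accuracy estimates on synthetic families are optimistic for real data in
  exact proportion to how much cleaner the generator's classes are than
  real subtype boundaries; the generator's separation parameters are the
  knobs to stress this.
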