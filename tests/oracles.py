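"""Independent reference implementations used only to cross-check the
package.

These are deliberately written from first principles — a plain Gotoh
three-state dynamic program for affine-gap local alignment and an
enumerate-everything PROSITE matcher — and share no code path with the
package modules they validate.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_affine(a: str, b: str, gap_open: int = 11,
                             gap_extend: int = 1) -> int:
    """Optimal local alignment score, affine gaps (BLAST convention: a gap of
    length L costs gap_open + L * gap_extend)."""
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            sub = H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0, sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = int(H[i][j])
    return best


def karlin_altschul(raw_score: int, m: int, n: int, lam: float,
                    kappa: float) -> tuple[float, float]:
    """Bit score and E-value, written straight from the defining formulas."""
    bits = (lam * raw_score - math.log(kappa)) / math.log(2.0)
    return bits, m * n * math.exp(-bits * math.log(2.0))


def _expand_elements(elements):
    """Yield every concrete sequence of position sets a pattern can take."""
    per_element = []
    for kind, residues, lo, hi in elements:
        if kind == "fixed":
            allowed = set(residues)
        elif kind == "choice":
            allowed = set(residues)
        elif kind == "exclusion":
            allowed = set("ACDEFGHIKLMNPQRSTVWY") - set(residues)
        else:  # wildcard
            allowed = set("ACDEFGHIKLMNPQRSTVWY")
        per_element.append([[allowed] * r for r in range(lo, hi + 1)])
    for combo in itertools.product(*per_element):
        yield [s for chunk in combo for s in chunk]


def brute_force_prosite_starts(seq: str, elements) -> set[int]:
    """All 0-based start offsets where the pattern matches.

    ``elements`` is a list of (kind, residues, min_repeat, max_repeat)
    tuples.  Every expansion of variable-length elements is tried at every
    offset.
    """
    starts = set()
    expansions = list(_expand_elements(elements))
    for off in range(len(seq)):
        for sets in expansions:
            if off + len(sets) > len(seq):
                continue
            if all(seq[off + i] in allowed for i, allowed in enumerate(sets)):
                starts.add(off)
                break
    return starts
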