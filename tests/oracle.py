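"""Independent scoring oracles for local alignment tests.

``brute_force_best`` enumerates every canonical gapped local alignment by
depth-first search and scores it directly — no dynamic-programming
matrices — so it is usable only at tiny sequence lengths. Canonical means
a gap run in one sequence is never immediately followed by a gap run in
the other (the standard alignment convention, matched by the engine's
recurrences); under the basic model the restriction does not change the
optimum because every gap column costs the same.

``biopython_best`` asks Bio.Align.PairwiseAligner for the optimal local
score. Its gap model permits adjacent opposite-sequence gap runs, which a
three-state affine recurrence does not; the two models share the same
optimum whenever every substitution score is >= -2 * gap_extension, so
affine comparisons must use schemes generated with ``free_model_safe``.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from localsw import ScoringScheme

DIAG, GAP_Q, GAP_T = 0, 1, 2


def brute_force_best(q: str, t: str, scheme: ScoringScheme) -> float:
    """Best local alignment score by exhaustive path enumeration."""
    n, m = len(q), len(t)
    g_open = scheme.gap_open_penalty
    g_ext = scheme.gap_extension_penalty if scheme.affine else scheme.gap_open_penalty
    sub = scheme.substitution
    best = 0.0

    def dfs(i: int, j: int, score: float, last: int) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            dfs(i + 1, j + 1, score + sub(q[i], t[j]), DIAG)
        if i < n and last != GAP_T:
            dfs(i + 1, j, score - (g_ext if last == GAP_Q else g_open), GAP_Q)
        if j < m and last != GAP_Q:
            dfs(i, j + 1, score - (g_ext if last == GAP_T else g_open), GAP_T)

    # optimal local alignments start (and end) with an aligned column
    for i0 in range(n):
        for j0 in range(m):
            dfs(i0 + 1, j0 + 1, sub(q[i0], t[j0]), DIAG)
    return best


def biopython_best(q: str, t: str, scheme: ScoringScheme) -> float:
    """Optimal local score from Bio.Align.PairwiseAligner."""
    arr = substitution_matrices.Array(alphabet=scheme.alphabet, dims=2)
    for i, a in enumerate(scheme.alphabet):
        for j, b in enumerate(scheme.alphabet):
            arr[a, b] = scheme.matrix[i, j]
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = arr
    if scheme.affine:
        aligner.open_gap_score = -scheme.gap_open_penalty
        aligner.extend_gap_score = -scheme.gap_extension_penalty
    else:
        aligner.open_gap_score = -scheme.gap_open_penalty
        aligner.extend_gap_score = -scheme.gap_open_penalty
    return float(aligner.score(q, t))


def random_seq(rng: np.random.Generator, length: int,
               alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def random_scheme(rng: np.random.Generator, affine: bool,
                  alphabet: str = "ACGT",
                  free_model_safe: bool = False) -> ScoringScheme:
    """Random integer substitution table (asymmetric allowed) plus penalties.

    With ``free_model_safe`` every entry is >= -2 * gap_extension (or
    -2 * gap_open in basic mode), the regime where restricted and free gap
    placement agree — required when comparing against ``biopython_best``
    in affine mode, and for the affine/basic reduction property.
    """
    if affine:
        g_ext = int(rng.integers(1, 4))
        g_open = int(rng.integers(g_ext, 7))
        floor = -2 * g_ext if free_model_safe else -8
    else:
        g_open = int(rng.integers(1, 7))
        g_ext = 0
        floor = -2 * g_open if free_model_safe else -8
    k = len(alphabet)
    mat = rng.integers(floor, 4, size=(k, k)).astype(float)
    best = int(rng.integers(1, 7))
    mat[rng.integers(0, k), rng.integers(0, k)] = best  # ensure a positive max
    return ScoringScheme(alphabet, mat, float(g_open), float(g_ext))
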