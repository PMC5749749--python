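"""Smith-Waterman matrix fill, hit-start discovery and traceback.

Two gap models are supported, selected by the scoring scheme:

* **basic** (``gap_extension_penalty == 0``): a single score grid H with
  every gap column charged the full open penalty,

      H(i,j) = max(0, H(i-1,j-1) + s(q_i, t_j),
                      H(i-1,j) - g_o,  H(i,j-1) - g_o)

* **affine** (Gotoh): three grids — M for match/mismatch states, I for
  gaps in the target (query symbol over '-'), J for gaps in the query —

      M(i,j) = max(0, s(q_i, t_j) + max(M, I, J)(i-1, j-1))
      I(i,j) = max(M(i-1,j) - g_o,  I(i-1,j) - g_e)
      J(i,j) = max(M(i,j-1) - g_o,  J(i,j-1) - g_e)

  with the cell score max(M, I, J)(i,j), so a gap of length L costs
  g_o + (L-1) * g_e.

Cell scores are floored at zero (local alignment); a per-cell direction
record stores the move and, in affine mode, which grid won, which drives
the traceback. Sub-optimal hits are recovered by tracing every start
point above threshold in score order while skipping starts whose cell a
higher-scoring traceback already consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernel import NEG_INF, fill_block_affine, fill_block_basic
from .errors import InputError
from .filtering import FilterSettings, HitMetrics, compute_metrics, passes_filters
from .scoring import ScoringScheme

logger = logging.getLogger(__name__)

# move codes in the direction grid
STOP, DIAG, UP, LEFT = 0, 1, 2, 3
# origin-matrix codes
MAT_M, MAT_I, MAT_J = 0, 1, 2

GAP = "-"


def _residues(seq) -> str:
    return seq.residues if hasattr(seq, "residues") else str(seq)


def _seq_id(seq, default: str) -> str:
    return seq.id if hasattr(seq, "id") else default


@dataclass
class DPState:
    """Filled dynamic-programming matrices for one query/target pair.

    Grids have shape ``(n_rows + 1, n_cols + 1)``; row 0 and column 0 are
    boundary cells, interior cell (i, j) scores query residue i against
    target residue j (1-based). ``global_max`` is ``(score, row, col)``
    with ties resolved to the smallest (row, col).
    """

    mode: str                       # "basic" | "affine"
    n_rows: int
    n_cols: int
    scheme: ScoringScheme
    H: np.ndarray | None = None     # basic mode
    M: np.ndarray | None = None     # affine mode
    I: np.ndarray | None = None
    J: np.ndarray | None = None
    move: np.ndarray = None         # int8 direction grid
    origin: np.ndarray = None       # int8 winning-matrix grid (affine)
    global_max: tuple[float, int, int] = (0.0, 0, 0)
    visited: np.ndarray = field(default=None, repr=False)

    @property
    def cell_count(self) -> int:
        """Interior score cells allocated: n*m in basic mode, 3*n*m affine."""
        grids = 3 if self.mode == "affine" else 1
        return self.n_rows * self.n_cols * grids

    @property
    def cell_updates(self) -> int:
        """Cell updates performed by the fill (throughput accounting hook)."""
        return self.cell_count

    def cell_scores(self) -> np.ndarray:
        """Winning score of each interior cell, shape (n_rows, n_cols)."""
        if self.mode == "basic":
            return self.H[1:, 1:]
        return np.maximum(np.maximum(self.M, self.I), self.J)[1:, 1:]

    def direction(self, row: int, col: int) -> tuple[int, int]:
        """(origin_matrix, move) of interior cell (row, col), 1-based."""
        om = int(self.origin[row, col]) if self.origin is not None else MAT_M
        return om, int(self.move[row, col])


def new_state(query, target, scheme: ScoringScheme) -> DPState:
    """Allocate boundary-initialised matrices for a pair (no fill)."""
    q = _residues(query)
    t = _residues(target)
    if not q:
        raise InputError(f"empty query sequence {_seq_id(query, 'query')!r}")
    if not t:
        raise InputError(f"empty target sequence {_seq_id(target, 'target')!r}")
    n, m = len(q), len(t)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)
    if scheme.affine:
        M = np.zeros((n + 1, m + 1))
        I = np.full((n + 1, m + 1), NEG_INF)
        J = np.full((n + 1, m + 1), NEG_INF)
        origin = np.zeros((n + 1, m + 1), dtype=np.int8)
        state = DPState("affine", n, m, scheme, M=M, I=I, J=J,
                        move=move, origin=origin)
    else:
        state = DPState("basic", n, m, scheme, H=np.zeros((n + 1, m + 1)),
                        move=move)
    state.visited = np.zeros((n + 1, m + 1), dtype=bool)
    return state


def fill_block(state: DPState, q_codes, t_codes, sub, r0, r1, c0, c1) -> None:
    """Fill interior rows [r0, r1) x cols [c0, c1) (1-based bounds)."""
    if state.mode == "basic":
        fill_block_basic(q_codes, t_codes, sub, state.scheme.gap_open_penalty,
                         state.H, state.move, r0, r1, c0, c1)
    else:
        fill_block_affine(q_codes, t_codes, sub,
                          state.scheme.gap_open_penalty,
                          state.scheme.gap_extension_penalty,
                          state.M, state.I, state.J, state.move, state.origin,
                          r0, r1, c0, c1)


def finalize(state: DPState) -> DPState:
    """Locate the global maximum (score desc, then row asc, col asc)."""
    scores = state.cell_scores()
    flat = int(np.argmax(scores))          # first occurrence in row-major order
    row, col = divmod(flat, state.n_cols)
    state.global_max = (float(scores[row, col]), row + 1, col + 1)
    return state


def align_pair(query, target, scheme: ScoringScheme) -> DPState:
    """Fill the full matrices sequentially and locate the global maximum."""
    state = new_state(query, target, scheme)
    q_codes = scheme.encode(_residues(query))
    t_codes = scheme.encode(_residues(target))
    sub = scheme.encoded_matrix()
    fill_block(state, q_codes, t_codes, sub, 1, state.n_rows + 1,
               1, state.n_cols + 1)
    return finalize(state)


def find_hit_starts(state: DPState, filters: FilterSettings) -> list[tuple[float, int, int]]:
    """Cells worth backtracing: score >= max(minimum_score,
    lower_limit_score * global_max.score), best first.

    Returned as (score, row, col) sorted by score descending, ties broken
    by (row, col) ascending; empty when even the global maximum is below
    ``minimum_score``.
    """
    gmax = state.global_max[0]
    if gmax < filters.minimum_score:
        return []
    threshold = max(filters.minimum_score, filters.lower_limit_score * gmax)
    scores = state.cell_scores()
    rows, cols = np.nonzero(scores >= threshold)
    starts = [(float(scores[r, c]), int(r) + 1, int(c) + 1)
              for r, c in zip(rows, cols)]
    starts.sort(key=lambda s: (-s[0], s[1], s[2]))
    return starts


@dataclass
class Hit:
    """One local alignment with 1-based inclusive coordinates."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_query: str
    aligned_target: str
    score: float
    matches: int
    mismatches: int
    gap_columns: int
    metrics: HitMetrics | None = field(default=None, compare=False)

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_query)

    def validate(self, query: str | None = None, target: str | None = None) -> None:
        """Raise AssertionError if any structural invariant is broken."""
        la, lb = len(self.aligned_query), len(self.aligned_target)
        assert la == lb, "aligned strings differ in length"
        assert la == self.matches + self.mismatches + self.gap_columns, \
            "column counts do not add up"
        assert self.score > 0, "hit score must be positive"
        for a, b in zip(self.aligned_query, self.aligned_target):
            assert not (a == GAP and b == GAP), "column gapped on both sides"
        if query is not None:
            span = self.aligned_query.replace(GAP, "")
            assert span == query[self.query_start - 1:self.query_end], \
                "aligned query does not spell the query interval"
        if target is not None:
            span = self.aligned_target.replace(GAP, "")
            assert span == target[self.target_start - 1:self.target_end], \
                "aligned target does not spell the target interval"


def _count_columns(cols: list[tuple[str, str]]) -> tuple[int, int, int]:
    matches = mismatches = gaps = 0
    for a, b in cols:
        if a == GAP or b == GAP:
            gaps += 1
        elif a.upper() == b.upper():
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, gaps


def traceback(state: DPState, start: tuple[int, int], query, target) -> Hit:
    """Walk the direction record from ``start`` back to a zero cell.

    diag emits an aligned column, up emits (query symbol, '-') — a gap in
    the target — and left emits ('-', target symbol). Every traversed cell
    is marked visited so lower-scoring starts sharing the path are skipped.
    """
    i, j = start
    q = _residues(query)
    t = _residues(target)
    if state.mode == "basic":
        score = float(state.H[i, j])
    else:
        score = float(max(state.M[i, j], state.I[i, j], state.J[i, j]))
    if score <= 0:
        raise ValueError(f"traceback started on a non-positive cell ({i}, {j})")
    cols: list[tuple[str, str]] = []
    end = (i, j)
    if state.mode == "basic":
        move = state.move
        while move[i, j] != STOP:
            state.visited[i, j] = True
            mv = move[i, j]
            if mv == DIAG:
                cols.append((q[i - 1], t[j - 1]))
                i -= 1
                j -= 1
            elif mv == UP:
                cols.append((q[i - 1], GAP))
                i -= 1
            else:
                cols.append((GAP, t[j - 1]))
                j -= 1
    else:
        i, j = _walk_affine(state, i, j, q, t, cols)
    cols.reverse()
    matches, mismatches, gaps = _count_columns(cols)
    hit = Hit(
        query_id=_seq_id(query, "query"),
        target_id=_seq_id(target, "target"),
        query_start=i + 1,
        query_end=end[0],
        target_start=j + 1,
        target_end=end[1],
        aligned_query="".join(a for a, _ in cols),
        aligned_target="".join(b for _, b in cols),
        score=score,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
    )
    return hit


def _walk_affine(state: DPState, i: int, j: int, q: str, t: str,
                 cols: list) -> tuple[int, int]:
    """Gotoh traceback; transitions between M/I/J are reconstructed from
    the stored grids (exact float equality holds because the same
    expressions produced the stored values). Returns the cell just before
    the alignment start."""
    M, I, J = state.M, state.I, state.J
    g_o = state.scheme.gap_open_penalty
    g_e = state.scheme.gap_extension_penalty
    cur = int(state.origin[i, j])
    while True:
        state.visited[i, j] = True
        if cur == MAT_M:
            cols.append((q[i - 1], t[j - 1]))
            pm, pi, pj = M[i - 1, j - 1], I[i - 1, j - 1], J[i - 1, j - 1]
            prev = max(pm, pi, pj)
            i -= 1
            j -= 1
            if prev <= 0:
                return i, j
            if pm >= pi and pm >= pj:       # prefer M, then I, then J
                cur = MAT_M
            elif pi >= pj:
                cur = MAT_I
            else:
                cur = MAT_J
        elif cur == MAT_I:                  # gap in target, consume query
            cols.append((q[i - 1], GAP))
            cur = MAT_M if M[i - 1, j] - g_o == I[i, j] else MAT_I
            i -= 1
        else:                               # gap in query, consume target
            cols.append((GAP, t[j - 1]))
            cur = MAT_M if M[i, j - 1] - g_o == J[i, j] else MAT_J
            j -= 1


def align_all(queries, targets, scheme: ScoringScheme,
              filters: FilterSettings | None = None,
              backend=None) -> list[Hit]:
    """Align every query against every target and return the filtered hits.

    Hits are ordered by input pair (query-major), then by traceback start
    order (score descending). Starts whose cell was consumed by an earlier
    traceback of the same pair are skipped. Metrics are attached to every
    traced hit before filtering so rejected hits can be logged.
    """
    if not queries or not targets:
        raise InputError("align_all needs at least one query and one target")
    filters = filters if filters is not None else FilterSettings()
    filters.validate(scheme.max_match_score)
    hits: list[Hit] = []
    for query in queries:
        for target in targets:
            try:
                if backend is not None:
                    state = backend.align(query, target, scheme)
                else:
                    state = align_pair(query, target, scheme)
            except InputError:
                raise
            except Exception as exc:  # annotate with the offending pair
                raise InputError(
                    f"alignment failed for pair ({_seq_id(query, 'query')!r}, "
                    f"{_seq_id(target, 'target')!r}): {exc}") from exc
            qlen, tlen = state.n_rows, state.n_cols
            for _, row, col in find_hit_starts(state, filters):
                if state.visited[row, col]:
                    continue
                hit = traceback(state, (row, col), query, target)
                hit.metrics = compute_metrics(hit, qlen, tlen, scheme)
                verdict = passes_filters(hit.metrics, filters)
                if verdict.passed:
                    hits.append(hit)
                else:
                    logger.debug("rejected %s vs %s (score %.1f): failed %s",
                                 hit.query_id, hit.target_id, hit.score,
                                 ",".join(verdict.failed))
    return hits
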