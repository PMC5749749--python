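"""Cell-fill kernels for the Smith-Waterman recurrences.

The kernels fill a rectangular block [r0, r1) x [c0, c1) of the (n+1) x
(m+1) matrices in place; row 0 and column 0 are boundary cells. They are
written in nopython-compatible Python and JIT-compiled with numba when it
is importable; the undecorated functions compute identically (slower), so
the package has no hard runtime dependency on the compiler.

Conventions shared with the traceback code:
  move:   0 = stop, 1 = diag, 2 = up (gap in target), 3 = left (gap in query)
  origin: 0 = H/M,  1 = I,    2 = J
Ties prefer diag over up over left (equivalently M over I over J), so the
traceback is deterministic and gap-minimal.

In affine mode only M is floored at zero; I and J run on the standard
Gotoh-local treatment with a large negative boundary sentinel.
"""

import numpy as np

NEG_INF = -1.0e30


def _fill_block_basic(q, t, sub, gap_open, H, move, r0, r1, c0, c1):
    for i in range(r0, r1):
        qi = q[i - 1]
        for j in range(c0, c1):
            best = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            mv = 1
            up = H[i - 1, j] - gap_open
            if up > best:
                best = up
                mv = 2
            left = H[i, j - 1] - gap_open
            if left > best:
                best = left
                mv = 3
            if best <= 0.0:
                best = 0.0
                mv = 0
            H[i, j] = best
            move[i, j] = mv


def _fill_block_affine(q, t, sub, gap_open, gap_ext, M, I, J, move, origin,
                       r0, r1, c0, c1):
    for i in range(r0, r1):
        qi = q[i - 1]
        for j in range(c0, c1):
            prev = M[i - 1, j - 1]
            if I[i - 1, j - 1] > prev:
                prev = I[i - 1, j - 1]
            if J[i - 1, j - 1] > prev:
                prev = J[i - 1, j - 1]
            m = prev + sub[qi, t[j - 1]]
            if m < 0.0:
                m = 0.0
            i_open = M[i - 1, j] - gap_open
            i_ext = I[i - 1, j] - gap_ext
            ival = i_open if i_open >= i_ext else i_ext
            j_open = M[i, j - 1] - gap_open
            j_ext = J[i, j - 1] - gap_ext
            jval = j_open if j_open >= j_ext else j_ext
            M[i, j] = m
            I[i, j] = ival
            J[i, j] = jval
            best = m
            om = 0
            mv = 1
            if ival > best:
                best = ival
                om = 1
                mv = 2
            if jval > best:
                best = jval
                om = 2
                mv = 3
            if best <= 0.0:
                mv = 0
                om = 0
            move[i, j] = mv
            origin[i, j] = om


try:  # pragma: no cover - exercised implicitly by every alignment test
    from numba import njit

    fill_block_basic = njit(nogil=True, cache=True)(_fill_block_basic)
    fill_block_affine = njit(nogil=True, cache=True)(_fill_block_affine)
    JIT = True
except ImportError:  # pragma: no cover
    fill_block_basic = _fill_block_basic
    fill_block_affine = _fill_block_affine
    JIT = False
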