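"""Execution backends for the matrix fill.

The dynamic-programming grid is decomposed into rectangular blocks that
are processed in anti-diagonal batches: a block depends only on its left,
upper and upper-left neighbours, so all blocks with the same
``block_row + block_col`` are mutually independent and may run
concurrently. Batches are barrier-synchronised, every cell is written by
exactly one block, and the global maximum is reduced with a fixed
(score desc, row asc, col asc) comparator — so the result is cell-for-cell
identical to the sequential fill for every worker count and block size.

Workers are threads; the fill kernels release the GIL, so blocks within a
batch genuinely run in parallel on multi-core hosts.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

from . import core
from .core import DPState, _residues
from .errors import ConfigurationError
from .scoring import ScoringScheme

DEFAULT_BLOCK = 64
#: bytes per interior cell: one float64 score + one int8 direction entry,
#: per grid (affine mode has three grids plus the origin record)
_BYTES_PER_CELL = {"basic": 9, "affine": 28}


@dataclass(frozen=True)
class WavefrontPlan:
    """Block decomposition of an (n_rows x n_cols) grid.

    ``batches[k]`` holds the (block_row, block_col) indices with
    block_row + block_col == k; cell ranges are recovered from the block
    shape, clipped at the grid edge.
    """

    n_rows: int
    n_cols: int
    block_rows: int
    block_cols: int
    batches: tuple[tuple[tuple[int, int], ...], ...]

    @property
    def n_block_rows(self) -> int:
        return -(-self.n_rows // self.block_rows)

    @property
    def n_block_cols(self) -> int:
        return -(-self.n_cols // self.block_cols)

    def cell_range(self, block_row: int, block_col: int) -> tuple[int, int, int, int]:
        """Interior 1-based (r0, r1, c0, c1) bounds of one block."""
        r0 = block_row * self.block_rows + 1
        c0 = block_col * self.block_cols + 1
        r1 = min(r0 + self.block_rows, self.n_rows + 1)
        c1 = min(c0 + self.block_cols, self.n_cols + 1)
        return r0, r1, c0, c1


def plan_wavefront(n_rows: int, n_cols: int,
                   block_rows: int = DEFAULT_BLOCK,
                   block_cols: int = DEFAULT_BLOCK) -> WavefrontPlan:
    """Partition an n_rows x n_cols grid into anti-diagonal block batches."""
    for name, val in (("n_rows", n_rows), ("n_cols", n_cols),
                      ("block_rows", block_rows), ("block_cols", block_cols)):
        if val < 1:
            raise ConfigurationError(f"{name} must be >= 1, got {val}")
    nbr = -(-n_rows // block_rows)
    nbc = -(-n_cols // block_cols)
    batches = tuple(
        tuple((br, k - br) for br in range(max(0, k - nbc + 1), min(nbr, k + 1)))
        for k in range(nbr + nbc - 1)
    )
    return WavefrontPlan(n_rows, n_cols, block_rows, block_cols, batches)


def execute(plan: WavefrontPlan, query, target, scheme: ScoringScheme,
            workers: int = 1) -> DPState:
    """Fill the matrices block-wise according to ``plan``.

    The result is identical to :func:`localsw.core.align_pair` for any
    worker count; ``workers`` only controls how many blocks of one batch
    run concurrently.
    """
    state = core.new_state(query, target, scheme)
    if (state.n_rows, state.n_cols) != (plan.n_rows, plan.n_cols):
        raise ConfigurationError(
            f"plan is for a {plan.n_rows}x{plan.n_cols} grid but the pair "
            f"is {state.n_rows}x{state.n_cols}")
    q_codes = scheme.encode(_residues(query))
    t_codes = scheme.encode(_residues(target))
    sub = scheme.encoded_matrix()

    def run_block(block: tuple[int, int]) -> None:
        r0, r1, c0, c1 = plan.cell_range(*block)
        core.fill_block(state, q_codes, t_codes, sub, r0, r1, c0, c1)

    if workers <= 1:
        for batch in plan.batches:
            for block in batch:
                run_block(block)
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            for batch in plan.batches:
                # barrier between batches; list() propagates worker errors
                list(pool.map(run_block, batch))
    return core.finalize(state)


def limit_workers(requested: int, available: int | None = None) -> int:
    """Resolve a worker count; 0 (or None) means "use all available"."""
    if available is None:
        available = os.cpu_count() or 1
    if requested is None:
        requested = 0
    if requested < 0:
        raise ConfigurationError(f"worker count must be >= 0, got {requested}")
    if requested == 0:
        return available
    return min(requested, available)


def estimate_state_bytes(n_rows: int, n_cols: int, affine: bool) -> int:
    """Approximate matrix footprint of one pair alignment."""
    mode = "affine" if affine else "basic"
    return (n_rows + 1) * (n_cols + 1) * _BYTES_PER_CELL[mode]


def check_memory(n_rows: int, n_cols: int, affine: bool,
                 max_fraction: float | None,
                 total_bytes: int | None = None) -> None:
    """Reject a pair whose matrices would exceed the configured share of
    memory (``max_fraction`` in (0, 1]; None disables the check)."""
    if max_fraction is None:
        return
    if not 0.0 < max_fraction <= 1.0:
        raise ConfigurationError(
            f"maximum_memory_usage must be in (0, 1], got {max_fraction}")
    if total_bytes is None:
        pages = os.sysconf("SC_PHYS_PAGES")
        total_bytes = pages * os.sysconf("SC_PAGE_SIZE")
    need = estimate_state_bytes(n_rows, n_cols, affine)
    if need > max_fraction * total_bytes:
        raise ConfigurationError(
            f"a {n_rows}x{n_cols} alignment needs ~{need / 1e6:.0f} MB of "
            f"matrices, above the configured cap of "
            f"{max_fraction * total_bytes / 1e6:.0f} MB")


@dataclass
class SequentialBackend:
    """Reference backend: plain row-major fill of the whole grid."""

    max_memory_fraction: float | None = None

    def align(self, query, target, scheme: ScoringScheme) -> DPState:
        check_memory(len(_residues(query)), len(_residues(target)),
                     scheme.affine, self.max_memory_fraction)
        return core.align_pair(query, target, scheme)


@dataclass
class WavefrontBackend:
    """Block-wavefront backend; deterministic for any worker count."""

    workers: int = 0
    block_rows: int = DEFAULT_BLOCK
    block_cols: int = DEFAULT_BLOCK
    max_memory_fraction: float | None = None

    def align(self, query, target, scheme: ScoringScheme) -> DPState:
        n, m = len(_residues(query)), len(_residues(target))
        check_memory(n, m, scheme.affine, self.max_memory_fraction)
        plan = plan_wavefront(n, m, self.block_rows, self.block_cols)
        return execute(plan, query, target, scheme,
                       workers=limit_workers(self.workers))


def make_backend(device: str = "CPU", workers: int = 0,
                 block_rows: int = DEFAULT_BLOCK, block_cols: int = DEFAULT_BLOCK,
                 max_memory_fraction: float | None = None):
    """Backend factory keyed by device name (CPU | parallel-CPU)."""
    dev = device.replace("_", "-").upper()
    if dev == "CPU":
        return SequentialBackend(max_memory_fraction)
    if dev == "PARALLEL-CPU":
        return WavefrontBackend(workers, block_rows, block_cols,
                                max_memory_fraction)
    raise ConfigurationError(
        f"unknown device {device!r} (choose CPU or parallel-CPU)")
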