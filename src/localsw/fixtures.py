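"""Deterministic synthetic homologous sequence pairs.

Each generated target embeds a mutated copy of a query subsequence —
point substitutions at rate ``1 - identity``, single-residue indels at
``indel_rate`` per position — between random flanks; the true homologous
interval on both sequences is recorded so recovery (recall) can be scored
without external data. Decoy targets are i.i.d. uniform sequences of
matched length, the simplest null.

All randomness flows through numpy's PCG64 generator seeded from
``HomologySpec.seed``, so the same spec reproduces byte-identical
sequences on any platform.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io_formats import SequenceRecord

MANIFEST_COLUMNS = ("query_id", "target_id",
                    "query_start", "query_end", "target_start", "target_end")


@dataclass(frozen=True)
class HomologySpec:
    """Parameters of one planted-homology pair.

    length: query length in residues; identity: fraction of conserved
    positions in the planted copy; indel_rate: per-position probability
    of a single-residue insertion or deletion; alphabet: residue symbols;
    seed: PCG64 seed.
    """

    length: int = 150
    identity: float = 0.9
    indel_rate: float = 0.02
    alphabet: str = "ACGT"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConfigurationError("length must be >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise ConfigurationError("identity must be in [0, 1]")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ConfigurationError("indel_rate must be in [0, 1)")
        if len(self.alphabet) < 2:
            raise ConfigurationError("alphabet needs at least 2 symbols")


@dataclass(frozen=True)
class PlantedRegion:
    """1-based inclusive coordinates of the true homologous interval."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def _mutate(rng: np.random.Generator, segment: str, spec: HomologySpec) -> str:
    """Substitutions at rate 1 - identity, indels at indel_rate.

    A substituted position draws uniformly from the whole alphabet (it may
    redraw the original symbol), so identity 0 leaves the 1/|alphabet|
    background match rate of unrelated sequences."""
    alphabet = spec.alphabet
    out: list[str] = []
    for c in segment:
        r = rng.random()
        if r < spec.indel_rate / 2:
            continue                                    # deletion
        if r < spec.indel_rate:
            out.append(alphabet[rng.integers(0, len(alphabet))])  # insertion
        if rng.random() >= spec.identity:
            out.append(alphabet[rng.integers(0, len(alphabet))])
        else:
            out.append(c)
    if not out:                                         # degenerate tiny input
        out.append(segment[0])
    return "".join(out)


def generate_pair(spec: HomologySpec,
                  pair_index: int = 0) -> tuple[SequenceRecord, SequenceRecord, PlantedRegion]:
    """One query, one homologous target and the planted coordinates.

    The planted copy spans 70-90% of the query and sits between random
    flanks of up to half the query length each. ``pair_index`` offsets
    the stream so batches share one seed while pairs stay independent.
    """
    rng = np.random.Generator(np.random.PCG64([spec.seed, pair_index]))
    query = _random_seq(rng, spec.alphabet, spec.length)
    span = max(1, int(spec.length * rng.uniform(0.7, 0.9)))
    q_start = int(rng.integers(0, spec.length - span + 1))     # 0-based
    segment = query[q_start:q_start + span]
    mutated = _mutate(rng, segment, spec)
    max_flank = max(1, spec.length // 2)
    left = _random_seq(rng, spec.alphabet, int(rng.integers(0, max_flank)))
    right = _random_seq(rng, spec.alphabet, int(rng.integers(0, max_flank)))
    target = left + mutated + right
    tag = f"{pair_index + 1:04d}"
    region = PlantedRegion(
        query_start=q_start + 1,
        query_end=q_start + span,
        target_start=len(left) + 1,
        target_end=len(left) + len(mutated),
    )
    return (
        SequenceRecord(id=f"q{tag}", residues=query,
                       description=f"synthetic query {tag}"),
        SequenceRecord(id=f"t{tag}", residues=target,
                       description=f"synthetic homolog of q{tag}"),
        region,
    )


def generate_batch(n: int, spec: HomologySpec, out_dir: str
                   ) -> tuple[str, str, str]:
    """Write ``n`` planted pairs plus ``n`` decoy targets to FASTA files.

    Returns the paths of (queries.fasta, targets.fasta, manifest.tsv);
    the manifest records the planted coordinates for recall scoring.
    Decoys carry ids ``dNNNN`` and never appear in the manifest.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    q_path = os.path.join(out_dir, "queries.fasta")
    t_path = os.path.join(out_dir, "targets.fasta")
    m_path = os.path.join(out_dir, "manifest.tsv")
    decoy_rng = np.random.Generator(np.random.PCG64([spec.seed, 10 ** 6]))
    with open(q_path, "w") as qf, open(t_path, "w") as tf, open(m_path, "w") as mf:
        mf.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for k in range(n):
            query, target, region = generate_pair(spec, pair_index=k)
            qf.write(f">{query.id} {query.description}\n{query.residues}\n")
            tf.write(f">{target.id} {target.description}\n{target.residues}\n")
            mf.write("\t".join(map(str, (
                query.id, target.id,
                region.query_start, region.query_end,
                region.target_start, region.target_end))) + "\n")
        for k in range(n):
            decoy = _random_seq(decoy_rng, spec.alphabet, spec.length)
            tf.write(f">d{k + 1:04d} synthetic decoy\n{decoy}\n")
    return q_path, t_path, m_path


def read_manifest(path: str) -> list[dict]:
    """Parse a manifest written by :func:`generate_batch`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            vals = line.strip().split("\t")
            row = dict(zip(header, vals))
            for key in MANIFEST_COLUMNS[2:]:
                row[key] = int(row[key])
            rows.append(row)
    return rows
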