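"""Substitution-scoring schemes and gap penalties.

A :class:`ScoringScheme` bundles a substitution table s(a, b) over an
alphabet of at most 255 symbols with two non-negative gap penalties:
``gap_open_penalty`` (charged when a gap run starts) and
``gap_extension_penalty`` (charged for every further column of the run).
A gap-extension penalty of 0 selects the basic (linear) gap model, in
which every gap column costs the full open penalty.

The maximum entry of the substitution table (``max_match_score``) is the
score of one perfectly matching column; the hit filters use it to build
the theoretical maximum score of an alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FormatError

MAX_ALPHABET = 255

#: index reserved in the encoded table for symbols outside the alphabet
UNKNOWN = -1


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution table plus gap penalties.

    Parameters
    ----------
    alphabet : str
        The symbols the table is defined over (upper case, unique).
    matrix : numpy.ndarray
        Square float array, ``matrix[i, j]`` = score of aligning
        ``alphabet[i]`` (query) against ``alphabet[j]`` (target).
    gap_open_penalty, gap_extension_penalty : float
        Non-negative magnitudes subtracted in the recurrences.
    unknown_score : float
        Score used for any pair involving a symbol outside the alphabet.
        Defaults to the minimum table entry, so unexpected residues are
        treated as the worst mismatch instead of crashing a batch.
    """

    alphabet: str
    matrix: np.ndarray
    gap_open_penalty: float
    gap_extension_penalty: float = 0.0
    unknown_score: float | None = None
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.alphabet)
        if len(set(self.alphabet)) != n:
            raise ConfigurationError("alphabet contains duplicate symbols")
        if n == 0 or n > MAX_ALPHABET:
            raise ConfigurationError(
                f"alphabet size must be between 1 and {MAX_ALPHABET}, got {n}"
            )
        if mat.shape != (n, n):
            raise ConfigurationError(
                f"substitution table shape {mat.shape} does not match "
                f"alphabet size {n}"
            )
        if self.gap_open_penalty < self.gap_extension_penalty or self.gap_extension_penalty < 0:
            raise ConfigurationError(
                "penalties must satisfy gap_open >= gap_extension >= 0 "
                f"(got open={self.gap_open_penalty}, ext={self.gap_extension_penalty})"
            )
        if mat.max() <= 0:
            raise ConfigurationError("substitution table has no positive entry")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(
            self,
            "unknown_score",
            float(mat.min()) if self.unknown_score is None else float(self.unknown_score),
        )
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.alphabet)})

    # -- derived quantities -------------------------------------------------

    @property
    def max_match_score(self) -> float:
        """Largest entry of the substitution table (score of a perfect column)."""
        return float(self.matrix.max())

    @property
    def affine(self) -> bool:
        """True when a non-zero gap-extension penalty selects the affine model."""
        return self.gap_extension_penalty != 0

    # -- lookups ------------------------------------------------------------

    def substitution(self, a: str, b: str) -> float:
        """Score of aligning query symbol ``a`` against target symbol ``b``."""
        ia = self._index.get(a.upper(), UNKNOWN)
        ib = self._index.get(b.upper(), UNKNOWN)
        if ia == UNKNOWN or ib == UNKNOWN:
            return self.unknown_score
        return float(self.matrix[ia, ib])

    def encode(self, residues: str) -> np.ndarray:
        """Map residues onto table indices; out-of-alphabet symbols map to the
        extra 'unknown' row appended by :meth:`encoded_matrix`."""
        n = len(self.alphabet)
        idx = self._index
        out = np.empty(len(residues), dtype=np.int64)
        for k, c in enumerate(residues.upper()):
            out[k] = idx.get(c, n)
        return out

    def encoded_matrix(self) -> np.ndarray:
        """Table extended with one row/column for out-of-alphabet symbols."""
        n = len(self.alphabet)
        ext = np.full((n + 1, n + 1), self.unknown_score, dtype=np.float64)
        ext[:n, :n] = self.matrix
        return ext


# default penalties for the stock DNA scheme; the match score of 5 follows
# the convention that a full-length DNA self-match has relative score 5.0
DEFAULT_MATCH = 5.0
DEFAULT_MISMATCH = -4.0
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTENSION = 0.0

_DNA_ALPHABET = "ACGTUN"


def make_dna_scheme(
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_ext: float = DEFAULT_GAP_EXTENSION,
) -> ScoringScheme:
    """Build a match/mismatch scheme over the DNA/RNA alphabet ACGTUN.

    ``match`` is placed on the diagonal for A, C, G, T and U; every other
    pair scores ``mismatch``. N never rewards a match (ambiguity must not
    score), so N-N pairs also score ``mismatch``.
    """
    if match <= 0:
        raise ConfigurationError(f"match score must be positive, got {match}")
    if mismatch >= match:
        raise ConfigurationError(
            f"mismatch score ({mismatch}) must be below match score ({match})"
        )
    n = len(_DNA_ALPHABET)
    mat = np.full((n, n), float(mismatch))
    for i, c in enumerate(_DNA_ALPHABET):
        if c != "N":
            mat[i, i] = float(match)
    return ScoringScheme(_DNA_ALPHABET, mat, float(gap_open), float(gap_ext),
                         unknown_score=float(mismatch))


def load_matrix(
    path,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_ext: float = DEFAULT_GAP_EXTENSION,
) -> ScoringScheme:
    """Read a substitution table in the NCBI/EMBOSS matrix dialect.

    The file is whitespace-delimited: ``#`` comment lines, a header row of
    symbols, then one row per symbol starting with its own symbol. Matrices
    need not be symmetric; rows are queries, columns targets.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append(line.split())
    if not rows:
        raise FormatError(f"{path}: no matrix content found")
    header = [tok.upper() for tok in rows[0]]
    if len(set(header)) != len(header):
        dup = next(s for s in header if header.count(s) > 1)
        raise FormatError(f"{path}: duplicate symbol {dup!r} in header")
    if len(header) > MAX_ALPHABET:
        raise FormatError(
            f"{path}: {len(header)} symbols exceed the {MAX_ALPHABET}-symbol limit"
        )
    body = rows[1:]
    if len(body) != len(header):
        raise FormatError(
            f"{path}: {len(body)} body rows for {len(header)} header symbols "
            "(matrix must be square)"
        )
    n = len(header)
    mat = np.zeros((n, n))
    seen = set()
    for r, row in enumerate(body):
        sym = row[0].upper()
        if sym not in header:
            raise FormatError(f"{path}: row symbol {sym!r} not in header")
        if sym in seen:
            raise FormatError(f"{path}: duplicate row symbol {sym!r}")
        seen.add(sym)
        if len(row) != n + 1:
            raise FormatError(
                f"{path}: row {sym!r} has {len(row) - 1} values, expected {n}"
            )
        i = header.index(sym)
        for c, tok in enumerate(row[1:]):
            try:
                mat[i, c] = float(tok)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {tok!r} at row {sym!r}, "
                    f"column {header[c]!r}"
                ) from None
    return ScoringScheme("".join(header), mat, float(gap_open), float(gap_ext))


def write_matrix(scheme: ScoringScheme, path) -> None:
    """Write the substitution table in the same dialect ``load_matrix`` reads."""
    with open(path, "w") as fh:
        fh.write("# substitution matrix\n")
        fh.write("  " + "  ".join(scheme.alphabet) + "\n")
        for i, sym in enumerate(scheme.alphabet):
            vals = "  ".join(format(v, "g") for v in scheme.matrix[i])
            fh.write(f"{sym}  {vals}\n")
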