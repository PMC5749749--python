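"""Per-hit metrics and the seven-parameter filter battery.

Every hit carries five derived quantities next to its raw score:

* ``query_coverage`` — fraction of the query's residues present (non-gap)
  in the alignment,
* ``query_identity`` — match columns divided by the query length,
* ``relative_score`` — score divided by the length of the shorter
  sequence (a full match of a DNA sequence under the default scheme gives
  the match score, 5.0),
* ``base_score`` — score divided by the alignment length,
* ``theoretical_max`` — shorter-sequence length times the maximum match
  score, i.e. the score of a hypothetical perfect alignment.

The filters: ``lower_limit_score`` and ``minimum_score`` act during
hit-start discovery; ``minimum_score``, ``filter_factor`` (score must be
strictly above ``filter_factor * theoretical_max``), ``query_coverage``,
``query_identity``, ``relative_score`` and ``base_score`` act on traced
hits. All "minimum" thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ConfigurationError

GAP = "-"


@dataclass
class FilterSettings:
    """Thresholds for selecting and filtering alignments.

    Legal ranges (``validate``): 0 < lower_limit_score <= 1;
    minimum_score > 0; 0 < filter_factor <= 1; 0 <= query_coverage <= 1;
    0 <= query_identity <= 1; 0 < relative_score <= max match score;
    0 < base_score <= max match score.
    """

    lower_limit_score: float = 1.0
    minimum_score: float = 30.0
    filter_factor: float = 0.2
    query_coverage: float = 0.2
    query_identity: float = 0.2
    relative_score: float = 2.0
    base_score: float = 2.0

    def validate(self, max_match_score: float | None = None) -> "FilterSettings":
        """Check every threshold against its legal range; returns self."""
        def bad(name, rng):
            raise ConfigurationError(
                f"{name}={getattr(self, name)} outside legal range {rng}")

        if not 0.0 < self.lower_limit_score <= 1.0:
            bad("lower_limit_score", "0 < x <= 1")
        if not self.minimum_score > 0:
            bad("minimum_score", "x > 0")
        if not 0.0 < self.filter_factor <= 1.0:
            bad("filter_factor", "0 < x <= 1")
        if not 0.0 <= self.query_coverage <= 1.0:
            bad("query_coverage", "0 <= x <= 1")
        if not 0.0 <= self.query_identity <= 1.0:
            bad("query_identity", "0 <= x <= 1")
        upper = max_match_score if max_match_score is not None else float("inf")
        if not 0.0 < self.relative_score <= upper:
            bad("relative_score", f"0 < x <= {upper} (max match score)")
        if not 0.0 < self.base_score <= upper:
            bad("base_score", f"0 < x <= {upper} (max match score)")
        return self

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class HitMetrics:
    """Derived per-hit quantities (see module docstring for definitions)."""

    score: float
    query_coverage: float
    query_identity: float
    relative_score: float
    base_score: float
    theoretical_max: float


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the filter battery; ``failed`` names every criterion the
    hit did not meet (empty iff ``passed``)."""

    passed: bool
    failed: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.passed


def compute_metrics(hit, query_len: int, target_len: int, scheme) -> HitMetrics:
    """Compute the five derived metrics for one hit.

    ``query_identity`` divides by the full query length by default; the
    module switch ``IDENTITY_OVER_ALIGNED_SPAN`` selects the aligned-span
    convention instead (the wording "relative to the query" admits both).
    """
    if query_len <= 0 or target_len <= 0:
        raise ValueError("sequence lengths must be positive")
    length = hit.alignment_length
    if length == 0:
        raise ValueError("zero-length alignment")
    shortest = min(query_len, target_len)
    covered = sum(1 for c in hit.aligned_query if c != GAP)
    return HitMetrics(
        score=hit.score,
        query_coverage=covered / query_len,
        query_identity=hit.matches / identity_denominator(hit, query_len),
        relative_score=hit.score / shortest,
        base_score=hit.score / length,
        theoretical_max=shortest * scheme.max_match_score,
    )


#: When True, query_identity divides by the aligned query span instead of
#: the full query length. Off by default: "relative to the query" is read
#: as the whole query sequence.
IDENTITY_OVER_ALIGNED_SPAN = False


def identity_denominator(hit, query_len: int) -> int:
    if IDENTITY_OVER_ALIGNED_SPAN:
        return max(1, sum(1 for c in hit.aligned_query if c != GAP))
    return query_len


def passes_filters(metrics: HitMetrics, settings: FilterSettings) -> FilterVerdict:
    """Apply the post-traceback filter battery to one hit's metrics.

    ``filter_factor`` is strict (score must exceed the fraction of the
    theoretical maximum); the remaining thresholds are inclusive minima.
    """
    failed = []
    if metrics.score < settings.minimum_score:
        failed.append("minimum_score")
    if not metrics.score > settings.filter_factor * metrics.theoretical_max:
        failed.append("filter_factor")
    if metrics.query_coverage < settings.query_coverage:
        failed.append("query_coverage")
    if metrics.query_identity < settings.query_identity:
        failed.append("query_identity")
    if metrics.relative_score < settings.relative_score:
        failed.append("relative_score")
    if metrics.base_score < settings.base_score:
        failed.append("base_score")
    return FilterVerdict(passed=not failed, failed=tuple(failed))
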