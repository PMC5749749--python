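import numpy as np
import pytest

from localsw import (FilterSettings, InputError, ScoringScheme, align_all,
                     align_pair, find_hit_starts, make_dna_scheme, traceback)
from localsw.core import DPState, STOP
from localsw.io_formats import SequenceRecord

from .oracle import biopython_best, brute_force_best, random_scheme, random_seq


def loose_filters(**kw):
    base = dict(lower_limit_score=1.0, minimum_score=1e-9, filter_factor=1e-9,
                query_coverage=0.0, query_identity=0.0,
                relative_score=1e-9, base_score=1e-9)
    base.update(kw)
    return FilterSettings(**base)


class TestAlignPair:
    def test_single_cell(self):
        state = align_pair("A", "A", make_dna_scheme(5, -4, 10, 0))
        assert state.global_max == (5.0, 1, 1)

    def test_cell_count_basic_vs_affine(self, rng):
        q, t = random_seq(rng, 100), random_seq(rng, 100)
        assert align_pair(q, t, make_dna_scheme(5, -4, 10, 0)).cell_count == 10_000
        assert align_pair(q, t, make_dna_scheme(5, -4, 10, 1)).cell_count == 30_000

    def test_grid_layout_matches_mode(self):
        basic = align_pair("ACGT", "ACG", make_dna_scheme(5, -4, 10, 0))
        assert basic.H is not None and basic.M is None
        affine = align_pair("ACGT", "ACG", make_dna_scheme(5, -4, 10, 2))
        assert affine.H is None
        assert all(g is not None for g in (affine.M, affine.I, affine.J))

    def test_empty_sequence_rejected(self, dna_scheme):
        with pytest.raises(InputError, match="query"):
            align_pair("", "ACGT", dna_scheme)
        with pytest.raises(InputError, match="target"):
            align_pair("ACGT", "", dna_scheme)

    def test_stop_move_iff_zero_score(self, rng):
        for affine in (False, True):
            scheme = random_scheme(rng, affine)
            q, t = random_seq(rng, 12), random_seq(rng, 15)
            state = align_pair(q, t, scheme)
            scores = state.cell_scores()
            stops = state.move[1:, 1:] == STOP
            assert np.array_equal(stops, scores <= 0)
            assert scores[~stops].min() > 0

    def test_global_max_is_grid_maximum(self, rng):
        for affine in (False, True):
            state = align_pair(random_seq(rng, 20), random_seq(rng, 30),
                               random_scheme(rng, affine))
            scores = state.cell_scores()
            gscore, grow, gcol = state.global_max
            assert gscore == scores.max()
            assert scores[grow - 1, gcol - 1] == gscore


class TestOracleEquivalence:
    """Best scores must match independent references at tiny lengths."""

    @pytest.mark.parametrize("affine", [False, True])
    def test_brute_force_enumeration(self, affine):
        rng = np.random.default_rng(7 if affine else 8)
        for _ in range(40):
            scheme = random_scheme(rng, affine, free_model_safe=True)
            q = random_seq(rng, int(rng.integers(2, 5)))
            t = random_seq(rng, int(rng.integers(2, 5)))
            expected = brute_force_best(q, t, scheme)
            assert align_pair(q, t, scheme).global_max[0] == expected

    @pytest.mark.parametrize("affine", [False, True])
    def test_biopython_reference(self, affine):
        rng = np.random.default_rng(17 if affine else 18)
        for _ in range(150):
            scheme = random_scheme(rng, affine, free_model_safe=True)
            q = random_seq(rng, int(rng.integers(3, 9)))
            t = random_seq(rng, int(rng.integers(3, 9)))
            expected = biopython_best(q, t, scheme)
            assert align_pair(q, t, scheme).global_max[0] == expected

    def test_adversarial_scheme_restricted_gap_placement(self):
        """With extreme mismatch costs the engine and the canonical
        enumerator still agree (both forbid adjacent opposite-sequence
        gap runs)."""
        mat = np.full((3, 3), -100.0)
        np.fill_diagonal(mat, 5.0)
        mat[1, 1] = -100.0  # B never matches
        scheme = ScoringScheme("ABC", mat, 2.0, 1.0)
        rng = np.random.default_rng(5)
        for _ in range(25):
            q = random_seq(rng, int(rng.integers(2, 6)), "ABC")
            t = random_seq(rng, int(rng.integers(2, 6)), "ABC")
            assert align_pair(q, t, scheme).global_max[0] == \
                brute_force_best(q, t, scheme)

    def test_affine_reduces_to_basic_when_penalties_equal(self, rng):
        for _ in range(60):
            g = int(rng.integers(1, 7))
            mat = rng.integers(-2 * g, 4, size=(4, 4)).astype(float)
            mat[0, 0] = 5
            basic = ScoringScheme("ACGT", mat, float(g), 0.0)
            affine = ScoringScheme("ACGT", mat, float(g), float(g))
            q = random_seq(rng, int(rng.integers(3, 25)))
            t = random_seq(rng, int(rng.integers(3, 25)))
            assert align_pair(q, t, basic).global_max[0] == \
                align_pair(q, t, affine).global_max[0]

    def test_score_symmetry_for_symmetric_tables(self, rng):
        for affine in (False, True):
            scheme = random_scheme(rng, affine, free_model_safe=True)
            sym = ScoringScheme(scheme.alphabet,
                                np.maximum(scheme.matrix, scheme.matrix.T),
                                scheme.gap_open_penalty,
                                scheme.gap_extension_penalty)
            for _ in range(20):
                q = random_seq(rng, int(rng.integers(3, 20)))
                t = random_seq(rng, int(rng.integers(3, 20)))
                assert align_pair(q, t, sym).global_max[0] == \
                    align_pair(t, q, sym).global_max[0]

    def test_duplicating_target_never_decreases_score(self, rng, dna_scheme):
        for _ in range(20):
            q = random_seq(rng, int(rng.integers(3, 15)))
            t = random_seq(rng, int(rng.integers(3, 15)))
            single = align_pair(q, t, dna_scheme).global_max[0]
            doubled = align_pair(q, t + t, dna_scheme).global_max[0]
            assert doubled >= single


class TestHitStarts:
    def _toy_state(self):
        """Hand-filled 3x3 basic state with cell scores 9, 7, 5."""
        H = np.zeros((4, 4))
        H[1, 1], H[2, 3], H[3, 2] = 9.0, 7.0, 5.0
        scheme = make_dna_scheme(5, -4, 10, 0)
        state = DPState("basic", 3, 3, scheme, H=H,
                        move=np.zeros((4, 4), dtype=np.int8))
        state.global_max = (9.0, 1, 1)
        return state

    def test_toy_state_ordering(self):
        starts = find_hit_starts(
            self._toy_state(),
            loose_filters(lower_limit_score=0.5, minimum_score=1e-9))
        assert starts == [(9.0, 1, 1), (7.0, 2, 3), (5.0, 3, 2)]

    def test_lower_limit_one_keeps_only_maxima(self):
        starts = find_hit_starts(
            self._toy_state(),
            loose_filters(lower_limit_score=1.0, minimum_score=1e-9))
        assert starts == [(9.0, 1, 1)]

    def test_minimum_score_excludes_everything(self):
        state = self._toy_state()
        state.global_max = (9.0, 1, 1)
        assert find_hit_starts(state, loose_filters(minimum_score=30)) == []

    def test_tie_break_row_then_col(self, dna_scheme):
        state = align_pair("ACAC", "ACAC", dna_scheme)
        starts = find_hit_starts(state, loose_filters(lower_limit_score=1.0))
        scores = {s for s, _, _ in starts}
        assert len(scores) == 1
        assert starts == sorted(starts, key=lambda s: (s[1], s[2]))


class TestTraceback:
    def test_perfect_diagonal(self, dna_scheme):
        state = align_pair("ACGT", "ACGT", dna_scheme)
        hit = traceback(state, state.global_max[1:], "ACGT", "ACGT")
        assert hit.aligned_query == hit.aligned_target == "ACGT"
        assert hit.score == 20 and hit.matches == 4
        assert (hit.query_start, hit.query_end) == (1, 4)

    def test_single_cell_hit_coordinates(self):
        scheme = make_dna_scheme(5, -4, 10, 0)
        state = align_pair("A", "A", scheme)
        hit = traceback(state, (1, 1), "A", "A")
        assert (hit.query_start, hit.query_end,
                hit.target_start, hit.target_end, hit.score) == (1, 1, 1, 1, 5)

    def test_affine_gap_run_scoring(self):
        q, t = "AAATTTAAA", "AAAAAA"
        affine = align_pair(q, t, make_dna_scheme(5, -4, 4, 1))
        hit = traceback(affine, affine.global_max[1:], q, t)
        assert hit.score == 24  # 30 - (4 + 1 + 1)
        assert hit.aligned_target.count("-") == 3
        assert hit.gap_columns == 3
        basic = align_pair(q, t, make_dna_scheme(5, -4, 4, 0))
        assert basic.global_max[0] == 18  # 30 - 3 * 4

    def test_nonpositive_start_rejected(self, dna_scheme):
        state = align_pair("AAAA", "TTTT", dna_scheme)
        with pytest.raises(ValueError):
            traceback(state, (1, 1), "AAAA", "TTTT")

    @pytest.mark.parametrize("affine", [False, True])
    def test_hit_invariants_on_random_pairs(self, affine):
        rng = np.random.default_rng(27 if affine else 28)
        for _ in range(60):
            scheme = random_scheme(rng, affine, free_model_safe=True)
            q = random_seq(rng, int(rng.integers(4, 30)))
            t = random_seq(rng, int(rng.integers(4, 30)))
            state = align_pair(q, t, scheme)
            if state.global_max[0] <= 0:
                continue
            hit = traceback(state, state.global_max[1:], q, t)
            hit.validate(q, t)
            assert hit.score == state.global_max[0]


class TestAlignAll:
    def test_identical_pair_single_hit(self, dna_scheme):
        q = [SequenceRecord("q1", "ACGTACGTAC")]
        t = [SequenceRecord("t1", "ACGTACGTAC")]
        hits = align_all(q, t, dna_scheme, loose_filters())
        assert len(hits) == 1
        assert hits[0].query_id == "q1" and hits[0].target_id == "t1"

    def test_pair_major_ordering(self, dna_scheme, rng):
        queries = [SequenceRecord(f"q{i}", random_seq(rng, 12)) for i in range(2)]
        targets = [SequenceRecord(f"t{j}", q.residues)
                   for j, q in enumerate(queries + queries[:1])]
        hits = align_all(queries, targets, dna_scheme, loose_filters())
        order = [(h.query_id, h.target_id) for h in hits]
        assert order == sorted(order, key=lambda p: (p[0], p[1]))

    def test_shuffled_inputs_same_hit_multiset(self, dna_scheme, rng):
        queries = [SequenceRecord(f"q{i}", random_seq(rng, 15)) for i in range(3)]
        targets = [SequenceRecord(f"t{j}", random_seq(rng, 15)) for j in range(3)]
        filters = loose_filters()
        ref = align_all(queries, targets, dna_scheme, filters)
        shuffled = align_all(queries[::-1], targets[::-1], dna_scheme, filters)
        key = lambda h: (h.query_id, h.target_id, h.score,
                         h.aligned_query, h.aligned_target)
        assert sorted(map(key, ref)) == sorted(map(key, shuffled))

    def test_visited_cells_suppress_contained_suboptima(self, dna_scheme):
        q = [SequenceRecord("q", "ACGTACGT")]
        t = [SequenceRecord("t", "ACGTACGT")]
        hits = align_all(q, t, dna_scheme,
                         loose_filters(lower_limit_score=0.2))
        assert len([h for h in hits if h.score == 40]) == 1

    def test_empty_input_rejected(self, dna_scheme):
        with pytest.raises(InputError):
            align_all([], [SequenceRecord("t", "ACGT")], dna_scheme)

    def test_error_names_offending_record(self, dna_scheme):
        bad = SequenceRecord.__new__(SequenceRecord)  # bypass validation
        object.__setattr__(bad, "id", "broken")
        object.__setattr__(bad, "residues", "")
        object.__setattr__(bad, "description", "")
        object.__setattr__(bad, "qualities", None)
        with pytest.raises(InputError, match="broken"):
            align_all([SequenceRecord("q", "ACGT")], [bad], dna_scheme)
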