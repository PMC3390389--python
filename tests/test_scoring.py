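"""Binomial scores, window count tables, and window/strand optimization.

The oracles here are deliberately naive: exact-fraction tail summation for
the binomial, and per-window direct re-scans of every sequence for the
count tables and window optimization.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from powrs.matching import find_word_matches, single_mutation_variants
from powrs.scoring import (
    ScoringEngine,
    WindowGrid,
    best_window,
    binomial_tail_pvalue,
    enrichment_score,
    window_count_table,
)
from powrs.seqmodel import SequenceSet, WordSet

from conftest import random_sequence_set


def exact_tail(x: int, y: int, p: Fraction) -> Fraction:
    """P(X >= x) by exact rational summation."""
    return sum(
        Fraction(comb(y, m)) * p**m * (1 - p) ** (y - m) for m in range(x, y + 1)
    )


def count_in_window_oracle(word_set, seqs, start, end, strand_mode):
    """Sequences containing any matching word starting in [start, end)."""
    n = 0
    for s in seqs:
        hits = set()
        for w in word_set.matching_words:
            hits.update(find_word_matches(w, s, strand_mode))
        if any(start <= p < end for p in hits):
            n += 1
    return n


def best_window_oracle(word_set, fg, bg, grid, strand_modes):
    """Exhaustive one-window-at-a-time maximization."""
    best = None
    b = grid.boundaries
    for mode in strand_modes:
        for i in range(len(b)):
            for j in range(i + 1, len(b)):
                x = count_in_window_oracle(word_set, fg, b[i], b[j], mode)
                xb = count_in_window_oracle(word_set, bg, b[i], b[j], mode)
                enr = enrichment_score(x, len(fg), xb, len(bg))
                key = (-enr.score, -(b[j] - b[i]), b[i], mode != "sense")
                if best is None or key < best[0]:
                    best = (key, (b[i], b[j]), mode, enr)
    return best[1], best[2], best[3]


def random_word_set(rng, length=4):
    seed = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    variants = rng.choice(
        single_mutation_variants(seed), size=int(rng.integers(0, 4)), replace=False
    )
    return WordSet(seed, frozenset(str(v) for v in variants))


class TestBinomialTail:
    def test_trivial_values(self):
        assert binomial_tail_pvalue(0, 10, 0.3) == 1.0
        assert binomial_tail_pvalue(2, 2, 0.5) == pytest.approx(0.25, rel=1e-14)

    def test_against_exact_summation(self):
        expected = float(exact_tail(3, 10, Fraction(1, 10)))
        assert binomial_tail_pvalue(3, 10, 0.1) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("y,p", [(17, 0.01), (100, 0.5), (200, 0.97), (1000, 0.003)])
    def test_exact_to_ten_digits_across_x(self, y, p):
        pf = Fraction(p).limit_denominator(10**6)
        for x in range(0, y + 1, max(1, y // 25)):
            expected = exact_tail(x, y, pf)
            got = binomial_tail_pvalue(x, y, float(pf))
            if expected > Fraction(1, 10**290):
                assert abs(got / float(expected) - 1) < 1e-10

    @pytest.mark.parametrize("x,y,p", [(-1, 5, 0.5), (6, 5, 0.5), (1, 5, 0.0), (1, 5, 1.0)])
    def test_domain_violations(self, x, y, p):
        with pytest.raises(ValueError):
            binomial_tail_pvalue(x, y, p)


class TestEnrichmentScore:
    def test_score_is_minus_log10_pvalue(self):
        # a tail probability of 1e-10 corresponds to a score of exactly 10
        from powrs.scoring import _log10_sf

        l10 = float(_log10_sf(np.array([2]), 2, np.array([1e-5]))[0])
        assert -l10 == pytest.approx(10.0, abs=1e-9)

    def test_no_matches_scores_zero(self):
        e = enrichment_score(0, 10, 5, 100)
        assert e.pvalue == 1.0 and e.score == 0.0

    def test_half_enrichment_example(self):
        e = enrichment_score(5, 10, 50, 100)
        assert e.pvalue == pytest.approx(0.623046875, rel=1e-12)
        assert e.score == pytest.approx(0.20547927791865, rel=1e-10)

    def test_background_probability_clamping(self):
        assert enrichment_score(1, 10, 0, 100).p == pytest.approx(1 / 101)
        assert enrichment_score(1, 10, 100, 100).p == pytest.approx(100 / 101)

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(0, 0, 1, 10)

    def test_huge_enrichment_stays_finite(self):
        # deep tails must come back as finite scores, not inf/overflow
        e = enrichment_score(500, 500, 0, 2000)
        assert np.isfinite(e.score) and e.score > 300

    @given(st.integers(0, 49))
    @settings(max_examples=30)
    def test_score_monotone_in_successes(self, x):
        a = enrichment_score(x, 50, 10, 100).score
        b = enrichment_score(x + 1, 50, 10, 100).score
        assert b >= a


class TestWindowGrid:
    def test_boundaries_on_granularity_multiples(self):
        g = WindowGrid.from_extent(-1000, 50, 25)
        assert g.boundaries[0] == -1000 and g.boundaries[-1] == 50
        assert all(b % 25 == 0 for b in g.boundaries)
        assert 0 in g.boundaries

    def test_truncated_edges(self):
        g = WindowGrid.from_extent(-110, 42, 25)
        assert g.boundaries == (-110, -100, -75, -50, -25, 0, 25, 42)

    def test_degenerate_extent_collapses_to_full_length(self):
        g = WindowGrid.from_extent(-30, 10, 100)
        assert g.boundaries == (-30, 10)
        assert g.is_full_length

    def test_bin_lookup(self):
        g = WindowGrid.from_extent(-50, 50, 25)
        assert g.bin_of(-50) == 0
        assert g.bin_of(-1) == 1
        assert g.bin_of(0) == 2
        with pytest.raises(ValueError):
            g.bin_of(50)


class TestWindowCountTable:
    @pytest.mark.parametrize("strand_mode", ["sense", "both"])
    def test_equals_brute_force_rescan(self, rng, strand_mode):
        seqs = random_sequence_set(rng, n=12, length=50, anchor_offset=25)
        grid = WindowGrid.from_extent(-25, 25, 10)  # 5 full bins + edges
        for _ in range(20):
            ws = random_word_set(rng)
            table = window_count_table(ws, seqs, grid, strand_mode)
            b = grid.boundaries
            for i in range(len(b)):
                for j in range(i + 1, len(b)):
                    assert table.count(b[i], b[j]) == count_in_window_oracle(
                        ws, seqs, b[i], b[j], strand_mode
                    )

    def test_monotone_under_window_inclusion(self, rng):
        seqs = random_sequence_set(rng, n=15, length=60, anchor_offset=30)
        grid = WindowGrid.from_extent(-30, 30, 10)
        ws = random_word_set(rng, length=3)
        t = window_count_table(ws, seqs, grid, "sense")
        b = grid.boundaries
        for i in range(len(b)):
            for j in range(i + 1, len(b)):
                for i2 in range(i + 1):
                    for j2 in range(j, len(b)):
                        assert t.count(b[i], b[j]) <= t.count(b[i2], b[j2])
                assert t.count(b[i], b[j]) <= len(seqs)

    def test_both_strand_counts_at_least_sense(self, rng):
        seqs = random_sequence_set(rng, n=10, length=40, anchor_offset=20)
        grid = WindowGrid.from_extent(-20, 20, 10)
        ws = random_word_set(rng)
        ts = window_count_table(ws, seqs, grid, "sense")
        tb = window_count_table(ws, seqs, grid, "both")
        assert (tb.counts[np.triu_indices(len(grid.boundaries), 1)]
                >= ts.counts[np.triu_indices(len(grid.boundaries), 1)]).all()

    def test_unmatched_word_set_all_zero(self, rng):
        from powrs.seqmodel import AnchoredSequence

        seqs = SequenceSet((AnchoredSequence("a", "A" * 30, 15),))
        grid = WindowGrid.from_extent(-15, 15, 10)
        t = window_count_table(WordSet("CCGG"), seqs, grid, "both")
        assert t.counts.max() == 0

    def test_full_length_window_counts_any_occurrence(self, rng):
        seqs = random_sequence_set(rng, n=20, length=50, anchor_offset=25)
        ws = random_word_set(rng, length=2)
        grid = WindowGrid.full_length(-25, 25)
        t = window_count_table(ws, seqs, grid, "sense")
        expected = sum(
            1
            for s in seqs
            if any(find_word_matches(w, s, "sense") for w in ws.matching_words)
        )
        assert t.count(-25, 25) == expected


class TestBestWindow:
    def test_equals_exhaustive_oracle(self, rng):
        fg = random_sequence_set(rng, n=10, length=50, anchor_offset=25, id_prefix="f")
        bg = random_sequence_set(rng, n=14, length=50, anchor_offset=25, id_prefix="b")
        grid = WindowGrid.from_extent(-25, 25, 10)
        for _ in range(15):
            ws = random_word_set(rng)
            win, mode, enr = best_window(ws, fg, bg, grid, "auto")
            owin, omode, oenr = best_window_oracle(ws, fg, bg, grid, ("sense", "both"))
            assert enr.score == pytest.approx(oenr.score, abs=1e-9)
            assert (win.start, win.end) == owin
            assert mode == omode

    def test_planted_window_recovered_and_beats_full_length(self, rng):
        from conftest import all_base_sequences, plant_at

        fg = all_base_sequences("A", 20, 60, 30, prefix="f")
        fg = plant_at(
            fg, {f"f{i}": (int(rng.integers(-20, -4)), "GCGT") for i in range(20)}
        )
        # background carries the word too, but only downstream of the anchor
        bg = plant_at(
            all_base_sequences("A", 30, 60, 30, prefix="b"),
            {f"b{i}": (10, "GCGT") for i in range(30)},
        )
        grid = WindowGrid.from_extent(-30, 30, 10)
        ws = WordSet("GCGT")
        win, mode, enr = best_window(ws, fg, bg, grid, "sense")
        assert win.overlaps(type(win)(-20, 0))
        full = enrichment_score(
            count_in_window_oracle(ws, fg, -30, 30, "sense"), 20,
            count_in_window_oracle(ws, bg, -30, 30, "sense"), 30,
        )
        assert enr.score > full.score

    def test_returned_boundaries_on_grid(self, rng):
        fg = random_sequence_set(rng, n=8, length=100, anchor_offset=75, id_prefix="f")
        bg = random_sequence_set(rng, n=8, length=100, anchor_offset=75, id_prefix="b")
        grid = WindowGrid.from_sets(25, fg, bg)
        for _ in range(10):
            ws = random_word_set(rng)
            win, _, _ = best_window(ws, fg, bg, grid, "auto")
            assert win.start in grid.boundaries and win.end in grid.boundaries

    def test_full_span_granularity_gives_whole_sequence_window(self, rng):
        fg = random_sequence_set(rng, n=6, length=40, anchor_offset=20, id_prefix="f")
        bg = random_sequence_set(rng, n=6, length=40, anchor_offset=20, id_prefix="b")
        grid = WindowGrid.from_sets(1000, fg, bg)
        win, _, _ = best_window(random_word_set(rng), fg, bg, grid, "sense")
        assert (win.start, win.end) == (-20, 20)
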