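"""Position-sensitive word-set motif discovery.

The algorithm: every possible seed word of a given length is scored as a
bare single-word motif, with its window of maximal enrichment (and strand
mode) optimized; the most promising seeds are then each grown into a word
set by greedily adding, one per cycle, the single-mutation variant of the
*original* seed that most increases the window-optimized score.  Growth
stops when no variant strictly improves the score.  Variants of variants
are never considered — but every word gets its own chance to be a seed.

Run modes:

``powrs``
    the full algorithm on a granularity grid of windows;
``powrs_fl``
    identical, but the grid is collapsed to the single full-length window
    (no position sensitivity);
``simple``
    single words only (no variants), full-length window — a plain
    discriminative k-mer scan with the same binomial score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matching import encode_word, rc_code, single_mutation_variants
from .scoring import (
    SCORE_EPS,
    BinomialEnrichment,
    ScoringEngine,
    WindowGrid,
)
from .seqmodel import MotifResult, SequenceSet, Window, WordSet

__all__ = ["ConfigError", "SeedScore", "seed_pass", "grow_motif", "run_powrs"]

RUN_MODES = ("powrs", "powrs_fl", "simple")
STRAND_POLICIES = ("sense", "both", "auto")

DEFAULT_WORD_LENGTH = 8
DEFAULT_GRANULARITY = 25
DEFAULT_TOP_N = 800


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass(frozen=True)
class SeedScore:
    """A single seed word with its optimized window, strand and score."""

    word: str
    window: Window
    strand_mode: str
    enrichment: BinomialEnrichment

    @property
    def score(self) -> float:
        return self.enrichment.score


def _pick_by_policy(engine: ScoringEngine, per_mode, strand_policy: str):
    """Choose among per-strand-mode (window, enrichment) results.

    Ties prefer the wider window, then the earlier start, then sense-only.
    """
    best = None
    for mode, (window, enr) in per_mode:
        key = (-enr.score, -window.width, window.start, mode != "sense")
        if best is None or key < best[0]:
            best = (key, window, mode, enr)
    return best[1], best[2], best[3]


def seed_pass(
    fg: SequenceSet,
    bg: SequenceSet,
    word_length: int = DEFAULT_WORD_LENGTH,
    grid: WindowGrid | None = None,
    strand_policy: str = "auto",
    top_n: int = DEFAULT_TOP_N,
    granularity: int = DEFAULT_GRANULARITY,
    engine: ScoringEngine | None = None,
) -> list[SeedScore]:
    """Score every word of the given length and keep the best ``top_n``.

    Each word is scored as a bare single-word motif with window and strand
    optimized.  The returned list is sorted by score descending, ties broken
    lexicographically by word.
    """
    _validate(word_length=word_length, top_n=top_n, strand_policy=strand_policy)
    if engine is None:
        if grid is None:
            grid = WindowGrid.from_sets(granularity, fg, bg)
        engine = ScoringEngine(fg, bg, word_length, grid)

    n_codes = 4**word_length
    codes = np.arange(n_codes, dtype=np.int64)
    # vectorized reverse-complement codes
    rc = np.zeros(n_codes, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(word_length):
        rc = rc * 4 + (3 - (tmp & 3))
        tmp >>= 2
    modes = ("sense", "both") if strand_policy == "auto" else (strand_policy,)

    results: list[SeedScore] = []
    one = np.empty(1, dtype=np.int64)
    for code in range(n_codes):
        per_mode = []
        for mode in modes:
            if mode == "sense":
                one[0] = code
                word_codes = one
            else:
                c, r = code, int(rc[code])
                word_codes = np.array([c] if c == r else sorted((c, r)), dtype=np.int64)
            per_mode.append((mode, engine.best_for_codes(word_codes)))
        window, mode, enr = _pick_by_policy(engine, per_mode, strand_policy)
        results.append(SeedScore(_decode(code, word_length), window, mode, enr))
    results.sort(key=lambda r: (-r.score, r.word))
    return results[:top_n]


def _decode(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def grow_motif(
    seed: str,
    fg: SequenceSet,
    bg: SequenceSet,
    grid: WindowGrid | None = None,
    strand_policy: str = "auto",
    granularity: int = DEFAULT_GRANULARITY,
    engine: ScoringEngine | None = None,
) -> MotifResult:
    """Grow a seed word into a word set by greedy variant addition.

    Every cycle re-evaluates each not-yet-included single-mutation variant
    of the original seed (window and strand re-optimized each time) and adds
    the one with the largest strictly positive score gain; among equal
    gains, the lexicographically smallest variant wins.  Stops when no
    variant improves the score by more than a small numeric epsilon.
    """
    seed = seed.upper()
    _validate(strand_policy=strand_policy)
    if engine is None:
        if grid is None:
            grid = WindowGrid.from_sets(granularity, fg, bg)
        engine = ScoringEngine(fg, bg, len(seed), grid)

    word_set = WordSet(seed)
    window, mode, enr = engine.evaluate(word_set, strand_policy)
    remaining = sorted(single_mutation_variants(seed))
    while remaining:
        best = None
        for v in remaining:
            cand = word_set.with_variant(v)
            w2, m2, e2 = engine.evaluate(cand, strand_policy)
            if e2.score > enr.score + SCORE_EPS and (
                best is None or e2.score > best[1].score
            ):
                best = (v, e2, w2, m2, cand)
        if best is None:
            break
        v, enr, window, mode, word_set = best
        remaining.remove(v)

    return MotifResult(
        word_set=word_set,
        window=window,
        strand_mode=mode,
        score=enr.score,
        pvalue=enr.pvalue,
        fg_matched=enr.x,
        fg_total=len(fg),
        bg_matched=engine.background_count(word_set, window, mode),
        bg_total=len(bg),
    )


def _seed_to_result(
    engine: ScoringEngine, s: SeedScore, fg: SequenceSet, bg: SequenceSet
) -> MotifResult:
    ws = WordSet(s.word)
    return MotifResult(
        word_set=ws,
        window=s.window,
        strand_mode=s.strand_mode,
        score=s.score,
        pvalue=s.enrichment.pvalue,
        fg_matched=s.enrichment.x,
        fg_total=len(fg),
        bg_matched=engine.background_count(ws, s.window, s.strand_mode),
        bg_total=len(bg),
    )


def _validate(**kwargs) -> None:
    if "word_length" in kwargs and not 1 <= kwargs["word_length"] <= 12:
        raise ConfigError(f"word_length: must be in [1, 12], got {kwargs['word_length']}")
    if "top_n" in kwargs and kwargs["top_n"] < 1:
        raise ConfigError(f"top_n: must be >= 1, got {kwargs['top_n']}")
    if "granularity" in kwargs and kwargs["granularity"] < 1:
        raise ConfigError(f"granularity: must be >= 1, got {kwargs['granularity']}")
    if "strand_policy" in kwargs and kwargs["strand_policy"] not in STRAND_POLICIES:
        raise ConfigError(
            f"strand_policy: must be one of {STRAND_POLICIES}, got {kwargs['strand_policy']!r}"
        )
    if "mode" in kwargs and kwargs["mode"] not in RUN_MODES:
        raise ConfigError(f"mode: must be one of {RUN_MODES}, got {kwargs['mode']!r}")


def run_powrs(
    fg: SequenceSet,
    bg: SequenceSet,
    word_length: int = DEFAULT_WORD_LENGTH,
    granularity: int = DEFAULT_GRANULARITY,
    top_n: int = DEFAULT_TOP_N,
    strand_policy: str = "auto",
    mode: str = "powrs",
    progress=None,
) -> list[MotifResult]:
    """Run the full discovery pipeline in one of the three modes.

    Returns one :class:`MotifResult` per retained seed, sorted by score
    descending (ties broken by seed word), before any suppression/grouping.
    ``progress``, if given, is called with status strings.
    """
    _validate(
        word_length=word_length,
        granularity=granularity,
        top_n=top_n,
        strand_policy=strand_policy,
        mode=mode,
    )
    if word_length < 4:
        raise ConfigError(f"word_length: must be in [4, 12], got {word_length}")
    lo = min(fg.extent()[0], bg.extent()[0])
    hi = max(fg.extent()[1], bg.extent()[1])
    if mode == "powrs":
        grid = WindowGrid.from_extent(lo, hi, granularity)
    else:
        grid = WindowGrid.full_length(lo, hi)
    engine = ScoringEngine(fg, bg, word_length, grid)

    if progress:
        progress(f"seed pass: scoring {4**word_length} words of length {word_length}")
    seeds = seed_pass(
        fg, bg, word_length, grid, strand_policy, top_n=top_n, engine=engine
    )
    if progress:
        progress(f"seed pass done; optimizing {len(seeds)} motifs")

    results: list[MotifResult] = []
    if mode == "simple":
        results = [_seed_to_result(engine, s, fg, bg) for s in seeds]
    else:
        for i, s in enumerate(seeds):
            results.append(
                grow_motif(s.word, fg, bg, grid, strand_policy, engine=engine)
            )
            if progress and (i + 1) % 100 == 0:
                progress(f"optimized {i + 1}/{len(seeds)} motifs")
    results.sort(key=lambda r: (-r.score, r.word_set.seed))
    return results
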