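"""Binomial enrichment scoring over windows of anchor-relative positions.

The central statistic: for a word-set motif, let ``x`` be the number of
foreground sequences containing at least one matching word whose start
position lies in a window ``[i, j)``, out of ``y`` foreground sequences, and
let ``p`` be the fraction of background sequences containing such a match in
the same window.  The enrichment score is ``-log10 P(X >= x)`` for
``X ~ Binomial(y, p)``.  A score of 10 therefore corresponds to an
uncorrected p-value of 1e-10; no multiple-testing correction is applied
because overlapping windows and similar motifs are not independent tests.

Window boundaries live on a grid: multiples of a granularity step (anchored
at coordinate 0, so windows land at round positions relative to the TSS),
truncated at the sequence extent.  Sequences are counted at most once per
window regardless of how many occurrences they contain, and a match belongs
to a window by its start position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .matching import encode_word, rc_code, sequence_codes
from .seqmodel import SequenceSet, Window, WordSet

__all__ = [
    "WindowGrid",
    "BinomialEnrichment",
    "WindowCountTable",
    "ScoringEngine",
    "binomial_tail_pvalue",
    "enrichment_score",
    "window_count_table",
    "best_window",
]

_LN10 = math.log(10.0)

#: a variant must beat the incumbent score by this much to count as an
#: improvement (guards greedy growth against float noise)
SCORE_EPS = 1e-9


# ---------------------------------------------------------------------------
# Binomial tail


def _log10_sf_exact(x: int, y: int, p: float) -> float:
    """log10 P(X >= x) by log-space summation (used when sf underflows)."""
    m = np.arange(x, y + 1, dtype=np.float64)
    logt = (
        special.gammaln(y + 1)
        - special.gammaln(m + 1)
        - special.gammaln(y - m + 1)
        + m * math.log(p)
        + (y - m) * math.log1p(-p)
    )
    return float(special.logsumexp(logt)) / _LN10


def _log10_sf(x: np.ndarray, y: int, p: np.ndarray) -> np.ndarray:
    """Vectorized log10 of the upper binomial tail, stable for tiny tails."""
    x = np.asarray(x)
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros(x.shape, dtype=np.float64)
    pos = np.flatnonzero(x > 0)
    if pos.size:
        with np.errstate(divide="ignore"):
            sf = special.bdtrc(x.ravel()[pos] - 1.0, y, p.ravel()[pos])
            vals = np.log10(sf)
        flat = out.ravel()
        flat[pos] = vals
        under = pos[~np.isfinite(vals)]
        for i in under:
            flat[i] = _log10_sf_exact(int(x.ravel()[i]), y, float(p.ravel()[i]))
        out = flat.reshape(x.shape)
    return np.minimum(out, 0.0)


def binomial_tail_pvalue(x: int, y: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(y, p), via the regularized incomplete beta."""
    if not 0 <= x <= y:
        raise ValueError(f"need 0 <= x <= y, got x={x}, y={y}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"need 0 < p < 1, got p={p}")
    if x == 0:
        return 1.0
    return float(special.bdtrc(x - 1, y, p))


@dataclass(frozen=True)
class BinomialEnrichment:
    """Foreground-vs-background binomial test for one window and motif."""

    x: int  # foreground sequences matched in the window
    y: int  # foreground sequences total
    p: float  # background per-sequence match probability (clamped)
    pvalue: float
    score: float  # -log10 pvalue


def clamp_background_probability(bg_matched: int, bg_total: int) -> float:
    """Background match frequency, kept away from 0 and 1.

    The smallest resolvable frequency given ``bg_total`` observations is
    ``1/(bg_total+1)``; a background count of 0 (or of ``bg_total``) is
    clamped there so no motif gets an infinite score.
    """
    if bg_matched == 0:
        return 1.0 / (bg_total + 1)
    if bg_matched == bg_total:
        return bg_total / (bg_total + 1)
    return bg_matched / bg_total


def enrichment_score(
    fg_matched: int, fg_total: int, bg_matched: int, bg_total: int
) -> BinomialEnrichment:
    """Binomial enrichment of foreground counts given background frequency."""
    if fg_total < 1 or bg_total < 1:
        raise ValueError("totals must be >= 1")
    if not 0 <= fg_matched <= fg_total or not 0 <= bg_matched <= bg_total:
        raise ValueError("matched counts must lie in [0, total]")
    p = clamp_background_probability(bg_matched, bg_total)
    l10 = float(_log10_sf(np.array([fg_matched]), fg_total, np.array([p]))[0])
    return BinomialEnrichment(
        x=fg_matched, y=fg_total, p=p, pvalue=float(10.0 ** l10), score=max(0.0, -l10)
    )


# ---------------------------------------------------------------------------
# Window grid


@dataclass(frozen=True)
class WindowGrid:
    """Anchor-relative window boundaries at multiples of a granularity step.

    Boundaries span ``[lo, hi]`` of the sequence extent; interior boundaries
    are multiples of ``granularity`` (so grid point 0 is a boundary whenever
    the sequences span the anchor), and the first/last boundaries are
    truncated to the extent.  A granularity at least as large as the span
    collapses the grid to the single full-length window.
    """

    boundaries: tuple[int, ...]
    granularity: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries must be strictly increasing, got {b}")

    @classmethod
    def from_extent(cls, lo: int, hi: int, granularity: int) -> "WindowGrid":
        if granularity < 1:
            raise ValueError(f"granularity must be >= 1, got {granularity}")
        if lo >= hi:
            raise ValueError(f"empty extent [{lo}, {hi})")
        if granularity >= hi - lo:
            return cls((lo, hi), granularity)
        first = granularity * math.ceil(lo / granularity)
        if first == lo:
            first += granularity
        interior = list(range(first, hi, granularity))
        return cls(tuple([lo] + interior + [hi]), granularity)

    @classmethod
    def from_sets(cls, granularity: int, *seq_sets: SequenceSet) -> "WindowGrid":
        extents = [s.extent() for s in seq_sets if len(s)]
        if not extents:
            raise ValueError("cannot build a grid from empty sequence sets")
        lo = min(e[0] for e in extents)
        hi = max(e[1] for e in extents)
        return cls.from_extent(lo, hi, granularity)

    @classmethod
    def full_length(cls, lo: int, hi: int) -> "WindowGrid":
        """Degenerate grid with the whole extent as the only window."""
        return cls((lo, hi), granularity=hi - lo)

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) - 1

    @property
    def is_full_length(self) -> bool:
        return len(self.boundaries) == 2

    def bin_of(self, position: int) -> int:
        """Index of the grid bin containing an anchor-relative position."""
        i = int(np.searchsorted(self.boundaries, position, side="right")) - 1
        if not 0 <= i < self.n_bins:
            raise ValueError(f"position {position} outside grid extent")
        return i


# ---------------------------------------------------------------------------
# Per-word presence index and count tables


class _KmerPresence:
    """(word code, sequence, grid bin) presence triples for one sequence set.

    Built once per (set, word length, grid); word-set evaluation then reduces
    to slicing out each member word's (sequence, bin) pairs and filling the
    window count table.
    """

    def __init__(self, seqs: SequenceSet, word_length: int, grid: WindowGrid):
        self.n_seqs = len(seqs)
        self.grid = grid
        self.word_length = word_length
        n_bins = grid.n_bins
        boundaries = np.asarray(grid.boundaries)
        code_parts, seq_parts, bin_parts = [], [], []
        for si, s in enumerate(seqs):
            positions, codes = sequence_codes(s, word_length)
            if not positions.size:
                continue
            bins = np.searchsorted(boundaries, positions, side="right") - 1
            ok = (bins >= 0) & (bins < n_bins)
            code_parts.append(codes[ok])
            seq_parts.append(np.full(int(ok.sum()), si, dtype=np.int64))
            bin_parts.append(bins[ok].astype(np.int64))
        if code_parts:
            codes = np.concatenate(code_parts)
            seq_idx = np.concatenate(seq_parts)
            bin_idx = np.concatenate(bin_parts)
            key = (codes * self.n_seqs + seq_idx) * n_bins + bin_idx
            key = np.unique(key)
            self._codes = key // (self.n_seqs * n_bins)
            rem = key % (self.n_seqs * n_bins)
            self._seq_idx = (rem // n_bins).astype(np.int64)
            self._bin_idx = (rem % n_bins).astype(np.int64)
        else:
            self._codes = np.empty(0, dtype=np.int64)
            self._seq_idx = np.empty(0, dtype=np.int64)
            self._bin_idx = np.empty(0, dtype=np.int64)
        # direct offset table for fast per-code slicing at small word lengths
        n_codes = 4**word_length
        if n_codes <= (1 << 18):
            self._offsets = np.searchsorted(self._codes, np.arange(n_codes + 1))
        else:
            self._offsets = None

    def pairs(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(sequence, bin) pairs for any word whose code is in ``codes``."""
        seq_out, bin_out = [], []
        for code in codes:
            if self._offsets is not None:
                lo, hi = self._offsets[code], self._offsets[code + 1]
            else:
                lo = np.searchsorted(self._codes, code, side="left")
                hi = np.searchsorted(self._codes, code, side="right")
            if lo < hi:
                seq_out.append(self._seq_idx[lo:hi])
                bin_out.append(self._bin_idx[lo:hi])
        if not seq_out:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        return np.concatenate(seq_out), np.concatenate(bin_out)

    def count_table(self, codes: np.ndarray) -> np.ndarray:
        """Upper-triangular window count table for a set of word codes.

        ``T[i, j]`` (boundary indices, ``i < j``) is the number of sequences
        with at least one match starting in ``[boundaries[i], boundaries[j])``.
        """
        seq_idx, bin_idx = self.pairs(codes)
        return _count_table_from_pairs(seq_idx, bin_idx, self.grid.n_bins)


def _count_table_from_pairs(
    seq_idx: np.ndarray, bin_idx: np.ndarray, n_bins: int
) -> np.ndarray:
    nb = n_bins + 1
    T = np.zeros((nb, nb), dtype=np.int64)
    if seq_idx.size == 0:
        return T
    uniq, inv = np.unique(seq_idx, return_inverse=True)
    m = uniq.size
    present = np.zeros((m, n_bins), dtype=bool)
    present[inv, bin_idx] = True
    # nxt[:, i] = first bin >= i holding a match (n_bins if none)
    nxt = np.empty((m, n_bins), dtype=np.int64)
    last = np.full(m, n_bins, dtype=np.int64)
    for i in range(n_bins - 1, -1, -1):
        last = np.where(present[:, i], i, last)
        nxt[:, i] = last
    # T[i, j] = #rows whose first match bin at/after i is < j
    T[:n_bins, :] = (nxt[:, :, None] < np.arange(n_bins + 1)[None, None, :]).sum(axis=0)
    return T


@dataclass(frozen=True)
class WindowCountTable:
    """Sequence counts for every grid window (upper triangle only)."""

    grid: WindowGrid
    counts: np.ndarray  # (n_boundaries, n_boundaries), valid for j > i

    def count(self, start: int, end: int) -> int:
        """Count for the window [start, end); both must be grid boundaries."""
        b = self.grid.boundaries
        try:
            i, j = b.index(start), b.index(end)
        except ValueError:
            raise ValueError(f"window [{start}, {end}) is off-grid {b}") from None
        if i >= j:
            raise ValueError(f"empty window [{start}, {end})")
        return int(self.counts[i, j])


def _codes_for(word_set: WordSet, strand_mode: str) -> np.ndarray:
    codes = {encode_word(w) for w in word_set.matching_words}
    if strand_mode == "both":
        codes |= {rc_code(c, word_set.length) for c in set(codes)}
    return np.array(sorted(codes), dtype=np.int64)


def window_count_table(
    m: WordSet, seqs: SequenceSet, grid: WindowGrid, strand_mode: str = "sense"
) -> WindowCountTable:
    """Count, for every grid window, the sequences containing the motif.

    A sequence is counted once per window if any of the motif's matching
    words starts inside it (in ``"both"`` mode, reverse-strand occurrences
    count too, located by their forward-strand start).
    """
    if strand_mode not in ("sense", "both"):
        raise ValueError(f"strand_mode must be 'sense' or 'both', got {strand_mode!r}")
    pres = _KmerPresence(seqs, m.length, grid)
    return WindowCountTable(grid, pres.count_table(_codes_for(m, strand_mode)))


# ---------------------------------------------------------------------------
# Window/strand optimization


class ScoringEngine:
    """Reusable foreground/background presence indexes plus window scoring.

    Building the per-set k-mer indexes dominates the cost of a single
    :func:`best_window` call; discovery builds one engine and evaluates
    thousands of word sets against it.
    """

    def __init__(
        self, fg: SequenceSet, bg: SequenceSet, word_length: int, grid: WindowGrid
    ):
        if len(fg) < 1 or len(bg) < 1:
            raise ValueError("scoring requires non-empty foreground and background")
        self.fg = fg
        self.bg = bg
        self.word_length = word_length
        self.grid = grid
        self._fg_pres = _KmerPresence(fg, word_length, grid)
        self._bg_pres = _KmerPresence(bg, word_length, grid)
        nb = len(grid.boundaries)
        self._iu = np.triu_indices(nb, k=1)
        b = np.asarray(grid.boundaries)
        self._starts = b[self._iu[0]]
        self._widths = b[self._iu[1]] - b[self._iu[0]]

    def best_for_codes(
        self, codes: np.ndarray
    ) -> tuple[Window, BinomialEnrichment]:
        """Best window and enrichment for the union of the given word codes."""
        Tfg = self._fg_pres.count_table(codes)
        Tbg = self._bg_pres.count_table(codes)
        n_fg, n_bg = len(self.fg), len(self.bg)
        x = Tfg[self._iu]
        xb = Tbg[self._iu]
        p = np.clip(xb / n_bg, 1.0 / (n_bg + 1), n_bg / (n_bg + 1))
        scores = -_log10_sf(x, n_fg, p)
        # ties: wider window first, then earlier start
        k = int(np.argmax(scores))
        tied = np.flatnonzero(scores == scores[k])
        if tied.size > 1:
            sub = np.lexsort((self._starts[tied], -self._widths[tied]))
            k = int(tied[sub[0]])
        i, j = self._iu[0][k], self._iu[1][k]
        b = self.grid.boundaries
        window = Window(int(b[i]), int(b[j]))
        enr = BinomialEnrichment(
            x=int(x[k]),
            y=n_fg,
            p=float(p[k]),
            pvalue=float(10.0 ** (-scores[k])),
            score=float(scores[k]),
        )
        return window, enr

    def evaluate(
        self, word_set: WordSet, strand_policy: str = "auto"
    ) -> tuple[Window, str, BinomialEnrichment]:
        """Best (window, strand mode, enrichment) for a word set.

        ``strand_policy`` is ``"sense"``, ``"both"``, or ``"auto"`` (try both
        and keep the better; ties prefer the wider window, then the earlier
        start, then sense-only).
        """
        if strand_policy not in ("sense", "both", "auto"):
            raise ValueError(f"invalid strand policy {strand_policy!r}")
        modes = ("sense", "both") if strand_policy == "auto" else (strand_policy,)
        best = None
        for mode in modes:
            window, enr = self.best_for_codes(_codes_for(word_set, mode))
            key = (-enr.score, -window.width, window.start, mode != "sense")
            if best is None or key < best[0]:
                best = (key, window, mode, enr)
        assert best is not None
        return best[1], best[2], best[3]

    def background_count(self, word_set: WordSet, window: Window, strand_mode: str) -> int:
        """Background sequences matching the motif within a given grid window."""
        T = self._bg_pres.count_table(_codes_for(word_set, strand_mode))
        b = self.grid.boundaries
        return int(T[b.index(window.start), b.index(window.end)])


def best_window(
    m: WordSet,
    fg: SequenceSet,
    bg: SequenceSet,
    grid: WindowGrid,
    strand_policy: str = "auto",
) -> tuple[Window, str, BinomialEnrichment]:
    """Maximize the enrichment score over all grid windows (and strands).

    Equivalent to scoring every window ``[boundaries[i], boundaries[j])``
    with ``i < j`` one at a time and returning the argmax; see
    :class:`ScoringEngine` for the reusable fast path.
    """
    engine = ScoringEngine(fg, bg, m.length, grid)
    return engine.evaluate(m, strand_policy)
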