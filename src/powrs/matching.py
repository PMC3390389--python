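"""Word enumeration, single-mutation variants, and strand-aware match indexing.

Matches are located by the forward-strand coordinate of their leftmost base,
on both strands: a reverse-strand occurrence of word ``w`` at forward
positions ``p..p+len(w)-1`` is the same thing as a forward occurrence of
``reverse_complement(w)`` starting at ``p``.  Overlapping occurrences are all
reported; ``N`` bases never match.

The integer k-mer encoding here (A=0, C=1, G=2, T=3, base-4 big-endian, so
codes sort lexicographically) is shared with the scoring engine.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .seqmodel import AnchoredSequence, SequenceSet, reverse_complement

__all__ = [
    "enumerate_seed_words",
    "single_mutation_variants",
    "find_word_matches",
    "MatchIndex",
    "build_match_index",
    "encode_word",
    "decode_word",
    "rc_code",
    "sequence_codes",
]

_BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

MAX_WORD_LENGTH = 12


def enumerate_seed_words(length: int) -> list[str]:
    """All 4^length ACGT words of the given length, lexicographic order."""
    if not 1 <= length <= MAX_WORD_LENGTH:
        raise ValueError(f"word length must be in [1, {MAX_WORD_LENGTH}], got {length}")
    return ["".join(p) for p in product(_BASES, repeat=length)]


def single_mutation_variants(seed: str) -> list[str]:
    """The 3*len(seed) words at Hamming distance exactly 1 from the seed."""
    seed = seed.upper()
    if not set(seed) <= set(_BASES):
        raise ValueError(f"seed must be an ACGT word, got {seed!r}")
    out = []
    for i, orig in enumerate(seed):
        for b in _BASES:
            if b != orig:
                out.append(seed[:i] + b + seed[i + 1 :])
    return out


def encode_word(w: str) -> int:
    """Base-4 integer code of an ACGT word (lexicographic order preserved)."""
    code = 0
    for c in w:
        code = code * 4 + _BASE_CODE[c]
    return code


def decode_word(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def rc_code(code: int, length: int) -> int:
    """Code of the reverse complement of the word with the given code."""
    out = 0
    for _ in range(length):
        out = out * 4 + (3 - (code & 3))
        code >>= 2
    return out


def sequence_codes(s: AnchoredSequence, length: int) -> tuple[np.ndarray, np.ndarray]:
    """K-mer codes for every valid start in a sequence.

    Returns ``(positions, codes)`` where positions are anchor-relative start
    coordinates and codes the base-4 word codes.  Starts whose word spans an
    ``N`` are omitted.
    """
    n = len(s.bases)
    if n < length:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    arr = np.frombuffer(s.bases.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
    base_codes = lut[arr].astype(np.int64)
    valid = base_codes >= 0
    # rolling base-4 code over windows of `length`
    codes = np.zeros(n - length + 1, dtype=np.int64)
    ok = np.ones(n - length + 1, dtype=bool)
    for k in range(length):
        codes = codes * 4 + np.where(valid[k : n - length + 1 + k], base_codes[k : n - length + 1 + k], 0)
        ok &= valid[k : n - length + 1 + k]
    positions = np.arange(n - length + 1, dtype=np.int64) - s.anchor_offset
    return positions[ok], codes[ok]


def find_word_matches(
    w: str, s: AnchoredSequence, strand_mode: str = "sense"
) -> list[int]:
    """Sorted anchor-relative start positions where the word matches.

    In ``"both"`` mode, forward-text matches of ``reverse_complement(w)``
    are included too (reverse-strand occurrences located by their leftmost
    forward-strand base); duplicates (palindromes) are collapsed.
    """
    if strand_mode not in ("sense", "both"):
        raise ValueError(f"strand_mode must be 'sense' or 'both', got {strand_mode!r}")
    w = w.upper()
    targets = {w}
    if strand_mode == "both":
        targets.add(reverse_complement(w))
    hits: set[int] = set()
    text = s.bases
    for t in targets:
        start = text.find(t)
        while start != -1:
            hits.add(start - s.anchor_offset)
            start = text.find(t, start + 1)
    return sorted(hits)


class MatchIndex:
    """Positions of each word in each sequence, for a declared strand mode.

    Querying ``(word, sequence id)`` returns exactly what a direct scan
    (:func:`find_word_matches`) would; the index is just precomputation.
    """

    def __init__(self, words: Sequence[str], seqs: SequenceSet, strand_mode: str):
        words = [w.upper() for w in words]
        if len({len(w) for w in words}) > 1:
            raise ValueError("all indexed words must have the same length")
        if strand_mode not in ("sense", "both"):
            raise ValueError(f"strand_mode must be 'sense' or 'both', got {strand_mode!r}")
        self.strand_mode = strand_mode
        self.word_length = len(words[0]) if words else 0
        self._index: dict[tuple[str, str], np.ndarray] = {}
        if not words:
            return
        length = self.word_length
        want: dict[int, list[str]] = {}
        for w in words:
            want.setdefault(encode_word(w), []).append(w)
            if strand_mode == "both":
                want.setdefault(encode_word(reverse_complement(w)), []).append(w)
        for s in seqs:
            positions, codes = sequence_codes(s, length)
            order = np.argsort(codes, kind="stable")
            codes_sorted = codes[order]
            pos_sorted = positions[order]
            for code, owners in want.items():
                lo = np.searchsorted(codes_sorted, code, side="left")
                hi = np.searchsorted(codes_sorted, code, side="right")
                if lo == hi:
                    continue
                found = pos_sorted[lo:hi]
                for w in owners:
                    key = (w, s.id)
                    prev = self._index.get(key)
                    self._index[key] = found if prev is None else np.union1d(prev, found)
        for key, v in self._index.items():
            self._index[key] = np.unique(v)

    def positions(self, word: str, seq_id: str) -> list[int]:
        """Sorted anchor-relative match start positions (empty if none)."""
        hit = self._index.get((word.upper(), seq_id))
        return [] if hit is None else [int(p) for p in hit]


def build_match_index(
    words: Iterable[str], seqs: SequenceSet, strand_mode: str = "sense"
) -> MatchIndex:
    """Build a :class:`MatchIndex` over the given words and sequences."""
    return MatchIndex(list(words), seqs, strand_mode)
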