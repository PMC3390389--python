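"""Anchored DNA sequences, the word-set motif model, and their on-disk formats.

All coordinates in this package are *anchor-relative*: every sequence carries
an ``anchor_offset`` giving the 0-based index of the base that sits at
anchor-relative position 0 (typically the transcription start site, or the
5' end of a 3' UTR).  Upstream positions are negative.  Windows of positions
are half-open ``[start, end)``.

A motif is a *word set*: a consensus seed word of fixed length plus a chosen
subset of its single-mutation variants.  Word sets are serialized as strings
with the seed base uppercase and variant bases lowercase, degenerate
positions grouped in square brackets, e.g. ``[Tac]GCTGCT[Agt]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "AnchoredSequence",
    "SequenceSet",
    "WordSet",
    "Window",
    "MotifResult",
    "FastaParseError",
    "AnchorRangeError",
    "MotifNotationError",
    "read_fasta_anchored",
    "write_fasta_anchored",
    "reverse_complement",
    "parse_motif_notation",
    "format_motif_notation",
    "hamming",
]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ANCHOR_TOKEN = re.compile(r"(?:^|\s)anchor=(-?\d+)(?:\s|$)")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class AnchorRangeError(ValueError):
    """Raised when an anchor offset falls outside a record's sequence."""


class MotifNotationError(ValueError):
    """Raised for malformed word-set motif notation strings."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length words."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length words")
    return sum(x != y for x, y in zip(a, b))


def reverse_complement(w: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    w = w.upper()
    if not set(w) <= DNA_ALPHABET:
        bad = sorted(set(w) - DNA_ALPHABET)
        raise ValueError(f"non-nucleotide characters in word: {bad}")
    return w.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchoredSequence:
    """A DNA sequence with a coordinate system relative to an anchor.

    Parameters
    ----------
    id :
        Sequence label, unique within a set.
    bases :
        Forward-strand sequence, 5'->3', over {A,C,G,T,N}.
    anchor_offset :
        0-based index of the base at anchor-relative position 0.  The base
        at string index ``t`` has anchor-relative coordinate
        ``t - anchor_offset``.
    """

    id: str
    bases: str
    anchor_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if not set(self.bases) <= DNA_ALPHABET:
            bad = sorted(set(self.bases) - DNA_ALPHABET)
            raise ValueError(f"sequence {self.id!r}: invalid characters {bad}")
        if not 0 <= self.anchor_offset <= len(self.bases):
            raise AnchorRangeError(
                f"sequence {self.id!r}: anchor offset {self.anchor_offset} "
                f"outside [0, {len(self.bases)}]"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def start(self) -> int:
        """Anchor-relative coordinate of the first base."""
        return -self.anchor_offset

    @property
    def end(self) -> int:
        """Anchor-relative coordinate one past the last base."""
        return len(self.bases) - self.anchor_offset

    def base_at(self, position: int) -> str:
        """Base at an anchor-relative position."""
        return self.bases[position + self.anchor_offset]


@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of anchored sequences with unique ids."""

    members: tuple[AnchoredSequence, ...]
    role: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        ids = [s.id for s in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in set: {dupes}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[AnchoredSequence]:
        return iter(self.members)

    def __getitem__(self, i: int) -> AnchoredSequence:
        return self.members[i]

    @property
    def size(self) -> int:
        return len(self.members)

    def extent(self) -> tuple[int, int]:
        """Anchor-relative [min, max) coordinate range covered by any member."""
        if not self.members:
            raise ValueError("empty sequence set has no extent")
        return (min(s.start for s in self.members), max(s.end for s in self.members))


@dataclass(frozen=True)
class WordSet:
    """A motif: a seed word plus single-mutation variant words.

    Every variant differs from the seed at exactly one position; a sequence
    matches the motif wherever it contains any member word.
    """

    seed: str
    variants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seed = self.seed.upper()
        object.__setattr__(self, "seed", seed)
        object.__setattr__(self, "variants", frozenset(v.upper() for v in self.variants))
        if not seed or not set(seed) <= set("ACGT"):
            raise ValueError(f"seed must be a nonempty ACGT word, got {self.seed!r}")
        for v in self.variants:
            if len(v) != len(seed) or hamming(v, seed) != 1:
                raise ValueError(
                    f"variant {v!r} is not at Hamming distance 1 from seed {seed!r}"
                )

    @property
    def length(self) -> int:
        return len(self.seed)

    @property
    def matching_words(self) -> tuple[str, ...]:
        """Seed plus variants, deterministically ordered (seed first)."""
        return (self.seed, *sorted(self.variants))

    def with_variant(self, variant: str) -> "WordSet":
        return WordSet(self.seed, self.variants | {variant.upper()})

    def __str__(self) -> str:
        return format_motif_notation(self)


@dataclass(frozen=True)
class Window:
    """Half-open range [start, end) of anchor-relative positions."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Window") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class MotifResult:
    """An optimized motif with its best window, strand mode and score."""

    word_set: WordSet
    window: Window
    strand_mode: str  # "sense" or "both"
    score: float
    pvalue: float
    fg_matched: int
    fg_total: int
    bg_matched: int
    bg_total: int
    suppressed: bool = False
    group_id: int | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fg_matched <= self.fg_total:
            raise ValueError("foreground counts out of range")
        if not 0 <= self.bg_matched <= self.bg_total:
            raise ValueError("background counts out of range")
        if self.score < 0:
            raise ValueError("score must be non-negative")


# ---------------------------------------------------------------------------
# FASTA I/O


def _global_offset_for(record_len: int, anchor_offset) -> int | None:
    if anchor_offset is None:
        return None
    return int(anchor_offset)


def read_fasta_anchored(
    path: str | Path,
    anchor_offset: int | None = None,
    role: str = "",
) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet` with anchor coordinates.

    A header token ``anchor=<int>`` on a record overrides the global
    ``anchor_offset`` for that record.  Records whose effective offset falls
    outside their sequence are rejected.

    Raises
    ------
    FastaParseError
        Malformed FASTA (names the offending line) or an empty file.
    AnchorRangeError
        Anchor offset out of range for one or more records (names their ids),
        or a record with no usable offset at all.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: no sequences")

    members: list[AnchoredSequence] = []
    bad_anchor: list[str] = []
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            m = _ANCHOR_TOKEN.search(record.description)
            if m:
                offset = int(m.group(1))
            elif anchor_offset is not None:
                offset = int(anchor_offset)
            else:
                raise AnchorRangeError(
                    f"record {record.id!r}: no anchor offset (no global value and "
                    "no 'anchor=' header token)"
                )
            bases = str(record.seq).upper()
            if not 0 <= offset <= len(bases):
                bad_anchor.append(record.id)
                continue
            members.append(AnchoredSequence(record.id, bases, offset))
    if bad_anchor:
        raise AnchorRangeError(
            f"anchor offset out of range for records: {', '.join(bad_anchor)}"
        )
    if not members:
        raise FastaParseError(f"{path}: no sequences")
    return SequenceSet(tuple(members), role=role)


def write_fasta_anchored(seqs: SequenceSet | Iterable[AnchoredSequence], path: str | Path) -> None:
    """Write sequences as FASTA with an ``anchor=<int>`` header token."""
    with open(path, "w") as out:
        for s in seqs:
            out.write(f">{s.id} anchor={s.anchor_offset}\n")
            for i in range(0, len(s.bases), 70):
                out.write(s.bases[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Word-set motif notation


_NOTATION_TOKEN = re.compile(r"\[([A-Za-z]+)\]|([ACGT])")


def parse_motif_notation(s: str) -> WordSet:
    """Parse a word-set notation string into a :class:`WordSet`.

    Each position is either a bare uppercase base (seed base, no variants)
    or a bracket group of exactly one uppercase base followed by one or more
    lowercase variant bases, e.g. ``[Tac]GCTGCT[Agt]``.
    """
    seed_chars: list[str] = []
    variant_specs: list[tuple[int, str]] = []  # (position, variant base)
    pos = 0
    i = 0
    while i < len(s):
        m = _NOTATION_TOKEN.match(s, i)
        if not m:
            raise MotifNotationError(f"bad character at offset {i} in {s!r}")
        if m.group(2):
            seed_chars.append(m.group(2))
        else:
            group = m.group(1)
            uppers = [c for c in group if c.isupper()]
            lowers = [c for c in group if c.islower()]
            if len(uppers) != 1 or not lowers:
                raise MotifNotationError(
                    f"bracket group {group!r} must have exactly one uppercase "
                    "seed base and at least one lowercase variant base"
                )
            if uppers[0] not in "ACGT" or not set(lowers) <= set("acgt"):
                raise MotifNotationError(f"non-ACGT base in group {group!r}")
            if group[0] != uppers[0]:
                raise MotifNotationError(
                    f"bracket group {group!r} must start with the seed base"
                )
            seed_chars.append(uppers[0])
            for c in lowers:
                if c.upper() == uppers[0]:
                    raise MotifNotationError(
                        f"variant base {c!r} repeats the seed base in {group!r}"
                    )
                variant_specs.append((pos, c.upper()))
        pos += 1
        i = m.end()
    seed = "".join(seed_chars)
    if not seed:
        raise MotifNotationError("empty motif string")
    variants = frozenset(
        seed[:p] + base + seed[p + 1 :] for p, base in variant_specs
    )
    return WordSet(seed, variants)


def format_motif_notation(m: WordSet) -> str:
    """Render a :class:`WordSet` in bracket notation (inverse of parsing).

    Variant bases within a bracket are lowercase, alphabetically ordered;
    positions without variants are bare uppercase seed bases.
    """
    by_pos: dict[int, list[str]] = {}
    for v in m.variants:
        (p,) = [i for i, (a, b) in enumerate(zip(m.seed, v)) if a != b]
        by_pos.setdefault(p, []).append(v[p].lower())
    out = []
    for p, base in enumerate(m.seed):
        if p in by_pos:
            out.append("[" + base + "".join(sorted(by_pos[p])) + "]")
        else:
            out.append(base)
    return "".join(out)
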