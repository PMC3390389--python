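"""Synthetic anchored-sequence fixtures with planted, position-biased motifs.

The generator emulates the enrichment structure that position-sensitive
discovery assumes: an i.i.d. random background of configurable base
composition, plus a foreground set in which a consensus word is planted —
at start positions drawn uniformly from a bounded anchor-relative window,
on a chosen strand, with a controlled chance of carrying exactly one
single-base mutation (the reach of the word-set motif model).  Planting
overwrites bases in place, so sequence lengths and anchor coordinates are
untouched.  All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqmodel import (
    AnchoredSequence,
    SequenceSet,
    reverse_complement,
    write_fasta_anchored,
)

__all__ = [
    "PlantSpec",
    "PlantRecord",
    "generate_background",
    "plant_motif",
    "transversion_series",
    "make_benchmark_fixture",
    "write_manifest",
    "BENCHMARK_PROFILES",
]

_BASES = "ACGT"

#: fixed seed giving the canonical benchmark fixture
DEFAULT_FIXTURE_SEED = 20120101


@dataclass(frozen=True)
class PlantSpec:
    """How to plant motif instances into a foreground set."""

    consensus: str
    window: tuple[int, int]  # anchor-relative [lo, hi) for planted starts
    strand: str = "sense"  # sense | antisense | both (50/50)
    per_seq_prob: float = 1.0
    variant_prob: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.consensus.upper()) <= set(_BASES):
            raise ValueError(f"consensus must be an ACGT word, got {self.consensus!r}")
        object.__setattr__(self, "consensus", self.consensus.upper())
        if self.strand not in ("sense", "antisense", "both"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0.0 <= self.per_seq_prob <= 1.0:
            raise ValueError("per_seq_prob must be in [0, 1]")
        if not 0.0 <= self.variant_prob <= 1.0:
            raise ValueError("variant_prob must be in [0, 1]")
        lo, hi = self.window
        if hi - len(self.consensus) + 1 <= lo:
            raise ValueError(
                f"window [{lo}, {hi}) too small for a {len(self.consensus)}-mer"
            )


@dataclass(frozen=True)
class PlantRecord:
    """One planted instance: where it went and what was written."""

    seq_id: str
    position: int  # anchor-relative start of the written word (forward strand)
    strand: str  # sense | antisense
    word: str  # the exact forward-strand text written


def generate_background(
    n: int,
    length: int,
    anchor_offset: int,
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    rng_seed: int = 0,
    id_prefix: str = "seq",
    role: str = "background",
) -> SequenceSet:
    """n i.i.d. random sequences of the given composition (A, C, G, T order)."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-12 or (comp < 0).any():
        raise ValueError(f"composition must be 4 non-negative probabilities summing to 1")
    rng = np.random.default_rng(rng_seed)
    draws = rng.choice(4, size=(n, length), p=comp)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    members = tuple(
        AnchoredSequence(f"{id_prefix}_{i:05d}", lut[row].tobytes().decode(), anchor_offset)
        for i, row in enumerate(draws)
    )
    return SequenceSet(members, role=role)


def _mutate_once(word: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(len(word)))
    alternatives = [b for b in _BASES if b != word[pos]]
    base = alternatives[int(rng.integers(3))]
    return word[:pos] + base + word[pos + 1 :]


def plant_motif(
    seqs: SequenceSet, spec: PlantSpec
) -> tuple[SequenceSet, list[PlantRecord]]:
    """Overwrite motif instances into sequences per the plant spec.

    Each sequence independently receives, with probability ``per_seq_prob``,
    one instance: the consensus, mutated at exactly one uniform position
    with probability ``variant_prob``, reverse-complemented for antisense
    plants, written at a start position uniform over the spec window (the
    whole word lies inside the window).  Returns the new set plus a
    manifest of what was planted where.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ell = len(spec.consensus)
    lo, hi = spec.window
    manifest: list[PlantRecord] = []
    members: list[AnchoredSequence] = []
    for s in seqs:
        if lo < s.start or hi > s.end:
            raise ValueError(
                f"plant window [{lo}, {hi}) outside sequence {s.id!r} extent "
                f"[{s.start}, {s.end})"
            )
        if rng.random() >= spec.per_seq_prob:
            members.append(s)
            continue
        word = spec.consensus
        if rng.random() < spec.variant_prob:
            word = _mutate_once(word, rng)
        if spec.strand == "both":
            strand = "sense" if rng.random() < 0.5 else "antisense"
        else:
            strand = spec.strand
        text = word if strand == "sense" else reverse_complement(word)
        position = int(rng.integers(lo, hi - ell + 1))  # word fits in window
        t = position + s.anchor_offset
        bases = s.bases[:t] + text + s.bases[t + ell :]
        members.append(AnchoredSequence(s.id, bases, s.anchor_offset))
        manifest.append(PlantRecord(s.id, position, strand, text))
    return SequenceSet(tuple(members), role=seqs.role), manifest


_TRANSVERSION = str.maketrans("ACGTN", "CATGN")


def transversion_series(
    s: AnchoredSequence, block: int = 10
) -> list[AnchoredSequence]:
    """Systematic per-block transversion mutants of a sequence.

    Output ``k`` (1-based from the 5' end) equals the input with bases in
    block ``k`` mapped A<->C and G<->T; all other bases untouched.  The last
    block may be short; N bases are preserved with a warning.
    """
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    out = []
    for k, start in enumerate(range(0, len(s.bases), block), start=1):
        segment = s.bases[start : start + block]
        if "N" in segment:
            warnings.warn(
                f"sequence {s.id!r} block {k}: N bases preserved under transversion"
            )
        mutated = s.bases[:start] + segment.translate(_TRANSVERSION) + s.bases[start + block :]
        out.append(AnchoredSequence(f"{s.id}_tv{k:02d}", mutated, s.anchor_offset))
    return out


#: named fixture presets: (n_bg, n_fg, length, anchor_offset, plant parameters)
BENCHMARK_PROFILES: dict[str, dict] = {
    # dimensions of a typical plant-promoter run: 1000 bp upstream + 50 bp
    # downstream of the TSS, a few hundred foreground sequences against a
    # genome-scale background, with a motif confined to the 100 bp upstream
    # of the anchor
    "default": dict(
        n_bg=2000,
        n_fg=200,
        length=1050,
        anchor_offset=1000,
        consensus="AAACCCTA",
        window=(-100, 0),
        strand="sense",
        per_seq_prob=0.4,
        variant_prob=0.3,
    ),
    # scaled-down variant for fast exercises
    "small": dict(
        n_bg=300,
        n_fg=60,
        length=300,
        anchor_offset=250,
        consensus="AAACCCTA",
        window=(-100, 0),
        strand="sense",
        per_seq_prob=0.6,
        variant_prob=0.3,
    ),
}


def make_benchmark_fixture(
    profile: str = "default", rng_seed: int | None = None
) -> tuple[SequenceSet, SequenceSet, list[PlantRecord]]:
    """Build a named (foreground, background, manifest) benchmark fixture.

    Foreground and background share the same uniform composition process;
    the foreground additionally carries planted instances.  Reproducible:
    the profile's canonical form uses a fixed seed unless one is given.
    """
    if profile not in BENCHMARK_PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; known: {sorted(BENCHMARK_PROFILES)}"
        )
    p = BENCHMARK_PROFILES[profile]
    seed = DEFAULT_FIXTURE_SEED if rng_seed is None else int(rng_seed)
    ss = np.random.SeedSequence(seed)
    bg_seed, fg_seed, plant_seed = (int(s) for s in ss.generate_state(3) >> 1)
    bg = generate_background(
        p["n_bg"], p["length"], p["anchor_offset"], rng_seed=bg_seed,
        id_prefix="bg", role="background",
    )
    fg_clean = generate_background(
        p["n_fg"], p["length"], p["anchor_offset"], rng_seed=fg_seed,
        id_prefix="fg", role="foreground",
    )
    spec = PlantSpec(
        consensus=p["consensus"],
        window=p["window"],
        strand=p["strand"],
        per_seq_prob=p["per_seq_prob"],
        variant_prob=p["variant_prob"],
        rng_seed=plant_seed,
    )
    fg, manifest = plant_motif(fg_clean, spec)
    return fg, bg, manifest


def write_manifest(manifest: list[PlantRecord], path: str | Path) -> None:
    """Write a planting manifest as TSV (seq id, position, strand, word)."""
    with open(path, "w") as out:
        out.write("seq_id\tposition\tstrand\tword\n")
        for rec in manifest:
            out.write(f"{rec.seq_id}\t{rec.position}\t{rec.strand}\t{rec.word}\n")
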