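import numpy as np
import pytest

from powrs.seqmodel import AnchoredSequence, SequenceSet
from powrs.synthetic import make_benchmark_fixture


def random_sequence_set(
    rng: np.random.Generator,
    n: int,
    length: int,
    anchor_offset: int,
    id_prefix: str = "s",
) -> SequenceSet:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    members = tuple(
        AnchoredSequence(
            f"{id_prefix}{i}",
            lut[rng.integers(0, 4, size=length)].tobytes().decode(),
            anchor_offset,
        )
        for i in range(n)
    )
    return SequenceSet(members)


def all_base_sequences(base: str, n: int, length: int, anchor_offset: int, prefix="s"):
    """Homopolymer sequences: a blank canvas for hand-planted matches."""
    return SequenceSet(
        tuple(
            AnchoredSequence(f"{prefix}{i}", base * length, anchor_offset)
            for i in range(n)
        )
    )


def plant_at(seqs: SequenceSet, plants: dict[str, tuple[int, str]]) -> SequenceSet:
    """Overwrite `word` at anchor-relative `position` in the named sequences."""
    members = []
    for s in seqs:
        if s.id in plants:
            pos, word = plants[s.id]
            t = pos + s.anchor_offset
            members.append(
                AnchoredSequence(s.id, s.bases[:t] + word + s.bases[t + len(word):], s.anchor_offset)
            )
        else:
            members.append(s)
    return SequenceSet(tuple(members))


@pytest.fixture(scope="session")
def small_fixture():
    """The scaled-down planted-motif benchmark fixture (fixed seed)."""
    return make_benchmark_fixture("small")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
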