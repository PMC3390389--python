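"""Result de-duplication, grouping, ranking, density profiles and reports.

Discovery deliberately returns similar, redundant motifs for a real binding
site.  Post-processing (a) suppresses any motif whose seed appears among the
*included* variants of a higher-scoring, itself-unsuppressed motif, (b)
groups motifs that plainly describe the same binding site — seeds sharing at
least 6 contiguous identical bases under some ungapped shift, in either
orientation — and (c) ranks one unsuppressed representative per group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqmodel import (
    MotifResult,
    SequenceSet,
    WordSet,
    format_motif_notation,
    reverse_complement,
)

__all__ = [
    "MotifReport",
    "suppress_subsumed",
    "group_related_motifs",
    "seeds_share_contiguous_run",
    "positional_density",
    "write_report",
    "build_report",
]

REPORT_COLUMNS = [
    "rank",
    "group_id",
    "motif",
    "seed",
    "score",
    "window_start",
    "window_end",
    "strands",
    "fg_matched",
    "fg_total",
    "bg_matched",
    "bg_total",
    "pvalue",
    "suppressed",
]

_STRAND_LABEL = {"sense": "One", "both": "Both"}


def suppress_subsumed(results: list[MotifResult]) -> list[MotifResult]:
    """Flag motifs whose seed is an included variant of a better motif.

    Results must be sorted by score descending.  Only strictly
    higher-scoring motifs that are themselves unsuppressed act as
    suppressors, so a suppressed duplicate never erases a distinct motif
    further down the list.  Flags are set in place; the list is returned.
    """
    for idx, r in enumerate(results):
        r.suppressed = False
        for r2 in results[:idx]:
            if (
                not r2.suppressed
                and r2.score > r.score
                and r.word_set.seed in r2.word_set.variants
            ):
                r.suppressed = True
                break
    return results


def _longest_common_run(a: str, b: str) -> int:
    """Longest run of identical bases between equal-position characters."""
    best = run = 0
    for x, y in zip(a, b):
        run = run + 1 if x == y else 0
        best = max(best, run)
    return best


def seeds_share_contiguous_run(a: str, b: str, min_contig: int = 6) -> bool:
    """True if some ungapped shift/orientation aligns >= min_contig identical bases.

    Both relative shifts of either seed and the reverse-complement
    orientation of the second seed are considered.
    """
    for bb in (b, reverse_complement(b)):
        for shift in range(-(len(bb) - min_contig), len(a) - min_contig + 1):
            if shift >= 0:
                ov_a, ov_b = a[shift:], bb
            else:
                ov_a, ov_b = a, bb[-shift:]
            if _longest_common_run(ov_a, ov_b) >= min_contig:
                return True
    return False


def group_related_motifs(
    results: list[MotifResult], min_contig: int = 6
) -> list[int]:
    """Partition motifs into connected components of seed similarity.

    Two motifs are linked when their seeds share at least ``min_contig``
    contiguous identical bases under some ungapped shift, in either
    orientation; groups are the connected components of that relation.
    Group ids are 1-based, ordered by each group's best score.  The ids are
    also written onto the results' ``group_id`` fields.
    """
    n = len(results)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if seeds_share_contiguous_run(
                results[i].word_set.seed, results[j].word_set.seed, min_contig
            ):
                parent[find(i)] = find(j)

    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    # order groups by their best member's (score, seed) for determinism
    ordered = sorted(
        roots.values(),
        key=lambda idxs: min(
            (-results[i].score, results[i].word_set.seed) for i in idxs
        ),
    )
    ids = [0] * n
    for gid, idxs in enumerate(ordered, start=1):
        for i in idxs:
            ids[i] = gid
            results[i].group_id = gid
    return ids


@dataclass
class MotifReport:
    """Ordered, grouped, rank-annotated discovery results with provenance."""

    results: list[MotifResult]
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def representatives(self) -> list[MotifResult]:
        """The ranked, unsuppressed group representatives, best first."""
        return sorted(
            (r for r in self.results if r.rank is not None),
            key=lambda r: r.rank,
        )


def build_report(
    results: list[MotifResult],
    min_contig: int = 6,
    config: dict | None = None,
    provenance: dict | None = None,
) -> MotifReport:
    """Sort, suppress, group and rank raw discovery results.

    One unsuppressed representative per group (its highest-scoring member)
    receives a dense 1-based rank; all other rows carry no rank.
    """
    results = sorted(results, key=lambda r: (-r.score, r.word_set.seed))
    suppress_subsumed(results)
    group_related_motifs(results, min_contig)
    for r in results:
        r.rank = None
    groups: dict[int, list[MotifResult]] = {}
    for r in results:
        groups.setdefault(r.group_id, []).append(r)
    reps = []
    for gid, members in groups.items():
        unsup = [r for r in members if not r.suppressed]
        rep = min(
            unsup or members, key=lambda r: (-r.score, r.word_set.seed)
        )
        reps.append(rep)
    reps.sort(key=lambda r: (-r.score, r.word_set.seed))
    for rank, rep in enumerate(reps, start=1):
        rep.rank = rank
    return MotifReport(results, config=config or {}, provenance=provenance or {})


def positional_density(
    m: WordSet,
    seqs: SequenceSet,
    bandwidth: float = 25.0,
    strand_mode: str = "sense",
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of motif occurrence positions.

    Every occurrence of every matching word contributes one Gaussian kernel
    centered on its start position.  The curve is evaluated on a 1-bp
    lattice spanning the sequences' coordinate extent and normalized so
    that it integrates to (total occurrences / number of sequences) —
    occurrences per base pair per sequence.  Kernel mass falling outside
    the lattice is lost to truncation, so the integral is approximate for
    occurrences within a few bandwidths of the extent edges.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    from .matching import find_word_matches

    lo, hi = seqs.extent()
    lattice = np.arange(lo, hi, dtype=np.float64)
    centers: list[int] = []
    for s in seqs:
        for w in m.matching_words:
            centers.extend(find_word_matches(w, s, strand_mode))
    density = np.zeros_like(lattice)
    if centers:
        c = np.asarray(centers, dtype=np.float64)
        norm = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
        for chunk in np.array_split(c, max(1, len(c) // 512)):
            z = (lattice[None, :] - chunk[:, None]) / bandwidth
            density += norm * np.exp(-0.5 * z * z).sum(axis=0)
        density /= len(seqs)
    return lattice, density


def _format_row(r: MotifResult) -> list[str]:
    return [
        "" if r.rank is None else str(r.rank),
        str(r.group_id if r.group_id is not None else ""),
        format_motif_notation(r.word_set),
        r.word_set.seed,
        f"{r.score:.1f}",
        str(r.window.start),
        str(r.window.end),
        _STRAND_LABEL[r.strand_mode],
        str(r.fg_matched),
        str(r.fg_total),
        str(r.bg_matched),
        str(r.bg_total),
        f"{r.pvalue:.3e}",
        "yes" if r.suppressed else "no",
    ]


def write_report(
    report: MotifReport, path: str | Path, json_twin: str | Path | None = None
) -> None:
    """Write the report as a TSV table (optionally with a JSON twin).

    Configuration echo and provenance are embedded as ``#`` comment lines
    before the header; scores are printed with one decimal place and
    p-values in scientific notation; the strands column uses "One"/"Both".
    """
    path = Path(path)
    with open(path, "w") as out:
        for k, v in report.config.items():
            out.write(f"# config: {k}={v}\n")
        for k, v in report.provenance.items():
            out.write(f"# {k}: {v}\n")
        out.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in report.results:
            out.write("\t".join(_format_row(r)) + "\n")
    if json_twin is not None:
        payload = {
            "config": report.config,
            "provenance": report.provenance,
            "results": [
                dict(zip(REPORT_COLUMNS, _format_row(r))) for r in report.results
            ],
        }
        with open(json_twin, "w") as out:
            json.dump(payload, out, indent=2)
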