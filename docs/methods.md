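# Methods

## Model and procedure

`powrs` searches for word-set motifs enriched in a foreground set *A* of
anchored DNA sequences relative to a background set *B*. A word set is a
seed word k\* of fixed length ℓ plus a subset of its 3ℓ single-mutation
variants; a sequence matches wherever it contains any member word exactly.
The statistic for a motif K, window [i, j) and strand mode is the upper
binomial tail

    score = −log10 P(X ≥ x),   X ~ Binomial(y, p)

with x = |{s ∈ A : some word of K starts in [i, j) in s}|, y = |A|, and
p the analogous fraction of B. The assumptions are those of the binomial
approximation: background sequences are treated as independent trials with
a common per-sequence match probability, and sequences are counted at most
once per window (occurrence multiplicity is deliberately ignored, which
makes the statistic robust to repeats within one promoter). Windows live
on a granularity grid anchored at coordinate 0 so that reported boundaries
are round numbers relative to the TSS; p-values are not corrected for
multiple testing because overlapping windows and similar motifs are highly
dependent — scores are comparable, not calibrated error rates.

Discovery proceeds in two passes. The seed pass scores all 4^ℓ words as
bare motifs, window- and strand-optimized, and retains the `top_n` best.
Scoring the seed pass position-sensitively (rather than full-length)
matters: strongly localized elements such as the TATA box can rank highly
in a narrow window while invisible over the full sequence. Each retained
seed is then grown greedily: every cycle re-evaluates all not-yet-included
variants of the *original* seed (window and strand re-optimized per
candidate) and adds the best strictly-improving one. Restricting to
variants of the seed (no variants of variants) bounds the motif at
Hamming distance 1 from its consensus; words two mutations away get their
own chance as seeds, which is why results deliberately contain redundant
near-duplicates, handled by suppression and grouping rather than by
broadening the model.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `word_length` ℓ | 8 | seed word length (bp); 6 is a useful faster setting for short cores |
| `granularity` | 25 | window grid step (bp); ~1/40 of the sequence span balances localization against count statistics |
| `top_n` | 800 | seeds optimized after the seed pass; compute-saving cutoff, not statistical |
| `strand_policy` | `auto` | score sense-only and both-strand matching, keep the better |
| `min_contig` | 6 | contiguous identical bases (any ungapped shift, either orientation) linking two seeds into one group |
| density `bandwidth` | 25 bp | Gaussian kernel width for occurrence profiles, one grid step |

## Numerical choices

- Binomial tails go through the regularized incomplete beta
  (`scipy.special.bdtrc`); where the tail underflows float64, the score is
  recovered by log-space summation of the terms, so deep enrichments
  (scores ≫ 300) remain finite and ordered.
- The background probability is clamped to [1/(|B|+1), |B|/(|B|+1)]: a
  motif absent from the background gets the smallest resolvable frequency
  rather than an infinite score.
- Greedy growth requires an improvement > 1e−9 in score; among equal
  gains the lexicographically smallest variant wins. All other ties are
  fixed (wider window first, then earlier start, then sense before both;
  equal scores order by seed word), making runs byte-reproducible.
- A match belongs to a window by its start position (forward-strand
  coordinate of the leftmost base, on either strand); matches may span
  the anchor. Grid edges are truncated to the sequence extent, and a
  granularity at least the span collapses the grid to one full-length
  window.
- `N` bases never match any word; ragged sequence lengths are allowed,
  each sequence carrying its own anchor offset.

## Synthetic data

The generator emulates exactly the structure the algorithm assumes: i.i.d.
background of configurable composition, plus a consensus planted into
foreground sequences at starts uniform in a bounded anchor-relative window
(the whole word inside the window), on a chosen strand, with probability
`variant_prob` of exactly one uniform single-base mutation — the word-set
model's reach. Planting overwrites in place, preserving lengths and
coordinates. The default benchmark profile is 2000 background and 200
foreground sequences of 1050 bp (anchor offset 1000, i.e. −1000..+50),
consensus `AAACCCTA` planted sense-strand in [−100, 0) at per-sequence
probability 0.4 with `variant_prob` 0.3 — a few hundred co-regulated
promoters against a genome-scale background with a moderately degenerate,
localized element. A `small` profile (60/300 × 300 bp) serves fast
exercises.

What the generator does *not* emulate: repeat families, transposons,
nucleosome positioning, CpG/GC skew, higher-order composition, or
correlated backgrounds. Passing recovery tests therefore demonstrates
correctness of the search and scoring machinery under the model's own
assumptions, not performance on real genomes, where background structure
can mimic positional enrichment.

## Design decisions

- Coordinates are anchor-relative and 0-based with half-open windows
  [i, j); position 0 is the base at the anchor. Inclusive prose ranges
  like "−300 to −75" map to [−300, −75).
- Reverse-strand occurrences are indexed by the forward-strand coordinate
  of their leftmost base, which keeps windowing strand-symmetric and makes
  both-strand matching a pure union of the word's and its reverse
  complement's sense matches.
- Suppression uses only *unsuppressed* higher-scoring motifs as
  suppressors, so a suppressed duplicate cannot erase a distinct motif
  further down the ranking. Grouping considers reverse-complement
  orientation, since the same element can surface in both orientations.
- The seed pass optimizes windows and strands (not a fixed full-length
  window), so position-specific elements are already visible at seed
  selection.
- The match index is a sorted k-mer code array per sequence set; any
  index with the same contract (suffix array, hash) would do — the
  contract, not the data structure, is what the tests pin down.
- `Simple6`/`Simple8`-style ablations are one `simple` mode with
  `word_length` a parameter; `powrs_fl` forces the full-length grid.

## Problem sizes in tests

Unit tests use handcrafted or small random instances (tens of sequences,
ℓ ≤ 6) with exhaustive oracles: exact-fraction or extended-precision tail
summation for the binomial, and per-window direct re-scans for count
tables and window optimization. The end-to-end recovery test and the
acceptance script run the full default profile (200/2000 × 1050 bp,
ℓ = 8, 800 seeds grown), a few minutes of compute, and check seed
identity (Hamming ≤ 1 to the planted consensus at group rank 1), window
overlap with the planted [−100, 0), sense-strand call, and that the
full-length ablation scores the same seed no higher.

## Known limitations

- The binomial treats background sequences as exchangeable; composition
  differences between foreground and background are not modeled and can
  produce enriched low-complexity words (real analyses should use a
  matched background).
- Greedy variant addition is not guaranteed to find the optimal variant
  subset; ties and near-ties can path-depend (resolved deterministically).
- Window optimization maximizes an uncorrected score over ~O((L/B)²)
  windows; reported windows are best-scoring, not confidence regions, and
  low-power settings default to wide windows.
- Gapped or longer-than-ℓ motifs surface as groups of overlapping word
  sets rather than as single results.
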