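# Methods

## Segmentation model

The genome is treated as a union of per-chromosome half-open integer
intervals (BED convention, 0-based). Given M merged peak tracks, the
per-base mark-presence vector is a function from positions to {0,1}^M;
the segmentation is the coarsest partition of each chromosome into
intervals on which that function is constant. It is computed by a
boundary sweep: the sorted union of all peak starts/ends plus the
chromosome bounds yields elementary ranges of constant membership; the
code of each range is assembled bitwise (track i → bit i, track 0 →
least significant); equal-code neighbours are then coalesced so that
adjacent segments always differ in code (maximality). Chromosomes with
no peaks are one code-0 segment. Because membership is constant on each
elementary range, testing the range's first base is exact, not a
sampling approximation.

Same-track peaks are merged on load (union, including book-ended
intervals): presence is per-base boolean, so overlap structure within
one track carries no information. Peaks overhanging the chromosome end
are clipped with a warning rather than rejected, since public peak files
commonly overhang; peaks on chromosomes absent from the genome index are
an error. Strand is ignored for peak tracks (histone marks are
unstranded).

**Short-segment filter.** Segments with length strictly below
`min_length` (default 200 nt) go to a *discarded* side list. The strict
inequality means a 200-nt segment is retained. Discarded segments keep
their coordinates and codes: the chain, triplet and lost-peak
diagnostics need them. The default reflects the observation that
sub-200-nt fragments are dominated by peak-caller boundary uncertainty
(their lengths concentrate on small multiples of the peak callers'
rounding grid).

## Descriptive statistics

**Adjacent pairs.** Pairs are ordered (5′, 3′) and counted only for
retained segments *directly contiguous in the full tiling*; a pair
separated by a discarded segment is routed to the triplet analysis
instead. This keeps the observed diagonal structurally zero (contiguous
maximal ranges differ in code), which in turn fixes the expected model:
the independence product of retained code frequencies renormalized over
off-diagonal cells,

    E[i,j] = n_pairs · p_i · p_j / (1 − Σ_k p_k²),  i ≠ j,   E[i,i] = 0,

the minimal model consistent with a zero diagonal; it sums to `n_pairs`
exactly and is symmetric. Log-odds are natural-log `ln(obs/exp)` with no
pseudocount; cells with zero observed or zero expected carry a NaN
sentinel and render black. A distance view re-bins each row by the
Hamming distance between the two codes (column 0 is structurally zero).

**Triplets and chains.** A chain is a maximal run of consecutive
discarded segments. Runs flanked by retained segments on both sides
contribute one triplet (5′ flank code, member code, 3′ flank code) per
member; runs touching a chromosome end do not. The triplet distance
column is measured to the 5′ flank — the choice of reference flank was
open, and 5′ keeps the orientation consistent with the pair matrices. A
high fraction of triplets with equal flank codes would indicate that
short partially-overlapping peaks are splitting otherwise-identical
segments, i.e. a problematic segmentation.

**Lost peaks.** A merged input peak counts as lost when it overlaps no
retained segment whose code carries that track's bit — everything it
covered was discarded.

## Annotation

**Coverage** of a segment by a track is the covered-base fraction on
merged intervals (double-covered bases count once), computed by prefix
sums, in [0,1]. **Fate-of-code** thresholds the coverages of one
additional track per reference mark: derived bit i = coverage_i ≥ t. The
comparison is inclusive so t = 1.0 means "fully covered"; with the
reference tracks as additional tracks the table is exactly diagonal at
any t ≤ 1 (retained segments are covered 0 or 1 by their own marks), a
property used as an end-to-end check. The display transform is
log10(1 + count), defined at zero.

**CpG density** is (# of `CG` dinucleotides at offsets 0..len−2) /
segment length — the simplest reading of "density"; the denominator is
the full length, not len−1 and not an observed/expected ratio, which
users comparing against other tools should note. Windows containing
non-ACGT characters never match.

**PWM scanning.** Windows are scored as
`Σ_pos log2((p[pos,base] + ε·bg[base]) / ((1+ε)·bg[base]))` with
pseudocount ε = 0.01 and uniform background by default; both strands are
scanned (reverse complement) and hits may overlap. The hit threshold is
a fraction of the achievable score *range*:
`min_score + f·(max_score − min_score)`, the standard relative-score
convention. At f = 1.0 only maximal-score (consensus) windows hit; at
f = 0 every valid window on both strands hits, giving the exact count
`2·max(0, len − width + 1)` used as an invariant. Default f = 0.8.
Segments shorter than the motif count zero, not an error.

## Correlation

Attributes over segments are heavily tied (0/1 indicators, small
integer codes, exact-zero coverages), so Spearman's coefficient is
computed tie-adjusted: midranks (average rank within each tie group) for
both vectors, then the Pearson product-moment correlation of the
midranks. On tie-free data this equals the classical
`1 − 6Σd²/(n(n²−1))`. Missing values are dropped pairwise, not listwise,
because annotations may be partially available for some tracks. Columns
that are constant (or have < 2 complete pairs) get a NaN sentinel with a
warning rather than a fabricated value. The integer code is ranked as a
plain number; its ordinal meaning is weak (code 4 is not "more modified"
than code 3), so code correlations should be read qualitatively. No
p-values are produced: every statistic here is descriptive.

## Synthetic data generator

The generator emulates the structure the method is meant to detect, not
read-level noise. Defaults model a three-mark reference cell type:

| track | density (peaks/Mb) | median length | shape |
|-------|-------------------:|--------------:|-------|
| K4 (narrow, active)       | 300 | 1 kb | log-normal, σ=0.4 |
| K27 (broad, repressive)   |  60 | 4 kb | log-normal, σ=0.5 |
| K9 (broad, heterochromatin) | 15 | 8 kb | log-normal, σ=0.5 |

Peak counts are Poisson at the configured density; lengths are
log-normal (many short, few long, matching observed peak-length
distributions); boundaries snap to a 50-nt grid, emulating peak callers
that round boundaries — which is also why discarded-segment lengths come
out as multiples of 50. Embedding rules place each inner-track peak
inside a uniformly chosen outer-track domain with the rule's probability
(truncated to fit), uniformly elsewhere otherwise; the defaults nest K4
in K27 with probability 0.9 (peak-within-domain) and K27 in K9 with 0.5
(nested superdomains). A config whose typical inner peak is longer than
the typical outer domain is rejected as infeasible. One global seed
drives everything through per-track derived substreams, so outputs are
bit-identical across runs. The generator returns the exact per-base code
array, making "segmentation reproduces the truth exactly" a testable
end-to-end oracle.

The FASTA simulator writes uniform-random sequence with CG dinucleotides
planted at `cpg_rate` per nt and PWM-consensus sites planted at
`motif_plant_rate` per kb, returning planted positions as truth. It does
not model isochores, repeats or realistic CpG-island structure — so
passing tests demonstrate correctness of the *computations* on
known-structure input, not biological realism of any particular value.

## Numerical and design notes

- All coordinates are int64; no floating point enters the segmentation.
- Pair/fate matrices are dense over all 2^M codes (M ≤ 16 enforced;
  in practice M ≤ 5 is sensible — the code space doubles per mark).
- PWM window scores use a 1e-12 absolute tolerance on the threshold
  comparison so consensus windows at f = 1.0 are not lost to rounding.
- Exports are plain text (BED with code/length columns, labeled TSV with
  `NA` sentinel) and round-trip exactly; matrix TSV uses `repr(float)`
  so values survive read-back bit-identically.
- Problem sizes in the test-suite and acceptance script (2-Mb
  chromosomes, 20 replicates, ≤ 10-kb oracle fixtures) were chosen so the
  brute-force per-base oracles stay exact while the statistics of
  interest (hundreds of drawn peaks per track) are well resolved.

## Known limitations

- The expected-pair model assumes code independence between neighbours
  given the marginal frequencies; it is a null model for display, not a
  generative claim.
- Coverage, fate and correlation operate on retained segments only;
  discarded segments appear solely in the diagnostics.
- No HMM/probabilistic segmentation and no significance testing — by
  design, this is the fast descriptive layer that precedes such methods.
- PWM scanning counts potential sites; it does not model binding
  affinity, cooperativity or chromatin accessibility.
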