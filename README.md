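# markseg

Genome segmentation by histone-mark combination, with the descriptive
statistics needed to judge whether the segmentation — and the tracks that
went into it — is any good.

## The problem

Chromatin-state analyses often start from called peaks of a few histone
modifications (e.g. H3K4me3, H3K27me3, H3K9me3) in a reference cell type.
Instead of anchoring on promoters or genes, `markseg` partitions every
chromosome into **maximal ranges over which the set of overlapping marks
is constant**. Each range (a *segment*) carries an integer **code**: bit
*i* is set iff the peaks of input track *i* cover the segment, so with
three marks the codes run 0–7, code 0 = unmodified, code 3 = the
"bivalent" H3K4me3+H3K27me3 combination, and so on. Adjacent segments in
the tiling always differ in code — that is what maximality means. Segments
shorter than a minimum length (default 200 nt, an artifact of peak-caller
boundary uncertainty) are set aside but kept for diagnostics.

On top of the segmentation the package computes, purely descriptively:

- **code frequencies** and paired **length distributions**
  (modified vs unmodified; per-mark peaks vs single-mark-only segments);
- **adjacent-pair analysis**: observed counts of (5′ code, 3′ code) pairs
  of directly contiguous retained segments, the expected counts under the
  independence model
  `E[i,j] = n_pairs · p_i · p_j / (1 − Σ_k p_k²)` (i ≠ j, zero diagonal),
  and `ln(obs/exp)` log-odds — positive values flag enriched transitions
  such as a peak nested inside a broader domain;
- **short-segment diagnostics**: chains of consecutive discarded segments,
  triplets (flank, short segment, flank) with a same-flank counter, and
  per-track counts of peaks lost entirely to discarding;
- **fate-of-code**: re-derive each segment's code from another cell
  type's peaks by thresholding per-segment coverage (bit set iff coverage
  ≥ t, default t = 0.8) and tabulate reference × derived code counts;
- **sequence annotation**: CpG dinucleotide density and PWM motif
  scanning (log₂-odds scores, both strands, hits at a fraction of the
  achievable score range);
- **correlation**: all-pairs Spearman correlation **adjusted for ties**
  (midranks + Pearson) across every per-segment attribute — essential
  because indicator and coverage columns are massively tied;
- static **plots** (bar charts, log-scaled paired histograms, heatmaps
  with sequential-pink / diverging palettes, black = never observed);
- a **synthetic generator** that emulates narrow/broad peak tracks with
  controlled peak-within-domain nesting and returns exact per-base ground
  truth, so the whole pipeline is testable without downloads.

## Worked example

```python
from markseg import code_frequencies, default_config, segment_genome, simulate_tracks

cfg = default_config(seed=1, chrom_size=2_000_000)   # K4 / K27 / K9 study conditions
tracks, truth = simulate_tracks(cfg)
seg = segment_genome(tracks, cfg.genome, min_length=200)
```

Running `python examples/01_segment_genome.py` prints:

```
tracks (bit order): ['K4', 'K27', 'K9']
retained segments : 985
discarded (<200nt): 41
  code 0 (      none):   347 segments
  code 1 (        K4):   321 segments
  code 2 (       K27):    80 segments
  code 3 (    K4+K27):    57 segments
  code 4 (        K9):    49 segments
  code 5 (     K4+K9):    32 segments
  code 6 (    K27+K9):    60 segments
  code 7 ( K4+K27+K9):    39 segments
per-base codes match the simulated ground truth
```

Most segments are unmodified or single-mark, multi-mark combinations are
rarer, and the 41 sub-200-nt fragments were routed to the discarded list —
the same qualitative picture the method is designed to surface on real
Roadmap tracks. `examples/02_adjacency_logodds.py` shows the nesting
signature: with narrow peaks embedded in broad domains at probability 0.9
the outer→outer+inner adjacency is observed 135 times against 78.5
expected (`ln(obs/exp) = 0.54 > 0`), while the unmodified→both transition
is strongly depleted. The other examples cover fate-of-code
(`03`), annotation + correlation (`04`) and the plot gallery (`05`).

## Command line

Every analysis is also a subcommand of the `markseg` CLI
(`segment`, `stats`, `annotate`, `fate`, `correlate`, `plot`,
`simulate`), and `markseg run --config job.yaml` executes the whole
pipeline from a flat YAML job file, writing BED/TSV/PNG outputs plus a
`manifest.json` with parameters and input checksums. Reruns of the same
config are byte-identical.

```sh
markseg simulate --seed 5 --chrom-size 300000 --out sim/
markseg stats --track K4=sim/K4.bed --track K27=sim/K27.bed --track K9=sim/K9.bed \
        --genome sim/genome.chrom.sizes --out-dir out/
```

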