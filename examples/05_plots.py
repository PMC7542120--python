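"""Render the statistical graphics: bar charts and heatmaps.

Writes four PNG files into ./example-plots: the code-frequency bar
chart, paired length histograms (log frequency axis), the observed
adjacent-pair heatmap (sequential pink) and the observed-vs-expected
log-odds heatmap (blue = depleted, red = enriched, black = never
observed).
"""

from pathlib import Path

from markseg import (
    adjacent_pairs,
    code_frequencies,
    default_config,
    length_histograms,
    segment_genome,
    simulate_tracks,
)
from markseg.viz import HeatmapSpec, plot_code_frequency, plot_heatmap, plot_length_histograms

out = Path("example-plots")
out.mkdir(exist_ok=True)

cfg = default_config(seed=1, chrom_size=2_000_000)
tracks, _ = simulate_tracks(cfg)
seg = segment_genome(tracks, cfg.genome, min_length=200)

plot_code_frequency(
    code_frequencies(seg), out / "code_frequency.png",
    labels={c: seg.code_label(c) for c in range(seg.n_codes)},
)

pairs = length_histograms(seg, "modified")
pairs += length_histograms(seg, "per-mark", tracks=tracks)
plot_length_histograms(pairs, out / "length_histograms.png")

pm = adjacent_pairs(seg)
codes = list(range(seg.n_codes))
plot_heatmap(
    HeatmapSpec(pm.observed, codes, codes, "sequential-pink",
                title="adjacent pairs (observed)"),
    out / "pairs_observed.png",
)
plot_heatmap(
    HeatmapSpec(pm.log_odds, codes, codes, "diverging-blue-red",
                title="adjacent pairs ln(obs/exp)"),
    out / "pairs_log_odds.png",
)
print(f"wrote 4 plots to {out}/")
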