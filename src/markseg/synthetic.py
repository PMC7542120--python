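"""Synthetic genomes, peak tracks and FASTA with controlled nested structure.

The generator emulates Roadmap-style histone-mark peak tracks: a narrow
promoter-like mark (H3K4me3-like), a broad repressive domain mark
(H3K27me3-like) and a very broad heterochromatin mark (H3K9me3-like),
with *embedding rules* that place a configurable fraction of one mark's
peaks inside another mark's domains.  Embedding a narrow active mark
inside broad repressive domains reproduces the peak-within-domain
adjacency signature (unmodified -> outer-only -> outer+inner -> ...);
chaining two rules nests that pattern inside a superdomain.

Everything is driven by one integer seed; per-track substreams are
derived deterministically from it, so the same config always produces
bit-identical BED/FASTA output.  The generator also returns the exact
per-base ground truth so segmentation can be checked end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import GenomeIndex, PeakTrack, PositionWeightMatrix, _merge_starts_ends

logger = logging.getLogger(__name__)

__all__ = [
    "TrackSpec",
    "EmbeddingRule",
    "SimConfig",
    "default_config",
    "simulate_tracks",
    "simulate_fasta",
]


@dataclass(frozen=True)
class TrackSpec:
    """One simulated mark: peak density and log-normal length distribution."""

    name: str
    density_per_mb: float  # expected peak count per megabase
    length_log_mean: float  # log-normal mu of peak length (nt)
    length_log_sd: float  # log-normal sigma

    def __post_init__(self) -> None:
        if self.density_per_mb < 0:
            raise ValueError("density must be >= 0")
        if self.length_log_sd < 0:
            raise ValueError("length_log_sd must be >= 0")


@dataclass(frozen=True)
class EmbeddingRule:
    """Place each ``inner`` peak inside a random ``outer`` domain with this probability."""

    inner: str
    outer: str
    probability: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("embedding probability must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    chrom_sizes: dict[str, int]
    tracks: tuple[TrackSpec, ...]
    embeddings: tuple[EmbeddingRule, ...] = ()
    grid: int = 50  # peak boundaries snap to this grid (nt)
    cpg_rate: float = 0.0  # planted CG dinucleotides per nt
    motif_plant_rate: float = 0.0  # planted consensus sites per kb

    def __post_init__(self) -> None:
        if self.grid < 1:
            raise ValueError("grid must be >= 1")
        if self.cpg_rate < 0 or self.motif_plant_rate < 0:
            raise ValueError("rates must be >= 0")
        names = [t.name for t in self.tracks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate track names")
        for rule in self.embeddings:
            if rule.inner not in names or rule.outer not in names:
                raise ValueError(f"embedding rule references unknown track: {rule}")
            inner = next(t for t in self.tracks if t.name == rule.inner)
            outer = next(t for t in self.tracks if t.name == rule.outer)
            if np.exp(inner.length_log_mean) > np.exp(outer.length_log_mean):
                raise ValueError(
                    f"infeasible embedding: typical {rule.inner} peak is longer "
                    f"than a typical {rule.outer} domain"
                )

    @property
    def genome(self) -> GenomeIndex:
        return GenomeIndex(chrom_sizes=dict(self.chrom_sizes))


def default_config(seed: int = 0, chrom_size: int = 2_000_000, n_chroms: int = 1) -> SimConfig:
    """Three-mark study conditions: narrow active peaks embedded in broad domains.

    Densities and length scales follow typical Roadmap narrow/broad track
    shapes: the H3K4me3-like mark has many ~1 kb peaks, the H3K27me3-like
    mark fewer ~4 kb domains, the H3K9me3-like mark sparse ~8 kb domains.
    Case-1 nesting (active peaks inside repressive domains, probability
    0.9) and Case-2 nesting (repressive domains inside heterochromatin
    superdomains, probability 0.5) are both on by default.
    """
    return SimConfig(
        seed=seed,
        chrom_sizes={f"chr{i + 1}": chrom_size for i in range(n_chroms)},
        tracks=(
            TrackSpec("K4", density_per_mb=300.0, length_log_mean=np.log(1000.0), length_log_sd=0.4),
            TrackSpec("K27", density_per_mb=60.0, length_log_mean=np.log(4000.0), length_log_sd=0.5),
            TrackSpec("K9", density_per_mb=15.0, length_log_mean=np.log(8000.0), length_log_sd=0.5),
        ),
        embeddings=(
            EmbeddingRule(inner="K4", outer="K27", probability=0.9),
            EmbeddingRule(inner="K27", outer="K9", probability=0.5),
        ),
        grid=50,
    )


def _snap(start: float, length: float, grid: int, size: int) -> tuple[int, int]:
    """Snap a peak to the grid, keeping length >= one grid step, inside [0, size)."""
    s = int(round(start / grid)) * grid
    e = int(round((start + max(length, grid)) / grid)) * grid
    if e <= s:
        e = s + grid
    s = max(0, min(s, size - grid))
    e = max(s + grid, min(e, size))
    return s, e


def _track_rng(cfg: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))


def simulate_tracks(cfg: SimConfig) -> tuple[list[PeakTrack], dict[str, np.ndarray]]:
    """Draw all peak tracks plus the exact per-base ground-truth code array.

    Outer (non-embedded) tracks are drawn first: Poisson peak counts at
    the configured density, uniform placement, log-normal lengths snapped
    to the grid.  Tracks that appear as ``inner`` in an embedding rule
    place each peak inside a uniformly chosen outer domain with the
    rule's probability (truncated to fit), uniformly elsewhere otherwise.

    Returns the tracks in config order and, per chromosome, a uint8 array
    of the true per-base code (bit i = track i present).
    """
    by_name = {t.name: i for i, t in enumerate(cfg.tracks)}
    rule_for: dict[str, EmbeddingRule] = {r.inner: r for r in cfg.embeddings}

    # generation order: outers before the tracks embedded in them
    order = sorted(
        range(len(cfg.tracks)),
        key=lambda i: 0 if cfg.tracks[i].name not in rule_for else 1,
    )
    raw: dict[str, dict[str, np.ndarray]] = {}

    for i in order:
        spec = cfg.tracks[i]
        rng = _track_rng(cfg, i)
        rule = rule_for.get(spec.name)
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, size in cfg.chrom_sizes.items():
            n = rng.poisson(spec.density_per_mb * size / 1e6)
            pairs: list[tuple[int, int]] = []
            outer_arr = (
                raw.get(rule.outer, {}).get(chrom) if rule is not None else None
            )
            for _ in range(n):
                length = float(rng.lognormal(spec.length_log_mean, spec.length_log_sd))
                if (
                    rule is not None
                    and outer_arr is not None
                    and len(outer_arr)
                    and rng.random() < rule.probability
                ):
                    k = rng.integers(len(outer_arr))
                    os_, oe = int(outer_arr[k, 0]), int(outer_arr[k, 1])
                    length = min(length, oe - os_)
                    lo, hi = os_, max(os_, oe - int(length))
                    start = float(rng.integers(lo, hi + 1))
                    s, e = _snap(start, length, cfg.grid, cfg.chrom_sizes[chrom])
                    # keep strictly inside the chosen outer domain
                    s = max(s, os_)
                    e = min(max(e, s + cfg.grid), oe) if oe - s >= cfg.grid else oe
                    if e <= s:
                        continue
                else:
                    start = rng.uniform(0, size)
                    s, e = _snap(start, length, cfg.grid, size)
                pairs.append((s, e))
            arr = (
                _merge_starts_ends(
                    np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
                )
                if pairs
                else np.empty((0, 2), dtype=np.int64)
            )
            per_chrom[chrom] = arr
        raw[spec.name] = per_chrom

    tracks = [
        PeakTrack(name=t.name, by_chrom=raw[t.name], mark=t.name)
        for t in cfg.tracks
    ]

    truth: dict[str, np.ndarray] = {}
    for chrom, size in cfg.chrom_sizes.items():
        codes = np.zeros(size, dtype=np.uint8)
        for i, t in enumerate(cfg.tracks):
            for s, e in raw[t.name].get(chrom, ()):
                codes[s:e] |= 1 << i
        truth[chrom] = codes
    return tracks, truth


def simulate_fasta(
    cfg: SimConfig,
    path: str | Path,
    pwm: PositionWeightMatrix | None = None,
    line_width: int = 70,
) -> dict[str, dict[str, list[int]]]:
    """Write a FASTA of uniform random sequence with planted features.

    CG dinucleotides are planted at ``cpg_rate`` per nt and, when a PWM is
    given, its consensus is planted at ``motif_plant_rate`` sites per kb
    (forward strand).  Planted positions are returned as ground truth:
    ``{chrom: {"cpg": [...], "motif": [...]}}``.  Later plants overwrite
    earlier sequence, so truth lists record where a feature was written,
    not a guarantee of non-collision at very high rates.
    """
    if cfg.motif_plant_rate > 0 and pwm is None:
        raise ValueError("motif planting requires a PWM")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_000]))
    bases = np.array(list("ACGT"))
    truth: dict[str, dict[str, list[int]]] = {}
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, size in cfg.chrom_sizes.items():
            seq = rng.choice(bases, size=size)
            chrom_truth: dict[str, list[int]] = {"cpg": [], "motif": []}

            n_cpg = int(round(cfg.cpg_rate * size))
            if n_cpg > 0:
                if 2 * n_cpg > size:
                    raise ValueError("cpg_rate too high for sequence length")
                pos = np.sort(rng.choice(size - 1, size=n_cpg, replace=False))
                for p in pos:
                    seq[p] = "C"
                    seq[p + 1] = "G"
                chrom_truth["cpg"] = [int(p) for p in pos]

            if cfg.motif_plant_rate > 0:
                consensus = np.array(list(pwm.consensus()))
                w = len(consensus)
                n_sites = int(round(cfg.motif_plant_rate * size / 1000.0))
                if n_sites * w > size:
                    raise ValueError("motif_plant_rate too high for sequence length")
                if n_sites > 0:
                    pos = np.sort(rng.choice(size - w + 1, size=n_sites, replace=False))
                    for p in pos:
                        seq[p : p + w] = consensus
                    chrom_truth["motif"] = [int(p) for p in pos]

            truth[chrom] = chrom_truth
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for k in range(0, size, line_width):
                fh.write(s[k : k + line_width] + "\n")
    return truth
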