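"""Maximal-range decomposition of a genome by histone-mark combination.

Given one merged peak track per reference mark, each chromosome is
partitioned into *maximal ranges* over which the set of overlapping marks
is constant.  Each range carries an integer *code*: bit ``i`` of the code
is set iff the peaks of input track ``i`` cover the range (track 0 maps to
the least significant bit).  Code 0 means unmodified.  Adjacent ranges in
the full tiling always differ in code; that is what makes them maximal.

Ranges shorter than ``min_length`` (default 200 nt) are moved to a
*discarded* side list but keep their coordinates and codes: the short
segments still participate in chain and triplet diagnostics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .io import GenomeIndex, GenomicInterval, PeakTrack

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "ChromTiling",
    "Segmentation",
    "segment_genome",
    "code_of",
    "code_distance",
    "lost_peaks",
    "DEFAULT_MIN_LENGTH",
]

DEFAULT_MIN_LENGTH = 200
MAX_TRACKS = 16


@dataclass(frozen=True)
class Segment:
    interval: GenomicInterval
    code: int

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ChromTiling:
    """Full tiling of one chromosome: arrays over the tiling positions.

    ``retained[k]`` is False exactly when segment ``k`` is shorter than the
    segmentation's ``min_length``.
    """

    starts: np.ndarray
    ends: np.ndarray
    codes: np.ndarray
    retained: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts


@dataclass
class Segmentation:
    """Per-chromosome tilings plus the track order that defines code bits."""

    tracks: list[str]
    genome: GenomeIndex
    min_length: int
    chroms: dict[str, ChromTiling] = field(default_factory=dict)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    @property
    def n_codes(self) -> int:
        return 1 << len(self.tracks)

    def iter_segments(self, which: str = "retained") -> Iterator[Segment]:
        """Yield segments genome-ordered; ``which`` in {retained, discarded, all}."""
        if which not in ("retained", "discarded", "all"):
            raise ValueError(f"unknown scope {which!r}")
        for chrom in self.genome.chrom_order:
            tiling = self.chroms.get(chrom)
            if tiling is None:
                continue
            for k in range(len(tiling)):
                if which == "retained" and not tiling.retained[k]:
                    continue
                if which == "discarded" and tiling.retained[k]:
                    continue
                yield Segment(
                    GenomicInterval(chrom, int(tiling.starts[k]), int(tiling.ends[k])),
                    int(tiling.codes[k]),
                )

    @property
    def retained(self) -> list[Segment]:
        return list(self.iter_segments("retained"))

    @property
    def discarded(self) -> list[Segment]:
        return list(self.iter_segments("discarded"))

    def n_segments(self, which: str = "retained") -> int:
        return sum(1 for _ in self.iter_segments(which))

    def per_base_codes(self, chrom: str) -> np.ndarray:
        """Expand the tiling of one chromosome to a per-base code array."""
        tiling = self.chroms[chrom]
        return np.repeat(tiling.codes, tiling.lengths).astype(np.int64)

    def code_label(self, code: int) -> str:
        """Human-readable mark combination, e.g. ``H3K4me3+H3K27me3``."""
        marks = [t for i, t in enumerate(self.tracks) if code >> i & 1]
        return "+".join(marks) if marks else "none"


def code_of(marks_present: Sequence[bool], track_order: Sequence[str] | None = None) -> int:
    """Bitmask code of a mark-presence vector: value = sum of 2^i over set bits."""
    if track_order is not None and len(marks_present) != len(track_order):
        raise ValueError("marks_present length must equal number of tracks")
    return int(sum(1 << i for i, present in enumerate(marks_present) if present))


def code_distance(a: int, b: int) -> int:
    """Hamming distance between two codes: number of marks in which they differ."""
    return int(a ^ b).bit_count()


def _covering_mask(arr: np.ndarray, points: np.ndarray) -> np.ndarray:
    """For each point, True iff some interval [s, e) in ``arr`` contains it."""
    if len(arr) == 0:
        return np.zeros(len(points), dtype=bool)
    idx = np.searchsorted(arr[:, 0], points, side="right") - 1
    valid = idx >= 0
    out = np.zeros(len(points), dtype=bool)
    out[valid] = arr[idx[valid], 1] > points[valid]
    return out


def segment_genome(
    tracks: Sequence[PeakTrack],
    genome: GenomeIndex,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> Segmentation:
    """Decompose every chromosome of ``genome`` into coded maximal ranges.

    A boundary sweep over all peak starts and ends (plus 0 and the
    chromosome size) yields elementary ranges of constant mark membership;
    equal-code neighbours are coalesced so maximality holds even when a
    peak end coincides with another peak's start without changing the
    combination.  Chromosomes with no peaks yield one code-0 segment.

    Parameters
    ----------
    tracks
        One merged :class:`PeakTrack` per reference mark; input order
        defines the code's bit order (track 0 -> least significant bit).
    min_length
        Segments strictly shorter than this go to the discarded list.
    """
    if len(tracks) == 0:
        raise ValueError("at least one reference track is required")
    if len(tracks) > MAX_TRACKS:
        raise ValueError(f"at most {MAX_TRACKS} reference tracks are supported")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")

    tracks = [t.clipped(genome) for t in tracks]
    names = [t.name for t in tracks]
    seg = Segmentation(tracks=names, genome=genome, min_length=min_length)

    for chrom, size in genome.chrom_sizes.items():
        boundaries = [np.array([0, size], dtype=np.int64)]
        per_track = []
        for t in tracks:
            arr = t.by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))
            per_track.append(arr)
            if len(arr):
                boundaries.append(arr[:, 0])
                boundaries.append(arr[:, 1])
        bounds = np.unique(np.concatenate(boundaries))
        bounds = bounds[(bounds >= 0) & (bounds <= size)]
        starts, ends = bounds[:-1], bounds[1:]

        codes = np.zeros(len(starts), dtype=np.int64)
        for i, arr in enumerate(per_track):
            # membership is constant on each elementary range, so testing
            # the start base suffices
            codes |= _covering_mask(arr, starts).astype(np.int64) << i

        if len(codes) > 1:  # coalesce equal-code neighbours
            keep = np.empty(len(codes), dtype=bool)
            keep[0] = True
            keep[1:] = codes[1:] != codes[:-1]
            starts = starts[keep]
            codes = codes[keep]
            ends = np.append(starts[1:], size)

        lengths = ends - starts
        seg.chroms[chrom] = ChromTiling(
            starts=starts,
            ends=ends,
            codes=codes,
            retained=lengths >= min_length,
        )

    return seg


def lost_peaks(tracks: Sequence[PeakTrack], seg: Segmentation) -> dict[str, int]:
    """Count, per track, input peaks that survive in no retained segment.

    A peak is *lost* when every segment it overlaps was discarded, i.e. it
    overlaps no retained segment whose code carries that track's bit.
    Counts are over the merged per-track intervals.
    """
    out: dict[str, int] = {}
    for i, track in enumerate(tracks):
        track = track.clipped(seg.genome)
        lost = 0
        for chrom, arr in track.by_chrom.items():
            tiling = seg.chroms.get(chrom)
            if tiling is None or len(arr) == 0:
                lost += len(arr)
                continue
            mask = tiling.retained & ((tiling.codes >> i & 1) == 1)
            ret_s, ret_e = tiling.starts[mask], tiling.ends[mask]
            for ps, pe in arr:
                # overlap exists iff some retained carrier segment intersects [ps, pe)
                j = np.searchsorted(ret_s, pe, side="left")
                if j == 0 or ret_e[j - 1] <= ps:
                    lost += 1
        out[track.name] = lost
    return out
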