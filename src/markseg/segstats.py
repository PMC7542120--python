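"""Descriptive statistics over a segmentation.

Covers code frequencies, length distributions, adjacent-pair
observed/expected analysis, segment--short segment--segment triplets, and
chains of discarded short segments.  Everything here is purely
descriptive; no significance testing is attempted.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PeakTrack
from .segmentation import Segmentation, code_distance

logger = logging.getLogger(__name__)

__all__ = [
    "CodeFrequency",
    "LengthHistogram",
    "PairMatrix",
    "TripletTable",
    "Chain",
    "ChainReport",
    "code_frequencies",
    "length_histograms",
    "adjacent_pairs",
    "triplet_analysis",
    "chain_report",
    "DEFAULT_BIN_WIDTH",
]

DEFAULT_BIN_WIDTH = 50


@dataclass
class CodeFrequency:
    """Segment count per code, over retained segments or the full tiling."""

    counts: dict[int, int]
    scope: str = "retained"
    n_codes: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[int, float]:
        total = self.total
        return {c: n / total for c, n in self.counts.items()} if total else {}

    def as_array(self) -> np.ndarray:
        out = np.zeros(self.n_codes or (max(self.counts, default=0) + 1), dtype=np.int64)
        for c, n in self.counts.items():
            out[c] = n
        return out


@dataclass
class LengthHistogram:
    """Counts of lengths in half-open bins [k*w, (k+1)*w)."""

    bin_width: int
    counts: dict[int, int] = field(default_factory=dict)  # bin index k -> count
    series_label: str = ""

    @classmethod
    def from_lengths(
        cls, lengths: Sequence[int], bin_width: int = DEFAULT_BIN_WIDTH, label: str = ""
    ) -> "LengthHistogram":
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        counts = Counter(int(x) // bin_width for x in lengths)
        return cls(bin_width=bin_width, counts=dict(counts), series_label=label)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_series(self) -> pd.Series:
        if not self.counts:
            return pd.Series(dtype=np.int64, name=self.series_label)
        kmax = max(self.counts)
        idx = [k * self.bin_width for k in range(kmax + 1)]
        vals = [self.counts.get(k, 0) for k in range(kmax + 1)]
        return pd.Series(vals, index=idx, name=self.series_label)


@dataclass
class PairMatrix:
    """Adjacent-pair counts and the independence-model expectations.

    Rows index the 5' segment's code, columns the 3' segment's code.
    ``log_odds`` is ln(observed/expected) with NaN marking absent cells
    (zero observed or zero expected).  ``distance_counts`` re-bins each
    row by the Hamming distance between the two codes.
    """

    observed: np.ndarray
    expected: np.ndarray
    log_odds: np.ndarray
    distance_counts: np.ndarray
    n_pairs: int

    @property
    def n_codes(self) -> int:
        return self.observed.shape[0]


@dataclass
class TripletTable:
    """Flank-pair x short-segment-code counts for discarded-run triplets.

    One triplet per discarded member of every maximal run of consecutive
    discarded segments flanked on both sides by retained segments.  A
    large ``n_same_flank`` fraction (two flanks with equal codes around a
    short segment) would indicate a problematic segmentation.
    """

    counts: dict[tuple[int, int], dict[int, int]]
    distance_counts: dict[tuple[int, int], dict[int, int]]
    n_same_flank: int

    @property
    def total(self) -> int:
        return sum(n for row in self.counts.values() for n in row.values())

    def to_frame(self, n_codes: int) -> pd.DataFrame:
        rows = sorted(self.counts)
        data = np.zeros((len(rows), n_codes), dtype=np.int64)
        for r, key in enumerate(rows):
            for code, n in self.counts[key].items():
                data[r, code] = n
        index = pd.MultiIndex.from_tuples(rows, names=["code_5p", "code_3p"])
        return pd.DataFrame(data, index=index, columns=range(n_codes))


@dataclass
class Chain:
    chrom: str
    start: int
    end: int
    members: int

    @property
    def total_length(self) -> int:
        return self.end - self.start


@dataclass
class ChainReport:
    """Runs of consecutive discarded segments and their summary statistics."""

    chains: list[Chain]
    bin_width: int = DEFAULT_BIN_WIDTH

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_multi_member(self) -> int:
        return sum(1 for c in self.chains if c.members >= 2)

    @property
    def max_total_length(self) -> int:
        return max((c.total_length for c in self.chains), default=0)

    def length_histogram(self) -> LengthHistogram:
        return LengthHistogram.from_lengths(
            [c.total_length for c in self.chains], self.bin_width, "chain length"
        )


def code_frequencies(seg: Segmentation, scope: str = "retained") -> CodeFrequency:
    """Tally segments per code over ``scope`` in {retained, discarded, all}."""
    counts = Counter(s.code for s in seg.iter_segments(scope))
    return CodeFrequency(counts=dict(counts), scope=scope, n_codes=seg.n_codes)


def _single_mark_code(seg: Segmentation, mark: str) -> int:
    try:
        i = seg.tracks.index(mark)
    except ValueError:
        raise ValueError(f"unknown mark {mark!r}; tracks are {seg.tracks}") from None
    return 1 << i


def length_histograms(
    seg: Segmentation,
    split: str = "modified",
    tracks: Sequence[PeakTrack] | None = None,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> list[tuple[LengthHistogram, LengthHistogram]]:
    """Paired length distributions for side-by-side comparison.

    ``split='modified'`` pairs the lengths of modified (code > 0) retained
    segments against unmodified (code 0) ones.  ``split='per-mark'`` pairs,
    for every reference mark, the merged input peak lengths against the
    lengths of retained segments carrying *only* that mark's bit; the
    originating tracks must be supplied in segmentation order.
    """
    if split == "modified":
        modified = [s.length for s in seg.iter_segments("retained") if s.code != 0]
        unmodified = [s.length for s in seg.iter_segments("retained") if s.code == 0]
        return [
            (
                LengthHistogram.from_lengths(modified, bin_width, "modified segments"),
                LengthHistogram.from_lengths(unmodified, bin_width, "unmodified segments"),
            )
        ]
    if split == "per-mark":
        if tracks is None:
            raise ValueError("per-mark histograms require the originating peak tracks")
        pairs = []
        for track in tracks:
            only_code = _single_mark_code(seg, track.name)
            peak_lengths = [
                int(e - s) for arr in track.by_chrom.values() for s, e in arr
            ]
            seg_lengths = [
                s.length for s in seg.iter_segments("retained") if s.code == only_code
            ]
            pairs.append(
                (
                    LengthHistogram.from_lengths(
                        peak_lengths, bin_width, f"{track.name} peaks"
                    ),
                    LengthHistogram.from_lengths(
                        seg_lengths, bin_width, f"{track.name}-only segments"
                    ),
                )
            )
        return pairs
    raise ValueError(f"unknown split {split!r}")


def adjacent_pairs(seg: Segmentation) -> PairMatrix:
    """Observed and expected counts of adjacent retained-segment code pairs.

    Pairs are ordered (5' segment, 3' segment) over retained segments that
    are directly contiguous in the full tiling; pairs separated by a
    discarded segment are routed to the triplet analysis instead, and
    pairs never span chromosome boundaries.  The expected model is the
    independence product of retained code frequencies renormalized over
    the off-diagonal cells::

        expected[i][j] = n_pairs * p_i * p_j / (1 - sum_k p_k^2),  i != j

    which keeps the diagonal structurally zero (adjacent maximal ranges
    always differ in code) and sums to ``n_pairs``.
    """
    n_codes = seg.n_codes
    m = seg.n_tracks
    observed = np.zeros((n_codes, n_codes), dtype=np.int64)
    distance_counts = np.zeros((n_codes, m + 1), dtype=np.int64)

    for chrom in seg.genome.chrom_order:
        tiling = seg.chroms.get(chrom)
        if tiling is None or len(tiling) < 2:
            continue
        both = tiling.retained[:-1] & tiling.retained[1:]
        for k in np.flatnonzero(both):
            i, j = int(tiling.codes[k]), int(tiling.codes[k + 1])
            observed[i, j] += 1
            distance_counts[i, code_distance(i, j)] += 1

    n_pairs = int(observed.sum())
    expected = np.zeros((n_codes, n_codes), dtype=float)
    if n_pairs == 0:
        warnings.warn("no adjacent retained pairs found; matrices are empty")
        log_odds = np.full((n_codes, n_codes), np.nan)
        return PairMatrix(observed, expected, log_odds, distance_counts, 0)

    freq = code_frequencies(seg, "retained")
    p = np.zeros(n_codes)
    for c, f in freq.fractions().items():
        p[c] = f
    denom = 1.0 - float(p @ p)
    if denom > 0:
        expected = n_pairs * np.outer(p, p) / denom
    np.fill_diagonal(expected, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_odds = np.log(observed / expected)
    log_odds[(observed == 0) | (expected == 0)] = np.nan

    return PairMatrix(observed, expected, log_odds, distance_counts, n_pairs)


def triplet_analysis(seg: Segmentation) -> TripletTable:
    """Triplets (5' flank, short segment, 3' flank) around discarded runs.

    Every maximal run of consecutive discarded segments that has a
    retained segment on both sides contributes one triplet per discarded
    member.  The distance view maps each short segment's code to its
    Hamming distance from the 5' flank's code.
    """
    counts: dict[tuple[int, int], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    dist_counts: dict[tuple[int, int], dict[int, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    n_same = 0
    for chrom in seg.genome.chrom_order:
        tiling = seg.chroms.get(chrom)
        if tiling is None:
            continue
        k = 0
        n = len(tiling)
        while k < n:
            if tiling.retained[k]:
                k += 1
                continue
            run_start = k
            while k < n and not tiling.retained[k]:
                k += 1
            run_end = k  # exclusive
            if run_start == 0 or run_end == n:
                continue  # no flank on one side: not a triplet
            c5 = int(tiling.codes[run_start - 1])
            c3 = int(tiling.codes[run_end])
            for m in range(run_start, run_end):
                cshort = int(tiling.codes[m])
                counts[(c5, c3)][cshort] += 1
                dist_counts[(c5, c3)][code_distance(cshort, c5)] += 1
                if c5 == c3:
                    n_same += 1
    return TripletTable(
        counts={k: dict(v) for k, v in counts.items()},
        distance_counts={k: dict(v) for k, v in dist_counts.items()},
        n_same_flank=n_same,
    )


def chain_report(seg: Segmentation, bin_width: int = DEFAULT_BIN_WIDTH) -> ChainReport:
    """Group consecutive discarded segments into chains and summarize them."""
    chains: list[Chain] = []
    for chrom in seg.genome.chrom_order:
        tiling = seg.chroms.get(chrom)
        if tiling is None:
            continue
        k = 0
        n = len(tiling)
        while k < n:
            if tiling.retained[k]:
                k += 1
                continue
            run_start = k
            while k < n and not tiling.retained[k]:
                k += 1
            chains.append(
                Chain(
                    chrom=chrom,
                    start=int(tiling.starts[run_start]),
                    end=int(tiling.ends[k - 1]),
                    members=k - run_start,
                )
            )
    return ChainReport(chains=chains, bin_width=bin_width)
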