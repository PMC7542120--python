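"""Mapping additional tracks, sequence features and motifs onto segments.

The central operations are per-segment *coverage* by a peak track (the
fraction of the segment's bases under peaks, in [0, 1]), the fate-of-code
contingency table built by thresholding those coverages, CpG dinucleotide
density from a genome FASTA, and PWM motif scanning on both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FastaStore, PeakTrack, PositionWeightMatrix
from .segmentation import Segmentation

logger = logging.getLogger(__name__)

__all__ = [
    "FateTable",
    "coverage",
    "fate_of_code",
    "cpg_density",
    "pwm_scan",
    "build_segment_table",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def coverage(seg: Segmentation, track: PeakTrack) -> np.ndarray:
    """Fraction of each retained segment's bases covered by ``track``.

    Returns one value in [0, 1] per retained segment, in genome order.
    Overlap is computed on the merged track intervals, so double-covered
    bases count once.
    """
    values: list[float] = []
    for chrom in seg.genome.chrom_order:
        tiling = seg.chroms.get(chrom)
        if tiling is None:
            continue
        mask = tiling.retained
        seg_s = tiling.starts[mask]
        seg_e = tiling.ends[mask]
        arr = track.by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))
        if len(arr) == 0:
            values.extend([0.0] * len(seg_s))
            continue
        # covered(x) = total covered length in [0, x), via prefix sums
        starts, ends = arr[:, 0], arr[:, 1]
        prefix = np.concatenate([[0], np.cumsum(ends - starts)])

        def covered_up_to(x: np.ndarray) -> np.ndarray:
            # idx = number of intervals starting before x; the last of those
            # (idx-1) may extend past x, so subtract its overhang
            idx = np.searchsorted(starts, x, side="right")
            overhang = np.zeros(len(x), dtype=np.int64)
            inside = idx > 0
            overhang[inside] = np.maximum(0, ends[idx[inside] - 1] - x[inside])
            return prefix[idx] - overhang

        cov = covered_up_to(seg_e) - covered_up_to(seg_s)
        values.extend((cov / (seg_e - seg_s)).tolist())
    return np.asarray(values, dtype=float)


@dataclass
class FateTable:
    """Reference-code x derived-code contingency counts at one threshold."""

    counts: np.ndarray  # (n_codes, n_codes) int
    threshold: float
    cell_type: str = ""

    @property
    def n_codes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def log_view(self) -> np.ndarray:
        """log10(1 + count), defined at zero, for heatmap display."""
        return np.log10(1.0 + self.counts)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_codes
        return pd.DataFrame(self.counts, index=range(n), columns=range(n))


def fate_of_code(
    seg: Segmentation,
    tracks_by_mark: Sequence[PeakTrack],
    threshold: float = 0.8,
    cell_type: str = "",
) -> FateTable:
    """Re-derive each retained segment's code from another cell type's peaks.

    ``tracks_by_mark`` must correspond one-to-one, in order, to the
    reference marks.  Derived code bit ``i`` is set iff the segment's
    coverage by additional track ``i`` is >= ``threshold`` (inclusive, so
    a threshold of 1.0 means fully covered).
    """
    if len(tracks_by_mark) != seg.n_tracks:
        raise ValueError(
            f"need one additional track per reference mark "
            f"({seg.n_tracks}), got {len(tracks_by_mark)}"
        )
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")

    ref_codes = np.array([s.code for s in seg.iter_segments("retained")], dtype=np.int64)
    derived = np.zeros(len(ref_codes), dtype=np.int64)
    for i, track in enumerate(tracks_by_mark):
        derived |= (coverage(seg, track) >= threshold).astype(np.int64) << i

    n = seg.n_codes
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (ref_codes, derived), 1)
    return FateTable(counts=counts, threshold=threshold, cell_type=cell_type)


def cpg_density(seg: Segmentation, fasta: FastaStore) -> np.ndarray:
    """CpG dinucleotide density per retained segment.

    Density = (number of "CG" occurrences at offsets 0..len-2) / segment
    length.  Windows containing a non-ACGT character never match.
    """
    values = []
    for s in seg.iter_segments("retained"):
        seq = fasta.fetch(s.interval)
        values.append(seq.count("CG") / len(seq))
    return np.asarray(values, dtype=float)


def _score_matrix(
    pwm: PositionWeightMatrix, background: np.ndarray, pseudocount: float
) -> np.ndarray:
    """Per-position log2-odds scores with a background-weighted pseudocount."""
    return np.log2(
        (pwm.probs + pseudocount * background) / ((1.0 + pseudocount) * background)
    )


def _scan_one_strand(
    idx: np.ndarray, score: np.ndarray, threshold: float
) -> int:
    """Count windows with total score >= threshold; invalid bases kill a window."""
    w = score.shape[0]
    n = len(idx)
    hits = 0
    for pos in range(n - w + 1):
        window = idx[pos : pos + w]
        if np.any(window < 0):
            continue
        if score[np.arange(w), window].sum() >= threshold - 1e-12:
            hits += 1
    return hits


def pwm_scan(
    seg: Segmentation,
    fasta: FastaStore,
    pwm: PositionWeightMatrix,
    score_fraction: float = 0.8,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Count potential binding sites per retained segment on both strands.

    Each window of motif width is scored as the sum of per-position
    log2-odds terms; the reverse strand is scanned via the reverse
    complement.  A window is a hit when its score reaches
    ``min + score_fraction * (max - min)`` of the achievable score range,
    so ``score_fraction=1.0`` accepts only maximal-score (consensus)
    windows and ``score_fraction=0.0`` accepts every valid window.  Hits
    may overlap; windows containing non-ACGT characters never hit.
    Returns (count, density) arrays; density = count / segment length.
    """
    if not (0.0 <= score_fraction <= 1.0):
        raise ValueError("score_fraction must lie in [0, 1]")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities")
    bg = bg / bg.sum()

    score = _score_matrix(pwm, bg, pseudocount)
    max_score = score.max(axis=1).sum()
    min_score = score.min(axis=1).sum()
    threshold = min_score + score_fraction * (max_score - min_score)

    counts = []
    densities = []
    lut = np.full(256, -1, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        lut[ord(base)] = i

    for s in seg.iter_segments("retained"):
        seq = fasta.fetch(s.interval)
        if len(seq) < pwm.width:
            counts.append(0)
            densities.append(0.0)
            continue
        fwd = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        rc = lut[
            np.frombuffer(
                seq.translate(_COMPLEMENT)[::-1].encode("ascii"), dtype=np.uint8
            )
        ]
        n_hits = _scan_one_strand(fwd, score, threshold) + _scan_one_strand(
            rc, score, threshold
        )
        counts.append(n_hits)
        densities.append(n_hits / len(seq))
    return np.asarray(counts, dtype=np.int64), np.asarray(densities, dtype=float)


def build_segment_table(
    seg: Segmentation,
    additional_tracks: Mapping[str, PeakTrack] | None = None,
    fasta: FastaStore | None = None,
    pwm: PositionWeightMatrix | None = None,
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Assemble one row per retained segment with all requested attributes.

    Base columns: segment id, chrom, start, end, length, code, and one 0/1
    indicator per reference mark.  Each additional track adds one coverage
    column; a FASTA adds ``cpg_density``; FASTA + PWM add ``motif_count``
    and ``motif_density``.  Absent annotations yield absent columns, never
    silent zeros.
    """
    segments = list(seg.iter_segments("retained"))
    table = pd.DataFrame(
        {
            "segment_id": range(len(segments)),
            "chrom": [s.interval.chrom for s in segments],
            "start": [s.interval.start for s in segments],
            "end": [s.interval.end for s in segments],
            "length": [s.length for s in segments],
            "code": [s.code for s in segments],
        }
    )
    columns = set(table.columns)

    def add_column(label: str, values) -> None:
        if label in columns:
            raise ValueError(f"duplicate column label {label!r}")
        columns.add(label)
        table[label] = values

    codes = table["code"].to_numpy()
    for i, mark in enumerate(seg.tracks):
        add_column(mark, (codes >> i & 1).astype(np.int64))

    for label, track in (additional_tracks or {}).items():
        add_column(label, coverage(seg, track))

    if fasta is not None:
        add_column("cpg_density", cpg_density(seg, fasta))
        if pwm is not None:
            count, density = pwm_scan(seg, fasta, pwm, score_fraction=score_fraction)
            add_column("motif_count", count)
            add_column("motif_density", density)
    elif pwm is not None:
        raise ValueError("PWM scanning requires a FASTA")

    return table
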