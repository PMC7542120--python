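"""Readers and writers for the external formats the tool touches.

All coordinates are BED-convention 0-based half-open, both internally and
in every export.  Same-track overlapping or book-ended peaks are merged on
load, because downstream segmentation semantics ("mark present at a base")
is per-base boolean.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

try:  # pyfaidx is the FASTA backend; imported lazily so BED-only use works anywhere
    from pyfaidx import Fasta as _PyfaidxFasta
except ImportError:  # pragma: no cover
    _PyfaidxFasta = None

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "PeakTrack",
    "GenomeIndex",
    "PositionWeightMatrix",
    "FastaStore",
    "read_bed",
    "read_chrom_sizes",
    "read_fasta",
    "read_pwm",
    "write_segments_bed",
    "read_segments_bed",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open range of nucleotides [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_starts_ends(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Union of intervals; overlapping or book-ended intervals coalesce.

    Returns an (N, 2) int64 array sorted by start.
    """
    if len(starts) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    starts = np.asarray(starts, dtype=np.int64)[order]
    ends = np.asarray(ends, dtype=np.int64)[order]
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:  # overlap or book-ended -> merge
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.column_stack([out_s, out_e])


@dataclass
class PeakTrack:
    """A named set of peaks, stored merged and sorted per chromosome.

    ``by_chrom`` maps chromosome name to an (N, 2) array of [start, end)
    rows sorted by start and pairwise non-overlapping.
    """

    name: str
    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)
    cell_type: str = ""
    mark: str = ""

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[GenomicInterval],
        name: str = "",
        cell_type: str = "",
        mark: str = "",
    ) -> "PeakTrack":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
        by_chrom = {}
        for chrom, pairs in grouped.items():
            arr = np.asarray(pairs, dtype=np.int64)
            by_chrom[chrom] = _merge_starts_ends(arr[:, 0], arr[:, 1])
        return cls(name=name, by_chrom=by_chrom, cell_type=cell_type, mark=mark)

    @property
    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in self.by_chrom:
            for s, e in self.by_chrom[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    @property
    def n_peaks(self) -> int:
        return sum(len(a) for a in self.by_chrom.values())

    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self.by_chrom.values() if len(a))
        )

    def clipped(self, genome: "GenomeIndex") -> "PeakTrack":
        """Clip peaks to chromosome bounds; error on unknown chromosomes."""
        by_chrom: dict[str, np.ndarray] = {}
        for chrom, arr in self.by_chrom.items():
            if chrom not in genome.chrom_sizes:
                raise ValueError(
                    f"track {self.name!r} has peaks on chromosome {chrom!r} "
                    "absent from the genome index"
                )
            size = genome.chrom_sizes[chrom]
            if len(arr) and arr[:, 1].max() > size:
                logger.warning(
                    "track %s: clipping peaks overhanging %s (size %d)",
                    self.name, chrom, size,
                )
            clipped = np.clip(arr, 0, size)
            keep = clipped[:, 1] > clipped[:, 0]
            by_chrom[chrom] = clipped[keep]
        return PeakTrack(self.name, by_chrom, self.cell_type, self.mark)


@dataclass
class GenomeIndex:
    """Chromosome sizes with a stable ordering (file order)."""

    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size {size}")

    @property
    def chrom_order(self) -> list[str]:
        return list(self.chrom_sizes)

    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities of a motif, alphabet order A,C,G,T."""

    probs: np.ndarray  # (width, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be a width x 4 matrix (A, C, G, T)")
        if np.any(self.probs < 0):
            raise ValueError("PWM entries must be non-negative")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each PWM row must sum to 1 within 1e-6")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probs, axis=1))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_bed(
    path: str | Path, name: str | None = None, cell_type: str = "", mark: str = ""
) -> PeakTrack:
    """Read a BED3+ file into a merged, sorted :class:`PeakTrack`.

    Columns beyond the third are ignored; ``track``/``browser`` lines and
    ``#`` comments are skipped.  Overlapping or book-ended intervals of the
    same track are merged on load.
    """
    path = Path(path)
    if name is None:
        name = path.name.removesuffix(".gz").removesuffix(".bed")
    grouped: dict[str, tuple[list[int], list[int]]] = {}
    n_lines = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()  # tolerate space-delimited BED
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start},{end})"
                )
            grouped.setdefault(chrom, ([], []))
            grouped[chrom][0].append(start)
            grouped[chrom][1].append(end)
            n_lines += 1
    if n_lines == 0:
        logger.warning("BED file %s contains no peaks", path)
    by_chrom = {
        chrom: _merge_starts_ends(np.array(starts), np.array(ends))
        for chrom, (starts, ends) in grouped.items()
    }
    return PeakTrack(name=name, by_chrom=by_chrom, cell_type=cell_type, mark=mark)


def read_chrom_sizes(path: str | Path) -> GenomeIndex:
    """Read a two-column chromosome-sizes table, preserving file order."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name and length")
            chrom = fields[0]
            if chrom in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            try:
                size = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length") from exc
            if size <= 0:
                raise ValueError(
                    f"{path}:{lineno}: non-positive length {size} for {chrom!r}"
                )
            sizes[chrom] = size
    return GenomeIndex(chrom_sizes=sizes)


class FastaStore:
    """Random access to uppercase-normalized subsequences of a FASTA file."""

    def __init__(self, path: str | Path):
        if _PyfaidxFasta is None:  # pragma: no cover
            raise ImportError("pyfaidx is required for FASTA access")
        self._fasta = _PyfaidxFasta(str(path), as_raw=True, sequence_always_upper=True)

    @property
    def chroms(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not present in FASTA")
        return len(self._fasta[chrom])

    def fetch(self, interval: GenomicInterval) -> str:
        if interval.chrom not in self._fasta:
            raise KeyError(f"chromosome {interval.chrom!r} not present in FASTA")
        if interval.end > self.length(interval.chrom):
            raise ValueError(
                f"interval {interval.chrom}:[{interval.start},{interval.end}) "
                f"extends beyond sequence length {self.length(interval.chrom)}"
            )
        return str(self._fasta[interval.chrom][interval.start : interval.end])


def read_fasta(path: str | Path) -> FastaStore:
    return FastaStore(path)


def read_pwm(path: str | Path) -> PositionWeightMatrix:
    """Read a whitespace-delimited numeric matrix, one row per motif position.

    Rows may be counts or probabilities; each row is normalized by its sum.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", ">")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns (A C G T), got {len(fields)}"
                )
            try:
                vals = [float(v) for v in fields]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
            if any(v < 0 for v in vals):
                raise ValueError(f"{path}:{lineno}: negative entry")
            total = sum(vals)
            if total == 0:
                raise ValueError(f"{path}:{lineno}: row sum is zero")
            rows.append([v / total for v in vals])
    if not rows:
        raise ValueError(f"{path}: empty PWM")
    return PositionWeightMatrix(probs=np.array(rows))


_SEG_HEADER = "#chrom\tstart\tend\tcode\tlength"


def write_segments_bed(segmentation, path: str | Path, which: str = "retained") -> None:
    """Export segments as BED with name = decimal code and score = length."""
    from .segmentation import Segmentation  # local import avoids a cycle

    if not isinstance(segmentation, Segmentation):
        raise TypeError("expected a Segmentation")
    with open(path, "w") as fh:
        fh.write(_SEG_HEADER + "\n")
        for seg in segmentation.iter_segments(which):
            fh.write(
                f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}"
                f"\t{seg.code}\t{seg.interval.length}\n"
            )


def read_segments_bed(path: str | Path) -> list[tuple[GenomicInterval, int]]:
    """Read back a segments BED written by :func:`write_segments_bed`."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 fields")
            out.append(
                (
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    int(fields[3]),
                )
            )
    return out


def write_matrix_tsv(
    matrix: np.ndarray,
    row_labels: Sequence,
    col_labels: Sequence,
    path: str | Path,
) -> None:
    """Write a labeled matrix as TSV; NaN cells become the "NA" sentinel."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(row_labels), len(col_labels)):
        raise ValueError("matrix shape does not match label lengths")
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(str(c) for c in col_labels) + "\n")
        for label, row in zip(row_labels, matrix):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(label) + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read back a TSV written by :func:`write_matrix_tsv`."""
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_labels = header[1:]
        row_labels = []
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row_labels.append(fields[0])
            rows.append([np.nan if v == "NA" else float(v) for v in fields[1:]])
    matrix = np.array(rows, dtype=float) if rows else np.empty((0, len(col_labels)))
    return matrix, row_labels, col_labels
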