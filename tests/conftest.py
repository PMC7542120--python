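"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: per-base
membership is computed by scanning raw peak lines base by base, ranks are
assigned by explicit tie-group averaging, and PWM windows are scored with
pure-Python string handling.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from markseg import GenomeIndex, GenomicInterval, PeakTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_fixture(
    rng: np.random.Generator,
    max_chrom_size: int = 10_000,
    max_tracks: int = 3,
    max_peaks: int = 20,
):
    """A small random genome + raw (unmerged) peak tracks for oracle tests."""
    n_chroms = int(rng.integers(1, 3))
    sizes = {
        f"chr{i + 1}": int(rng.integers(300, max_chrom_size + 1))
        for i in range(n_chroms)
    }
    genome = GenomeIndex(chrom_sizes=dict(sizes))
    n_tracks = int(rng.integers(1, max_tracks + 1))
    tracks = []
    raw_intervals: list[list[GenomicInterval]] = []
    for t in range(n_tracks):
        ivs = []
        for chrom, size in sizes.items():
            for _ in range(int(rng.integers(0, max_peaks + 1))):
                start = int(rng.integers(0, size - 1))
                end = int(rng.integers(start + 1, size + 1))
                ivs.append(GenomicInterval(chrom, start, end))
        raw_intervals.append(ivs)
        tracks.append(PeakTrack.from_intervals(ivs, name=f"mark{t}"))
    return genome, tracks, raw_intervals


def per_base_codes_oracle(
    raw_intervals: list[list[GenomicInterval]], chrom: str, size: int
) -> np.ndarray:
    """Per-base code computed directly from raw peak membership."""
    codes = np.zeros(size, dtype=np.int64)
    for bit, ivs in enumerate(raw_intervals):
        member = np.zeros(size, dtype=bool)
        for iv in ivs:
            if iv.chrom == chrom:
                member[iv.start : min(iv.end, size)] = True
        codes |= member.astype(np.int64) << bit
    return codes


def midrank_oracle(values) -> list[float]:
    """Midranks by explicit sort + tie-group averaging (no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_oracle(x, y) -> float:
    """Pearson correlation via the direct sums formula, pure Python."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def pwm_hits_oracle(seq: str, probs, score_fraction: float, pseudocount: float = 0.01) -> int:
    """Exhaustive both-strand window enumeration with pure-Python scoring."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    bg = 0.25
    w = len(probs)
    scores = [
        [
            math.log2((p + pseudocount * bg) / ((1 + pseudocount) * bg))
            for p in row
        ]
        for row in probs
    ]
    max_s = sum(max(row) for row in scores)
    min_s = sum(min(row) for row in scores)
    threshold = min_s + score_fraction * (max_s - min_s)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def count(s: str) -> int:
        hits = 0
        for pos in range(len(s) - w + 1):
            window = s[pos : pos + w]
            if any(c not in idx for c in window):
                continue
            total = sum(scores[k][idx[c]] for k, c in enumerate(window))
            if total >= threshold - 1e-12:
                hits += 1
        return hits

    rc = "".join(comp.get(c, "N") for c in reversed(seq))
    return count(seq) + count(rc)


def write_fasta(path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n{seq}\n")
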