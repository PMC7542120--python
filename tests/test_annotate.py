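"""Coverage, fate-of-code, CpG density, PWM scanning, segment table."""

import numpy as np
import pytest

from markseg import (
    GenomeIndex,
    GenomicInterval,
    PeakTrack,
    PositionWeightMatrix,
    build_segment_table,
    coverage,
    cpg_density,
    fate_of_code,
    pwm_scan,
    read_fasta,
    segment_genome,
)

from conftest import pwm_hits_oracle, random_fixture, write_fasta


def one_segment_seg(size=100, nmarks=1):
    """A segmentation whose single retained segment spans the chromosome."""
    g = GenomeIndex({"chr1": size})
    tracks = [PeakTrack(name=f"m{i}") for i in range(nmarks)]
    return segment_genome(tracks, g, min_length=1)


def track(*pairs, chrom="chr1", name="t"):
    return PeakTrack.from_intervals(
        [GenomicInterval(chrom, s, e) for s, e in pairs], name=name
    )


class TestCoverage:
    @pytest.mark.parametrize(
        "seg_size,peaks,expected",
        [
            (100, [(50, 150)], 0.5),
            (100, [(0, 100)], 1.0),
            (100, [(0, 200)], 1.0),  # fully inside a larger peak
            (300, [(0, 50), (250, 300)], 100 / 300),
            (100, [], 0.0),
        ],
    )
    def test_fraction_of_covered_bases(self, seg_size, peaks, expected):
        seg = one_segment_seg(seg_size)
        cov = coverage(seg, track(*peaks))
        np.testing.assert_allclose(cov, [expected])

    def test_matches_per_base_oracle_on_random_fixtures(self, rng):
        for _ in range(20):
            genome, tracks, raw = random_fixture(rng)
            seg = segment_genome(tracks[:1], genome, min_length=100)
            other = tracks[-1]
            cov = coverage(seg, other)
            k = 0
            for s in seg.iter_segments("retained"):
                member = np.zeros(s.length, dtype=bool)
                for iv in other.intervals:
                    if iv.chrom == s.interval.chrom:
                        lo = max(iv.start, s.interval.start)
                        hi = min(iv.end, s.interval.end)
                        if hi > lo:
                            member[lo - s.interval.start : hi - s.interval.start] = True
                assert cov[k] == pytest.approx(member.mean())
                k += 1

    def test_monotone_under_peak_extension(self, rng):
        genome, tracks, _ = random_fixture(rng)
        seg = segment_genome(tracks, genome, min_length=100)
        t = tracks[0]
        extended = PeakTrack.from_intervals(
            [GenomicInterval(iv.chrom, max(0, iv.start - 37), iv.end) for iv in t.intervals],
            name=t.name,
        )
        assert np.all(coverage(seg, extended) >= coverage(seg, t) - 1e-12)


class TestFateOfCode:
    def test_threshold_boundary_is_inclusive(self):
        g = GenomeIndex({"chr1": 1000})
        ref = track((0, 1000), name="m0")
        seg = segment_genome([ref], g, min_length=1)
        # additional track covers exactly 80% of the single code-1 segment
        fate = fate_of_code(seg, [track((0, 800))], threshold=0.8)
        assert fate.counts[1, 1] == 1  # coverage 0.8 >= 0.8 sets the bit
        fate_low = fate_of_code(seg, [track((0, 799))], threshold=0.8)
        assert fate_low.counts[1, 0] == 1

    def test_self_fate_is_diagonal(self, rng):
        """Deriving codes from the reference tracks themselves changes nothing."""
        for _ in range(10):
            genome, tracks, _ = random_fixture(rng)
            seg = segment_genome(tracks, genome, min_length=200)
            t = float(rng.uniform(0.05, 1.0))
            fate = fate_of_code(seg, tracks, threshold=t)
            assert fate.total == seg.n_segments("retained")
            off_diag = fate.counts - np.diag(np.diag(fate.counts))
            assert off_diag.sum() == 0

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold can only clear derived bits, never set them."""
        genome, tracks, _ = random_fixture(rng)
        seg = segment_genome(tracks[:1], genome, min_length=100)
        other = tracks[-1]
        low = (coverage(seg, other) >= 0.3).astype(int)
        high = (coverage(seg, other) >= 0.7).astype(int)
        assert np.all(high <= low)

    def test_errors(self):
        seg = one_segment_seg(nmarks=2)
        with pytest.raises(ValueError, match="one additional track per"):
            fate_of_code(seg, [track((0, 10))])
        with pytest.raises(ValueError, match="threshold"):
            fate_of_code(seg, [track((0, 10)), track((0, 10))], threshold=1.5)

    def test_row_marginal_equals_reference_frequency(self, rng):
        from markseg import code_frequencies

        genome, tracks, _ = random_fixture(rng)
        seg = segment_genome(tracks, genome, min_length=200)
        fate = fate_of_code(seg, tracks, threshold=0.8)
        freq = code_frequencies(seg, "retained")
        for c in range(seg.n_codes):
            assert fate.counts[c].sum() == freq.counts.get(c, 0)

    def test_log_view_defined_at_zero(self):
        seg = one_segment_seg()
        fate = fate_of_code(seg, [track((0, 100))], threshold=0.5)
        assert np.isfinite(fate.log_view()).all()


class TestCpgDensity:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("CGCG", 0.5),
            ("AAAA", 0.0),
            ("CGNCG", 0.4),  # N-window does not match; 2 CG in 5 nt
            ("ACGT", 0.25),
        ],
    )
    def test_window_counting(self, tmp_path, seq, expected):
        write_fasta(tmp_path / "g.fa", {"chr1": seq})
        fa = read_fasta(tmp_path / "g.fa")
        seg = one_segment_seg(len(seq))
        np.testing.assert_allclose(cpg_density(seg, fa), [expected])

    def test_density_bounded_by_half(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=501))
        write_fasta(tmp_path / "g.fa", {"chr1": seq})
        fa = read_fasta(tmp_path / "g.fa")
        seg = one_segment_seg(len(seq))
        assert 0 <= cpg_density(seg, fa)[0] <= 0.5


class TestPwmScan:
    def _scan_seq(self, tmp_path, seq, probs, **kw):
        write_fasta(tmp_path / "g.fa", {"chr1": seq})
        fa = read_fasta(tmp_path / "g.fa")
        seg = one_segment_seg(len(seq))
        pwm = PositionWeightMatrix(np.asarray(probs, dtype=float))
        return pwm_scan(seg, fa, pwm, **kw)

    def test_single_base_motif_both_strands(self, tmp_path):
        # G motif on GGAG: forward hits at 0,1,3; reverse strand (CTCC) has
        # no G, so the total is 3 — frozen from the exhaustive-window oracle
        assert pwm_hits_oracle("GGAG", [[0, 0, 1, 0]], 1.0) == 3
        counts, density = self._scan_seq(
            tmp_path, "GGAG", [[0, 0, 1, 0]], score_fraction=1.0
        )
        assert counts[0] == 3
        assert density[0] == pytest.approx(3 / 4)

    def test_all_n_sequence_has_no_hits(self, tmp_path):
        counts, _ = self._scan_seq(
            tmp_path, "NNNNNN", [[0.25] * 4, [0.25] * 4], score_fraction=0.0
        )
        assert counts[0] == 0

    def test_fraction_zero_counts_every_window_both_strands(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        probs = rng.dirichlet(np.ones(4), size=5)
        counts, _ = self._scan_seq(tmp_path, seq, probs, score_fraction=0.0)
        assert counts[0] == 2 * (60 - 5 + 1)

    def test_segment_shorter_than_motif_counts_zero(self, tmp_path):
        counts, density = self._scan_seq(
            tmp_path, "AC", [[1, 0, 0, 0]] * 5, score_fraction=0.5
        )
        assert counts[0] == 0 and density[0] == 0.0

    def test_palindromic_motif_strand_symmetry(self, tmp_path, rng):
        # "AT" reverse-complements to itself, so forward and reverse hit sets mirror
        probs = [[1, 0, 0, 0], [0, 0, 0, 1]]
        seq = "".join(rng.choice(list("ACGT"), size=80))
        counts, _ = self._scan_seq(tmp_path, seq, probs, score_fraction=1.0)
        assert counts[0] % 2 == 0  # every forward AT has a mirrored reverse hit

    def test_matches_exhaustive_oracle_on_random_inputs(self, tmp_path, rng):
        for i in range(15):
            n = int(rng.integers(10, 80))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            w = int(rng.integers(1, 7))
            probs = rng.dirichlet(np.ones(4), size=w)
            frac = float(rng.uniform(0, 1))
            counts, _ = self._scan_seq(tmp_path, seq, probs, score_fraction=frac)
            assert counts[0] == pwm_hits_oracle(seq, probs.tolist(), frac)


class TestSegmentTable:
    def test_base_columns_only(self):
        seg = one_segment_seg(nmarks=2)
        table = build_segment_table(seg)
        assert list(table.columns) == [
            "segment_id", "chrom", "start", "end", "length", "code", "m0", "m1",
        ]
        assert len(table) == seg.n_segments("retained")

    def test_one_track_adds_one_column(self):
        seg = one_segment_seg()
        t0 = build_segment_table(seg)
        t1 = build_segment_table(seg, {"extra": track((0, 50))})
        assert set(t1.columns) - set(t0.columns) == {"extra"}
        assert t1["extra"].iloc[0] == 0.5

    def test_duplicate_column_label_rejected(self):
        seg = one_segment_seg()
        with pytest.raises(ValueError, match="duplicate column"):
            build_segment_table(seg, {"length": track((0, 50))})

    def test_pwm_without_fasta_rejected(self):
        seg = one_segment_seg()
        pwm = PositionWeightMatrix(np.array([[1.0, 0, 0, 0]]))
        with pytest.raises(ValueError, match="requires a FASTA"):
            build_segment_table(seg, pwm=pwm)

    def test_full_annotation_row_count(self, tmp_path, rng):
        genome, tracks, _ = random_fixture(rng, max_chrom_size=2000)
        seqs = {
            c: "".join(rng.choice(list("ACGT"), size=s))
            for c, s in genome.chrom_sizes.items()
        }
        write_fasta(tmp_path / "g.fa", seqs)
        fa = read_fasta(tmp_path / "g.fa")
        seg = segment_genome(tracks, genome, min_length=100)
        pwm = PositionWeightMatrix(np.array([[0.7, 0.1, 0.1, 0.1]] * 4))
        table = build_segment_table(seg, {"x": tracks[0]}, fa, pwm)
        assert len(table) == seg.n_segments("retained")
        assert {"cpg_density", "motif_count", "motif_density", "x"} <= set(table.columns)
        assert table["x"].between(0, 1).all()
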