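"""Alignment loading, dedup, fragment extension, binning, RPM, merging."""

import numpy as np
import pytest
from scipy import stats

from methylcap.alignment_io import (
    AlignedRead,
    BinCountVector,
    Lane,
    ManifestEntry,
    bin_counts,
    extend_read,
    load_alignments,
    merge_replicate_lanes,
    read_manifest,
    rpm_normalize,
)
from methylcap.simulate import GENOME_CHROM, simulate_lane


def make_lane(index, reads, fragment_length=150, total_raw=None, **kw):
    """Build a Lane directly from (chrom, start, strand, read_len) tuples."""
    name_to_idx = {c: i for i, c in enumerate(index.chrom_names)}
    return Lane(
        sample_id=kw.get("sample_id", "S"),
        lane_id=kw.get("lane_id", "L"),
        library_id=kw.get("library_id", "lib"),
        chrom_names=list(index.chrom_names),
        chrom_idx=np.array([name_to_idx[r[0]] for r in reads], dtype=np.int32),
        start=np.array([r[1] for r in reads], dtype=np.int64),
        strand=np.array([1 if r[2] == "-" else 0 for r in reads], dtype=np.int8),
        read_length=np.array([r[3] for r in reads], dtype=np.int32),
        total_raw_reads=total_raw or len(reads),
        fragment_length=fragment_length,
    )


class TestExtendRead:
    def test_plus_strand(self, make_index):
        idx = make_index("A" * 2000)
        r = AlignedRead("chr1", 1000, "+", 36)
        assert extend_read(r, 150, idx) == (1000, 1150)

    def test_minus_strand(self, make_index):
        idx = make_index("A" * 2000)
        r = AlignedRead("chr1", 1000, "-", 36)
        assert extend_read(r, 150, idx) == (886, 1036)

    def test_clipped_at_contig_end(self, make_index):
        idx = make_index("A" * 2000)
        r = AlignedRead("chr1", 1990, "+", 10)
        assert extend_read(r, 150, idx) == (1990, 2000)

    def test_clipped_at_contig_start(self, make_index):
        idx = make_index("A" * 2000)
        r = AlignedRead("chr1", 10, "-", 36)
        assert extend_read(r, 150, idx) == (0, 46)

    def test_fragment_shorter_than_read_errors(self, make_index):
        idx = make_index("A" * 2000)
        with pytest.raises(ValueError):
            extend_read(AlignedRead("chr1", 0, "+", 36), 20, idx)


class TestBinCounts:
    def test_single_fragment_first_bin(self, make_index):
        idx = make_index("A" * 2000)
        lane = make_lane(idx, [("chr1", 0, "+", 36)])
        bv = bin_counts(lane, idx)
        assert bv.counts.tolist() == [1, 0, 0, 0]

    def test_midpoint_rule_straddling_fragment(self, make_index):
        # fragment [400, 550) has midpoint 474 -> bin 0, not bin 1
        idx = make_index("A" * 2000)
        lane = make_lane(idx, [("chr1", 400, "+", 36)])
        assert bin_counts(lane, idx).counts.tolist() == [1, 0, 0, 0]

    def test_count_conservation(self, captured_lane, sim_index):
        bv = bin_counts(captured_lane, sim_index)
        assert bv.counts.sum() == captured_lane.total_unique_aligned
        assert bv.total_assigned == captured_lane.total_unique_aligned

    def test_uniform_fragments_multinomial(self, make_index):
        # uniformly placed fragments fill bins per a uniform multinomial
        idx = make_index("A" * 500_000)
        rng = np.random.default_rng(5)
        n = 100_000
        starts = rng.integers(0, 500_000 - 150, n)
        lane = make_lane(idx, [("chr1", int(s), "+", 36) for s in starts])
        counts = bin_counts(lane, idx).counts
        # drop the last bin: fragment starts cannot reach its far edge
        observed = counts[:-1]
        expected = np.full(observed.size, observed.sum() / observed.size)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, observed.size - 1)
        assert p > 0.01


class TestRPM:
    def test_scaling(self, make_index):
        idx = make_index("A" * 2000)
        bv = BinCountVector(
            counts=np.array([500, 0, 0, 0]), total_assigned=500, bin_size=500
        )
        bv.total_assigned = 10_000_000  # 500 reads of 10M
        out = rpm_normalize(bv)
        assert out.rpm[0] == pytest.approx(50.0)

    def test_all_reads_one_bin(self):
        bv = BinCountVector(counts=np.array([7, 0]), total_assigned=7)
        out = rpm_normalize(bv)
        assert out.rpm[0] == pytest.approx(1e6, rel=1e-12)
        assert out.rpm[1] == 0.0

    def test_sum_is_one_million(self, captured_lane, sim_index):
        out = rpm_normalize(bin_counts(captured_lane, sim_index))
        assert out.rpm.sum() == pytest.approx(1e6, rel=1e-9)

    def test_zero_reads_error(self):
        with pytest.raises(ValueError):
            rpm_normalize(BinCountVector(counts=np.zeros(3, int), total_assigned=0))


class TestMerge:
    def _bv(self, rpm):
        rpm = np.asarray(rpm, float)
        return BinCountVector(
            counts=np.zeros_like(rpm, dtype=int), total_assigned=1, rpm=rpm
        )

    def test_identical_lanes(self):
        out = merge_replicate_lanes([self._bv([2e5, 8e5])] * 2)
        assert out.rpm.tolist() == [2e5, 8e5]

    def test_opposite_lanes_average(self):
        out = merge_replicate_lanes([self._bv([0, 1e6]), self._bv([1e6, 0])])
        assert out.rpm.tolist() == [5e5, 5e5]

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_idempotent_over_copies(self, k):
        out = merge_replicate_lanes([self._bv([3e5, 7e5])] * k)
        assert out.rpm.tolist() == [3e5, 7e5]
        assert out.rpm.sum() == pytest.approx(1e6)

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError):
            merge_replicate_lanes([self._bv([1e6]), self._bv([5e5, 5e5])])

    def test_empty_error(self):
        with pytest.raises(ValueError):
            merge_replicate_lanes([])


class TestLoadAlignments:
    def test_bed_dedup(self, tmp_path, make_index):
        idx = make_index("A" * 2000)
        bed = tmp_path / "l.bed"
        bed.write_text(
            "chr1\t100\t136\tr1\t0\t+\n"
            "chr1\t100\t136\tr2\t0\t+\n"  # duplicate of r1
            "chr1\t100\t136\tr3\t0\t-\n"  # same position, other strand
        )
        entry = ManifestEntry("S", "L", "lib", str(bed), total_raw_reads=5)
        lane = load_alignments(str(bed), entry, idx)
        assert lane.total_unique_aligned == 2
        assert lane.total_raw_reads == 5  # BED raw total comes from manifest

    def test_sam_unmapped_counted_raw_only(self, tmp_path, make_index):
        idx = make_index("A" * 2000)
        sam = tmp_path / "l.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:2000\n"
            "r1\t0\tchr1\t101\t255\t4M\t*\t0\t0\tACGT\t*\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
        )
        entry = ManifestEntry("S", "L", "lib", str(sam))
        lane = load_alignments(str(sam), entry, idx)
        assert lane.total_unique_aligned == 1
        assert lane.total_raw_reads == 2
        assert lane.start[0] == 100  # SAM POS is 1-based

    def test_headerless_sam(self, tmp_path, make_index):
        idx = make_index("A" * 2000)
        sam = tmp_path / "l.sam"
        sam.write_text(
            "r1\t0\tchr1\t101\t255\t4M\t*\t0\t0\tACGT\t*\n"
            "r2\t16\tchr1\t301\t255\t4M\t*\t0\t0\tACGT\t*\n"
        )
        entry = ManifestEntry("S", "L", "lib", str(sam))
        lane = load_alignments(str(sam), entry, idx)
        assert lane.total_unique_aligned == 2
        assert lane.strand.tolist() == [0, 1]

    def test_unknown_contig_errors(self, tmp_path, make_index):
        idx = make_index("A" * 2000)
        sam = tmp_path / "l.sam"
        sam.write_text(
            "@SQ\tSN:chrX\tLN:2000\n"
            "r1\t0\tchrX\t101\t255\t4M\t*\t0\t0\tACGT\t*\n"
        )
        entry = ManifestEntry("S", "L", "lib", str(sam))
        with pytest.raises(ValueError, match="chrX"):
            load_alignments(str(sam), entry, idx)

    def test_skip_contigs_drops_construct(self, tmp_path, make_index):
        idx = make_index("A" * 2000)
        sam = tmp_path / "l.sam"
        sam.write_text(
            "@SQ\tSN:chr1\tLN:2000\n@SQ\tSN:spike\tLN:500\n"
            "r1\t0\tchr1\t101\t255\t4M\t*\t0\t0\tACGT\t*\n"
            "r2\t0\tspike\t11\t255\t4M\t*\t0\t0\tACGT\t*\n"
        )
        entry = ManifestEntry("S", "L", "lib", str(sam))
        lane = load_alignments(str(sam), entry, idx, skip_contigs=("spike",))
        assert lane.total_unique_aligned == 1

    def test_zero_usable_reads_error(self, tmp_path, make_index):
        idx = make_index("A" * 2000)
        sam = tmp_path / "l.sam"
        sam.write_text(
            "@SQ\tSN:chr1\tLN:2000\n"
            "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n"
        )
        entry = ManifestEntry("S", "L", "lib", str(sam))
        with pytest.raises(ValueError, match="no usable reads"):
            load_alignments(str(sam), entry, idx)

    def test_sam_round_trip_matches_in_memory(
        self, tmp_path, captured_sim_lane, sim_index
    ):
        """Writing the simulated lane to SAM and loading it back gives the
        same deduplicated lane as the in-memory fast path."""
        sam = tmp_path / "lane.sam"
        captured_sim_lane.to_sam(str(sam))
        entry = ManifestEntry("S1", "L1", "lib1", str(sam))
        loaded = load_alignments(
            str(sam), entry, sim_index, skip_contigs=("spike_construct",)
        )
        fast = captured_sim_lane.to_lane(sim_index)
        assert loaded.total_unique_aligned == fast.total_unique_aligned
        assert (
            loaded.total_unique_aligned
            == captured_sim_lane.truth["expected_unique_genome"]
        )
        np.testing.assert_array_equal(
            np.sort(loaded.start * 2 + loaded.strand),
            np.sort(fast.start * 2 + fast.strand),
        )


class TestDedupProperties:
    def test_dedup_idempotent(self, captured_lane, sim_index):
        from methylcap.alignment_io import _dedup

        c, s, v, l = _dedup(
            captured_lane.chrom_idx,
            captured_lane.start,
            captured_lane.strand,
            captured_lane.read_length,
        )
        assert s.size == captured_lane.total_unique_aligned
        np.testing.assert_array_equal(s, captured_lane.start)

    def test_zero_duplicate_rate_removes_nothing(self, sim_genome, sim_methylation):
        from dataclasses import replace

        cfg = replace(sim_genome.config, duplicate_rate=0.0, reads_per_lane=20_000)
        sl = simulate_lane(sim_genome, sim_methylation, seed=9, config=cfg)
        assert sl.n_duplicates_injected == 0
        # any residual collisions are genuine coincidences of the draw
        lane = sl.to_lane(sim_genome.build_index())
        assert lane.total_unique_aligned == sl.truth["expected_unique_genome"]


class TestManifest:
    def test_round_trip(self, tmp_path):
        mf = tmp_path / "manifest.tsv"
        mf.write_text(
            "sample_id\tlane_id\tlibrary_id\tpath\tfragment_length\ttotal_raw_reads\tgroup\n"
            "S1\tL1\tlib1\tl1.sam\t150\t1000\tcase\n"
            "S1\tL2\tlib1\tl2.sam\t180\t\tcontrol\n"
        )
        entries = read_manifest(str(mf))
        assert len(entries) == 2
        assert entries[0].total_raw_reads == 1000
        assert entries[1].total_raw_reads is None
        assert entries[1].fragment_length == 180
        assert entries[0].path.endswith("l1.sam")

    def test_missing_columns_error(self, tmp_path):
        mf = tmp_path / "manifest.tsv"
        mf.write_text("sample_id\tpath\nS1\tl1.sam\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_manifest(str(mf))


class TestReplicateLaneCorrelation:
    def test_same_library_lanes_correlate(self, sim_genome, sim_methylation):
        """Two lanes drawn from the same library parameters reproduce each
        other's binned RPM profile (resequencing-correlation analogue)."""
        idx = sim_genome.build_index()
        lanes = [
            simulate_lane(sim_genome, sim_methylation, mode="captured", seed=s)
            for s in (21, 22)
        ]
        rpms = [
            rpm_normalize(bin_counts(sl.to_lane(idx), idx)).rpm for sl in lanes
        ]
        r = np.corrcoef(rpms[0], rpms[1])[0, 1]
        assert r**2 > 0.9
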