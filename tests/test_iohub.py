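import numpy as np
import pytest

from ibdbench import GeneticMap, HaplotypeId, HapPair, IBDSegment
from ibdbench.core import FormatError
from ibdbench.iohub import (
    HAPIBD_DIALECT,
    IbdDialect,
    read_genetic_map,
    read_ibd_calls,
    read_track,
    read_truth_ibd,
    read_vcf,
    write_plink_map,
    write_track,
    write_truth_ibd,
    write_vcf,
)
from ibdbench.panelops import HaplotypePanel
from ibdbench.synthdata import gen_panel, gen_track

from .conftest import cm_segment, make_pair

TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\t1|1
1\t200\t.\tG\tT\t.\tPASS\t.\tGT\t0|0\t0|1
1\t300\t.\tT\tA,G\t.\tPASS\t.\tGT\t1|2\t0|0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


class TestVcf:
    def test_toy_vcf_shape_and_alleles(self, toy_vcf):
        panel = read_vcf(toy_vcf)
        assert panel.n_haplotypes == 4
        assert panel.n_sites == 3
        assert panel.positions.tolist() == [100, 200, 300]
        assert panel.alleles.tolist() == [[0, 1, 1, 1], [0, 0, 0, 1], [1, 2, 0, 0]]
        assert panel.haplotypes[0] == HaplotypeId("A", 0)
        assert panel.is_biallelic().tolist() == [True, True, False]

    def test_unphased_genotype_is_hard_error(self, tmp_path):
        path = tmp_path / "unphased.vcf"
        path.write_text(TOY_VCF.replace("0|1\t1|1", "0/1\t1|1"))
        with pytest.raises(FormatError, match="unphased"):
            read_vcf(path)
        panel = read_vcf(path, phased_required=False)
        assert panel.n_sites == 3

    def test_round_trip_identity(self, toy_vcf, tmp_path):
        panel = read_vcf(toy_vcf)
        out = tmp_path / "rt.vcf"
        write_vcf(panel, out)
        back = read_vcf(out)
        assert np.array_equal(back.alleles, panel.alleles)
        assert back.positions.tolist() == panel.positions.tolist()
        assert back.haplotypes == panel.haplotypes
        assert back.ref == panel.ref and back.alt == panel.alt

    def test_large_panel_round_trip(self, tmp_path):
        # 8,000 haplotypes, modest site count
        panel = gen_panel(8000, 25, seed=7)
        out = tmp_path / "big.vcf"
        write_vcf(panel, out)
        back = read_vcf(out)
        assert back.n_haplotypes == 8000
        assert np.array_equal(back.alleles, panel.alleles)

    def test_empty_panel_writes_header_only(self, tmp_path):
        panel = HaplotypePanel(
            haplotypes=[HaplotypeId("A", 0), HaplotypeId("A", 1)],
            chrom="1",
            positions=np.array([], dtype=np.int64),
            alleles=np.empty((0, 2), dtype=np.int8),
            ref=[],
            alt=[],
        )
        out = tmp_path / "empty.vcf"
        write_vcf(panel, out)
        assert read_vcf(out).n_sites == 0


class TestGeneticMapIO:
    def test_plink_dialect(self, tmp_path):
        path = tmp_path / "toy.map"
        path.write_text("20 m0 0.0 1\n20 m1 1.5 1000000\n20 m2 2.0 3000000\n")
        gmap = read_genetic_map(path, "plink")
        assert gmap.pos_bp.tolist() == [1, 1000000, 3000000]
        assert gmap.pos_cm.tolist() == [0.0, 1.5, 2.0]
        assert gmap.chrom == "20"

    def test_hapmap_dialect_equivalent(self, tmp_path):
        path = tmp_path / "toy.txt"
        path.write_text(
            "chr position rate cM\n20 1 1.5 0.0\n20 1000000 0.5 1.5\n20 3000000 0.0 2.0\n"
        )
        gmap = read_genetic_map(path, "hapmap")
        assert gmap.pos_bp.tolist() == [1, 1000000, 3000000]
        assert gmap.pos_cm.tolist() == [0.0, 1.5, 2.0]

    def test_decreasing_cm_names_line(self, tmp_path):
        path = tmp_path / "bad.map"
        path.write_text("20 m0 1.0 1\n20 m1 0.5 1000000\n")
        with pytest.raises(FormatError, match="lines 1 and 2"):
            read_genetic_map(path, "plink")

    def test_truncated_map_rejected(self, tmp_path):
        path = tmp_path / "trunc.map"
        path.write_text("20 m0 0.0 1\n20 m1 1.5\n")
        with pytest.raises(FormatError):
            read_genetic_map(path, "plink")

    def test_plink_writer_round_trip(self, tmp_path):
        gmap = GeneticMap([0, 500_000, 2_000_000], [0.0, 0.7, 2.3], chrom="20")
        path = tmp_path / "out.map"
        write_plink_map(gmap, path)
        back = read_genetic_map(path, "plink")
        assert back.pos_bp.tolist() == gmap.pos_bp.tolist()
        assert back.pos_cm.tolist() == gmap.pos_cm.tolist()


class TestIbdCalls:
    def test_hapibd_row(self, tmp_path, umap):
        path = tmp_path / "calls.tsv"
        path.write_text("S1\t1\tS2\t2\t1\t1000001\t4000000\t3.0\n")
        segs = read_ibd_calls(path, HAPIBD_DIALECT, umap)
        (seg,) = segs
        assert seg.pair == HapPair(HaplotypeId("S1", 0), HaplotypeId("S2", 1))
        # 1-based inclusive [1000001, 4000000] -> half-open [1000000, 4000000)
        assert (seg.start_bp, seg.end_bp) == (1_000_000, 4_000_000)
        assert seg.length_cm == pytest.approx(3.0)

    def test_cm_recomputed_from_map_and_mismatch_counted(self, tmp_path, umap, caplog):
        path = tmp_path / "calls.tsv"
        # stated length 9.9 cM disagrees with the map's 3.0 cM
        path.write_text("S1\t1\tS2\t2\t1\t1000001\t4000000\t9.9\n")
        import logging

        with caplog.at_level(logging.DEBUG, logger="ibdbench.iohub"):
            (seg,) = read_ibd_calls(path, HAPIBD_DIALECT, umap)
        assert seg.length_cm == pytest.approx(3.0)  # map wins
        assert any("differs from the map" in r.message for r in caplog.records)

    def test_negative_length_rows_skipped_with_warning(self, tmp_path, umap, caplog):
        rows = [f"S1\t1\tS2\t1\t1\t{i * 1000000 + 1}\t{(i + 1) * 1000000}\t1.0" for i in range(9)]
        rows.insert(4, "S1\t1\tS2\t1\t1\t5000000\t4000000\t1.0")  # negative length
        path = tmp_path / "calls.tsv"
        path.write_text("\n".join(rows) + "\n")
        import logging

        with caplog.at_level(logging.WARNING, logger="ibdbench.iohub"):
            segs = read_ibd_calls(path, HAPIBD_DIALECT, umap)
        assert len(segs) == 9
        assert any("skipped 1" in r.message for r in caplog.records)

    def test_generic_dialect_without_haps_requires_individual_mode(self, tmp_path, umap):
        dialect = IbdDialect(
            name="generic",
            column_map={"sample1": 0, "sample2": 1, "chrom": 2, "start_bp": 3, "end_bp": 4},
        )
        path = tmp_path / "calls.tsv"
        path.write_text("S1\tS2\t1\t1\t1000000\n")
        with pytest.raises(FormatError, match="hap1"):
            read_ibd_calls(path, dialect, umap, pair_mode="haplotype")
        segs = read_ibd_calls(path, dialect, umap, pair_mode="individual")
        assert len(segs) == 1

    def test_truncated_line_rejected(self, tmp_path, umap):
        path = tmp_path / "calls.tsv"
        path.write_text("S1\t1\tS2\t2\t1\t1000001\t4000000\t3.0\nS1\t1\tS2\t2\t1\n")
        with pytest.raises(FormatError, match="line 2"):
            read_ibd_calls(path, HAPIBD_DIALECT, umap)


class TestTruthTsv:
    def test_round_trip_identity_on_random_segments(self, tmp_path, umap):
        rng = np.random.default_rng(11)
        segs = []
        for i in range(100):
            pair = make_pair(f"x{rng.integers(0, 20):02d}")
            start = int(rng.integers(0, 90_000_000))
            segs.append(cm_segment(umap, start / 1e6, start / 1e6 + rng.uniform(0.5, 9), pair=pair))
        path = tmp_path / "truth.tsv"
        write_truth_ibd(segs, path)
        back = read_truth_ibd(path)
        assert sorted(back, key=lambda s: s.sort_key()) == sorted(
            segs, key=lambda s: s.sort_key()
        )

    def test_empty_and_header_only_files(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        assert read_truth_ibd(empty) == []
        header_only = tmp_path / "header.tsv"
        header_only.write_text(
            "sample1\thap1\tsample2\thap2\tchrom\tstart_bp\tend_bp\tstart_cm\tend_cm\n"
        )
        assert read_truth_ibd(header_only) == []

    def test_truncated_truth_rejected(self, tmp_path, umap):
        path = tmp_path / "truth.tsv"
        write_truth_ibd([cm_segment(umap, 1, 4)], path)
        text = path.read_text()
        path.write_text(text + "a\t0\tb\t0\t1\n")
        with pytest.raises(FormatError, match="truncated"):
            read_truth_ibd(path)


class TestTrackIO:
    def test_track_round_trip(self, tmp_path):
        track = gen_track(8, 2_000_000, mean_segment_bp=400_000, seed=5)
        path = tmp_path / "track.tsv"
        write_track(track, path)
        back = read_track(path)
        assert back.chrom == track.chrom
        assert back.sequence_length == track.sequence_length
        assert back.haplotypes == track.haplotypes
        for pair in track.pairs(include_within_individual=True):
            e1, l1 = track.pair_intervals(pair)
            e2, l2 = back.pair_intervals(pair)
            assert np.array_equal(e1, e2) and np.array_equal(l1, l2)

    def test_truncated_track_rejected(self, tmp_path):
        track = gen_track(4, 1_000_000, seed=1)
        path = tmp_path / "track.tsv"
        write_track(track, path)
        path.write_text(path.read_text() + "s0000\t0\ts0001\n")
        with pytest.raises(FormatError):
            read_track(path)
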