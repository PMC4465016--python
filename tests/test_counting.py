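"""BAM import: admission filter, strand assignment, pileup-vs-oracle equality."""

import numpy as np
import pysam
import pytest

from asekit.counting import CountFilter, admit_read, count_alleles, fragment_strand
from asekit.dataset import NT_INDEX, STRAND_INDEX, SNPVariant
from asekit.errors import MalformedRecordError, ValidationError
from asekit.simulate import SimConfig, simulate

from conftest import degrade_bam, make_read, oracle_count_tensor, write_bam


class TestAdmitRead:
    def test_clean_read_admitted(self, sam_header):
        read = make_read(sam_header, mapq=30, baseq=35)
        assert admit_read(read, CountFilter(), 35) == (True, None)

    def test_duplicate_rejected_with_reason(self, sam_header):
        read = make_read(sam_header, duplicate=True)
        assert admit_read(read, CountFilter(), 35) == (False, "duplicate")
        assert admit_read(read, CountFilter(drop_duplicates=False), 35)[0]

    def test_thresholds_inclusive(self, sam_header):
        read = make_read(sam_header, mapq=20)
        assert admit_read(read, CountFilter(min_mapq=20), 10) == (True, None)
        assert admit_read(read, CountFilter(min_mapq=21), 10) == (False, "mapq")
        assert admit_read(read, CountFilter(min_baseq=11), 10) == (False, "baseq")

    def test_improper_pair_and_secondary(self, sam_header):
        assert admit_read(make_read(sam_header, proper=False), CountFilter(), 35) == (False, "not_proper")
        assert admit_read(make_read(sam_header, secondary=True), CountFilter(), 35) == (False, "secondary")
        # single-end reads are exempt from the proper-pair rule
        assert admit_read(make_read(sam_header, paired=False), CountFilter(), 35)[0]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            CountFilter(min_mapq=-1)


class TestFragmentStrand:
    @pytest.mark.parametrize(
        "strandedness,read2,reverse,expect",
        [
            ("fr-firststrand", True, False, "plus"),
            ("fr-firststrand", True, True, "minus"),
            ("fr-firststrand", False, False, "minus"),
            ("fr-firststrand", False, True, "plus"),
            ("fr-secondstrand", True, False, "minus"),
            ("fr-secondstrand", False, False, "plus"),
            ("unstranded", True, False, "both"),
            ("unstranded", False, True, "both"),
        ],
    )
    def test_protocol_conventions(self, sam_header, strandedness, read2, reverse, expect):
        read = make_read(sam_header, read2=read2, reverse=reverse)
        assert fragment_strand(read, strandedness) == expect

    def test_single_end_treated_as_read1(self, sam_header):
        read = make_read(sam_header, paired=False)
        assert fragment_strand(read, "fr-firststrand") == "minus"

    def test_contradictory_flags(self, sam_header):
        read = make_read(sam_header)
        read.flag |= 0x40 | 0x80  # both first and second in pair
        with pytest.raises(MalformedRecordError):
            fragment_strand(read, "fr-firststrand")

    def test_truth_strand_recovered_on_stranded_fixture(self, tmp_path):
        """On a simulated dUTP library every admitted fragment lands on the
        transcript strand recorded in the truth table."""
        for protocol in ("fr-firststrand", "fr-secondstrand"):
            cfg = SimConfig(
                n_snps=4, samples=("a",), depth=25, seed=17,
                strandedness=protocol, transcript_strand="random",
            )
            res = simulate(cfg, tmp_path / protocol)
            ds, _ = count_alleles(res.bams, res.variants, CountFilter.permissive(), protocol)
            truth = res.truth_frame()
            for row in truth.itertuples():
                j = ds.variant_index(row.id)
                plus = ds.counts[0, j, :, STRAND_INDEX["plus"]].sum()
                minus = ds.counts[0, j, :, STRAND_INDEX["minus"]].sum()
                assert plus == row.ref_plus + row.alt_plus
                assert minus == row.ref_minus + row.alt_minus


class TestCountAlleles:
    def _variant(self, pos=200):
        return SNPVariant("chr1", pos, "v", ref_allele="A", alt_allele="G")

    def _base_reads(self, header, pos=200, n_a=3, n_g=2, **kwargs):
        seq_a = "A" * 41
        seq_g = "A" * 20 + "G" + "A" * 20
        reads = []
        for k in range(n_a):
            reads.append(make_read(header, name=f"a{k}", pos=pos - 20, seq=seq_a, **kwargs))
        for k in range(n_g):
            reads.append(make_read(header, name=f"g{k}", pos=pos - 20, seq=seq_g, **kwargs))
        return reads

    def test_hand_built_counts(self, sam_header, tmp_path):
        bam = write_bam(self._base_reads(sam_header), sam_header, tmp_path / "t.bam")
        ds, report = count_alleles([bam], [self._variant()], CountFilter())
        cell = ds.counts[0, 0, :, STRAND_INDEX["both"]]
        assert list(cell) == [3, 0, 2, 0]
        assert report.admitted["t"] == 5

    def test_low_mapq_read_filtered(self, sam_header, tmp_path):
        reads = self._base_reads(sam_header, n_a=2, n_g=2)
        reads.append(make_read(sam_header, name="a_low", pos=180, seq="A" * 41, mapq=5))
        bam = write_bam(reads, sam_header, tmp_path / "t.bam")
        ds, report = count_alleles([bam], [self._variant()], CountFilter(min_mapq=20))
        assert list(ds.counts[0, 0, :, STRAND_INDEX["both"]]) == [2, 0, 2, 0]
        assert report.rejected["t"]["mapq"] == 1

    def test_deletion_spanning_snp_contributes_nothing(self, sam_header, tmp_path):
        # 20M5D21M starting at 190 deletes reference bases 210..214; put the
        # SNP inside the deletion
        read = make_read(sam_header, name="del", pos=190, seq="C" * 41, cigar="20M5D21M")
        bam = write_bam([read], sam_header, tmp_path / "t.bam")
        ds, _ = count_alleles([bam], [SNPVariant("chr1", 212, "v", ref_allele="A", alt_allele="G")])
        assert ds.counts.sum() == 0

    def test_refskip_and_softclip_contribute_nothing(self, sam_header, tmp_path):
        skip = make_read(sam_header, name="n", pos=190, seq="C" * 41, cigar="20M100N21M")
        # soft-clipped leading bases precede the alignment start at 213 and
        # never receive a reference coordinate, so the SNP at 212 is uncovered
        clip = make_read(sam_header, name="s", pos=213, seq="C" * 41, cigar="10S31M")
        bam = write_bam([skip, clip], sam_header, tmp_path / "t.bam")
        ds, _ = count_alleles([bam], [SNPVariant("chr1", 212, "v", ref_allele="A", alt_allele="G")])
        assert ds.counts.sum() == 0

    def test_mate_overlap_counts_fragment_once(self, sam_header, tmp_path):
        pair = [
            make_read(sam_header, name="f", pos=190, seq="G" * 41, read2=False),
            make_read(sam_header, name="f", pos=195, seq="G" * 41, read2=True, reverse=True),
        ]
        bam = write_bam(pair, sam_header, tmp_path / "t.bam")
        ds, report = count_alleles([bam], [self._variant()], CountFilter())
        assert ds.counts[0, 0, NT_INDEX["G"], STRAND_INDEX["both"]] == 1
        assert report.mate_deduplicated["t"] == 1

    def test_missing_chromosome_warns_zero_counts(self, sam_header, tmp_path):
        bam = write_bam(self._base_reads(sam_header), sam_header, tmp_path / "t.bam")
        v = SNPVariant("chr9", 200, "v", ref_allele="A", alt_allele="G")
        with pytest.warns(UserWarning, match="chr9"):
            ds, _ = count_alleles([bam], [v])
        assert ds.counts.sum() == 0

    def test_missing_index_raises(self, sam_header, tmp_path):
        bam = write_bam(self._base_reads(sam_header), sam_header, tmp_path / "t.bam")
        (tmp_path / "t.bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="t.bam"):
            count_alleles([bam], [self._variant()])


class TestOracleEquivalence:
    @pytest.mark.parametrize("strandedness", ["unstranded", "fr-firststrand", "fr-secondstrand"])
    @pytest.mark.parametrize("degrade", [False, True])
    def test_matches_brute_force(self, tmp_path, strandedness, degrade):
        cfg = SimConfig(
            n_snps=8, samples=("a", "b"), depth=30, seed=7 + degrade,
            strandedness=strandedness, transcript_strand="random",
        )
        res = simulate(cfg, tmp_path / "sim")
        paths = [res.bams[s] for s in cfg.samples]
        if degrade:
            for k, p in enumerate(paths):
                degrade_bam(p, seed=50 + k)
        flt = CountFilter() if degrade else CountFilter.permissive()
        ds, _ = count_alleles(dict(zip(cfg.samples, paths)), res.variants, flt, strandedness)
        expected = oracle_count_tensor(paths, res.variants, flt, strandedness)
        np.testing.assert_array_equal(ds.counts, expected)

    def test_order_independence(self, tmp_path, small_sim):
        res, cfg = small_sim
        path = res.bams["a"]
        ds1, _ = count_alleles([path], res.variants, CountFilter.permissive())
        # shuffle records, re-sort, rewrite
        with pysam.AlignmentFile(str(path)) as bam:
            header = bam.header
            records = list(bam.fetch(until_eof=True))
        rng = np.random.default_rng(0)
        rng.shuffle(records)
        shuffled = tmp_path / "shuffled.bam"
        write_bam(records, header, shuffled)
        ds2, _ = count_alleles([shuffled], res.variants, CountFilter.permissive())
        np.testing.assert_array_equal(ds1.counts, ds2.counts)

    def test_depth_bounded_by_fragments(self, small_sim):
        res, cfg = small_sim
        ds, _ = count_alleles(res.bams, res.variants, CountFilter.permissive())
        assert (ds.counts[..., STRAND_INDEX["both"]].sum(axis=2) <= cfg.depth).all()
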