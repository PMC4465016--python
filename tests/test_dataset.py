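"""Container semantics: construction, subsetting, fractions, genotypes, MAF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asekit.dataset import (
    ASEDataset,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    NT_INDEX,
    SNPVariant,
    STRAND_INDEX,
    build_dataset,
    normalize_genotype,
    parse_region,
)
from asekit.errors import DatasetStateError, DimensionError, ValidationError
from asekit.io import read_dataset_tsv, write_dataset_tsv
from asekit.simulate import simulate_count_dataset


def _variants(positions, chrom="chr1", with_alleles=True):
    return [
        SNPVariant(
            chrom=chrom,
            pos=p,
            id=f"v{k}",
            ref_allele="A" if with_alleles else None,
            alt_allele="G" if with_alleles else None,
        )
        for k, p in enumerate(positions)
    ]


def _single_cell(a=0, c=0, g=0, t=0, strand="both"):
    counts = np.zeros((1, 1, 4, 3), dtype=np.int64)
    counts[0, 0, :, STRAND_INDEX[strand]] = [a, c, g, t]
    return counts


class TestConstruction:
    def test_basic_unstranded(self):
        ds = build_dataset(_single_cell(a=3, g=1), _variants([10]), ["s1"])
        assert ds.counts[0, 0].sum() == 4

    def test_stranded_both_slice_recomputed(self):
        counts = np.zeros((1, 1, 4, 3), dtype=np.int64)
        counts[0, 0, NT_INDEX["A"], STRAND_INDEX["plus"]] = 2
        counts[0, 0, NT_INDEX["A"], STRAND_INDEX["minus"]] = 1
        ds = build_dataset(counts, _variants([10]), ["s1"], "fr-firststrand")
        assert list(ds.counts[0, 0, :, STRAND_INDEX["both"]]) == [3, 0, 0, 0]

    def test_negative_counts_rejected(self):
        counts = _single_cell(a=3)
        counts[0, 0, 1, 2] = -1
        with pytest.raises(ValidationError):
            build_dataset(counts, _variants([10]), ["s1"])

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            build_dataset(_single_cell(a=1), _variants([10, 20]), ["s1"])

    def test_unknown_strandedness(self):
        with pytest.raises(ValidationError):
            build_dataset(_single_cell(a=1), _variants([10]), ["s1"], "reverse")

    def test_variant_invariants(self):
        with pytest.raises(ValidationError):
            SNPVariant("chr1", 0, "bad")
        with pytest.raises(ValidationError):
            SNPVariant("chr1", 5, "same", ref_allele="A", alt_allele="A")


class TestSubset:
    @pytest.fixture()
    def ds(self):
        counts = np.zeros((3, 3, 4, 3), dtype=np.int64)
        counts[..., STRAND_INDEX["both"]] = np.arange(36).reshape(3, 3, 4)
        return build_dataset(counts, _variants([10, 20, 30]), ["s1", "s2", "s3"])

    def test_closed_interval_membership(self, ds):
        sub = ds.subset(region="chr1:15-30")
        assert [v.pos for v in sub.variants] == [20, 30]

    def test_absent_chromosome_gives_empty(self, ds):
        sub = ds.subset(region="chrX:1-100")
        assert sub.n_variants == 0 and sub.n_samples == 3

    def test_sample_projection(self, ds):
        sub = ds.subset(samples=["s2"])
        assert sub.counts.shape[0] == 1
        np.testing.assert_array_equal(sub.counts[0], ds.counts[1])

    def test_unknown_sample(self, ds):
        with pytest.raises(KeyError):
            ds.subset(samples=["nope"])

    def test_idempotence_and_identity(self, ds):
        sub1 = ds.subset(region="chr1:15-30")
        sub2 = sub1.subset(region="chr1:15-30")
        np.testing.assert_array_equal(sub1.counts, sub2.counts)
        full = ds.subset(region="chr1:1-1000", samples=list(ds.samples))
        np.testing.assert_array_equal(full.counts, ds.counts)
        assert full.samples == ds.samples

    def test_parse_region_errors(self):
        with pytest.raises(ValidationError):
            parse_region("chr1:20-10")


class TestFractions:
    @pytest.mark.parametrize(
        "ref,alt,min_depth,expect",
        [(3, 1, 1, 0.75), (0, 0, 1, np.nan), (5, 5, 1, 0.5), (2, 1, 4, np.nan)],
    )
    def test_fraction_values(self, ref, alt, min_depth, expect):
        ds = build_dataset(_single_cell(a=ref, g=alt), _variants([10]), ["s1"])
        got = ds.allele_fractions(min_depth=min_depth).values[0, 0]
        if np.isnan(expect):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expect)

    def test_unresolved_ref_alt_raises(self):
        ds = build_dataset(_single_cell(a=3, g=1), _variants([10], with_alleles=False), ["s1"])
        with pytest.raises(DatasetStateError, match="top_alleles"):
            ds.allele_fractions()
        assert ds.assign_top_alleles().allele_fractions().values[0, 0] == 0.75

    def test_other_nucleotides_ignored(self):
        ds = build_dataset(_single_cell(a=3, c=7, g=1, t=2), _variants([10]), ["s1"])
        assert ds.allele_fractions().values[0, 0] == 0.75
        assert ds.ref_alt_counts()[2][0, 0] == 9

    def test_complement_invariant(self):
        ds = simulate_count_dataset(4, 20, 30, 0.35, seed=5)
        f_ref = ds.allele_fractions(min_depth=1).values
        flipped = ASEDataset(
            ds.counts,
            [
                SNPVariant(v.chrom, v.pos, v.id, v.alt_allele, v.ref_allele)
                for v in ds.variants
            ],
            ds.samples,
            ds.strandedness,
        )
        f_alt = flipped.allele_fractions(min_depth=1).values
        mask = np.isfinite(f_ref)
        np.testing.assert_allclose(f_ref[mask] + f_alt[mask], 1.0)


class TestTopAlleles:
    def _ds(self, a, c, g, t):
        return build_dataset(_single_cell(a, c, g, t), _variants([10], with_alleles=False), ["s1"])

    def test_top_two_by_count(self):
        top = self._ds(90, 3, 85, 0).top_alleles()[0]
        assert (top.ref, top.alt) == ("A", "G") and not top.from_metadata

    def test_alphabetical_tie_break(self):
        top = self._ds(10, 10, 0, 0).top_alleles()[0]
        assert (top.ref, top.alt) == ("A", "C")

    def test_metadata_priority(self):
        v = [SNPVariant("chr1", 10, "v0", ref_allele="G", alt_allele="A")]
        ds = build_dataset(_single_cell(a=99, t=50), v, ["s1"])
        top = ds.top_alleles()[0]
        assert (top.ref, top.alt) == ("G", "A") and top.from_metadata

    def test_zero_counts_low_confidence(self):
        top = self._ds(0, 0, 0, 0).top_alleles()[0]
        assert (top.ref, top.alt) == ("A", "C") and top.low_confidence


class TestGenotypes:
    @pytest.mark.parametrize(
        "ref,alt,expect",
        [(12, 8, GT_HET), (20, 0, GT_HOM_REF), (0, 20, GT_HOM_ALT), (2, 1, None)],
    )
    def test_inference_rules(self, ref, alt, expect):
        ds = build_dataset(_single_cell(a=ref, g=alt), _variants([10]), ["s1"])
        assert ds.infer_genotypes(min_depth=10, het_min_minor=0.10)[0, 0] == expect

    def test_provided_genotypes_override(self):
        ds = build_dataset(_single_cell(a=20), _variants([10]), ["s1"])
        ds.genotypes = np.array([[GT_HET]], dtype=object)
        assert ds.effective_genotypes()[0, 0] == GT_HET

    def test_het_called_reliably_at_depth_30(self):
        # balanced het cells at depth 30: the minor fraction drops below 0.1
        # with probability ~9e-7, so 1000 cells should all be called het
        ds = simulate_count_dataset(10, 100, 30, 0.5, seed=42)
        gts = ds.infer_genotypes(min_depth=10, het_min_minor=0.10)
        assert (gts == GT_HET).all()

    @pytest.mark.parametrize(
        "token,expect",
        [("0/1", "0/1"), ("1|0", "0/1"), ("1/1", "1/1"), ("./.", None), (".", None)],
    )
    def test_normalize_genotype(self, token, expect):
        assert normalize_genotype(token) == expect


class TestMAF:
    def _ds_with_gts(self, gts):
        n = len(gts)
        counts = np.zeros((n, 1, 4, 3), dtype=np.int64)
        ds = build_dataset(counts, _variants([10]), [f"s{i}" for i in range(n)])
        ds.genotypes = np.array([[g] for g in gts], dtype=object)
        return ds

    def test_allele_counting_arithmetic(self):
        # 6 hom-ref + 2 het over 8 diploid samples: 14 ref alleles of 16,
        # f = 0.875, MAF = 0.125 — survives the 0.1 filter
        ds = self._ds_with_gts([GT_HOM_REF] * 6 + [GT_HET] * 2)
        assert ds.maf()[0] == pytest.approx(0.125)
        assert ds.maf_filter(0.1).n_variants == 1

    def test_monomorphic_removed(self):
        ds = self._ds_with_gts([GT_HOM_REF] * 5)
        assert ds.maf()[0] == 0.0
        assert ds.maf_filter(0.1).n_variants == 0

    def test_all_het_maximum(self):
        ds = self._ds_with_gts([GT_HET] * 4)
        assert ds.maf()[0] == pytest.approx(0.5)

    def test_no_calls_excluded(self):
        ds = self._ds_with_gts([None, None, GT_HET, GT_HOM_ALT])
        assert ds.maf()[0] == pytest.approx(0.25)  # f = 1/4
        assert np.isnan(self._ds_with_gts([None, None]).maf()[0])

    @given(st.lists(st.sampled_from([GT_HOM_REF, GT_HET, GT_HOM_ALT, None]), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_maf_bounds(self, gts):
        maf = self._ds_with_gts(gts).maf()[0]
        assert np.isnan(maf) or 0.0 <= maf <= 0.5


class TestSerialization:
    @pytest.mark.parametrize("strandedness", ["unstranded", "fr-firststrand"])
    def test_tsv_round_trip(self, tmp_path, strandedness):
        rng = np.random.default_rng(9)
        counts = np.zeros((2, 3, 4, 3), dtype=np.int64)
        if strandedness == "unstranded":
            counts[..., STRAND_INDEX["both"]] = rng.integers(0, 40, (2, 3, 4))
        else:
            counts[..., STRAND_INDEX["plus"]] = rng.integers(0, 40, (2, 3, 4))
            counts[..., STRAND_INDEX["minus"]] = rng.integers(0, 40, (2, 3, 4))
        gts = np.array([["0/1", "0/0", None], ["1/1", "0/1", "0/1"]], dtype=object)
        ds = build_dataset(counts, _variants([10, 20, 30]), ["s1", "s2"], strandedness, genotypes=gts)
        path = tmp_path / "ds.tsv"
        write_dataset_tsv(ds, path)
        back = read_dataset_tsv(path)
        np.testing.assert_array_equal(back.counts, ds.counts)
        assert back.samples == ds.samples
        assert back.variants == ds.variants
        assert back.strandedness == strandedness
        assert (back.genotypes == ds.genotypes).all()
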