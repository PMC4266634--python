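"""Region classification, inheritance extraction, and the MAF /
deleteriousness filters, checked against hand enumeration and a naive
per-base oracle."""

import itertools

import pytest

from varprior.genemodel import GeneModel, Transcript
from varprior.pedigree import Pedigree, Sample
from varprior.variants import (
    AnnotatedVariant,
    ConfigurationError,
    Genotype,
    MISSING_GT,
    annotate_regions,
    classify_region,
    deleteriousness_filter,
    inheritance_filter,
    maf_filter,
    read_vcf,
    summarize_counts,
)

HOM_REF, HET, HOM_ALT = Genotype(0, 0), Genotype(0, 1), Genotype(1, 1)


def make_variant(pos=1, genotypes=None, maf=None, deleteriousness=None,
                 region_class=None, gene=None, alt_index=1):
    return AnnotatedVariant(
        chrom="chr1", pos=pos, ref="A", alt="G", alt_index=alt_index,
        genotypes=genotypes or {}, maf=maf, deleteriousness=deleteriousness,
        region_class=region_class, gene=gene,
    )


def trio():
    return Pedigree([
        Sample("F", "1", None, None, 1, False),
        Sample("M", "1", None, None, 2, False),
        Sample("C", "1", "F", "M", 1, True),
    ])


class TestReadVcf:
    def test_reads_generator_output_roundtrip(self, make_dataset):
        """Positions, MAF and deleteriousness survive the VCF round trip."""
        vcf, truth = make_dataset(rng_seed=13)
        variants = read_vcf(vcf)
        assert len(variants) == len(truth)
        for v, row in zip(variants, truth.itertuples(index=False)):
            assert (v.chrom, v.pos, v.ref, v.alt) == (
                row.chrom, row.pos, row.ref, row.alt
            )
            assert v.maf == pytest.approx(row.maf, abs=1e-6)
            assert v.deleteriousness == (
                None if row.del_class is None else row.del_class
            )

    def test_multiallelic_records_are_split(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t10\t.\tC\tA,T\t.\tPASS\t.\tGT\t1/2\t0/1\n"
            "chr1\t20\t.\tG\tA\t.\tPASS\t.\tGT\t0/0\t./.\n"
        )
        variants = read_vcf(path)
        assert len(variants) == 3
        first, second, third = variants
        assert (first.alt, first.alt_index) == ("A", 1)
        assert (second.alt, second.alt_index) == ("T", 2)
        assert first.genotypes["S1"].is_het_for(1)
        assert second.genotypes["S1"].is_het_for(2)
        assert third.genotypes["S2"] is MISSING_GT or third.genotypes["S2"].missing
        assert first.maf is None and first.deleteriousness is None


def oracle_classify(pos0, transcripts):
    """Naive per-base oracle: materialize every region as a position set."""
    severity = ["exonic", "utr5", "utr3", "intronic", "intergenic"]
    found = ["intergenic"]
    for t in transcripts:
        exon = set()
        for s, e in t.exons:
            exon |= set(range(s, e))
        span = set(range(t.exons[0][0], t.exons[-1][1]))
        cds = set(range(t.cds_start, t.cds_end))
        left_utr = {p for p in exon if p < t.cds_start}
        right_utr = {p for p in exon if p >= t.cds_end}
        utr5 = left_utr if t.strand == "+" else right_utr
        utr3 = right_utr if t.strand == "+" else left_utr
        if pos0 in exon & cds:
            found.append("exonic")
        elif pos0 in utr5:
            found.append("utr5")
        elif pos0 in utr3:
            found.append("utr3")
        elif pos0 in span:
            found.append("intronic")
    return min(found, key=severity.index)


class TestClassifyRegion:
    def test_precedence_exon_over_intron(self, toy_model):
        # 0-based 230 is intron of GA but inside GB's CDS
        v = classify_region(make_variant(pos=231), toy_model)
        assert v.region_class == "exonic"
        assert v.gene == "GB"

    def test_minus_strand_utr_side(self, toy_model):
        # isolate GB(-): bases left of cds_start are 3'UTR, right are 5'UTR
        model = GeneModel([toy_model.transcripts[1]])
        v = classify_region(make_variant(pos=200), model)  # pos0=199 < 220
        assert v.region_class == "utr3"
        v = classify_region(make_variant(pos=256), model)  # pos0=255 >= 250
        assert v.region_class == "utr5"

    def test_intergenic_without_overlap(self, toy_model):
        v = classify_region(make_variant(pos=4000), toy_model)
        assert v.region_class == "intergenic"
        assert v.gene is None

    def test_agrees_with_per_base_oracle(self, toy_model):
        """Exhaustive sweep over a 6-kb window against the naive oracle."""
        for pos0 in range(0, 6000):
            v = classify_region(make_variant(pos=pos0 + 1), toy_model)
            assert v.region_class == oracle_classify(
                pos0, toy_model.transcripts
            ), f"mismatch at 0-based {pos0}"


class TestInheritanceFilter:
    def test_recessive_pattern_retained(self, study_pedigree):
        gts = {s: (HOM_ALT if "C" in s else HET)
               for s in study_pedigree.sample_ids}
        kept = inheritance_filter([make_variant(genotypes=gts)], study_pedigree)
        assert len(kept) == 1

    @pytest.mark.parametrize("bad_gt", [HET, HOM_REF, MISSING_GT])
    def test_one_nonconforming_proband_excludes(self, study_pedigree, bad_gt):
        gts = {s: (HOM_ALT if "C" in s else HET)
               for s in study_pedigree.sample_ids}
        gts["1C1"] = bad_gt
        assert inheritance_filter(
            [make_variant(genotypes=gts)], study_pedigree
        ) == []

    @pytest.mark.parametrize("bad_gt", [HOM_ALT, HOM_REF, MISSING_GT])
    def test_one_nonconforming_parent_excludes(self, study_pedigree, bad_gt):
        gts = {s: (HOM_ALT if "C" in s else HET)
               for s in study_pedigree.sample_ids}
        gts["2M"] = bad_gt
        assert inheritance_filter(
            [make_variant(genotypes=gts)], study_pedigree
        ) == []

    def test_hom_ref_probands_never_qualify(self, study_pedigree):
        gts = {s: (HOM_REF if "C" in s else HET)
               for s in study_pedigree.sample_ids}
        assert inheritance_filter(
            [make_variant(genotypes=gts)], study_pedigree
        ) == []

    def test_missing_sample_column_raises(self, study_pedigree):
        gts = {s: HOM_ALT for s in study_pedigree.sample_ids if s != "2F"}
        with pytest.raises(ConfigurationError):
            inheritance_filter([make_variant(genotypes=gts)], study_pedigree)

    def test_recovers_planted_set(self, make_dataset, study_pedigree,
                                  gene_model):
        vcf, truth = make_dataset(rng_seed=17, n_variants_total=100,
                                  n_qualifying=12, n_rare=30)
        variants = annotate_regions(read_vcf(vcf), gene_model)
        kept = inheritance_filter(variants, study_pedigree)
        expected = set(truth.loc[truth["qualifying"], "pos"])
        assert {v.pos for v in kept} == expected


class TestScalarFilters:
    def test_maf_zero_keeps_only_zero(self):
        vs = [make_variant(pos=i, maf=m) for i, m in
              enumerate([0.0, 0.01, 0.0], start=1)]
        assert len(maf_filter(vs, 0.0)) == 2

    def test_maf_one_is_identity_on_known(self):
        vs = [make_variant(pos=i, maf=m) for i, m in
              enumerate([0.0, 0.3, 1.0], start=1)]
        assert maf_filter(vs, 1.0) == vs

    def test_unknown_maf_policy(self):
        vs = [make_variant(pos=1, maf=None), make_variant(pos=2, maf=0.0)]
        assert len(maf_filter(vs, 0.0)) == 1
        assert len(maf_filter(vs, 0.0, keep_unknown=True)) == 2

    def test_deleteriousness_hand_enumeration(self):
        vs = [
            make_variant(pos=1, region_class="exonic",
                         deleteriousness="benign"),
            make_variant(pos=2, region_class="exonic",
                         deleteriousness="possibly_damaging"),
            make_variant(pos=3, region_class="exonic",
                         deleteriousness="probably_damaging"),
            make_variant(pos=4, region_class="exonic", deleteriousness=None),
            make_variant(pos=5, region_class="intronic",
                         deleteriousness="benign"),
            make_variant(pos=6, region_class="intergenic"),
        ]
        kept = deleteriousness_filter(vs)
        assert [v.pos for v in kept] == [2, 3, 5, 6]

    def test_filters_idempotent_and_commute(self):
        vs = [
            make_variant(pos=i, maf=m, region_class=rc, deleteriousness=dc)
            for i, (m, rc, dc) in enumerate(
                itertools.product(
                    [0.0, 0.2, None],
                    ["exonic", "intronic", "utr5"],
                    ["benign", "probably_damaging", None],
                ),
                start=1,
            )
        ]
        f1 = lambda x: maf_filter(x, 0.1)
        f2 = deleteriousness_filter
        once = f1(f2(vs))
        assert f1(f1(vs)) == f1(vs)
        assert f2(f2(vs)) == f2(vs)
        assert once == f2(f1(vs))
        assert f1(f2(once)) == once


class TestSummarize:
    def test_empty_input_all_zeros(self):
        counts = summarize_counts([])
        assert counts.sum() == 0
        assert len(counts) == 5

    def test_counts_sum_to_total_and_match_truth(self, make_dataset,
                                                 gene_model):
        vcf, truth = make_dataset(rng_seed=23)
        variants = annotate_regions(read_vcf(vcf), gene_model)
        counts = summarize_counts(variants)
        assert counts.sum() == len(truth)
        tallies = truth["region_class"].value_counts()
        for cls in counts.index:
            assert counts[cls] == tallies.get(cls, 0)

    def test_unclassified_variant_raises(self):
        with pytest.raises(ValueError):
            summarize_counts([make_variant()])
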