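"""VCF/BED/membership parsing and the pre-model basic filters."""

import textwrap

import pytest

from plasmasieve import (
    MembershipSet,
    Region,
    VariantCall,
    VariantKey,
    basic_filter,
    hotspot_panel_filter,
    read_membership,
    read_regions,
    read_variant_vcf,
)

MINI_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=1,length=10000>
    ##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """)


def write_vcf(tmp_path, body, name="mini.vcf"):
    p = tmp_path / name
    p.write_text(MINI_HEADER + body)
    return p


def make_call(chrom="1", pos=150, ref="A", alt="C", genotype="0/1",
              qual=50.0, ref_umi=95, alt_umi=5, **kw):
    return VariantCall(sample_id="S1", chrom=chrom, pos=pos, ref=ref, alt=alt,
                       qual=qual, genotype=genotype, ref_umi=ref_umi,
                       alt_umi=alt_umi, **kw)


class TestReadVariantVcf:
    def test_ad_maps_to_unique_molecule_depths_and_vaf(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tC\t60\t.\tDP=100\tGT:AD\t0/1:95,5\n")
        (call,) = read_variant_vcf(p, "S1")
        assert (call.ref_umi, call.alt_umi) == (95, 5)
        assert call.vaf == pytest.approx(0.05)
        assert call.genotype == "0/1"
        assert call.call_annotations["DP"] == 100.0

    def test_empty_body_yields_empty_list(self, tmp_path):
        assert read_variant_vcf(write_vcf(tmp_path, ""), "S1") == []

    def test_multiallelic_record_splits_into_flagged_calls(self, tmp_path):
        p = write_vcf(tmp_path, "1\t200\t.\tA\tC,G\t60\t.\t.\tGT:AD\t1/2:10,6,4\n")
        calls = read_variant_vcf(p, "S1")
        assert [c.alt for c in calls] == ["C", "G"]
        assert all(c.genotype == "1/2" for c in calls)
        assert [c.alt_umi for c in calls] == [6, 4]

    def test_missing_file_raises_parse_error(self, tmp_path):
        with pytest.raises(ValueError):
            read_variant_vcf(tmp_path / "absent.vcf", "S1")

    def test_roundtrip_of_simulated_cohort(self, cohort_dir, default_cohort):
        d, paths = cohort_dir
        patient = "P001"
        calls = read_variant_vcf(paths[f"vcf:{patient}"], patient)
        generated = default_cohort.calls[patient]
        assert len(calls) == len(generated)
        for got, want in zip(calls, generated):
            assert got.key == want.key
            assert (got.ref_umi, got.alt_umi) == (want.ref_umi, want.alt_umi)
            assert got.dp4 == want.dp4
            assert got.call_annotations["SGB"] == pytest.approx(
                want.call_annotations["SGB"], rel=1e-4)


class TestReadRegions:
    def test_bed3_verbatim_and_comments_skipped(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("# comment\ntrack name=x\nchr3\t100\t200\nchr3\t150\t250\n")
        regions = read_regions(p)
        assert regions == [Region("chr3", 100, 200), Region("chr3", 150, 250)]

    def test_inverted_interval_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="line 1"):
            read_regions(p)


class TestReadMembership:
    def test_deduplicates_and_looks_up(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tpos\tref\talt\n1\t100\tA\tC\n1\t100\tA\tC\n2\t5\tG\tT\n")
        mset = read_membership(p, "cosmic")
        assert len(mset) == 2
        assert VariantKey("chr1", 100, "A", "C") in mset  # prefix-normalized
        assert VariantKey("1", 101, "A", "C") not in mset

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tpos\tref\n1\t100\tA\n")
        with pytest.raises(ValueError, match="alt"):
            read_membership(p, "x")


class TestBasicFilter:
    REGIONS = [Region("1", 100, 200)]
    COSMIC = MembershipSet("cosmic", frozenset({VariantKey("1", 150, "A", "C"),
                                                VariantKey("Y", 150, "A", "C")}))

    def run(self, calls):
        return basic_filter(calls, self.REGIONS, self.COSMIC)

    @pytest.mark.parametrize("call,kept", [
        (make_call(), True),                                 # passing SNV
        (make_call(chrom="chr1"), True),                     # prefix normalized
        (make_call(chrom="Y"), False),                       # off-whitelist chromosome
        (make_call(genotype="1/1"), False),                  # homozygous
        (make_call(genotype="1/2"), False),                  # multi-allelic
        (make_call(genotype="0/0"), True),                   # 0/0 reaches the model
        (make_call(pos=250), False),                         # outside regions
        (make_call(alt="G"), False),                         # not in COSMIC
        (make_call(ref="AT", alt="A", pos=150), False),      # indel
    ])
    def test_keep_rules(self, call, kept):
        assert (self.run([call]) == [call]) is kept

    def test_idempotent_and_order_independent(self, default_cohort):
        calls = [c for v in default_cohort.calls.values() for c in v]
        once = basic_filter(calls, default_cohort.regions, default_cohort.cosmic)
        twice = basic_filter(once, default_cohort.regions, default_cohort.cosmic)
        assert twice == once
        rev = basic_filter(calls[::-1], default_cohort.regions, default_cohort.cosmic)
        assert {id(c) for c in rev} == {id(c) for c in once}
        assert all(c.key in default_cohort.cosmic for c in once)

    def test_removes_exactly_the_noncosmic_controls(self, default_cohort):
        for patient, calls in default_cohort.calls.items():
            kept = basic_filter(calls, default_cohort.regions, default_cohort.cosmic)
            removed_classes = {
                default_cohort.truth[(patient, c.key)]
                for c in calls if c not in kept
            }
            assert removed_classes <= {"control"}
            assert len(calls) - len(kept) == default_cohort.spec.n_control_calls


class TestHotspotPanelFilter:
    @pytest.mark.parametrize("kw,kept", [
        (dict(qual=19.9, alt_umi=10), False),     # below PHRED 20
        (dict(qual=20.0, alt_umi=4), True),       # at the boundary
        (dict(qual=30.0, alt_umi=3), False),      # too few unique molecules
        (dict(qual=30.0, alt_umi=4, allele_call="absent"), False),
        (dict(qual=30.0, alt_umi=4, allele_call="no call"), False),
        (dict(qual=30.0, alt_umi=4, allele_call="heterozygous"), True),
    ])
    def test_keep_rules(self, kw, kept):
        call = make_call(**kw)
        assert (hotspot_panel_filter([call]) == [call]) is kept

    def test_blacklist_removes_listed_key(self):
        call = make_call(qual=30, alt_umi=10)
        assert hotspot_panel_filter([call], blacklist={call.key}) == []
        assert hotspot_panel_filter([call], blacklist=set()) == [call]
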