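import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecoal.patterns import (
    PatternHistogram,
    SampleConfig,
    merge_histograms,
    read_histogram,
    read_mask_bed,
    restrict_to_shared,
    vcf_to_histogram,
    write_histogram,
)

CFG2 = SampleConfig(("A", "B"), (4, 4))


def make_hist(counts, mono=100, over=5, config=CFG2, max_m=4):
    total = mono + over + sum(counts.values())
    h = PatternHistogram(
        config=config, max_m=max_m, counts=dict(counts),
        monomorphic=mono, overflow=over, total_sites=total,
    )
    h.check()
    return h


@st.composite
def histograms(draw):
    n_pops = draw(st.integers(2, 5))
    sizes = tuple(draw(st.integers(2, 8)) for _ in range(n_pops))
    config = SampleConfig(tuple(f"P{i}" for i in range(n_pops)), sizes)
    n_pat = draw(st.integers(0, 6))
    counts = {}
    for _ in range(n_pat):
        pat = tuple(
            draw(st.integers(0, min(2, s))) for s in sizes
        )
        if 1 <= sum(pat) <= 4:
            counts[pat] = draw(st.integers(1, 1000))
    mono = draw(st.integers(0, 10**6))
    over = draw(st.integers(0, 1000))
    return make_hist(counts, mono, over, config)


class TestFormat:
    @given(histograms())
    @settings(max_examples=40, deadline=None)
    def test_write_read_round_trip(self, h):
        h2 = read_histogram(write_histogram(h))
        assert h2.counts == h.counts
        assert h2.config == h.config
        assert (h2.monomorphic, h2.overflow, h2.total_sites) == (
            h.monomorphic, h.overflow, h.total_sites,
        )

    def test_empty_all_monomorphic_round_trips(self):
        h = make_hist({}, mono=1000, over=0)
        assert read_histogram(write_histogram(h)).monomorphic == 1000

    def test_arity_mismatch(self):
        text = "N=4,4\nMAX_M=4\nTOTAL_SITES=100\nMONOMORPHIC 99\n1,0,0 1\n"
        with pytest.raises(ValueError, match="arity"):
            read_histogram(text)

    def test_malformed_line(self):
        text = "N=4,4\nMAX_M=4\nTOTAL_SITES=100\nbogus line here\n"
        with pytest.raises(ValueError, match="malformed|line"):
            read_histogram(text)


class TestRestrict:
    def test_private_dropped_shared_kept(self):
        h = make_hist({(1, 0): 7, (1, 2): 3, (0, 2): 9})
        r = restrict_to_shared(h, "A")
        assert r.counts == {(1, 2): 3}
        assert r.monomorphic == 0 and r.overflow == 0
        assert r.total_sites == 3
        assert r.meta["original_total_sites"] == h.total_sites

    def test_no_shared_patterns_is_empty_not_error(self):
        h = make_hist({(1, 0): 7})
        r = restrict_to_shared(h, "A")
        assert r.counts == {} and r.total_sites == 0

    def test_unknown_population(self):
        with pytest.raises(KeyError):
            restrict_to_shared(make_hist({}), "Z")


class TestMerge:
    def test_identity_element(self):
        h = make_hist({(1, 1): 4})
        empty = make_hist({}, mono=0, over=0)
        merged = merge_histograms([h, empty])
        assert merged.counts == h.counts
        assert merged.total_sites == h.total_sites

    def test_associative(self):
        hs = [make_hist({(1, 0): i + 1, (2, 1): 2 * i + 1}) for i in range(3)]
        a = merge_histograms([merge_histograms(hs[:2]), hs[2]])
        b = merge_histograms([hs[0], merge_histograms(hs[1:])])
        assert a.counts == b.counts and a.total_sites == b.total_sites

    def test_config_mismatch(self):
        other = SampleConfig(("B", "A"), (4, 4))
        with pytest.raises(ValueError, match="mismatch"):
            merge_histograms([make_hist({}), make_hist({}, config=other)])


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta1\ta2\tb1\tb2
"""

POPS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}


def write_vcf(tmp_path, body):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_HEADER + body)
    return str(p)


class TestVcfIngestion:
    def test_single_carrier_site(self, tmp_path):
        vcf = write_vcf(
            tmp_path,
            "1\t10\t.\tA\tC\t.\t.\t.\tGT\t0|1\t0|0\t0|0\t0|0\n"
            "1\t20\t.\tG\tT\t.\t.\t.\tGT\t0|0\t0|0\t0|0\t0|0\n",
        )
        h = vcf_to_histogram(vcf, POPS, "1\t0\t1000\n")
        assert h.config.sizes == (4, 4)
        assert h.counts == {(1, 0): 1}
        assert h.total_sites == 1000
        assert h.monomorphic == 999

    def test_overflow_above_max_m(self, tmp_path):
        vcf = write_vcf(
            tmp_path, "1\t10\t.\tA\tC\t.\t.\t.\tGT\t1|1\t1|1\t1|0\t0|0\n"
        )
        h = vcf_to_histogram(vcf, POPS, "1\t0\t1000\n", max_m=4)
        assert h.overflow == 1 and not h.counts

    def test_masked_out_variant_ignored(self, tmp_path):
        vcf = write_vcf(
            tmp_path, "1\t500\t.\tA\tC\t.\t.\t.\tGT\t0|1\t0|0\t0|0\t0|0\n"
        )
        h = vcf_to_histogram(vcf, POPS, "1\t0\t100\n")
        assert not h.counts
        assert h.total_sites == 100
        assert h.meta["tallies"]["outside_mask"] == 1

    def test_missing_genotype_removed_from_denominator(self, tmp_path):
        vcf = write_vcf(
            tmp_path, "1\t10\t.\tA\tC\t.\t.\t.\tGT\t.|.\t0|1\t0|0\t0|0\n"
        )
        h = vcf_to_histogram(vcf, POPS, "1\t0\t1000\n")
        assert h.total_sites == 999 and not h.counts

    def test_indel_skipped_and_tallied(self, tmp_path):
        vcf = write_vcf(
            tmp_path, "1\t10\t.\tAT\tA\t.\t.\t.\tGT\t0|1\t0|0\t0|0\t0|0\n"
        )
        h = vcf_to_histogram(vcf, POPS, "1\t0\t1000\n")
        assert h.meta["tallies"]["non_snp_skipped"] == 1
        assert h.total_sites == 999

    def test_ancestral_tag_polarization_flips(self, tmp_path):
        vcf = write_vcf(
            tmp_path,
            "1\t10\t.\tA\tC\t.\t.\tAA=C\tGT\t0|1\t1|1\t1|1\t1|1\n"
            "1\t20\t.\tG\tT\t.\t.\t.\tGT\t0|1\t0|0\t0|0\t0|0\n",
        )
        h = vcf_to_histogram(vcf, POPS, "1\t0\t1000\n", polarize="ancestral-tag")
        # site 10: ancestral is ALT, so REF copies are derived (one in pop A)
        assert h.counts == {(1, 0): 1}
        # site 20 lacks the tag: skipped and removed
        assert h.meta["tallies"]["no_ancestral_tag_skipped"] == 1
        assert h.total_sites == 999

    def test_sample_missing_from_vcf(self, tmp_path):
        vcf = write_vcf(tmp_path, "")
        with pytest.raises(ValueError, match="missing from VCF"):
            vcf_to_histogram(vcf, {**POPS, "ghost": "A"}, "1\t0\t10\n")

    def test_unsorted_mask_rejected(self):
        with pytest.raises(ValueError, match="unsorted|overlap"):
            read_mask_bed("1\t100\t200\n1\t50\t150\n")

    def test_class_conservation_everywhere(self, tmp_path):
        vcf = write_vcf(
            tmp_path,
            "1\t10\t.\tA\tC\t.\t.\t.\tGT\t0|1\t0|0\t0|0\t0|0\n"
            "1\t11\t.\tA\tC\t.\t.\t.\tGT\t1|1\t1|1\t1|0\t0|0\n",
        )
        h = vcf_to_histogram(vcf, POPS, "1\t0\t1000\n")
        h.check()
        restrict_to_shared(h, "A").check()
        merge_histograms([h, h]).check()
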