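"""SNP classification, QUAL filtering, window painting and composition."""

import textwrap

import pytest

from mosaicpaint.paint import (
    ClassifiedSite,
    OriginClass,
    SnpSite,
    classify_snp,
    composition_from_blocks,
    composition_from_counts,
    filter_sites,
    window_paint,
)
from mosaicpaint.simulate import (
    SimConfig,
    emit_vcf,
    realized_fractions,
    simulate_founders,
    simulate_offspring,
)
from mosaicpaint.paint import classify_sites


def site(off, pa, pb, qual=60.0):
    def gt(x):
        if x is None:
            return None
        return (x, x) if isinstance(x, str) and len(x) == 1 else x

    return SnpSite("chr1", 100, qual, gt(off), gt(pa), gt(pb))


class TestClassify:
    @pytest.mark.parametrize(
        "off,pa,pb,expected",
        [
            ("A", "A", "T", OriginClass.PARENT_A),
            ("T", "A", "T", OriginClass.PARENT_B),
            ("G", "A", "T", OriginClass.OTHER),
            ("A", "A", "A", OriginClass.UNINFORMATIVE),
            ("G", "A", "A", OriginClass.OTHER),  # parents equal, offspring not
        ],
    )
    def test_homozygous_rules(self, off, pa, pb, expected):
        assert classify_snp(site(off, pa, pb)) is expected

    def test_heterozygous_or_missing_uninformative(self):
        assert classify_snp(site(("A", "T"), "A", "T")) is OriginClass.UNINFORMATIVE
        assert classify_snp(site("A", None, "T")) is OriginClass.UNINFORMATIVE
        assert classify_snp(site("A", ("A", "G"), "T")) is OriginClass.UNINFORMATIVE


TOY_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##FILTER=<ID=PASS,Description="All filters passed">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\toffspring\tparentA\tparentB
    chr1\t100\t.\tA\tT\t60\tPASS\t.\tGT\t1/1\t1/1\t0/0
    chr1\t200\t.\tC\tG\t29\tPASS\t.\tGT\t1/1\t1/1\t0/0
    chr1\t300\t.\tG\tA\t30\tPASS\t.\tGT\t0/0\t1/1\t0/0
    chr1\t400\t.\tT\tTA\t60\tPASS\t.\tGT\t1/1\t0/0\t0/0
    chr1\t500\t.\tA\tC,G\t60\tPASS\t.\tGT\t1/1\t0/0\t2/2
    chr1\t600\t.\tC\tT\t60\tPASS\t.\tGT\t0/0\t0/0\t1/1
    """)


class TestFilterSites:
    def test_qual_threshold_inclusive_and_snp_only(self, tmp_path):
        """QUAL 29 is dropped, QUAL 30 kept; indel and multi-allelic excluded."""
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        kept = filter_sites(path, min_qual=30)
        assert [s.pos for s in kept] == [100, 300, 600]
        kept_all = filter_sites(path, min_qual=0)
        assert [s.pos for s in kept_all] == [100, 200, 300, 600]

    def test_unknown_sample_reports_available(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(TOY_VCF)
        with pytest.raises(ValueError, match="offspring.*parentA.*parentB"):
            filter_sites(path, offspring="child")


def cs(chrom, pos, origin):
    return ClassifiedSite(chrom, pos, origin)


A, B, O = OriginClass.PARENT_A, OriginClass.PARENT_B, OriginClass.OTHER


class TestWindowPaint:
    def test_boundary_positions(self):
        sites = [cs("chr1", 50_000, A), cs("chr1", 50_001, B)]
        blocks = window_paint(sites, {"chr1": 100_000}, 50_000)
        assert blocks[0].counts[A] == 1 and blocks[0].counts[B] == 0
        assert blocks[1].counts[B] == 1 and blocks[1].counts[A] == 0

    def test_window_count_is_ceiling(self):
        blocks = window_paint([], {"chr1": 250_001}, 50_000)
        assert len(blocks) == 6
        assert (blocks[-1].start, blocks[-1].end) == (250_001, 300_000)
        assert all(b.dominant is OriginClass.MISSING for b in blocks)

    def test_dominant_majority_tie_and_missing(self):
        sites = [cs("chr1", 1, A)] * 3 + [cs("chr1", 2, B)]
        blocks = window_paint(sites, {"chr1": 100_000}, 50_000)
        assert blocks[0].dominant is A
        assert blocks[1].dominant is OriginClass.MISSING
        tie = [cs("chr1", 1, A), cs("chr1", 2, B)]
        assert window_paint(tie, {"chr1": 50_000}, 50_000)[0].dominant is O

    def test_merged_windows_consistent_when_argmax_stable(self):
        """100 kb labels equal merged 50 kb pairs when the argmax survives."""
        sites = (
            [cs("chr1", 10_000 + i, A) for i in range(5)]
            + [cs("chr1", 60_000 + i, A) for i in range(4)]
            + [cs("chr1", 60_500 + i, B) for i in range(2)]
            + [cs("chr1", 110_000 + i, B) for i in range(6)]
            + [cs("chr1", 160_000 + i, B) for i in range(3)]
        )
        lengths = {"chr1": 200_000}
        fifty = window_paint(sites, lengths, 50_000)
        hundred = window_paint(sites, lengths, 100_000)
        for i, big in enumerate(hundred):
            pair = fifty[2 * i : 2 * i + 2]
            merged = {k: sum(b.counts[k] for b in pair) for k in (A, B, O)}
            argmax_label = max(merged, key=merged.get)
            if list(merged.values()).count(merged[argmax_label]) == 1:
                assert big.dominant is argmax_label


class TestComposition:
    def test_all_snp_scale_percentages(self):
        summ = composition_from_counts(515_698, 65_426, 9_540)
        assert summ.total == 590_664
        assert summ.percentages == {A: 87, B: 11, O: 2}

    def test_window_scale_percentages_50kb(self):
        summ = composition_from_counts(4_406, 1_791, 1_256)
        assert summ.total == 7_453
        assert summ.percentages == {A: 59, B: 24, O: 17}

    def test_window_scale_percentages_100kb(self):
        summ = composition_from_counts(2_328, 832, 564)
        assert summ.total == 3_724
        assert summ.percentages == {A: 63, B: 22, O: 15}

    def test_uniform_counts(self):
        assert composition_from_counts(1, 1, 1).percentages == {A: 33, B: 33, O: 33}

    def test_block_composition_counts_windows(self):
        sites = [cs("chr1", 1, A), cs("chr1", 60_000, B), cs("chr1", 60_001, B)]
        blocks = window_paint(sites, {"chr1": 150_000}, 50_000)
        summ = composition_from_blocks(blocks)
        assert summ.total == 2  # third window MISSING, excluded
        assert summ.counts == {A: 1, B: 1, O: 0}


@pytest.fixture(scope="module")
def painted(tmp_path_factory):
    cfg = SimConfig(n_chrom=10, chrom_len=500_000, snp_rate=0.005, seed=7)
    founders = simulate_founders(cfg)
    offspring, truth = simulate_offspring(founders, cfg)
    vcf = tmp_path_factory.mktemp("vcf") / "trio.vcf"
    vcf.write_text(emit_vcf(founders, offspring, cfg))
    classified = classify_sites(filter_sites(vcf))
    lengths = {c: cfg.chrom_len for c in cfg.chrom_names()}
    blocks = window_paint(classified, lengths, 50_000)
    return truth, blocks


class TestParameterRecovery:
    """Painting recovers the simulated mosaic composition (5 Mb, 1/200 bp)."""

    def test_composition_within_2pp_of_truth(self, painted):
        truth, blocks = painted
        fr = realized_fractions(truth)
        summ = composition_from_blocks(blocks)
        got = {k: 100.0 * v / summ.total for k, v in summ.counts.items()}
        assert abs(got[A] - 100 * fr["A"]) <= 2.0
        assert abs(got[B] - 100 * fr["B"]) <= 2.0
        assert abs(got[O] - 100 * fr["U"]) <= 2.0

    def test_windows_labelled_by_midpoint_origin(self, painted):
        truth, blocks = painted
        label_of = {A: "A", B: "B", O: "U"}

        def origin_at(chrom, pos):
            return next(s.origin for s in truth
                        if s.chrom == chrom and s.start <= pos <= s.end)

        informative = [b for b in blocks if b.dominant is not OriginClass.MISSING]
        correct = sum(
            label_of[b.dominant] == origin_at(b.chrom, (b.start + b.end) // 2)
            for b in informative
        )
        assert len(informative) >= 0.9 * len(blocks)
        assert correct / len(informative) >= 0.95

    def test_counts_partition_classified_sites(self, painted):
        _, blocks = painted
        per_class = {k: 0 for k in (A, B, O)}
        for b in blocks:
            for k in per_class:
                per_class[k] += b.counts[k]
        total_in_blocks = sum(per_class.values())
        assert total_in_blocks == sum(b.n_classified for b in blocks)
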