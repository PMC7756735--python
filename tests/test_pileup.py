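import pysam
import pytest

from smncopy.pileup import (
    MissingContigError,
    MissingIndexError,
    ReadFilters,
    ReferenceRequiredError,
    collect_sample_counts,
    count_discriminating_site,
    mean_gene_depth,
    open_alignment,
    screen_duplication_variant,
)
from smncopy.registry import GeneInterval
from smncopy.simulate import SyntheticSampleSpec, generate_sample

from conftest import make_header, make_read, write_bam

L = 100


def site_read(header, name, pos1, base, offset=30, **kw):
    """A read covering 1-based ``pos1`` carrying ``base`` there."""
    start0 = pos1 - 1 - offset
    seq = "A" * offset + base + "A" * (L - offset - 1)
    return make_read(header, name, "5", start0, seq, **kw)


@pytest.fixture(scope="module")
def header():
    return make_header()


class TestDiscriminatingSiteCounting:
    def test_pooled_counts_across_both_paralog_loci(self, header, registry, tmp_path):
        """Reads carrying the SMN1 base count toward D1 wherever they mapped."""
        b = registry.site("b")
        reads = []
        for i in range(10):  # SMN1 base, mapped at the SMN1 locus
            reads.append(site_read(header, f"m1_{i}", b.smn1_position, b.smn1_allele))
        for i in range(5):  # SMN1 base, mismapped to the SMN2 locus
            reads.append(site_read(header, f"m2_{i}", b.smn2_position, b.smn1_allele))
        for i in range(42):  # SMN2 base, split across loci
            pos = b.smn1_position if i % 2 else b.smn2_position
            reads.append(site_read(header, f"w_{i}", pos, b.smn2_allele))
        path = write_bam(tmp_path / "pooled.bam", header, reads)
        with open_alignment(path) as af:
            assert count_discriminating_site(af, b) == (10 + 5, 42)

    def test_empty_pileup(self, header, registry, tmp_path):
        path = write_bam(tmp_path / "empty.bam", header, [])
        with open_alignment(path) as af:
            assert count_discriminating_site(af, registry.site("a")) == (0, 0)

    def test_reads_with_neither_allele_count_nowhere(self, header, registry, tmp_path):
        a = registry.site("a")
        reads = [site_read(header, f"n{i}", a.smn1_position, "N") for i in range(4)]
        path = write_bam(tmp_path / "allN.bam", header, reads)
        with open_alignment(path) as af:
            assert count_discriminating_site(af, a) == (0, 0)

    def test_low_base_quality_excluded(self, header, registry, tmp_path):
        a = registry.site("a")
        reads = [
            site_read(header, "hq", a.smn1_position, a.smn1_allele, qual=20),
            site_read(header, "lq", a.smn1_position, a.smn1_allele, qual=5),
        ]
        path = write_bam(tmp_path / "qual.bam", header, reads)
        with open_alignment(path) as af:
            assert count_discriminating_site(af, a) == (1, 0)
            relaxed = ReadFilters(min_base_quality=0)
            assert count_discriminating_site(af, a, relaxed) == (2, 0)

    def test_overlapping_mates_count_once(self, header, registry, tmp_path):
        """Both mates of one fragment cover the site: one molecule, and the
        higher-quality mate decides the base."""
        a = registry.site("a")
        r1 = site_read(header, "frag", a.smn1_position, a.smn1_allele, qual=40, flag=0x43)
        r2 = site_read(
            header, "frag", a.smn1_position, a.smn2_allele, qual=20, offset=60, flag=0x83
        )
        path = write_bam(tmp_path / "mates.bam", header, [r1, r2])
        with open_alignment(path) as af:
            assert count_discriminating_site(af, a) == (1, 0)

    def test_flag_filters_keep_mapq0(self, header, registry, tmp_path):
        """Duplicates and secondaries are dropped; MAPQ-0 multi-mappers are not."""
        a = registry.site("a")
        reads = [
            site_read(header, "dup", a.smn1_position, a.smn1_allele, flag=0x400),
            site_read(header, "sec", a.smn1_position, a.smn1_allele, flag=0x100),
            site_read(header, "mq0", a.smn1_position, a.smn1_allele, mapq=0),
        ]
        path = write_bam(tmp_path / "flags.bam", header, reads)
        with open_alignment(path) as af:
            assert count_discriminating_site(af, a) == (1, 0)

    def test_deletion_at_site_counts_nowhere(self, header, registry, tmp_path):
        a = registry.site("a")
        start0 = a.smn1_position - 1 - 30
        read = make_read(
            header, "del", "5", start0, "A" * L, cigar=((0, 30), (2, 1), (0, 70))
        )
        path = write_bam(tmp_path / "delsite.bam", header, [read])
        with open_alignment(path) as af:
            assert count_discriminating_site(af, a) == (0, 0)


class TestMeanGeneDepth:
    interval = GeneInterval("FAKE", "5", 1000001, 1000200, "control")

    def test_uniform_coverage(self, header, tmp_path):
        reads = [
            make_read(header, f"u{i}", "5", 1000000, "A" * 200) for i in range(30)
        ]
        path = write_bam(tmp_path / "uniform.bam", header, reads)
        with open_alignment(path) as af:
            assert mean_gene_depth(af, self.interval) == pytest.approx(30.0)

    def test_mean_of_unequal_halves(self, header, tmp_path):
        reads = [make_read(header, "left", "5", 1000000, "A" * 100)]
        reads += [make_read(header, f"right{i}", "5", 1000100, "A" * 100) for i in range(2)]
        path = write_bam(tmp_path / "halves.bam", header, reads)
        with open_alignment(path) as af:
            assert mean_gene_depth(af, self.interval) == pytest.approx(1.5)

    def test_deleted_bases_do_not_contribute(self, header, tmp_path):
        read = make_read(
            header, "d", "5", 1000000, "A" * 200, cigar=((0, 100), (2, 20), (0, 100))
        )
        path = write_bam(tmp_path / "dele.bam", header, [read])
        with open_alignment(path) as af:
            assert mean_gene_depth(af, self.interval) == pytest.approx(180 / 200)

    def test_brute_force_oracle(self, header, fix_registry, tmp_path):
        """Mean depth equals an independent per-position pileup sum."""
        import numpy as np

        path, _ = generate_sample(
            SyntheticSampleSpec("oracle", 1, 2, seed=11), fix_registry, tmp_path
        )
        gene = fix_registry.control_genes[0]
        b0, e0 = gene.start - 1, gene.end - 1
        depth = np.zeros(len(gene))
        with pysam.AlignmentFile(path) as af:
            for col in af.pileup(gene.chromosome, b0, e0 + 1, truncate=True,
                                 min_base_quality=0, max_depth=100000):
                depth[col.reference_pos - b0] = col.nsegments
            expected = depth.mean()
            assert mean_gene_depth(af, gene) == pytest.approx(expected)


class TestDuplicationVariantScreening:
    def test_snv_support(self, header, registry, tmp_path):
        snv = next(v for v in registry.variants if v.variant_class == "SNV")
        reads = [site_read(header, f"alt{i}", snv.start, "G") for i in range(8)]
        reads += [site_read(header, f"ref{i}", snv.start, "T") for i in range(32)]
        path = write_bam(tmp_path / "snv.bam", header, reads)
        with open_alignment(path) as af:
            assert screen_duplication_variant(af, snv) == (8, 40)

    def test_absent_deletion(self, header, registry, tmp_path):
        dele = next(v for v in registry.variants if v.variant_class == "deletion")
        reads = [site_read(header, f"r{i}", dele.start, "A") for i in range(12)]
        path = write_bam(tmp_path / "nodel.bam", header, reads)
        with open_alignment(path) as af:
            assert screen_duplication_variant(af, dele) == (0, 12)

    def test_two_bp_deletion_required_exactly(self, header, registry, tmp_path):
        """Alignments deleting both AT bases support the event; a 1-bp
        deletion or a plain match does not."""
        dele = next(v for v in registry.variants if v.variant_class == "deletion")
        s0 = dele.start - 1 - 40
        reads = [
            make_read(header, f"full{i}", "5", s0, "A" * L,
                      cigar=((0, 40), (2, 2), (0, 60)))
            for i in range(6)
        ]
        reads.append(
            make_read(header, "partial", "5", s0, "A" * L,
                      cigar=((0, 40), (2, 1), (0, 60)))
        )
        reads.append(make_read(header, "match", "5", s0, "A" * L))
        path = write_bam(tmp_path / "del2.bam", header, reads)
        with open_alignment(path) as af:
            assert screen_duplication_variant(af, dele) == (6, 8)


class TestCollectSampleCounts:
    def test_header_only_alignment_gives_zeros(self, header, fix_registry, tmp_path):
        path = write_bam(tmp_path / "bare.bam", header, [])
        counts = collect_sample_counts(path, fix_registry)
        assert counts.d1 == {"a": 0, "b": 0, "c": 0}
        assert counts.smn1_mean_depth == 0.0
        assert all(v == 0.0 for v in counts.control_mean_depth.values())
        assert all(v == (0, 0) for v in counts.dup_variant_support.values())

    def test_round_trip_matches_generator_truth(self, fix_registry, tmp_path):
        spec = SyntheticSampleSpec("rt", 1, 2, seed=3)
        path, truth = generate_sample(spec, fix_registry, tmp_path)
        counts = collect_sample_counts(path, fix_registry)
        assert counts.d1 == truth.counts.d1
        assert counts.d2 == truth.counts.d2
        assert counts.dup_variant_support == truth.counts.dup_variant_support
        assert counts.smn1_mean_depth == pytest.approx(truth.counts.smn1_mean_depth)
        assert counts.smn2_mean_depth == pytest.approx(truth.counts.smn2_mean_depth)
        assert counts.control_mean_depth == pytest.approx(truth.counts.control_mean_depth)

    def test_merging_alignments_adds_counts(self, fix_registry, tmp_path):
        """Two runs of one sample merged: allele counts add, depths add."""
        p1, t1 = generate_sample(
            SyntheticSampleSpec("runA", 2, 2, seed=5), fix_registry, tmp_path
        )
        p2, t2 = generate_sample(
            SyntheticSampleSpec("runB", 2, 2, seed=6), fix_registry, tmp_path
        )
        merged = str(tmp_path / "merged.bam")
        pysam.merge("-f", merged, p1, p2)
        pysam.index(merged)
        counts = collect_sample_counts(merged, fix_registry)
        for lbl in "abc":
            assert counts.d1[lbl] == t1.counts.d1[lbl] + t2.counts.d1[lbl]
            assert counts.d2[lbl] == t1.counts.d2[lbl] + t2.counts.d2[lbl]
        assert counts.smn1_mean_depth == pytest.approx(
            t1.counts.smn1_mean_depth + t2.counts.smn1_mean_depth
        )

    def test_d1_d2_bounded_by_covering_reads(self, fix_registry, tmp_path):
        path, _ = generate_sample(
            SyntheticSampleSpec("bound", 2, 1, seed=8, base_error_rate=0.01),
            fix_registry,
            tmp_path,
        )
        counts = collect_sample_counts(path, fix_registry)
        with pysam.AlignmentFile(path) as af:
            for site in fix_registry.sites:
                covering = af.count(
                    site.chromosome, site.smn1_position - 1, site.smn1_position
                ) + af.count(
                    site.chromosome, site.smn2_position - 1, site.smn2_position
                )
                assert counts.d1[site.label] + counts.d2[site.label] <= covering

    def test_unindexed_bam_rejected(self, header, tmp_path):
        path = str(tmp_path / "noindex.bam")
        with pysam.AlignmentFile(path, "wb", header=header):
            pass
        with pytest.raises(MissingIndexError):
            open_alignment(path)

    def test_cram_requires_reference(self, tmp_path):
        with pytest.raises(ReferenceRequiredError):
            open_alignment(str(tmp_path / "sample.cram"))

    def test_missing_contig_is_explicit(self, fix_registry, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "99", "LN": 10_000_000}]}
        )
        path = write_bam(tmp_path / "badcontig.bam", header, [])
        with pytest.raises(MissingContigError, match="sample badcontig"):
            collect_sample_counts(path, fix_registry)
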