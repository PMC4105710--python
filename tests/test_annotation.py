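"""Gene-model parsing, extension building and hierarchical annotation."""

import itertools

import pytest

from pacall.annotation import (
    EXON,
    EXTENSION,
    FIVE_UTR,
    FEATURE_RANK,
    INTRON,
    THREE_UTR,
    UNASSIGNED,
    AnnotationIndex,
    GeneModel,
    annotate_cluster,
    annotate_clusters,
    build_extensions,
    parse_bed12,
    parse_gene_models,
)
from pacall.clustering import PACluster
from pacall.genomic_core import GenomicInterval

ALL_CLASSES = [THREE_UTR, EXON, INTRON, FIVE_UTR, EXTENSION]


def bed12_line(chrom, start, end, name, strand, thick_lo, thick_hi, blocks):
    sizes = ",".join(str(e - s) for s, e in blocks)
    offsets = ",".join(str(s - start) for s, _ in blocks)
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{thick_lo}\t{thick_hi}"
        f"\t0\t{len(blocks)}\t{sizes}\t{offsets}\n"
    )


def spans(intervals):
    return [(iv.start, iv.end) for iv in intervals]


class TestParseBed12:
    def test_single_exon_coding_span_partition(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(bed12_line("chr1", 0, 300, "G1", "+", 50, 250, [(0, 300)]))
        (m,) = parse_bed12(p)
        assert spans(m.five_utr) == [(0, 50)]
        assert spans(m.exons) == [(50, 250)]
        assert spans(m.three_utr) == [(250, 300)]
        assert m.introns == []

    def test_intron_from_exon_gap(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(bed12_line("chr1", 0, 300, "G1", "+", 50, 250, [(0, 100), (200, 300)]))
        (m,) = parse_bed12(p)
        assert spans(m.introns) == [(100, 200)]

    def test_minus_strand_three_utr_is_leftmost(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(bed12_line("chr1", 0, 300, "G1", "-", 50, 250, [(0, 300)]))
        (m,) = parse_bed12(p)
        assert spans(m.three_utr) == [(0, 50)]
        assert spans(m.five_utr) == [(250, 300)]

    def test_noncoding_transcript_flagged_all_exon(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(bed12_line("chr1", 0, 300, "NC1", "+", 0, 0, [(0, 300)]))
        (m,) = parse_bed12(p)
        assert not m.coding
        assert spans(m.exons) == [(0, 300)]
        assert m.five_utr == [] and m.three_utr == []

    def test_feature_classes_tile_the_transcript_span(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(
            bed12_line("chr1", 10, 600, "G1", "+", 120, 480, [(10, 200), (300, 450), (500, 600)])
        )
        (m,) = parse_bed12(p)
        bitmap = {}
        for cls, iv in m.features(include_extension=False):
            for b in range(iv.start, iv.end):
                assert b not in bitmap, "feature classes overlap"
                bitmap[b] = cls
        assert set(bitmap) == set(range(10, 600))


class TestGff3RoundTrip:
    def test_synthetic_models_reparse_exactly(self, fixture_dir):
        d, ds = fixture_dir
        parsed = {m.gene_symbol: m for m in parse_gene_models(str(d / "genes.gff3"))}
        assert len(parsed) == len(ds.models)
        for intended in ds.models:
            got = parsed[intended.gene_symbol]
            assert (got.chrom, got.strand) == (intended.chrom, intended.strand)
            assert spans(got.five_utr) == spans(intended.five_utr)
            assert spans(got.exons) == spans(intended.exons)
            assert spans(got.introns) == spans(intended.introns)
            assert spans(got.three_utr) == spans(intended.three_utr)


def simple_gene(symbol, start, utr3_end, strand="+", chrom="chr1"):
    """A compact coding gene: 5'UTR 50, exon 100, 3'UTR to utr3_end."""
    if strand == "+":
        return GeneModel(
            symbol, chrom, strand,
            five_utr=[GenomicInterval(chrom, start, start + 50, strand)],
            exons=[GenomicInterval(chrom, start + 50, start + 150, strand)],
            three_utr=[GenomicInterval(chrom, start + 150, utr3_end, strand)],
        )
    return GeneModel(
        symbol, chrom, strand,
        three_utr=[GenomicInterval(chrom, start, utr3_end, strand)],
        exons=[GenomicInterval(chrom, utr3_end, utr3_end + 100, strand)],
        five_utr=[GenomicInterval(chrom, utr3_end + 100, utr3_end + 150, strand)],
    )


class TestBuildExtensions:
    def test_isolated_gene_gets_full_extension(self):
        m = simple_gene("A", 9_700, 10_000)
        build_extensions([m])
        assert (m.extension.start, m.extension.end) == (10_000, 13_000)

    def test_truncated_at_downstream_feature(self):
        m = simple_gene("A", 9_700, 10_000)
        blocker = simple_gene("B", 10_500, 10_800)
        build_extensions([m, blocker])
        assert (m.extension.start, m.extension.end) == (10_000, 10_500)

    def test_blocked_by_opposite_strand_feature(self):
        m = simple_gene("A", 9_700, 10_000)
        blocker = simple_gene("B", 10_400, 10_700, strand="-")
        build_extensions([m, blocker])
        assert m.extension.end == 10_400

    def test_abutting_neighbour_leaves_no_extension(self):
        m = simple_gene("A", 9_700, 10_000)
        blocker = simple_gene("B", 10_000, 10_300)
        build_extensions([m, blocker])
        assert m.extension is None

    def test_minus_strand_extension_runs_left(self):
        m = simple_gene("A", 10_000, 10_300, strand="-")
        build_extensions([m])
        assert (m.extension.start, m.extension.end) == (7_000, 10_000)

    def test_matches_per_base_bitmap_oracle(self):
        """Extension equals the first max_ext free bases downstream, computed
        against an exhaustive per-base occupancy bitmap."""
        models = [
            simple_gene("A", 1_000, 1_400),
            simple_gene("B", 2_200, 2_600),
            simple_gene("C", 5_100, 5_400, strand="-"),
        ]
        build_extensions(models, max_ext=3_000)
        occupied = set()
        for m in models:
            for _, iv in m.features(include_extension=False):
                occupied.update(range(iv.start, iv.end))
        for m in models:
            span = m.three_utr_span()
            expected = []
            step = 1 if m.strand == "+" else -1
            pos = span.end if m.strand == "+" else span.start - 1
            for _ in range(3_000):
                if pos in occupied or pos < 0:
                    break
                expected.append(pos)
                pos += step
            if not expected:
                assert m.extension is None
            else:
                assert (m.extension.start, m.extension.end) == (
                    min(expected),
                    max(expected) + 1,
                )


_FIELD = {THREE_UTR: "three_utr", EXON: "exons", INTRON: "introns", FIVE_UTR: "five_utr"}


def single_feature_model(symbol, cls, iv):
    m = GeneModel(symbol, iv.chrom, iv.strand)
    if cls == EXTENSION:
        m.extension = iv
    else:
        getattr(m, _FIELD[cls]).append(iv)
    return m


class TestHierarchy:
    def _annotate(self, models, span=(1_000, 1_010), strand="+"):
        cluster = PACluster("chr1", strand, list(range(span[0], span[1])))
        return annotate_cluster(cluster, AnnotationIndex(models))

    @pytest.mark.parametrize(
        "present",
        [c for r in range(1, 6) for c in itertools.combinations(ALL_CLASSES, r)],
        ids=lambda cs: "+".join(cs),
    )
    def test_highest_class_wins_for_every_combination(self, present):
        """For every subset of co-overlapping feature classes the reported
        class is the maximum under 3'UTR > exon > intron > 5'UTR > extension."""
        models = [
            single_feature_model(f"G_{cls}", cls, GenomicInterval("chr1", 990, 1_020, "+"))
            for cls in present
        ]
        site = self._annotate(models)
        assert site.feature == max(present, key=FEATURE_RANK.get)
        assert site.gene_symbol == f"G_{site.feature}"
        assert len(site.secondary) == len(present) - 1

    def test_cross_gene_tie_breaks_by_overlap_then_symbol(self):
        short = single_feature_model("AAA", THREE_UTR, GenomicInterval("chr1", 1_005, 1_050, "+"))
        long = single_feature_model("ZZZ", THREE_UTR, GenomicInterval("chr1", 900, 1_050, "+"))
        site = self._annotate([short, long])
        assert site.gene_symbol == "ZZZ"  # longer overlap beats symbol order
        equal_a = single_feature_model("AAA", THREE_UTR, GenomicInterval("chr1", 900, 1_050, "+"))
        site = self._annotate([equal_a, long])
        assert site.gene_symbol == "AAA"  # equal overlap: lexicographic

    def test_strand_matched_annotation(self):
        model = single_feature_model("G", THREE_UTR, GenomicInterval("chr1", 990, 1_020, "-"))
        site = self._annotate([model], strand="+")
        assert site.feature == UNASSIGNED and site.gene_symbol == UNASSIGNED

    def test_gene_desert_unassigned(self):
        site = self._annotate([])
        assert site.feature == UNASSIGNED

    def test_isoform_disagreement_resolves_to_highest_class(self):
        """A base that is 3'UTR in one isoform and intron in another
        contributes the gene's highest-ranking class."""
        iso1 = single_feature_model("G", INTRON, GenomicInterval("chr1", 990, 1_020, "+"))
        iso2 = single_feature_model("G", THREE_UTR, GenomicInterval("chr1", 990, 1_020, "+"))
        site = self._annotate([iso1, iso2])
        assert (site.gene_symbol, site.feature) == ("G", THREE_UTR)
        assert site.secondary == []

    def test_order_invariance(self):
        models = [
            single_feature_model("A", EXON, GenomicInterval("chr1", 990, 1_020, "+")),
            single_feature_model("B", THREE_UTR, GenomicInterval("chr1", 1_005, 1_030, "+")),
            single_feature_model("C", INTRON, GenomicInterval("chr1", 900, 1_100, "+")),
        ]
        forward = self._annotate(models)
        backward = self._annotate(models[::-1])
        assert (forward.gene_symbol, forward.feature) == (backward.gene_symbol, backward.feature)
        assert sorted(forward.secondary) == sorted(backward.secondary)


class TestFixtureAnnotation:
    def test_planted_sites_annotate_per_construction(self, pipeline_result):
        """Every cluster from a planted 3'UTR site is three_utr; every
        planted extension-zone site annotates as extension."""
        result, ds = pipeline_result
        from conftest import match_clusters_to_truth

        matches = match_clusters_to_truth(result.clusters, ds.truth)
        by_cluster = {id(a.cluster): a for a in result.annotated}
        for t in ds.truth:
            if t.decoy:
                continue
            (cluster,) = matches[t.site_id]
            annotated = by_cluster[id(cluster)]
            expected = THREE_UTR if t.kind in ("distal", "proximal") else EXTENSION
            assert annotated.feature == expected
            assert annotated.gene_symbol == t.gene_symbol
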