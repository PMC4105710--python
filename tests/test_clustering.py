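"""Cleavage-coordinate extraction and 1-D rolling-median clustering."""

import numpy as np
import pytest

from pacall.clustering import (
    PACluster,
    cluster_coords,
    cluster_events,
    extract_cleavage_coords,
    read_clusters_bed,
    write_clusters_bed,
)
from pacall.genomic_core import CleavageEvent

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"


def _sam(tmp_path, records):
    path = tmp_path / "t.sam"
    path.write_text(SAM_HEADER + "".join(records))
    return str(path)


def _rec(name, flag, pos, mapq=60, cigar="30M", seq="A" * 30):
    return f"{name}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n"


class TestExtractCleavageCoords:
    def test_plus_strand_uses_rightmost_aligned_base(self, tmp_path):
        events = extract_cleavage_coords(_sam(tmp_path, [_rec("r1", 0, 101)]))
        assert events == [CleavageEvent("chr1", "+", 129, "r1")]

    def test_minus_strand_uses_leftmost_aligned_base(self, tmp_path):
        events = extract_cleavage_coords(_sam(tmp_path, [_rec("r1", 16, 101)]))
        assert events == [CleavageEvent("chr1", "-", 100, "r1")]

    def test_secondary_supplementary_unmapped_and_low_mapq_skipped(self, tmp_path):
        records = [
            _rec("sec", 256, 101),
            _rec("sup", 2048, 101),
            f"unm\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n",
            _rec("low", 0, 101, mapq=3),
            _rec("ok", 0, 101),
        ]
        events = extract_cleavage_coords(_sam(tmp_path, records))
        assert [e.read_id for e in events] == ["ok"]

    def test_keep_ids_restricts_to_surviving_reads(self, tmp_path):
        path = _sam(tmp_path, [_rec("a", 0, 101), _rec("b", 0, 201)])
        events = extract_cleavage_coords(path, keep_ids={"b"})
        assert [e.read_id for e in events] == ["b"]


class TestClusterCoords:
    def test_singleton(self):
        (c,) = cluster_coords([100])
        assert (c.read_count, c.median_coord, c.mode_coord) == (1, 100, 100)
        assert (c.start, c.end) == (100, 101)

    def test_rolling_median_chains_distant_coordinates(self):
        """Successive medians 100,100,110,110,120 keep every next coordinate
        within 25 bp of the representative, producing one 41-bp cluster."""
        clusters = cluster_coords([100, 110, 120, 130, 140])
        assert len(clusters) == 1
        assert clusters[0].end - clusters[0].start == 41
        assert clusters[0].median_coord == 120

    def test_gap_beyond_max_dist_closes_cluster(self):
        clusters = cluster_coords([100, 200])
        assert [c.members for c in clusters] == [[100], [200]]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_coords([5, 3])

    def test_mode_ties_break_to_smaller_coordinate(self):
        (c,) = cluster_coords([10, 10, 12, 12, 14])
        assert c.mode_coord == 10

    def test_lower_median_for_even_sizes_is_observed_coordinate(self):
        (c,) = cluster_coords([10, 11, 13, 20])
        assert c.median_coord == 11

    def test_partition_and_contiguity(self):
        """Clusters partition the input multiset without interleaving."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            coords = sorted(int(x) for x in rng.integers(0, 3000, size=200))
            clusters = cluster_coords(coords)
            flat = [m for c in clusters for m in c.members]
            assert flat == coords  # conservation and no interleaving
            assert sum(c.read_count for c in clusters) == len(coords)
            for c in clusters:
                assert c.start <= c.median_coord <= c.end - 1
                assert c.mode_coord in c.members

    def test_planted_sites_recovered_one_cluster_each(self):
        """Sites >= 60 bp apart with <= ±5 nt wobble give one cluster per
        site, mode at the planted coordinate."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_sites = int(rng.integers(2, 8))
            sites = np.cumsum(rng.integers(60, 200, size=n_sites)) + 100
            coords = []
            for s in sites:
                wob = rng.integers(-5, 6, size=30)
                wob[:10] = 0  # guarantee the planted coordinate is the mode
                coords.extend(int(s + w) for w in wob)
            clusters = cluster_coords(sorted(coords))
            assert len(clusters) == n_sites
            for c, s in zip(clusters, sites):
                assert c.mode_coord == s

    def test_strands_clustered_independently(self):
        events = [
            CleavageEvent("c", "+", 100, "a"),
            CleavageEvent("c", "-", 100, "b"),
        ]
        clusters = cluster_events(events)
        assert len(clusters) == 2
        assert {c.strand for c in clusters} == {"+", "-"}


class TestClusterBed:
    def _random_clusters(self, seed):
        rng = np.random.default_rng(seed)
        events = [
            CleavageEvent("chr1", "+-"[int(rng.integers(0, 2))], int(x), f"r{i}")
            for i, x in enumerate(rng.integers(0, 20_000, size=300))
        ]
        return cluster_events(events)

    def test_singleton_line_format(self, tmp_path):
        c = PACluster("chr1", "+", [100] * 7, name="PA000001")
        path = tmp_path / "c.bed"
        write_clusters_bed([c], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1] == "chr1\t100\t101\tPA000001\t7\t+\t100\t100\t."

    def test_empty_cluster_list_writes_header_only(self, tmp_path):
        path = tmp_path / "c.bed"
        write_clusters_bed([], path)
        assert path.read_text().startswith("#")

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_preserves_summary(self, seed, tmp_path):
        clusters = self._random_clusters(seed)
        path = tmp_path / "c.bed"
        write_clusters_bed(clusters, path)
        back = read_clusters_bed(path)
        assert [(c.name, *c.bed_fields()) for c in back] == [
            (c.name, *c.bed_fields()) for c in clusters
        ]

    def test_byte_identical_output(self, tmp_path):
        clusters = self._random_clusters(9)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_clusters_bed(clusters, p1)
        write_clusters_bed(clusters, p2)
        assert p1.read_bytes() == p2.read_bytes()
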