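"""Hybrid-chromosome reconstruction, lift-over, continuity, split mates."""

import numpy as np
import pysam
import pytest

from fourcmap.digest import digest, revcomp
from fourcmap.rearrange import (
    SegmentEnd,
    build_fusion,
    junction_continuity,
    junction_read_support,
    liftover_track,
    scan_split_mates,
)
from fourcmap.simulate import random_dna
from tests.test_pscore import make_track

GENOME = {
    "chr1": random_dna(200, 0.5, 31),
    "chr2": random_dna(200, 0.5, 32),
}


class TestBuildFusion:
    def test_toy_lengths_and_junction(self):
        fusion, seq = build_fusion(
            GENOME, SegmentEnd("chr1", 100, "left"), SegmentEnd("chr2", 50, "right")
        )
        assert len(seq) == 100 + 150
        assert fusion.junction == 100
        assert seq == GENOME["chr1"][:100] + GENOME["chr2"][50:]

    def test_identity_fusion_restores_chromosome(self):
        _, seq = build_fusion(
            GENOME, SegmentEnd("chr1", 100, "left"), SegmentEnd("chr1", 100, "right")
        )
        assert seq == GENOME["chr1"]

    def test_reverse_orientation_segment(self):
        _, seq = build_fusion(
            GENOME,
            SegmentEnd("chr1", 100, "left", "reverse"),
            SegmentEnd("chr2", 50, "right"),
        )
        assert seq[:100] == revcomp(GENOME["chr1"][:100])

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_fusion(
                GENOME, SegmentEnd("chr1", 150, "left"), SegmentEnd("chr1", 100, "right")
            )

    def test_every_hybrid_base_lifts_back_to_its_source(self):
        fusion, seq = build_fusion(
            GENOME,
            SegmentEnd("chr1", 120, "left", "reverse"),
            SegmentEnd("chr2", 30, "right"),
        )
        for hp in range(0, len(seq), 7):
            chrom, rp = fusion.to_ref(hp)
            expected = GENOME[chrom][rp]
            if hp < fusion.junction:  # reverse-complemented segment
                expected = revcomp(expected)
            assert seq[hp] == expected


class TestLiftover:
    @staticmethod
    def _track(n1=10, n2=15, spacing=1_000):
        pos1 = (np.arange(n1) + 1) * spacing
        pos2 = (np.arange(n2) + 1) * spacing
        rng = np.random.default_rng(8)
        return make_track(
            {"chr1": pos1, "chr2": pos2},
            {"chr1": rng.integers(0, 2, n1), "chr2": rng.integers(0, 2, n2)},
            chrom_len=20_000,
        )

    @staticmethod
    def _genome():
        return {"chr1": "A" * 20_000, "chr2": "A" * 20_000}

    def test_identity_fusion_preserves_track(self):
        track = self._track()
        fusion, _ = build_fusion(
            self._genome(), SegmentEnd("chr1", 9_000, "left"), SegmentEnd("chr1", 9_000, "right")
        )
        lifted = liftover_track(track, fusion)
        (name,) = lifted.site_map.sites
        assert lifted.site_map.sites[name].tolist() == track.site_map.sites["chr1"].tolist()
        assert (lifted.indicators[name] == track.indicators["chr1"]).all()

    def test_site_count_conserved_across_fusion(self):
        track = self._track(n1=10, n2=15)
        fusion, _ = build_fusion(
            self._genome(), SegmentEnd("chr1", 20_000, "left"), SegmentEnd("chr2", 0, "right")
        )
        lifted = liftover_track(track, fusion)
        (name,) = lifted.site_map.sites
        assert len(lifted.site_map.sites[name]) == 25

    def test_reverse_segment_reverses_order_and_preserves_distances(self):
        track = self._track(n1=10, n2=15)
        fusion, _ = build_fusion(
            self._genome(),
            SegmentEnd("chr1", 20_000, "left", "reverse"),
            SegmentEnd("chr2", 0, "right"),
        )
        lifted = liftover_track(track, fusion)
        (name,) = lifted.site_map.sites
        pos = lifted.site_map.sites[name]
        first = lifted.indicators[name][:10]
        # chr1 indicator order is reversed on the hybrid
        assert first.tolist() == track.indicators["chr1"][::-1].tolist()
        # pairwise distances within the reversed segment preserved
        orig = np.diff(track.site_map.sites["chr1"])
        assert np.diff(pos[:10]).tolist() == orig[::-1].tolist()

    def test_roundtrip_indicator_values_via_liftover_map(self):
        track = self._track()
        fusion, _ = build_fusion(
            self._genome(), SegmentEnd("chr1", 9_500, "left"), SegmentEnd("chr2", 4_500, "right")
        )
        lifted = liftover_track(track, fusion)
        (name,) = lifted.site_map.sites
        for hp, val in zip(lifted.site_map.sites[name], lifted.indicators[name]):
            chrom, rp = fusion.to_ref(int(hp))
            idx = int(np.searchsorted(track.site_map.sites[chrom], rp))
            assert track.site_map.sites[chrom][idx] == rp
            assert track.indicators[chrom][idx] == val


class TestJunctionContinuity:
    def test_uniform_random_track_is_continuous(self):
        rng = np.random.default_rng(9)
        pos = np.arange(200) * 1_000
        track = make_track({"h": pos}, {"h": rng.integers(0, 2, 200)}, chrom_len=200_000)
        verdict = junction_continuity(track, junction=100_000, flank=50_000)
        assert verdict.continuous

    def test_one_sided_coverage_is_discontinuous(self):
        pos = np.arange(200) * 1_000
        ind = np.concatenate([np.ones(100, dtype=np.uint8), np.zeros(100, dtype=np.uint8)])
        # sprinkle a thin background on the right so p0 sits between the flanks
        ind[105:200:10] = 1
        track = make_track({"h": pos}, {"h": ind}, chrom_len=200_000)
        verdict = junction_continuity(track, junction=100_000, flank=50_000)
        assert not verdict.continuous
        assert verdict.p_value < 0.01

    def test_junction_near_end_flagged_edge(self):
        rng = np.random.default_rng(10)
        pos = np.arange(100) * 1_000
        track = make_track({"h": pos}, {"h": rng.integers(0, 2, 100)}, chrom_len=100_000)
        verdict = junction_continuity(track, junction=10_000, flank=50_000)
        assert verdict.edge


def _write_pairs_sam(path, pairs, refs):
    """pairs: (name, chrom1, pos1, chrom2, pos2) -> two paired records."""
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": c, "LN": n} for c, n in refs.items()]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        names = out.header.references
        for name, c1, p1, c2, p2 in pairs:
            for which, (ca, pa, cb, pb) in enumerate(((c1, p1, c2, p2), (c2, p2, c1, p1))):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = name
                rec.flag = 0x1 | (0x40 if which == 0 else 0x80)
                rec.reference_id = names.index(ca)
                rec.reference_start = pa
                rec.next_reference_id = names.index(cb)
                rec.next_reference_start = pb
                rec.mapping_quality = 60
                rec.cigartuples = [(0, 75)]
                out.write(rec)


REFS = {"chr1": 2_000_000, "plasmid": 8_000}


class TestScanSplitMates:
    def test_clustered_split_pairs_become_one_call(self, tmp_path):
        sam = tmp_path / "a.sam"
        pairs = [(f"p{i}", "chr1", 500_000 + i * 150, "plasmid", 100 + i * 10) for i in range(5)]
        _write_pairs_sam(sam, pairs, REFS)
        calls = scan_split_mates(sam, "plasmid")
        assert len(calls) == 1
        call = calls[0]
        assert call.support == 5
        assert call.chrom == "chr1"
        assert call.start == 500_000 and call.end == 500_600
        assert len(call.plasmid_positions) == 5

    def test_fully_genomic_pairs_yield_nothing(self, tmp_path):
        sam = tmp_path / "b.sam"
        _write_pairs_sam(sam, [(f"p{i}", "chr1", 1000 + i, "chr1", 1400 + i) for i in range(5)], REFS)
        assert scan_split_mates(sam, "plasmid") == []

    def test_two_distant_insertions_give_two_calls(self, tmp_path):
        sam = tmp_path / "c.sam"
        pairs = [(f"p{i}", "chr1", 100_000 + i * 100, "plasmid", 50) for i in range(3)]
        pairs += [(f"q{i}", "chr1", 1_100_000 + i * 100, "plasmid", 7_900) for i in range(3)]
        _write_pairs_sam(sam, pairs, REFS)
        calls = scan_split_mates(sam, "plasmid")
        assert len(calls) == 2
        assert [c.support for c in calls] == [3, 3]

    def test_coordinate_duplicates_collapse(self, tmp_path):
        sam = tmp_path / "d.sam"
        pairs = [(f"p{i}", "chr1", 500_000, "plasmid", 100) for i in range(6)]
        pairs += [("u1", "chr1", 500_300, "plasmid", 220)]
        _write_pairs_sam(sam, pairs, REFS)
        calls = scan_split_mates(sam, "plasmid")
        assert len(calls) == 1
        assert calls[0].support == 2  # 6 duplicates count once, plus u1

    def test_below_min_support_suppressed(self, tmp_path):
        sam = tmp_path / "e.sam"
        _write_pairs_sam(sam, [("p0", "chr1", 500_000, "plasmid", 100)], REFS)
        assert scan_split_mates(sam, "plasmid", min_support=2) == []

    def test_missing_plasmid_contig_rejected(self, tmp_path):
        sam = tmp_path / "f.sam"
        _write_pairs_sam(sam, [("p0", "chr1", 1000, "chr1", 1400)], {"chr1": 2_000_000})
        with pytest.raises(ValueError, match="plasmid"):
            scan_split_mates(sam, "plasmid")


class TestJunctionReadSupport:
    @staticmethod
    def _fusion():
        genome = {"a": random_dna(5_000, 0.5, 41), "b": random_dna(5_000, 0.5, 42)}
        fusion, seq = build_fusion(
            genome, SegmentEnd("a", 2_500, "left"), SegmentEnd("b", 2_500, "right")
        )
        return fusion, seq

    def test_crossing_fragments_counted_exactly(self):
        fusion, seq = self._fusion()
        rng = np.random.default_rng(43)
        pairs, expected = [], 0
        for i in range(200):
            start = int(rng.integers(0, len(seq) - 400))
            frag = seq[start : start + 400]
            r1, r2 = frag[:75], revcomp(frag[-75:])
            pairs.append((f"p{i}", r1, r2))
            m1 = (start, start + 75)
            m2 = (start + 325, start + 400)
            j = fusion.junction
            crossing = m1[0] < j < m1[1] or m2[0] < j < m2[1]
            straddle = m1[1] <= j <= m2[0]
            if crossing or straddle:
                expected += 1
        assert expected > 0
        assert junction_read_support(seq, fusion.junction, pairs, span=3_000) == expected

    def test_no_nearby_fragments_gives_zero(self):
        fusion, seq = self._fusion()
        r1 = seq[100:175]
        r2 = revcomp(seq[300:375])
        assert junction_read_support(seq, fusion.junction, [("p", r1, r2)]) == 0

    def test_duplicated_fragments_count_once(self):
        fusion, seq = self._fusion()
        j = fusion.junction
        frag = seq[j - 200 : j + 200]
        pair = ("p", frag[:75], revcomp(frag[-75:]))
        assert junction_read_support(seq, j, [pair, pair, pair]) == 1
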