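import numpy as np
import pytest

from loopquant import fourc as fc
from loopquant.locus import EnzymePair, Haplotype, Region, build_fragment_map

from .conftest import random_dna


def make_vp(primer="ACGTACGTACGTACGTGATC", name="VP", max_mismatch=2, snv=None):
    return fc.ViewpointSpec(
        name=name, primer_seq=primer, viewpoint_fragment=0, max_mismatch=max_mismatch, allele_snv=snv
    )


class TestMatchViewpoint:
    def test_exact_match(self):
        vp = make_vp()
        name, status = fc.match_viewpoint(vp.primer_seq + "AAAA", [vp])
        assert (name, status) == ("VP", "matched")

    def test_two_mismatches_allowed(self):
        vp = make_vp()
        read = "TCGTACGTACGTACGTGATC" + "AAAA"  # A->T at 0, and one more below
        read = "T" + vp.primer_seq[1:10] + "A" + vp.primer_seq[11:] + "AAAA"
        assert sum(a != b for a, b in zip(read, vp.primer_seq)) == 2
        assert fc.match_viewpoint(read, [vp])[1] == "matched"

    def test_three_mismatches_rejected(self):
        vp = make_vp()
        read = "TTT" + vp.primer_seq[3:] + "AAAA"
        assert sum(a != b for a, b in zip(read, vp.primer_seq)) == 3
        assert fc.match_viewpoint(read, [vp]) == (None, "unmatched")

    def test_ambiguous_two_viewpoints(self):
        vp1 = make_vp(name="A")
        vp2 = make_vp(primer=make_vp().primer_seq[:-1] + "A", name="B")
        name, status = fc.match_viewpoint(vp1.primer_seq + "GG", [vp1, vp2])
        assert (name, status) == (None, "ambiguous")

    def test_short_read_unmatched(self):
        vp = make_vp()
        assert fc.match_viewpoint("ACGT", [vp]) == (None, "unmatched")

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            fc.match_viewpoint("", [make_vp()])


class TestTrimToPrimarySite:
    def test_primer_ending_in_motif(self):
        primer = "ACGTACGTACGTACGTGATC"
        read = primer + "TTTTGG"
        trimmed = fc.trim_to_primary_site(read, len(primer), "GATC")
        assert trimmed == "GATC" + "TTTTGG"

    def test_no_motif_returns_none(self):
        assert fc.trim_to_primary_site("ACGTACGTACGTAAAA", 12, "GATC") is None

    def test_leftmost_occurrence_used(self):
        primer = "ACGTACGTACGTACGTGATC"
        read = primer + "AA" + "GATC" + "CC"  # second motif downstream
        trimmed = fc.trim_to_primary_site(read, len(primer), "GATC")
        assert trimmed == "GATC" + "AA" + "GATC" + "CC"


class TestSplitAllele:
    snv = fc.AlleleSnv(offset=3, base129="A", baseCAST="G")

    def test_base129(self):
        assert fc.split_allele("CCCAT", self.snv) == "129"

    def test_base_cast(self):
        assert fc.split_allele("CCCGT", self.snv) == "CAST"

    def test_other_base_unassigned(self):
        assert fc.split_allele("CCCTT", self.snv) == "unassigned"

    def test_n_unassigned(self):
        assert fc.split_allele("CCCNT", self.snv) == "unassigned"

    def test_offset_out_of_range_unassigned(self):
        assert fc.split_allele("CC", self.snv) == "unassigned"


class TestDemuxConservation:
    def test_tallies_partition_input(self):
        vp = make_vp(snv=fc.AlleleSnv(offset=1, base129="A", baseCAST="G"))
        primer = vp.primer_seq
        pairs = [
            (primer + "TTTT", "CA"),            # matched, 129
            (primer + "TTTT", "CG"),            # matched, CAST
            (primer + "TTTT", "CT"),            # matched, unassigned
            ("T" * len(primer) + "AA", "CA"),   # unmatched primer
            (primer[:-4] + "AAAAGGGG", "CA"),   # matches with <=2 mm? 4 mism -> unmatched
        ]
        demuxed, tally = fc.demux_pairs(pairs, [vp], "GATC")
        assert tally.total == len(pairs)
        assert tally.total == tally.matched + tally.unmatched_primer + tally.ambiguous + tally.no_motif
        assert tally.matched == tally.allele_129 + tally.allele_cast + tally.allele_unassigned
        assert len(demuxed) == tally.matched

    def test_no_motif_tally(self):
        vp = make_vp(primer="ACGTACGTACGTACGTACGT")  # primer without the motif
        pairs = [(vp.primer_seq + "TTTT", "CC")]
        demuxed, tally = fc.demux_pairs(pairs, [vp], "GATC")
        assert tally.no_motif == 1 and not demuxed


class TestCountFragments:
    @pytest.fixture(scope="class")
    def fmap(self):
        rng = np.random.default_rng(5)
        return build_fragment_map(Haplotype("t", random_dna(rng, 30_000)), EnzymePair())

    def test_start_match_counted(self, fmap):
        frag = fmap[3]
        read = fc.AlignedReadRecord("t", frag.start, frag.start + 30)
        counts = fc.count_fragments([read], fmap)
        assert counts[3] == 1 and counts.sum() == 1

    def test_interior_read_not_counted(self, fmap):
        frag = fmap[3]
        if frag.end - frag.start > 40:
            read = fc.AlignedReadRecord("t", frag.start + 5, frag.start + 35)
            assert fc.count_fragments([read], fmap).sum() == 0

    def test_both_boundaries_same_fragment_counts_once(self, fmap):
        frag = fmap[4]
        read = fc.AlignedReadRecord("t", frag.start, frag.end)
        counts = fc.count_fragments([read], fmap)
        assert counts[4] == 1 and counts.sum() == 1

    def test_two_fragment_boundaries_discarded(self, fmap):
        # start of fragment 2, end of fragment 5 -> ambiguous, tallied
        read = fc.AlignedReadRecord("t", fmap[2].start, fmap[5].end)
        tally = fc.QCTally()
        counts = fc.count_fragments([read], fmap, tally)
        assert counts.sum() == 0
        assert tally.multi_fragment_discard == 1

    def test_unpaired_or_nonunique_skipped(self, fmap):
        frag = fmap[1]
        reads = [
            fc.AlignedReadRecord("t", frag.start, frag.start + 30, is_paired=False),
            fc.AlignedReadRecord("t", frag.start, frag.start + 30, is_unique=False),
        ]
        assert fc.count_fragments(reads, fmap).sum() == 0

    def test_brute_force_oracle(self, fmap):
        rng = np.random.default_rng(6)
        n = fmap.sequence_length
        reads = []
        starts = fmap.starts
        ends = fmap.ends
        for _ in range(5_000):
            if rng.random() < 0.5:  # boundary-anchored read
                f = int(rng.integers(0, len(fmap)))
                if rng.random() < 0.5:
                    s = int(starts[f])
                    e = min(s + int(rng.integers(20, 80)), n)
                else:
                    e = int(ends[f])
                    s = max(e - int(rng.integers(20, 80)), 0)
            else:  # random placement
                s = int(rng.integers(0, n - 50))
                e = s + int(rng.integers(20, 80))
            if s < e:
                reads.append(fc.AlignedReadRecord("t", s, e))
        counts = fc.count_fragments(reads, fmap)
        # independent per-read brute force over all fragments
        expected = np.zeros(len(fmap), dtype=int)
        for r in reads:
            hits = [f.index for f in fmap if r.start == f.start or r.end == f.end]
            if len(set(hits)) == 1:
                expected[hits[0]] += 1
        assert np.array_equal(counts, expected)


class TestCpmNormalize:
    def test_two_fragment_example(self):
        out = fc.cpm_normalize(np.array([1, 3]), np.array([True, True]))
        assert np.allclose(out, [250_000, 750_000])

    def test_single_fragment(self):
        assert np.allclose(fc.cpm_normalize(np.array([5]), np.array([True])), [1e6])

    def test_sum_is_million(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 100, size=500)
        mask = rng.random(500) < 0.8
        raw[mask.argmax()] += 1  # ensure nonzero
        out = fc.cpm_normalize(raw, mask)
        assert np.isclose(out.sum(), 1e6)

    def test_invalid_fragments_zeroed(self):
        out = fc.cpm_normalize(np.array([10, 10]), np.array([True, False]))
        assert out[1] == 0 and np.isclose(out[0], 1e6)

    def test_empty_library_error(self):
        with pytest.raises(ValueError, match="empty library"):
            fc.cpm_normalize(np.zeros(4), np.ones(4, dtype=bool))


class TestRollingMean:
    def test_constant_fixed_point(self):
        x = np.full(50, 3.7)
        assert np.allclose(fc.rolling_mean(x, 21), x)

    def test_window_one_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(fc.rolling_mean(x, 1), x)

    def test_hand_computed_example(self):
        out = fc.rolling_mean(np.array([0.0, 0, 21, 0, 0]), 3)
        assert np.allclose(out, [0, 7, 7, 7, 0])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            fc.rolling_mean(np.ones(5), 4)

    def test_nan_edge_policy(self):
        out = fc.rolling_mean(np.ones(7), 5, edge="nan")
        assert np.isnan(out[:2]).all() and np.isnan(out[-2:]).all()
        assert np.allclose(out[2:-2], 1.0)

    def test_zero_padded_total_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        w = 21
        padded = np.concatenate([np.zeros(w), x, np.zeros(w)])
        sm = fc.rolling_mean(padded, w)
        assert np.isclose(sm.sum(), padded.sum())

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random(57)
        w = 9
        out = fc.rolling_mean(x, w)
        for i in range(len(x)):
            h = min(w // 2, i, len(x) - 1 - i)
            assert np.isclose(out[i], x[i - h : i + h + 1].mean())


class TestQuantifyRegion:
    @pytest.fixture(scope="class")
    def setup(self):
        rng = np.random.default_rng(12)
        fmap = build_fragment_map(Haplotype("t", random_dna(rng, 30_000)), EnzymePair())
        raw = rng.integers(0, 50, size=len(fmap))
        raw[fmap.valid_mask.argmax()] += 1
        track = fc.build_track(raw, fmap, viewpoint="VP", viewpoint_fragment=None)
        return fmap, track

    def test_single_fragment_region(self, setup):
        fmap, track = setup
        idx = int(np.flatnonzero(track.included)[5])
        frag = fmap[idx]
        region = Region("one", frag.start, frag.end)
        # restrict so only this fragment's midpoint is inside
        q = fc.quantify_region(track, region, fmap)
        mids = fmap.midpoints
        sel = (mids >= region.start) & (mids < region.end) & track.included
        assert np.isclose(q.value, track.normalized[sel].mean())

    def test_mean_of_two_fragments(self, setup):
        fmap, track = setup
        inc = np.flatnonzero(track.included)
        i, j = int(inc[7]), int(inc[8])
        region = Region("two", fmap[i].start, fmap[j].end)
        q = fc.quantify_region(track, region, fmap)
        mids = fmap.midpoints
        sel = (mids >= region.start) & (mids < region.end) & track.included
        assert np.isclose(q.value, track.normalized[sel].mean())

    def test_midpoint_brute_force_oracle(self, setup):
        fmap, track = setup
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = int(rng.integers(0, fmap.sequence_length - 1_000))
            region = Region("r", a, a + int(rng.integers(500, 5_000)))
            mids = fmap.midpoints
            sel = (mids >= region.start) & (mids < region.end) & track.included
            if not sel.any():
                with pytest.raises(ValueError):
                    fc.quantify_region(track, region, fmap)
                continue
            q = fc.quantify_region(track, region, fmap)
            assert np.isclose(q.value, track.normalized[sel].mean())
            q_sum = fc.quantify_region(track, region, fmap, stat="sum")
            assert np.isclose(q_sum.value, track.normalized[sel].sum())

    def test_no_overlap_error(self, setup):
        fmap, track = setup
        # zero-width-ish region between midpoints of a long fragment
        frag = max(fmap, key=lambda f: f.end - f.start)
        region = Region("empty", frag.start, frag.start + 1)
        with pytest.raises(ValueError):
            fc.quantify_region(track, region, fmap)


class TestViewpointExclusion:
    def test_viewpoint_neighbors_excluded(self):
        rng = np.random.default_rng(13)
        fmap = build_fragment_map(Haplotype("t", random_dna(rng, 30_000)), EnzymePair())
        vp = 10
        mask = fc.included_fragments(fmap, viewpoint_fragment=vp, exclude_viewpoint_neighbors=1)
        assert not mask[vp - 1 : vp + 2].any()
        mask0 = fc.included_fragments(fmap, viewpoint_fragment=vp, exclude_viewpoint_neighbors=0)
        assert not mask0[vp]
        assert mask0[vp - 1] == fmap.valid_mask[vp - 1]


class TestAlignmentIO:
    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text("t\t100\t150\tpaired,unique\nt\t200\t260\tpaired\n")
        recs = fc.read_alignments_tsv(path)
        assert recs[0].is_unique and recs[0].is_paired
        assert not recs[1].is_unique
        assert (recs[0].start, recs[0].end) == (100, 150)

    def test_sam_reader(self, tmp_path):
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:t\tLN:1000\n"
            "r1\t99\tt\t101\t60\t50M\t=\t301\t250\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "r2\t99\tt\t201\t5\t50M\t=\t401\t250\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
        )
        recs = fc.read_alignments_sam(sam, min_mapq=20)
        assert len(recs) == 2
        assert recs[0].is_unique and recs[0].start == 100 and recs[0].end == 150
        assert not recs[1].is_unique  # MAPQ below threshold
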