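"""CDS/UTR delineation: frame recovery, start/stop placement, region filters."""

import pytest

from orthodiv import AnnotateParams, extract_regions, locate_start, locate_stop
from orthodiv.annotate import AnnotatedOrtholog, Rejection, protein_guided_cds
from orthodiv.genetics import reverse_complement, translate
from orthodiv.orthologs import OrthologPair

from _oracles import truth_accepted_pairs


def _pair(world, idx):
    rec_a = world.records_a[idx]
    rec_b = world.records_b[idx]
    prot_id = world.truth.transcripts[rec_a.id].protein_id
    pair = OrthologPair(rec_a.id, rec_b.id, None, None, 1.0, prot_id)
    return pair, rec_a, rec_b, world.proteins[prot_id]


class TestProteinGuidedCds:
    def test_exact_transcript_recovers_truth_interval(self, small_world):
        _, rec_a, _, protein = _pair(small_world, 0)
        t = small_world.truth.transcripts[rec_a.id]
        anchor = protein_guided_cds(rec_a.sequence, protein)
        assert anchor.strand == "+"
        # aligned protein covers [cds_start, cds_end - 3) (stop not encoded)
        assert anchor.tx_start == t.cds_start
        assert anchor.tx_end == t.cds_end - 3

    def test_reverse_complement_recovered_on_minus_strand(self, small_world):
        _, rec_a, _, protein = _pair(small_world, 1)
        rc = reverse_complement(rec_a.sequence)
        anchor = protein_guided_cds(rc, protein)
        assert anchor.strand == "-"
        t = small_world.truth.transcripts[rec_a.id]
        # coordinates refer to the re-oriented (= original) sequence
        assert anchor.tx_start == t.cds_start
        assert anchor.tx_end == t.cds_end - 3

    def test_frame_recovery_is_complete_at_one_percent_divergence(self, small_world):
        hits = 0
        for i in range(len(small_world.records_b)):
            _, _, rec_b, protein = _pair(small_world, i)
            t = small_world.truth.transcripts[rec_b.id]
            anchor = protein_guided_cds(rec_b.sequence, protein)
            assert anchor is not None
            assert anchor.tx_start % 3 == t.cds_start % 3
            hits += 1
        assert hits == len(small_world.records_b)


class TestStartStopPlacement:
    # transcript with in-frame ATG exactly at position 30
    BASE = "T" * 30 + "ATG" + "CAT" * 20 + "TAACCCTTT"

    def test_atg_at_anchor_is_returned(self):
        assert locate_start(self.BASE, 30) == 30

    def test_single_atg_fifteen_bp_upstream_accepted(self):
        seq = "T" * 15 + "ATG" + "T" * 12 + "CAT" * 20
        # anchor at 30, ATG at 15 (in frame, 15 bp upstream)
        assert locate_start(seq, 30) == 15

    def test_atg_beyond_window_rejected(self):
        seq = "T" * 33 + "CAT" * 30
        atg = "ATG"
        seq = atg + seq[3:]            # only ATG at 0; anchor at 33 -> 33 bp away
        assert locate_start(seq, 33) is None
        assert locate_start(seq, 30) == 0   # boundary: exactly 30 bp is allowed

    def test_nearest_atg_wins_and_tie_goes_upstream(self):
        #  ATG at anchor-6 and anchor+6: upstream wins the tie
        seq = "T" * 24 + "ATG" + "TTTCCCGGG" + "ATG" + "T" * 30
        assert locate_start(seq, 30) == 24
        #  nearest wins when distances differ
        seq2 = "T" * 24 + "ATG" + "TTTCCC" + "ATG" + "T" * 30
        assert locate_start(seq2, 30) == 33

    def test_stop_at_anchor_and_in_window(self):
        seq = "C" * 60 + "TAA" + "C" * 30
        assert locate_stop(seq, 60) == 60
        seq2 = "C" * 60 + "CCC" * 4 + "TGA" + "C" * 6
        assert locate_stop(seq2, 60) == 72      # TGA 12 bp downstream, in frame
        assert locate_stop("C" * 120, 60) is None

    def test_out_of_frame_motifs_ignored(self):
        seq = "C" * 59 + "TAACC" + "C" * 30    # TAA at 59, anchor 60 -> off frame
        assert locate_stop(seq, 60) is None


class TestExtractRegions:
    def test_clean_pair_regions_equal_truth(self, small_world):
        pair, rec_a, rec_b, protein = _pair(small_world, 2)
        res = extract_regions(pair, {rec_a.id: rec_a.sequence},
                              {rec_b.id: rec_b.sequence}, protein)
        assert isinstance(res, AnnotatedOrtholog)
        t = small_world.truth.transcripts[rec_a.id]
        assert res.member_a.cds == (t.cds_start, t.cds_end)
        assert res.member_a.utr5 == (0, t.cds_start)
        assert res.member_a.utr3 == (t.cds_end, len(rec_a.sequence))

    def test_cds_shorter_than_150_rejected(self):
        # hand-built 147 bp CDS (49 codons incl. stop) with UTRs
        cds = "ATG" + "CAT" * 47 + "TAA"
        seq = "T" * 50 + cds + "G" * 50
        protein = translate(cds[:-3])
        pair = OrthologPair("x_A", "x_B", None, None, 1.0, "P")
        res = extract_regions(pair, {"x_A": seq}, {"x_B": seq}, protein)
        assert isinstance(res, Rejection)
        assert res.reason == "cds_too_short"

    def test_tiling_and_equal_aligned_lengths(self, small_world):
        for i in range(10):
            pair, rec_a, rec_b, protein = _pair(small_world, i)
            res = extract_regions(pair, {rec_a.id: rec_a.sequence},
                                  {rec_b.id: rec_b.sequence}, protein)
            if not isinstance(res, AnnotatedOrtholog):
                continue
            for mem in (res.member_a, res.member_b):
                lo = mem.utr5[0] if mem.utr5 else mem.cds[0]
                hi = mem.utr3[1] if mem.utr3 else mem.cds[1]
                parts = [iv for iv in (mem.utr5, mem.cds, mem.utr3) if iv]
                # contiguous, non-overlapping tiling of [lo, hi)
                assert parts[0][0] == lo and parts[-1][1] == hi
                assert all(p[1] == q[0] for p, q in zip(parts, parts[1:]))
            cds_a, cds_b = res.aligned_cds
            assert len(cds_a) == len(cds_b)

    def test_acceptance_monotone_in_min_cds_length(self, small_world):
        counts = []
        for min_len in (150, 300, 450, 600):
            params = AnnotateParams(min_cds_length=min_len)
            n = 0
            for i in range(20):
                pair, rec_a, rec_b, protein = _pair(small_world, i)
                res = extract_regions(pair, {rec_a.id: rec_a.sequence},
                                      {rec_b.id: rec_b.sequence}, protein,
                                      params)
                n += isinstance(res, AnnotatedOrtholog)
            counts.append(n)
        assert counts == sorted(counts, reverse=True)

    def test_accepted_count_matches_truth_side_filter(self, small_world):
        accepted = set()
        for i in range(len(small_world.records_b)):
            pair, rec_a, rec_b, protein = _pair(small_world, i)
            res = extract_regions(pair, {rec_a.id: rec_a.sequence},
                                  {rec_b.id: rec_b.sequence}, protein)
            if isinstance(res, AnnotatedOrtholog):
                accepted.add((pair.id_a, pair.id_b))
        expected = truth_accepted_pairs(small_world)
        assert accepted == expected
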