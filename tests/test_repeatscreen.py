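import numpy as np
import pytest

from satconnect._align import revcomp
from satconnect.errors import SatconnectError
from satconnect.repeatscreen import (
    anchor_window,
    filter_reads,
    mask_read,
    read_start_coordinate,
)
from satconnect.seqio import SequenceRecord

from _oracles import naive_anchor_window, sw_best_over_strands
from conftest import random_seq


class TestMaskRead:
    def test_read_equal_to_monomer_fully_repetitive(self, monomer_record):
        ann = mask_read(monomer_record, [monomer_record])
        assert ann.repeat_fraction == 1.0
        assert ann.best_hit == "monomer"
        assert ann.intervals == [(0, len(monomer_record.bases))]

    def test_random_read_has_zero_fraction(self, monomer_record):
        rng = np.random.default_rng(5)
        read = SequenceRecord(id="rand", bases=random_seq(rng, 300))
        # oracle confirms no qualifying local alignment exists on the fixture
        score, matches, columns = sw_best_over_strands(
            read.bases, monomer_record.bases
        )
        assert columns < 25 or matches / columns < 0.7
        ann = mask_read(read, [monomer_record], min_local_identity=0.7)
        assert ann.repeat_fraction == 0.0
        assert ann.best_hit is None

    def test_half_repeat_read(self, monomer, rng):
        read = SequenceRecord(
            id="half", bases=monomer[:100] + random_seq(rng, 100)
        )
        ann = mask_read(read, [SequenceRecord(id="m", bases=monomer)])
        # the repeat half is recovered up to alignment end-trimming; chance
        # hits on the random tail must themselves qualify under the rule
        start, end = ann.intervals[0]
        # end-trimming can stop short of, or overshoot, the boundary by a
        # few chance-matching columns
        assert start <= 5 and 95 <= end <= 120
        assert 0.45 <= ann.repeat_fraction
        for s, e in ann.intervals[1:]:
            score, matches, columns = sw_best_over_strands(
                read.bases[s:e], monomer
            )
            assert columns >= 25 and matches / columns >= 0.7

    def test_junction_spanning_read_fully_covered(self, monomer):
        # read crosses a monomer junction: two partial copies
        read = SequenceRecord(id="junc", bases=monomer[-80:] + monomer[:80])
        ann = mask_read(read, [SequenceRecord(id="m", bases=monomer)])
        assert ann.repeat_fraction == 1.0

    def test_strand_invariance(self, monomer, rng):
        lib = [SequenceRecord(id="m", bases=monomer)]
        read = SequenceRecord(id="r", bases=monomer[50:250])
        flipped = SequenceRecord(id="r_rc", bases=revcomp(read.bases))
        a = mask_read(read, lib)
        b = mask_read(flipped, lib)
        assert a.repeat_fraction == pytest.approx(b.repeat_fraction, abs=0.02)

    def test_empty_library_rejected(self, monomer_record):
        with pytest.raises(SatconnectError):
            mask_read(monomer_record, [])


class TestFilterReads:
    def _reads(self, monomer, rng, n_repeat=10, n_random=5):
        reads = [
            SequenceRecord(id=f"rep{i}", bases=monomer) for i in range(n_repeat)
        ]
        reads += [
            SequenceRecord(id=f"rnd{i}", bases=random_seq(rng, 200))
            for i in range(n_random)
        ]
        return reads

    def test_exact_copies_retained_random_removed(self, monomer, rng):
        lib = [SequenceRecord(id="m", bases=monomer)]
        reads = self._reads(monomer, rng)
        retained, stats = filter_reads(reads, lib)
        assert stats.initial == 15
        assert stats.retained == 10
        assert {r.id for r in retained} == {f"rep{i}" for i in range(10)}
        assert stats.best_hit_tally == {"m": 10}

    def test_threshold_semantics_at_boundary(self, monomer):
        # a read at repeat fraction ~0.995: retained at 0.99, removed at 1.0
        lib = [SequenceRecord(id="m", bases=monomer)]
        read = SequenceRecord(id="edge", bases=monomer + "T")
        frac = mask_read(read, lib).repeat_fraction
        assert 0.99 <= frac < 1.0
        kept99, _ = filter_reads([read], lib, threshold=0.99)
        kept100, _ = filter_reads([read], lib, threshold=1.0)
        assert len(kept99) == 1
        assert len(kept100) == 0

    def test_retention_monotone_in_threshold(self, monomer, rng):
        lib = [SequenceRecord(id="m", bases=monomer)]
        reads = self._reads(monomer, rng, n_repeat=4, n_random=3)
        reads.append(
            SequenceRecord(id="mix", bases=monomer[:150] + random_seq(rng, 30))
        )
        sizes = []
        for threshold in (0.2, 0.5, 0.8, 0.99, 1.0):
            retained, _ = filter_reads(reads, lib, threshold)
            sizes.append(len(retained))
        assert sizes == sorted(sizes, reverse=True)


class TestAnchorWindow:
    def _reads_at(self, monomer, starts, length=60):
        return [
            SequenceRecord(id=f"r{i}", bases=monomer[s : s + length])
            for i, s in enumerate(starts)
        ]

    def test_all_reads_at_zero(self, monomer_record, monomer):
        reads = self._reads_at(monomer, [0] * 5)
        assert anchor_window(reads, monomer_record) == (0, 25)

    def test_modal_start_wins(self, monomer_record, monomer):
        starts = [0, 0, 0, 100, 100, 100, 100, 100]
        reads = self._reads_at(monomer, starts)
        window = anchor_window(reads, monomer_record)
        # the window must cover the modal start (100) and equal the
        # exhaustive scan; the smallest-start tie-break selects the
        # leftmost window containing it
        assert window[0] <= 100 < window[1]
        assert window == naive_anchor_window(starts, 345, 25)

    def test_tie_break_smallest_start(self, monomer_record, monomer):
        reads = self._reads_at(monomer, list(range(10)))
        assert anchor_window(reads, monomer_record) == (0, 25)

    def test_agrees_with_exhaustive_scan(self, monomer_record, monomer, rng):
        starts = [int(rng.integers(0, 280)) for _ in range(40)]
        reads = self._reads_at(monomer, starts)
        coords = [
            read_start_coordinate(r, monomer_record) for r in reads
        ]
        expected = naive_anchor_window(
            [c for c in coords if c is not None], len(monomer), 25
        )
        assert anchor_window(reads, monomer_record) == expected

    def test_reverse_strand_reads_anchor_at_leftmost_coordinate(
        self, monomer_record, monomer
    ):
        fwd = SequenceRecord(id="f", bases=monomer[40:120])
        rev = SequenceRecord(id="r", bases=revcomp(monomer[40:120]))
        assert read_start_coordinate(fwd, monomer_record) == 40
        assert read_start_coordinate(rev, monomer_record) == 40

    def test_no_anchors_error(self, monomer_record):
        rng = np.random.default_rng(3)
        # reads of pure homopolymer cannot produce a positive-score local hit
        reads = [SequenceRecord(id="r", bases=random_seq(rng, 30))]
        try:
            anchor_window([], monomer_record)
        except SatconnectError as exc:
            assert "no anchors" in str(exc)
        else:
            pytest.fail("expected a no-anchors error")
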