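"""Mapping, coverage stacking, RCI and candidate selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cleavemap import coverage as cov
from cleavemap import synthetic as syn
from conftest import brute_force_coverage


def _readset_from_seqs(seqs):
    width = max(len(s) for s in seqs)
    codes = np.full((len(seqs), width), syn.PAD, dtype=np.uint8)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = syn.encode(s)
    return syn.ReadSet(
        [f"r{i}" for i in range(len(seqs))],
        codes,
        np.array([len(s) for s in seqs], dtype=np.int64),
        truth={},
    )


class TestMapReads:
    def test_error_free_reads_map_to_truth(self):
        c = syn.make_construct(500, 2, 1, seed=21)
        frags = syn.digest(c, syn.default_rules(), 50, seed=21)
        reads = syn.simulate_library(
            frags, c, read_length=50, depth_target=100, background_fraction=0.0,
            error_rate=0.0, seed=21,
        )
        aln = cov.map_reads(reads, [c], max_mismatches=0)
        # reads shorter than the 20-mer seed (tiny terminal fragments) cannot
        # be seeded and are counted as unmapped
        n_seedable = int((reads.lengths >= cov.SEED_K).sum())
        assert len(aln) == n_seedable
        mapped = dict(zip(aln.read_ids, aln.starts))
        for rid, truth in reads.truth.items():
            if rid in mapped:
                assert mapped[rid] == truth.start

    def test_foreign_read_is_unmapped_and_counted(self):
        ref = syn.RNAConstruct("ref", "C" * 100)
        reads = _readset_from_seqs(["A" * 50])
        aln = cov.map_reads(reads, [ref], max_mismatches=2)
        assert len(aln) == 0 and aln.n_unmapped == 1

    def test_low_error_reads_mostly_map_to_truth(self):
        # binomial bound: P(>2 errors in 50 nt at 0.1%) is ~2e-5
        c = syn.make_construct(1000, 2, 1, seed=22)
        frags = syn.digest(c, syn.default_rules(), 100, seed=22)
        reads = syn.simulate_library(
            frags, c, read_length=50, depth_target=50, background_fraction=0.0,
            error_rate=0.001, seed=22,
        )
        assert len(reads) >= 1000
        aln = cov.map_reads(reads, [c], max_mismatches=2)
        mapped = dict(zip(aln.read_ids, aln.starts))
        seedable = {
            reads.ids[i] for i in range(len(reads)) if reads.lengths[i] >= cov.SEED_K
        }
        n_true = sum(
            1 for rid in seedable if mapped.get(rid) == reads.truth[rid].start
        )
        assert n_true / len(seedable) >= 0.99

    def test_duplicate_reference_ids_rejected(self):
        c = syn.make_construct(100, 0, 0, seed=1, construct_id="dup")
        with pytest.raises(ValueError, match="duplicate"):
            cov.map_reads(_readset_from_seqs(["A" * 30]), [c, c])

    def test_ambiguous_read_dropped(self):
        # identical 60-mer twice in one reference: an exact read hits both
        block = "ACGTTGCA" * 8  # 64 nt, aperiodic enough at 20-mer scale
        ref = syn.RNAConstruct("r", "CC" + block + "GGGG" + block + "CC")
        reads = _readset_from_seqs([block[:50]])
        aln = cov.map_reads(reads, [ref], max_mismatches=2)
        assert len(aln) == 0 and aln.n_unmapped == 1


class TestComputeCoverage:
    def _aln(self, ref_id, starts, lengths):
        return cov.AlignmentSet(
            [f"r{i}" for i in range(len(starts))],
            np.array([ref_id] * len(starts), dtype=object),
            np.array(starts, dtype=np.int64),
            np.array(lengths, dtype=np.int64),
        )

    def test_single_full_length_record(self):
        ref = syn.RNAConstruct("r", "A" * 10)
        profile = cov.compute_coverage(self._aln("r", [1], [10]), ref)
        assert np.array_equal(profile.c, np.ones(10, dtype=int))

    def test_two_overlapping_records(self):
        ref = syn.RNAConstruct("r", "A" * 10)
        profile = cov.compute_coverage(self._aln("r", [1, 4], [5, 7]), ref)
        expected = np.array([1, 1, 1, 2, 2, 1, 1, 1, 1, 1])
        assert np.array_equal(profile.c, expected)

    def test_out_of_bounds_record_rejected(self):
        ref = syn.RNAConstruct("r", "A" * 10)
        with pytest.raises(ValueError, match="beyond"):
            cov.compute_coverage(self._aln("r", [5], [7]), ref)

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(5, 200))
        n = int(rng.integers(1, 100))
        starts = rng.integers(1, L + 1, size=n)
        lengths = np.minimum(rng.integers(1, 60, size=n), L - starts + 1)
        ref = syn.RNAConstruct("r", "A" * L)
        profile = cov.compute_coverage(self._aln("r", starts, lengths), ref)
        assert np.array_equal(profile.c, brute_force_coverage(starts, lengths, L))


class TestRCI:
    def test_uniform_coverage_gives_unit_ratio(self):
        track = cov.relative_coverage_increase(cov.CoverageProfile("r", np.full(50, 7)))
        assert track.defined_mask.all()
        assert np.allclose(track.r, 1.0)

    def test_step_boundary_ratio(self):
        c = np.array([1000, 1000, 3000, 3000])
        track = cov.relative_coverage_increase(cov.CoverageProfile("r", c))
        assert track.r[1] == 3.0

    def test_zero_denominator_masked(self):
        c = np.array([5, 0, 8, 2])
        track = cov.relative_coverage_increase(cov.CoverageProfile("r", c))
        assert list(track.defined_mask) == [True, False, True]
        assert np.isnan(track.r[1])

    @given(st.integers(0, 10_000))
    def test_matches_naive_division(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 50, size=int(rng.integers(2, 300)))
        track = cov.relative_coverage_increase(cov.CoverageProfile("r", c))
        for n in range(len(c) - 1):
            if c[n] > 0:
                assert track.r[n] == c[n + 1] / c[n]
            else:
                assert not track.defined_mask[n]


class TestSelectCandidates:
    def _tp(self, ref_id, c):
        profile = cov.CoverageProfile(ref_id, np.asarray(c))
        return cov.relative_coverage_increase(profile), profile

    def test_single_step_selected(self):
        track, profile = self._tp("r", [600] * 10 + [1800] * 10)
        (cand,) = cov.select_candidates([track], [profile], min_coverage=500, top_n=1)
        assert (cand.reference_id, cand.position, cand.rci) == ("r", 11, 3.0)
        assert cand.coverage == 1800

    def test_all_below_min_coverage_is_empty(self):
        track, profile = self._tp("r", [100] * 10 + [300] * 10)
        assert cov.select_candidates([track], [profile], 500, 5) == []

    def test_top_n_larger_than_pool_returns_all(self, caplog):
        track, profile = self._tp("r", [600, 1200, 1200])
        with caplog.at_level("WARNING"):
            out = cov.select_candidates([track], [profile], 500, 99)
        assert len(out) == 2
        assert any("only" in r.message for r in caplog.records)

    def test_raising_min_coverage_never_adds_candidates(self):
        rng = np.random.default_rng(0)
        c = rng.integers(1, 2000, size=200)
        track, profile = self._tp("r", c)
        prev = None
        for mc in [0, 200, 500, 1000, 1500]:
            got = {
                (s.reference_id, s.position)
                for s in cov.select_candidates([track], [profile], mc, 10**9)
            }
            if prev is not None:
                assert got <= prev
            prev = got

    def test_reference_order_invariance(self):
        rng = np.random.default_rng(3)
        pairs = [self._tp(f"r{i}", rng.integers(400, 3000, size=100)) for i in range(4)]
        tracks = [t for t, _ in pairs]
        profiles = [p for _, p in pairs]
        a = cov.select_candidates(tracks, profiles, 500, 20)
        b = cov.select_candidates(tracks[::-1], profiles[::-1], 500, 20)
        assert a == b


class TestSAMInterop:
    def test_round_trip_preserves_candidates(self, tmp_path, small_config, small_run):
        refs, reads = small_run
        aln = cov.map_reads(reads, refs, small_config.max_mismatches)
        sam = tmp_path / "aln.sam"
        cov.write_sam(aln, reads, refs, str(sam))
        back = cov.read_sam(str(sam))
        for ref in refs:
            a = cov.compute_coverage(aln, ref)
            b = cov.compute_coverage(back, ref)
            assert np.array_equal(a.c, b.c)

    def test_indel_alignments_rejected(self, tmp_path):
        sam = tmp_path / "indel.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:r\tLN:100\n"
            "q1\t0\tr\t1\t60\t10M2I10M\t*\t0\t0\t" + "A" * 22 + "\t" + "I" * 22 + "\n"
        )
        with pytest.raises(ValueError, match="match-only"):
            cov.read_sam(str(sam))
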