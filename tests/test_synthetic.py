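"""Unit and property tests for the synthetic-data generators."""

import io
import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cleavemap import synthetic as syn

ALL_MOTIFS = (syn.PRIMARY_MOTIF, *syn.SUBOPTIMAL_MOTIFS)


def regex_scan(sequence: str, motif: str) -> list[int]:
    """Independent overlapping-occurrence oracle."""
    return [m.start() + 1 for m in re.finditer(f"(?={motif})", sequence)]


class TestMakeConstruct:
    def test_reporter_layout_matches_central_placement(self):
        # the 14-mer reporter design: one primary tetrad centred in poly-A
        c = syn.make_construct(14, 1, 0, seed=1, placement="central", fill="A")
        assert c.sequence == "AAAAATACAAAAAA"
        assert [(s.position, s.motif, s.site_class) for s in c.planted_sites] == [
            (6, "TACA", "primary")
        ]

    @pytest.mark.parametrize("seed", [0, 1, 7, 42])
    def test_truth_records_every_occurrence(self, seed):
        c = syn.make_construct(100, 0, 0, seed=seed)
        expected = sorted(
            (p, m) for m in ALL_MOTIFS for p in regex_scan(c.sequence, m)
        )
        assert sorted((s.position, s.motif) for s in c.planted_sites) == expected

    def test_deterministic_under_fixed_seed(self):
        a = syn.make_construct(500, 2, 1, seed=3)
        b = syn.make_construct(500, 2, 1, seed=3)
        assert a.sequence == b.sequence and a.planted_sites == b.planted_sites

    def test_planted_sites_match_sequence_and_are_increasing(self):
        c = syn.make_construct(1000, 3, 2, seed=5, min_spacing=30)
        positions = [s.position for s in c.planted_sites]
        assert positions == sorted(positions) and len(set(positions)) == len(positions)
        for s in c.planted_sites:
            assert c.sequence[s.position - 1 : s.position + 3] == s.motif

    def test_avoid_incidental_leaves_only_deliberate_sites(self):
        c = syn.make_construct(
            800, 3, 1, seed=2, avoid_incidental=True, min_spacing=40, end_margin=40
        )
        assert len(c.sites_of_class("primary")) == 3
        assert len(c.sites_of_class("suboptimal")) == 3  # one per alternate tetrad
        assert {s.motif for s in c.sites_of_class("suboptimal")} == set(syn.SUBOPTIMAL_MOTIFS)

    def test_impossible_placement_raises(self):
        with pytest.raises(syn.PlacementError):
            syn.make_construct(50, 13, 0, seed=1)  # 13 sites * 4 nt > 50

    def test_invalid_planted_site_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            syn.RNAConstruct("x", "ACGTACGT", [syn.PlantedSite(1, "TACA", "primary")])


class TestDigest:
    def test_k_cuts_make_k_plus_one_fragments(self):
        seq = "A" * 20 + "TACA" + "A" * 30 + "TACA" + "A" * 20
        c = syn.RNAConstruct("c", seq, syn._truth_sites(seq))
        rules = [syn.CleavageRule("TACA", 1, 1.0)]
        frags = syn.digest(c, rules, n_molecules=1, seed=1)
        assert len(frags.fragments) == 3

    def test_zero_efficiency_leaves_molecules_intact(self):
        c = syn.make_construct(300, 2, 1, seed=4)
        rules = [syn.CleavageRule(m, 1, 0.0) for m in ALL_MOTIFS]
        frags = syn.digest(c, rules, n_molecules=5, seed=1)
        assert len(frags.fragments) == 5
        for f in frags.fragments:
            assert (f.start, f.end) == (1, len(c))
            assert (f.left_boundary, f.right_boundary) == ("terminus", "terminus")

    def test_cut_fraction_matches_binomial(self):
        # one site, efficiency 0.5: fraction cut within 3 standard errors
        seq = "G" * 100 + "TACA" + "G" * 100
        c = syn.RNAConstruct("c", seq, syn._truth_sites(seq))
        n = 10_000
        frags = syn.digest(c, [syn.CleavageRule("TACA", 1, 0.5)], n, seed=8)
        n_cut = sum(1 for f in frags.fragments if f.right_boundary == "cut")
        se = (0.5 * 0.5 / n) ** 0.5
        assert abs(n_cut / n - 0.5) < 3 * se

    @pytest.mark.parametrize("seed", range(5))
    def test_fragments_tile_construct(self, seed):
        c = syn.make_construct(400, 2, 1, seed=seed)
        frags = syn.digest(c, syn.default_rules(), n_molecules=20, seed=seed)
        for frag_list in frags.by_molecule().values():
            rebuilt = "".join(c.sequence[f.start - 1 : f.end] for f in frag_list)
            assert rebuilt == c.sequence

    def test_cut_position_law(self):
        # every cut-started fragment begins cut_offset bases into a motif (on
        # the first A of ACA for U^ACA)
        c = syn.make_construct(600, 3, 1, seed=9)
        frags = syn.digest(c, syn.default_rules(), n_molecules=30, seed=9)
        site_positions = {s.position for s in c.planted_sites}
        for f in frags.fragments:
            if f.left_boundary == "cut":
                assert f.start - 1 in site_positions

    def test_duplicate_rule_motifs_rejected(self):
        c = syn.make_construct(200, 1, 0, seed=1)
        with pytest.raises(ValueError, match="distinct"):
            syn.digest(c, [syn.CleavageRule("TACA"), syn.CleavageRule("UACA")], 1, 1)


class TestSimulateLibrary:
    def _whole_molecule_fragments(self, c, n=50):
        return syn.FragmentSet(
            c.id,
            [syn.Fragment(1, len(c), "terminus", "terminus", m) for m in range(n)],
            n,
        )

    def test_error_free_reads_are_construct_prefix(self):
        c = syn.make_construct(200, 0, 0, seed=2)
        frags = self._whole_molecule_fragments(c)
        reads = syn.simulate_library(
            frags, c, read_length=50, depth_target=20, background_fraction=0.0,
            error_rate=0.0, seed=3,
        )
        for i in range(len(reads)):
            assert reads.sequence(i) == c.sequence[:50]

    def test_fastq_bytes_deterministic(self):
        c = syn.make_construct(200, 1, 0, seed=2)
        frags = syn.digest(c, syn.default_rules(), 20, seed=2)
        kw = dict(read_length=50, depth_target=30, background_fraction=0.3,
                  error_rate=0.001, seed=5)
        a = syn.fastq_bytes(syn.simulate_library(frags, c, **kw))
        b = syn.fastq_bytes(syn.simulate_library(frags, c, **kw))
        assert a == b and a.startswith(b"@")

    def test_depth_and_step_around_cuts(self):
        # oracle: stack sampled read intervals directly from truth, no mapping
        c = syn.make_construct(
            1000, 2, 0, seed=6, min_spacing=120, end_margin=80, avoid_incidental=True
        )
        frags = syn.digest(c, [syn.CleavageRule("TACA", 1, 0.8)], 300, seed=6)
        reads = syn.simulate_library(
            frags, c, read_length=50, depth_target=2000, background_fraction=0.3,
            error_rate=0.0, seed=6,
        )
        cov = np.zeros(len(c) + 1)
        lengths = reads.lengths
        for i, rid in enumerate(reads.ids):
            t = reads.truth[rid]
            cov[t.start - 1] += 1
            cov[t.start - 1 + int(lengths[i])] -= 1
        cov = np.cumsum(cov[:-1])
        assert abs(cov.mean() - 2000) / 2000 < 0.10
        for site in c.sites_of_class("primary"):
            cut = site.position + 1
            down = cov[cut - 1 : cut + 19].min()
            up = cov[cut - 2]
            assert down > up

    def test_empty_fragment_set_rejected(self):
        c = syn.make_construct(100, 0, 0, seed=1)
        with pytest.raises(ValueError, match="empty"):
            syn.simulate_library(syn.FragmentSet(c.id, [], 0), c)


class TestSimulateFluorescence:
    def test_zero_rate_is_flat_baseline(self):
        s = syn.simulate_fluorescence("x", "none", True, "no_enzyme", noise_sd=0.0)
        assert np.allclose(s.intensities, 100.0)

    def test_rnase_on_pure_dna_is_flat(self):
        s = syn.simulate_fluorescence("D-13-AAA", "none", False, "rnase_a", noise_sd=0.0)
        assert np.allclose(s.intensities, 100.0)

    def test_fast_rate_reaches_plateau(self):
        s = syn.simulate_fluorescence(
            "x", "primary", True, "enzyme_low", k_fast=0.5, t_max=120, noise_sd=0.0
        )
        assert abs(s.intensities[0, -1] - 1000.0) / 1000.0 < 0.01

    @pytest.mark.parametrize(
        "motif,cond,expected_k",
        [
            ("primary", "enzyme_low", 0.5),
            ("primary", "enzyme_high", 0.5),
            ("suboptimal", "enzyme_low", 0.0),
            ("suboptimal", "enzyme_high", 0.05),
            ("none", "enzyme_high", 0.0),
            ("none", "rnase_a", 0.5),
        ],
    )
    def test_condition_logic(self, motif, cond, expected_k):
        assert syn.dequenching_rate(motif, True, cond, 0.5, 0.05) == expected_k

    def test_csv_round_trip(self):
        series = [
            syn.simulate_fluorescence("s1", "primary", True, c, seed=4)
            for c in ("enzyme_low", "no_enzyme")
        ]
        buf = io.StringIO()
        syn.write_fluor_csv(series, buf)
        buf.seek(0)
        back = syn.read_fluor_csv(buf)
        by_cond = {s.condition: s for s in back}
        for s in series:
            r = by_cond[s.condition]
            assert np.array_equal(r.times, s.times)
            assert np.allclose(r.intensities, s.intensities, atol=1e-4)


@given(st.integers(0, 10_000))
def test_truth_completeness_property(seed):
    """Every tetrad occurrence in a generated construct appears in the truth."""
    c = syn.make_construct(120, 1, 0, seed=seed)
    recorded = {(s.position, s.motif) for s in c.planted_sites}
    for motif in ALL_MOTIFS:
        for pos in regex_scan(c.sequence, motif):
            assert (pos, motif) in recorded
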