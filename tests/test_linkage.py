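"""Transcription-unit calling from spanning read pairs."""

import numpy as np
import pytest

from punctless.coverage import AlignedFragment, CoverageProfile, compute_coverage
from punctless.genome import CircularGenome, GeneFeature
from punctless.linkage import (
    LinkageEvidence,
    TranscriptionUnit,
    call_units,
    circular_overlap,
    classify_units,
    collect_linkage,
)
from punctless.simulate import default_program, simulate_reads

TOY_FEATS = [
    GeneFeature("CytB", "PCG", "H", 100, 400),
    GeneFeature("ND6", "PCG", "H", 420, 600),
    GeneFeature("COIII", "PCG", "L", 700, 900),
]


def toy_genome():
    return CircularGenome("toy", "A" * 1000)


class TestCircularOverlap:
    @pytest.mark.parametrize("a,b,L,expected", [
        ((1, 10), (5, 20), 100, 6),
        ((1, 10), (11, 20), 100, 0),
        ((95, 5), (1, 10), 100, 5),      # a wraps
        ((95, 5), (98, 2), 100, 5),      # both wrap
        ((10, 90), (85, 15), 100, 6),    # two disjoint arcs: the larger one
    ])
    def test_cases(self, a, b, L, expected):
        assert circular_overlap(a, b, L) == expected
        assert circular_overlap(b, a, L) == expected


class TestCollectLinkage:
    def test_no_spanning_fragments(self):
        frags = [AlignedFragment((150, 199), (250, 299), "H")]
        out = collect_linkage(frags, TOY_FEATS, toy_genome())
        assert all(e.n_spanning == 0 for e in out)

    def test_one_spanning_pair(self):
        frags = [AlignedFragment((350, 399), (420, 469), "H")]
        out = collect_linkage(frags, TOY_FEATS, toy_genome())
        ev = {(e.gene_a, e.gene_b): e.n_spanning for e in out}
        assert ev[("CytB", "ND6")] == 1

    def test_single_read_crossing_igr(self):
        frags = [AlignedFragment((395, 425), None, "H")]
        out = collect_linkage(frags, TOY_FEATS, toy_genome())
        ev = {(e.gene_a, e.gene_b): e.n_spanning for e in out}
        assert ev[("CytB", "ND6")] == 1

    def test_wrong_strand_not_counted(self):
        frags = [AlignedFragment((350, 399), (420, 469), "L")]
        out = collect_linkage(frags, TOY_FEATS, toy_genome())
        assert all(e.n_spanning == 0 for e in out)

    def test_simulation_links_exactly_the_configured_units(self, program_a):
        """Spanning pairs appear for every within-unit adjacency and only there."""
        program, genome, feats = program_a
        program = __import__("copy").deepcopy(program)
        program.readthrough_fraction = 0.0
        rs = simulate_reads(program, genome, feats, depth=30, seed=42)
        prof = compute_coverage(rs.fragments, genome)
        linkage = collect_linkage(rs.fragments, feats, genome, prof)
        expected_linked = {("CytB", "ND6"), ("ND3", "ND4L"), ("ND4L", "mtMutS"),
                           ("ND2", "ND5"), ("ND5", "ND4"),
                           ("ATP6", "ATP8"), ("ATP8", "COII")}
        linked = {(e.gene_a, e.gene_b) for e in linkage if e.n_spanning > 0}
        assert linked == expected_linked


class TestCallUnits:
    def _linkage(self, features, spanning, depth=10.0):
        out = []
        from punctless.linkage import adjacent_pairs

        for fa, fb in adjacent_pairs(features):
            if fa.strand != fb.strand:
                continue
            n = spanning.get((fa.name, fb.name), 0)
            out.append(LinkageEvidence(fa.name, fb.name, fa.strand, n,
                                       depth, depth, depth))
        return out

    def test_zero_linkage_all_monocistronic(self):
        linkage = self._linkage(TOY_FEATS, {})
        res = call_units(linkage, TOY_FEATS)
        assert sorted(u.genes for u in res.units) == [("COIII",), ("CytB",), ("ND6",)]

    def test_joined_unit_in_transcript_order(self):
        linkage = self._linkage(TOY_FEATS, {("CytB", "ND6"): 5})
        res = call_units(linkage, TOY_FEATS)
        assert (("CytB", "ND6") in [u.genes for u in res.units])

    def test_precursor_demotion(self):
        feats = [GeneFeature("a", "PCG", "H", 100, 400),
                 GeneFeature("b", "rRNA", "H", 420, 600)]
        linkage = [LinkageEvidence("a", "b", "H", 1, 0.0, 2.0, 120.0),
                   LinkageEvidence("b", "a", "H", 0, 0.0, 120.0, 2.0)]
        res = call_units(linkage, feats)
        assert sorted(u.genes for u in res.units) == [("a",), ("b",)]
        assert len(res.demoted) == 1 and res.demoted[0].n_spanning == 1

    def test_strong_linkage_survives_depth_ratio(self):
        feats = [GeneFeature("a", "PCG", "H", 100, 400),
                 GeneFeature("b", "rRNA", "H", 420, 600)]
        linkage = [LinkageEvidence("a", "b", "H", 80, 50.0, 2.0, 120.0),
                   LinkageEvidence("b", "a", "H", 0, 0.0, 120.0, 2.0)]
        res = call_units(linkage, feats)
        assert (("a", "b") in [u.genes for u in res.units])

    def test_trna_is_always_a_boundary(self):
        feats = [GeneFeature("trnM", "tRNA", "L", 100, 170),
                 GeneFeature("COIII", "PCG", "L", 200, 400)]
        linkage = [LinkageEvidence("trnM", "COIII", "L", 9, 5.0, 5.0, 5.0),
                   LinkageEvidence("COIII", "trnM", "L", 9, 5.0, 5.0, 5.0)]
        res = call_units(linkage, feats)
        assert sorted(u.genes for u in res.units) == [("COIII",), ("trnM",)]

    def test_deterministic_under_fragment_order(self, program_a):
        program, genome, feats = program_a
        rs = simulate_reads(program, genome, feats, depth=10, seed=9)
        prof = compute_coverage(rs.fragments, genome)
        frags = list(rs.fragments)
        rng = np.random.default_rng(0)
        rng.shuffle(frags)
        l1 = collect_linkage(rs.fragments, feats, genome, prof)
        l2 = collect_linkage(frags, feats, genome, prof)
        assert call_units(l1, feats).units == call_units(l2, feats).units

    def test_partition_property(self, program_a):
        """Every annotated gene lands in exactly one called unit."""
        program, genome, feats = program_a
        rs = simulate_reads(program, genome, feats, depth=15, seed=21)
        prof = compute_coverage(rs.fragments, genome)
        res = call_units(collect_linkage(rs.fragments, feats, genome, prof), feats)
        all_genes = [g for u in res.units for g in u.genes]
        assert sorted(all_genes) == sorted(f.name for f in feats)


class TestClassifyUnits:
    def test_study_truth_unit_set(self):
        units = [
            TranscriptionUnit(("COI",), "H", n_cistrons=1),
            TranscriptionUnit(("CytB", "ND6"), "H", n_cistrons=2),
            TranscriptionUnit(("ND3", "ND4L", "mtMutS"), "H", n_cistrons=3),
            TranscriptionUnit(("ND2", "ND5", "ND4"), "H", n_cistrons=3),
            TranscriptionUnit(("COII", "ATP8", "ATP6"), "L", n_cistrons=3),
            TranscriptionUnit(("ND1",), "H", n_cistrons=1),
            TranscriptionUnit(("COIII",), "L", n_cistrons=1),
        ]
        s = classify_units(units)
        assert s["n_polycistronic"] == 4
        assert s["pcgs_in_polycistrons"] == 11
        assert s["n_monocistronic"] == 3

    def test_all_monocistronic(self):
        units = [TranscriptionUnit((f"g{i}",), "H", n_cistrons=1) for i in range(5)]
        assert classify_units(units)["n_polycistronic"] == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_random_partitions_match_tally_oracle(self, seed):
        rng = np.random.default_rng(seed)
        units = []
        for i in range(int(rng.integers(2, 8))):
            n = int(rng.integers(1, 4))
            units.append(TranscriptionUnit(tuple(f"u{i}g{j}" for j in range(n)),
                                           "H", n_cistrons=n))
        s = classify_units(units)
        assert s["n_monocistronic"] == sum(1 for u in units if u.n_cistrons == 1)
        assert s["n_polycistronic"] == sum(1 for u in units if u.n_cistrons >= 2)
        assert s["pcgs_in_polycistrons"] == sum(
            u.n_cistrons for u in units if u.n_cistrons >= 2)
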