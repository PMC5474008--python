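"""Junction/RACE end resolution, poly(A) soft-clips, APA clustering, UTRs, lncRNAs."""

import numpy as np
import pytest

from punctless.coverage import AlignedFragment, revcomp
from punctless.ends import (
    EndResolutionError,
    TranscriptEnd,
    annotate_utrs,
    call_polya_sites,
    classify_lncrna,
    cluster_apa,
    interpret_race_read,
    longest_orf_codons,
    resolve_crtpcr_junction,
)
from punctless.genome import CircularGenome, GeneFeature
from punctless.linkage import TranscriptionUnit

from conftest import make_toy_genome

ADAPTER = "GACTCGAGTCGACATCG"


@pytest.fixture()
def toy(rng):
    # sentinels keep the constructed ends canonical (no adjacent genomic A)
    return make_toy_genome(rng, 600, forbid_polya_at=(401, 94, 99, 431))


class TestJunctionResolution:
    def test_constructed_junction(self, toy):
        read = toy.fetch(380, 400) + "A" * 30 + toy.fetch(95, 130)
        three, five = resolve_crtpcr_junction(read, toy)
        assert (three.position, five.position) == (400, 95)
        assert three.polya_len == 30 and three.strand == "H"

    def test_l_strand_junction(self, toy):
        # transcript on L: sense sequence is the reverse complement
        read = revcomp(toy.fetch(100, 130)) + "A" * 25 + revcomp(toy.fetch(400, 430))
        three, five = resolve_crtpcr_junction(read, toy)
        assert three.strand == "L" and five.strand == "L"
        assert (three.position, five.position) == (100, 430)

    def test_no_polya_run(self, toy):
        with pytest.raises(EndResolutionError, match="no junction"):
            resolve_crtpcr_junction(toy.fetch(50, 150).replace("A", "C"), toy)

    def test_ambiguous_anchor(self, rng):
        block = "".join(rng.choice(list("CGT"), size=60))
        seq = block + "".join(rng.choice(list("CGT"), size=100)) + block
        genome = CircularGenome("dup", seq)
        read = block[-20:] + "A" * 20 + block[:20]
        with pytest.raises(EndResolutionError, match="ambiguous"):
            resolve_crtpcr_junction(read, genome)

    def test_strand_conflict(self, toy):
        read = toy.fetch(380, 400) + "A" * 30 + revcomp(toy.fetch(200, 235))
        with pytest.raises(EndResolutionError, match="strand conflict"):
            resolve_crtpcr_junction(read, toy)

    def test_exactness_over_many_random_constructions(self, reference):
        """Position-exact recovery for 1000 random junctions with unique anchors."""
        genome, _ = reference
        rng = np.random.default_rng(99)
        L = genome.length
        n_ok = n_tested = 0
        while n_tested < 1000:
            t3 = int(rng.integers(1, L + 1))
            t5 = int(rng.integers(1, L + 1))
            # truth must be canonical: no genomic A adjacent to either end
            if genome.sequence[t3 % L] == "A" or genome.sequence[(t5 - 2) % L] == "A":
                continue
            up_start = ((t3 - 36) % L) + 1
            down_end = ((t5 + 34) % L) + 1
            read = genome.fetch(up_start, t3) + "A" * 30 + genome.fetch(t5, down_end)
            n_tested += 1
            try:
                three, five = resolve_crtpcr_junction(read, genome)
            except EndResolutionError:
                continue  # non-unique anchor draws are excluded by contract
            assert (three.position, five.position) == (t3, t5)
            n_ok += 1
        assert n_ok > 950  # anchor collisions are rare on an 18.7 kb genome


class TestRace:
    def test_five_prime(self, toy):
        read = ADAPTER + toy.fetch(100, 160)
        end = interpret_race_read(read, toy, ADAPTER, side="five")
        assert (end.position, end.kind, end.strand) == (100, "five_prime", "H")

    def test_three_prime_with_tail(self, toy):
        read = toy.fetch(340, 400) + "A" * 20 + ADAPTER
        end = interpret_race_read(read, toy, ADAPTER, side="three")
        assert (end.position, end.kind, end.polya_len) == (400, "three_prime", 20)

    def test_no_adapter(self, toy):
        with pytest.raises(EndResolutionError, match="no adapter"):
            interpret_race_read(toy.fetch(100, 160), toy, ADAPTER, side="five")

    def test_complement_strand_orientation(self, toy):
        read = ADAPTER + revcomp(toy.fetch(100, 160))
        end = interpret_race_read(read, toy, ADAPTER, side="five")
        assert (end.position, end.strand) == (160, "L")


class TestPolyaSoftclips:
    def test_no_clips_empty(self):
        frags = [AlignedFragment((1, 50), None, "H")]
        assert call_polya_sites(frags, None) == []

    def test_aggregation(self):
        frags = [AlignedFragment((451, 500), None, "H", clip3="A" * 10)
                 for _ in range(5)]
        ends = call_polya_sites(frags, None)
        assert len(ends) == 1
        e = ends[0]
        assert (e.position, e.support, e.polya_len) == (500, 5, 10)

    def test_low_a_fraction_rejected(self):
        frags = [AlignedFragment((451, 500), None, "H", clip3="AAGAA")]
        assert call_polya_sites(frags, None) == []  # 0.8 < 0.9


class TestClusterApa:
    GENE = GeneFeature("g", "PCG", "H", 901, 1800)

    def _ends(self, positions, supports=None):
        supports = supports or [1] * len(positions)
        return [TranscriptEnd(p, "three_prime", "H", "crtpcr", support=s)
                for p, s in zip(positions, supports)]

    def test_within_tolerance_single_cluster(self, rng):
        genome = make_toy_genome(rng, 2000)
        sites = cluster_apa(self._ends([1000, 1001, 1002]), genome, self.GENE)
        assert len(sites) == 1
        assert sites[0].member_positions == (1000, 1001, 1002)

    def test_order_invariance_and_conservation(self, rng):
        genome = make_toy_genome(rng, 2000)
        pos = sorted(int(p) for p in rng.integers(950, 1750, size=30))
        shuffled = list(pos)
        rng.shuffle(shuffled)
        a = cluster_apa(self._ends(pos), genome, self.GENE)
        b = cluster_apa(self._ends(shuffled), genome, self.GENE)
        assert [s.representative_position for s in a] == \
            [s.representative_position for s in b]
        assert sum(len(s.member_positions) for s in a) == len(pos)

    @pytest.mark.parametrize("seed", range(5))
    def test_in_frame_matches_codon_enumeration(self, seed, rng):
        genome = make_toy_genome(rng, 2000)
        r = np.random.default_rng(seed)
        start = int(r.integers(100, 500))
        gene = GeneFeature("g", "PCG", "H", start, start + 899)
        boundaries = {start + 2 + 3 * k for k in range(300)}  # codon 3rd bases
        for pos in (int(p) for p in r.integers(start, start + 900, size=40)):
            sites = cluster_apa(self._ends([pos]), genome, gene)
            assert sites[0].in_frame == (pos in boundaries)

    def test_off_by_one_frame(self, rng):
        genome = make_toy_genome(rng, 2000)
        # an end 3n-1 bases into the CDS sits mid-codon
        pos = self.GENE.start + 3 * 30 - 2
        assert not cluster_apa(self._ends([pos]), genome, self.GENE)[0].in_frame

    def test_mixed_strands_rejected(self, rng):
        genome = make_toy_genome(rng, 2000)
        ends = self._ends([1000]) + [TranscriptEnd(1100, "three_prime", "L", "crtpcr")]
        with pytest.raises(Exception, match="single strand"):
            cluster_apa(ends, genome, self.GENE)

    def test_recovers_configured_apa_sites(self, program_a):
        """All six configured alternative mtMutS sites come back as clusters."""
        from punctless.simulate import MTMUTS_APA_SITES, simulate_junction_reads

        program, genome, feats = program_a
        reads, truth = simulate_junction_reads(program, genome, feats,
                                               n_per_end=3, seed=17)
        gene = next(f for f in feats if f.name == "mtMutS")
        threes = []
        for _, seq in reads:
            three, _ = resolve_crtpcr_junction(seq, genome)
            if gene.start <= three.position <= gene.end and three.strand == "H":
                threes.append(three)
        sites = cluster_apa(threes, genome, gene)
        reps = {s.representative_position for s in sites}
        assert {p for p, _ in MTMUTS_APA_SITES} <= reps
        assert all(not s.in_frame for s in sites if s.representative_position != 9135)


class TestUtrs:
    FEATS = [GeneFeature("a", "PCG", "H", 101, 400),
             GeneFeature("b", "PCG", "H", 421, 700)]
    UNIT = TranscriptionUnit(("a", "b"), "H", n_cistrons=2)

    def _run(self, genome, fives=(), threes=()):
        ends = [TranscriptEnd(p, "five_prime", "H", "crtpcr") for p in fives] + \
               [TranscriptEnd(p, "three_prime", "H", "crtpcr") for p in threes]
        return annotate_utrs([self.UNIT], ends, self.FEATS, genome)

    def test_exact_start_gives_zero_utr(self, rng):
        genome = make_toy_genome(rng, 1000)
        (rec,) = self._run(genome, fives=[101], threes=[744])
        assert (rec.utr5_len, rec.utr3_len) == (0, 44)

    def test_truncated_five_prime(self, rng):
        genome = make_toy_genome(rng, 1000)
        (rec,) = self._run(genome, fives=[107])
        assert rec.truncated5 and rec.truncated5_offset == 6
        assert rec.utr5_len is None

    def test_alternative_five_ends_give_multiple_records(self, rng):
        genome = make_toy_genome(rng, 1000)
        recs = self._run(genome, fives=[98, 101], threes=[700])
        assert len(recs) == 2
        assert {r.utr5_len for r in recs} == {3, 0}

    def test_l_strand_unit(self, rng):
        genome = make_toy_genome(rng, 1000)
        feats = [GeneFeature("x", "PCG", "L", 421, 700),
                 GeneFeature("y", "PCG", "L", 101, 400)]
        unit = TranscriptionUnit(("x", "y"), "L", n_cistrons=2)
        ends = [TranscriptEnd(703, "five_prime", "L", "crtpcr"),
                TranscriptEnd(91, "three_prime", "L", "crtpcr")]
        (rec,) = annotate_utrs([unit], ends, feats, genome)
        assert (rec.utr5_len, rec.utr3_len) == (3, 10)


class TestLncRna:
    def _features(self):
        return [GeneFeature("ATP6", "PCG", "L", 900, 1600)]

    def _genome_without_orfs(self, rng, length=2000):
        # alternate C/T in the candidate window so no ATG can open a long ORF
        genome = make_toy_genome(rng, length)
        seq = list(genome.sequence)
        seq[999:1211] = list("CT" * 106)
        return CircularGenome("toy", "".join(seq))

    def test_positive_call(self, rng):
        genome = self._genome_without_orfs(rng)
        call = classify_lncrna((1000, 1210, "H"), True, genome, self._features())
        assert call is not None
        assert call.antisense_of == "ATP6" and call.length == 211

    def test_short_interval_rejected(self, rng):
        genome = self._genome_without_orfs(rng)
        assert classify_lncrna((1000, 1150, "H"), True, genome, self._features()) is None

    def test_unpolyadenylated_rejected(self, rng):
        genome = self._genome_without_orfs(rng)
        assert classify_lncrna((1000, 1210, "H"), False, genome, self._features()) is None

    def test_constructed_orf_rejected(self, rng):
        genome = self._genome_without_orfs(rng)
        seq = list(genome.sequence)
        orf = "ATG" + "GGC" * 60 + "TAA"
        seq[1010 : 1010 + len(orf)] = list(orf)
        genome2 = CircularGenome("toy", "".join(seq))
        assert classify_lncrna((1000, 1210, "H"), True, genome2, self._features()) is None

    def test_no_antisense_gene_rejected(self, rng):
        genome = self._genome_without_orfs(rng)
        feats = [GeneFeature("far", "PCG", "L", 1700, 1900)]
        assert classify_lncrna((1000, 1210, "H"), True, genome, feats) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_orf_scanner_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=400))

        def brute(s):
            best = 0
            for i in range(len(s) - 2):
                if s[i : i + 3] != "ATG":
                    continue
                j = i
                while j + 3 <= len(s):
                    if s[j : j + 3] in ("TAA", "TAG") and j > i:
                        break
                    j += 3
                best = max(best, (j - i) // 3)
            return best

        assert longest_orf_codons(seq) == brute(seq)
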