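"""Hairpin enumeration, shared IGR motifs and control-region prediction."""

import numpy as np
import pytest

from punctless.coverage import CoverageProfile, revcomp
from punctless.genome import CircularGenome, GeneFeature, IntergenicRegion
from punctless.motifs import (
    _PAIRS,
    find_hairpins,
    predict_control_region,
    shared_igr_motifs,
)


def brute_force_hairpins(seq, min_stem=6, loop_min=3, loop_max=30):
    """Exhaustive oracle: enumerate every (start, stem, loop) triple, check
    pairing directly, keep only outward-maximal stems, then per start the
    longest stem.  Returns the {(1-based start, stem_len)} set."""
    seq = seq.upper()
    n = len(seq)
    best: dict[int, int] = {}
    for s0 in range(n):
        for loop in range(loop_min, loop_max + 1):
            for stem in range(min_stem, (n - loop) // 2 + 1):
                right_end = s0 + 2 * stem + loop  # exclusive
                if right_end > n:
                    break
                inner_i = s0 + stem - 1
                inner_j = s0 + stem + loop
                paired = all(
                    (seq[inner_i - k], seq[inner_j + k]) in _PAIRS
                    for k in range(stem)
                )
                if not paired:
                    continue
                extendable = (
                    s0 - 1 >= 0 and right_end < n
                    and (seq[s0 - 1], seq[right_end]) in _PAIRS
                )
                if extendable:
                    continue
                best[s0] = max(best.get(s0, 0), stem)
    return {(s + 1, stem) for s, stem in best.items()}


class TestFindHairpins:
    def test_homopolymer_has_none(self):
        assert find_hairpins("A" * 20) == []

    def test_constructed_inverted_repeat(self):
        seq = "GGGCGC" + "TTTT" + "GCGCCC"
        hps = find_hairpins(seq)
        assert len(hps) == 1
        hp = hps[0]
        assert (hp.start, hp.stem_len, hp.loop_len) == (1, 6, 4)

    def test_gu_wobble_pairs_count(self):
        # stem of G:T pairs only
        seq = "GGGGGG" + "CCC" + "TTTTTT"
        hps = find_hairpins(seq, min_stem=6)
        assert len(hps) == 1 and hps[0].stem_len == 6

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 61))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        got = {(h.start, h.stem_len) for h in find_hairpins(seq)}
        assert got == brute_force_hairpins(seq)


def brute_force_shared_kmers(seqs, k_lo, k_hi, min_igrs):
    """Set-intersection oracle over all k-mer sets (no redundancy pruning)."""
    out = {}
    for k in range(k_lo, k_hi + 1):
        counts = {}
        for name, s in seqs.items():
            for kmer in {s[i : i + k] for i in range(len(s) - k + 1)}:
                counts.setdefault(kmer, set()).add(name)
        for kmer, names in counts.items():
            if len(names) >= min_igrs:
                out[kmer] = frozenset(names)
    return out


class TestSharedMotifs:
    def test_disjoint_compositions_share_nothing(self):
        seqs = {"a": "AC" * 30, "b": "GT" * 30, "c": "AG" * 30, "d": "CT" * 30}
        assert shared_igr_motifs(seqs, (8, 15), min_igrs=3) == []

    def test_planted_motif_recovered(self, rng):
        motif = "GACTAGGCTAT"
        seqs = {}
        for i in range(4):
            s = "".join(rng.choice(list("ACGT"), size=80))
            if i < 3:
                s = s[:30] + motif + s[41:]
            seqs[f"igr{i}"] = s
        hits = shared_igr_motifs(seqs, (8, 15), min_igrs=3)
        top = [h for h in hits if h.k == 11]
        assert any(h.kmer == motif and set(h.igr_names) == {"igr0", "igr1", "igr2"}
                   for h in top)

    @pytest.mark.parametrize("seed", range(8))
    def test_against_intersection_oracle(self, seed):
        """Every reported hit is in the oracle set; every maximal oracle hit
        is reported (shorter substrings with identical IGR sets are pruned)."""
        rng = np.random.default_rng(seed)
        seqs = {f"i{j}": "".join(rng.choice(list("ACGT"), size=60)) for j in range(4)}
        # plant partial sharing to make the instance non-trivial
        shared = "".join(rng.choice(list("ACGT"), size=10))
        for j in range(3):
            s = seqs[f"i{j}"]
            seqs[f"i{j}"] = s[:20] + shared + s[30:]
        hits = shared_igr_motifs(seqs, (8, 12), min_igrs=3)
        oracle = brute_force_shared_kmers(seqs, 8, 12, 3)
        for h in hits:
            assert oracle[h.kmer] == frozenset(h.igr_names)
        reported = {h.kmer for h in hits}
        for kmer, names in oracle.items():
            covered = kmer in reported or any(
                kmer in h.kmer and frozenset(h.igr_names) == names for h in hits)
            assert covered

    def test_input_order_invariance(self, rng):
        seqs = {f"i{j}": "".join(rng.choice(list("ACGT"), size=70)) for j in range(4)}
        motif = "TTGACCATGGA"
        for j in (0, 1, 3):
            seqs[f"i{j}"] = seqs[f"i{j}"][:10] + motif + seqs[f"i{j}"][21:]
        a = shared_igr_motifs(seqs, (8, 15), 3)
        b = shared_igr_motifs(dict(reversed(list(seqs.items()))), (8, 15), 3)
        assert [(h.kmer, h.igr_names) for h in a] == [(h.kmer, h.igr_names) for h in b]

    def test_no_substring_redundancy(self, rng):
        seqs = {f"i{j}": "".join(rng.choice(list("ACGT"), size=70)) for j in range(4)}
        motif = "TTGACCATGGA"
        for j in (0, 1, 3):
            seqs[f"i{j}"] = seqs[f"i{j}"][:10] + motif + seqs[f"i{j}"][21:]
        hits = shared_igr_motifs(seqs, (8, 15), 3)
        for h in hits:
            for other in hits:
                if h is other:
                    continue
                assert not (h.kmer in other.kmer and
                            set(h.igr_names) == set(other.igr_names))


class TestControlRegion:
    def _setup(self, rng, plant=True):
        L = 3000
        seq = rng.choice(list("ACGT"), size=L)
        motif = "GACTAGGCTAT"
        arm = "GGATCGTTCAAC"
        igrs = [
            IntergenicRegion("g1", "g2", 501, 620, 120),
            IntergenicRegion("g2", "g3", 1501, 1560, 60),
            IntergenicRegion("g3", "g1", 2501, 2560, 60),
        ]
        if plant:
            seq[510:521] = list(motif)
            seq[540 : 540 + 30] = list(arm + "TTTATA" + revcomp(arm))
            seq[1510:1521] = list(motif)
            seq[2510:2521] = list(motif)
        genome = CircularGenome("t", "".join(seq))
        feats = [GeneFeature("g1", "PCG", "L", 100, 500),
                 GeneFeature("g2", "PCG", "H", 621, 1500),
                 GeneFeature("g3", "PCG", "H", 1561, 2500)]
        profile = CoverageProfile("t", L)
        profile.depth_h += 5
        profile.depth_h[500:620] = 0  # the g1--g2 IGR is silent
        return genome, feats, igrs, profile

    def test_recovery_of_planted_cr(self, rng):
        genome, feats, igrs, profile = self._setup(rng)
        calls = predict_control_region(igrs, profile, feats, genome, motif_min_igrs=3)
        called = [c for c in calls if c.called]
        assert [c.igr for c in called] == ["g1--g2"]
        c = called[0]
        assert c.zero_coverage and c.has_hairpin and c.polarity_inversion and c.motif_present

    def test_no_zero_coverage_no_call(self, rng):
        genome, feats, igrs, profile = self._setup(rng)
        profile.depth_h[500:620] = 4
        calls = predict_control_region(igrs, profile, feats, genome, motif_min_igrs=3)
        assert not any(c.called for c in calls)

    def test_reference_cr_is_the_wrap_igr(self, program_a):
        """On the simulated study system the COII--COI IGR is the single call."""
        from punctless.coverage import compute_coverage
        from punctless.genome import igr_table
        from punctless.simulate import simulate_reads

        program, genome, feats = program_a
        rs = simulate_reads(program, genome, feats, depth=30, seed=42)
        profile = compute_coverage(rs.fragments, genome)
        igrs, _ = igr_table(genome, feats)
        calls = predict_control_region(igrs, profile, feats, genome)
        assert [c.igr for c in calls if c.called] == ["COII--COI"]
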