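"""Stem-loop detection, shared IGR motif discovery and control-region prediction.

Secondary structure is operationalized as perfect inverted repeats (stems of
Watson-Crick or G·T/G·U pairs around a short loop) rather than by
thermodynamic folding: the biological claim being tested is structural
presence, not a folding energy.  A mitochondrial control region / OriH is
predicted for an intergenic region that is transcriptionally silent, folds
a hairpin, sits at an inversion of gene polarities, and carries a motif
shared with other unit-flanking IGRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .coverage import CoverageProfile
from .genome import CircularGenome, GeneFeature, IntergenicRegion

# stem pairing: Watson-Crick plus the G·U wobble (G-T in DNA space)
_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class Hairpin:
    start: int        # 1-based position of the first stem base (left arm)
    stem_len: int
    loop_len: int
    strand: str = "H"

    @property
    def end(self) -> int:
        return self.start + 2 * self.stem_len + self.loop_len - 1


@dataclass(frozen=True)
class MotifHit:
    kmer: str
    k: int
    igr_names: tuple[str, ...]
    positions: tuple[tuple[str, int], ...]  # (igr name, 1-based offset in that IGR)


@dataclass(frozen=True)
class ControlRegionCall:
    igr: str                 # "left--right" pair label
    zero_coverage: bool
    has_hairpin: bool
    polarity_inversion: bool
    motif_present: bool
    called: bool


# ---------------------------------------------------------------------------
# Hairpins
# ---------------------------------------------------------------------------

def _paired(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def find_hairpins(
    sequence: str,
    min_stem: int = 6,
    loop_min: int = 3,
    loop_max: int = 30,
) -> list[Hairpin]:
    """All maximal perfect inverted repeats folding into a stem-loop.

    For every candidate loop placement the stem is extended outward as far
    as pairing allows; hairpins sharing a start keep only the longest stem.
    Positions are 1-based within ``sequence``.
    """
    seq = sequence.upper()
    n = len(seq)
    best_by_start: dict[int, Hairpin] = {}
    for loop_len in range(loop_min, loop_max + 1):
        # i = index of last base of left arm, loop occupies [i+1, i+loop_len]
        for i in range(n):
            j = i + loop_len + 1  # first base of right arm
            stem = 0
            while i - stem >= 0 and j + stem < n and _paired(seq[i - stem], seq[j + stem]):
                stem += 1
            if stem >= min_stem:
                start = i - stem + 1  # 0-based start of left arm
                hp = Hairpin(start=start + 1, stem_len=stem, loop_len=loop_len)
                prev = best_by_start.get(start)
                if prev is None or stem > prev.stem_len:
                    best_by_start[start] = hp
    return sorted(best_by_start.values(), key=lambda h: (h.start, -h.stem_len))


# ---------------------------------------------------------------------------
# Shared motifs across IGRs
# ---------------------------------------------------------------------------

def _kmers_of(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_igr_motifs(
    igr_sequences: Mapping[str, str],
    k_range: tuple[int, int] = (8, 15),
    min_igrs: int = 3,
    include_revcomp: bool = False,
) -> list[MotifHit]:
    """Exact k-mers present in at least ``min_igrs`` IGR sequences.

    k is scanned descending; a k-mer that is a substring of an already
    reported longer hit with the same IGR set is redundant and dropped.
    Output is deterministic and independent of IGR input order.
    """
    from .coverage import revcomp

    seqs = {name: s.upper() for name, s in sorted(igr_sequences.items())}
    k_lo, k_hi = k_range
    hits: list[MotifHit] = []
    for k in range(k_hi, k_lo - 1, -1):
        presence: dict[str, set[str]] = {}
        for name, s in seqs.items():
            km = _kmers_of(s, k)
            if include_revcomp:
                km |= {revcomp(x) for x in km}
            for x in km:
                presence.setdefault(x, set()).add(name)
        for kmer in sorted(presence):
            names = presence[kmer]
            if len(names) < min_igrs:
                continue
            redundant = any(
                kmer in h.kmer and set(h.igr_names) == names for h in hits
            )
            if redundant:
                continue
            positions = []
            for name in sorted(names):
                s = seqs[name]
                idx = s.find(kmer)
                if idx < 0 and include_revcomp:
                    idx = s.find(revcomp(kmer))
                positions.append((name, idx + 1))
            hits.append(MotifHit(kmer, k, tuple(sorted(names)), tuple(positions)))
    return hits


# ---------------------------------------------------------------------------
# Control-region prediction
# ---------------------------------------------------------------------------

def predict_control_region(
    igrs: Sequence[IntergenicRegion],
    profile: CoverageProfile,
    features: Sequence[GeneFeature],
    genome: CircularGenome,
    min_stem: int = 6,
    loop_min: int = 3,
    loop_max: int = 30,
    motif_k_range: tuple[int, int] = (8, 15),
    motif_min_igrs: int = 3,
    zero_frac: float = 0.9,
    min_criteria: int = 4,
) -> list[ControlRegionCall]:
    """Score every IGR on the four control-region criteria.

    zero coverage: at least ``zero_frac`` of the IGR's positions have zero
    combined-strand depth (mapped UTR ends of the neighbouring units may
    nibble a few bases off an otherwise silent region); polarity inversion:
    the flanking genes lie on opposite strands; hairpin and shared-motif
    presence as computed by the sibling operations.  ``min_criteria`` of the
    four (default: all) must hold for a call.
    """
    strand_of = {f.name: f.strand for f in features}
    L = genome.length
    combined = profile.depth()
    igr_seqs = {
        f"{r.left_gene}--{r.right_gene}": genome.fetch(r.start, r.end)
        for r in igrs
        if r.length > 0
    }
    motif_hits = shared_igr_motifs(igr_seqs, motif_k_range, motif_min_igrs)
    motif_igrs = {name for h in motif_hits for name in h.igr_names}
    out: list[ControlRegionCall] = []
    for r in igrs:
        label = f"{r.left_gene}--{r.right_gene}"
        if r.length == 0:
            out.append(ControlRegionCall(label, False, False,
                                         strand_of[r.left_gene] != strand_of[r.right_gene],
                                         False, False))
            continue
        pos0 = [((r.start - 1) + i) % L for i in range(r.length)]
        n_zero = sum(1 for p in pos0 if combined[p] == 0)
        zero = n_zero >= zero_frac * r.length
        seq = igr_seqs[label]
        hairpin = bool(find_hairpins(seq, min_stem, loop_min, loop_max)) \
            if len(seq) >= 2 * min_stem + loop_min else False
        polarity = strand_of[r.left_gene] != strand_of[r.right_gene]
        motif = label in motif_igrs
        called = sum([zero, hairpin, polarity, motif]) >= min_criteria
        out.append(ControlRegionCall(label, zero, hairpin, polarity, motif, called))
    return out


def hairpins_to_tsv(hairpins: Sequence[Hairpin], path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tstem_len\tloop_len\tstrand\n")
        for h in hairpins:
            fh.write(f"{h.start}\t{h.end}\t{h.stem_len}\t{h.loop_len}\t{h.strand}\n")
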