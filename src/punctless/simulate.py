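"""Synthetic octocoral-style mitochondrial transcriptomes with known ground truth.

This module is the package's test bed: it emits an annotated ~18.7 kb
circular mitogenome, a transcription program (mono-/polycistronic units with
UTRs, weighted alternative polyadenylation sites, rRNA transcript excess, a
low-level precursor read-through fraction and one antisense lncRNA), and
simulators for 50 bp paired-end read sets, circularized-RT junction reads
and qPCR Cq tables — each with truth records sufficient to verify every
downstream inference by parameter recovery.

The bundled reference genome is SYNTHETIC: a constructed stand-in for a
soft-coral (arrangement 'A') mitogenome whose descriptive anatomy — length
18,730 nt; base composition A 30.2 / C 16.5 / G 19.3 / T 33.9 %, G+C
35.8 %; a 112 nt maximal and 4 nt minimal intergenic region; a single 13 nt
gene overlap; mtMutS (2,982 nt) the longest and ATP8 (216 nt) the shortest
protein-coding gene — is imposed by construction.  Its gene sequences are
random apart from start/stop codons, planted control-region structure
(hairpin + shared 11 nt motif) and open-reading-frame constraints.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .coverage import AlignedFragment, revcomp
from .genome import CircularGenome, GeneFeature, GenomeValidationError

# internal seed fixing the reference sequence itself; the reference is a
# study condition, not a per-run random quantity
_REFERENCE_SEED = 20170617

REFERENCE_LENGTH = 18730
# exact base counts realising the reference composition
_BASE_COUNTS = {"A": 5661, "C": 3098, "G": 3616, "T": 6355}

SHARED_MOTIF = "GACTAGGCTAT"  # 11 nt motif planted in unit-flanking IGRs
_HAIRPIN_ARM = "GGATCGTTCAAC"  # 12 bp stem arm planted in the control region
_HAIRPIN_LOOP = "TCTAGA"

STOPS = ("TAA", "TAG")

# (name, kind, strand, start, end), 1-based inclusive, arrangement 'A'
ARRANGEMENT_A_GENES: tuple[tuple[str, str, str, int, int], ...] = (
    ("COI", "PCG", "H", 110, 1666),
    ("rns", "rRNA", "H", 1672, 2721),
    ("ND1", "PCG", "H", 2726, 3646),
    ("CytB", "PCG", "H", 3677, 4861),
    ("ND6", "PCG", "H", 4870, 5433),
    ("ND3", "PCG", "H", 5473, 5829),
    ("ND4L", "PCG", "H", 5842, 6141),
    ("mtMutS", "PCG", "H", 6154, 9135),
    ("rnl", "rRNA", "H", 9181, 11133),
    ("ND2", "PCG", "H", 11174, 12265),
    ("ND5", "PCG", "H", 12285, 14102),
    ("ND4", "PCG", "H", 14090, 15868),   # 13 nt overlap with ND5
    ("trnM", "tRNA", "L", 15877, 15947),
    ("COIII", "PCG", "L", 15957, 16736),
    ("ATP6", "PCG", "L", 16827, 17528),
    ("ATP8", "PCG", "L", 17605, 17820),
    ("COII", "PCG", "L", 17903, 18727),
)

# control region: the wrap-around COII--COI IGR (18728..18730 + 1..109)
CONTROL_REGION = (18728, 109)

# 1-based genomic start offsets for planted elements
_MOTIF_SITES = (8, 3655, 5450, 16750)          # CR, ND1--CytB, ND6--ND3, COIII--ATP6
_CR_HAIRPIN_START = 30
_IGR_HAIRPIN = (16780, "GCGTTACG", "ATTA")     # small extra stem-loop, COIII--ATP6

# Positions planted as a non-A base (genomic 'C') so that every configured
# transcript terminus is canonical under the maximal-genomic poly(A)
# attribution rule: the sense base immediately 3' of each configured 3' end
# and immediately 5' of each configured 5' end must not be adenine.
_NONA_H = (105, 1670, 3682, 3925, 3969, 5441, 5442, 6541, 6747, 6771, 6912,
           8762, 8951, 8978, 9136, 11172, 15913, 16836, 17049)
_NONA_GENOMIC = (1, 16743)  # L-strand termini: genomic base must not be 'T'

LNC_ATP6 = (16837, 17048, "H")                 # antisense of ATP6, 212 nt


# ---------------------------------------------------------------------------
# Transcription program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth description of one mature transcription unit."""

    genes: tuple[str, ...]           # transcript order, 5' -> 3'
    strand: str
    abundance: float
    utr5: int | None = None          # negative = 5' end inside the first CDS
    utr3: int | None = None
    apa_sites: tuple[tuple[int, float], ...] = ()   # (genomic 3' position, weight share)
    alt_five: tuple[tuple[int, float], ...] = ()    # alternative 5' ends (position, weight)
    polyadenylated: bool = True
    kind: str = "mRNA"               # mRNA | rRNA | tRNA

    @property
    def ends_known(self) -> bool:
        return self.utr5 is not None or self.utr3 is not None


@dataclass(frozen=True)
class AntisenseSpec:
    interval: tuple[int, int, str]
    abundance: float
    polyadenylated: bool = True


@dataclass(frozen=True)
class InternalTranscript:
    """A transcript with both termini inside one gene (e.g. the internal mtMutS form)."""

    gene: str
    five: int
    three: int
    strand: str
    abundance: float


@dataclass
class TranscriptionProgram:
    units: list[UnitSpec]
    rrna_multiplier: float = 50.0
    readthrough_fraction: float = 0.01
    antisense: list[AntisenseSpec] = field(default_factory=list)
    internal: list[InternalTranscript] = field(default_factory=list)
    polya_len_mean: float = 35.0
    polya_len_sd: float = 5.0


@dataclass(frozen=True)
class TranscriptSpecies:
    """A concrete transcript molecule type realised from the program."""

    name: str
    start: int       # genomic 1-based, start <= end (no species wraps the origin)
    end: int
    strand: str
    weight: float    # per-molecule relative abundance
    polyadenylated: bool
    source_unit: tuple[str, ...] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def five_prime(self) -> int:
        return self.start if self.strand == "H" else self.end

    def three_prime(self) -> int:
        return self.end if self.strand == "H" else self.start


@dataclass
class SimulatedReadSet:
    fragments: list[AlignedFragment]
    truth: list[str]                  # species name per fragment
    species: list[TranscriptSpecies]
    read_len: int
    depth: float
    seed: int


# ---------------------------------------------------------------------------
# Reference sequence construction
# ---------------------------------------------------------------------------

def _feature_objects(table) -> list[GeneFeature]:
    return [GeneFeature(name=n, kind=k, strand=s, start=a, end=b)
            for n, k, s, a, b in table]


class _SeqBuilder:
    """Mutable sequence with locked positions and frame bookkeeping."""

    def __init__(self, length: int, rng: np.random.Generator, counts: dict[str, int]):
        pool = np.array(list("".join(b * c for b, c in counts.items())))
        rng.shuffle(pool)
        self.seq = pool.tolist()
        self.L = length
        self.locked: set[int] = set()       # 0-based
        self.rng = rng

    def write(self, pos1: int, text: str, lock: bool = True) -> None:
        for i, ch in enumerate(text):
            p = (pos1 - 1 + i) % self.L
            self.seq[p] = ch
            if lock:
                self.locked.add(p)

    def get(self, pos1: int, length: int) -> str:
        return "".join(self.seq[(pos1 - 1 + i) % self.L] for i in range(length))


def _sense_codon_positions(f: GeneFeature) -> list[tuple[int, int, int]]:
    """Genomic 0-based positions of each sense codon of a (non-wrapping) gene."""
    s0, e0 = f.start - 1, f.end - 1
    out = []
    if f.strand == "H":
        for c in range(s0, e0 - 1, 3):
            out.append((c, c + 1, c + 2))
    else:
        for c in range(e0, s0 + 1, -3):
            out.append((c, c - 1, c - 2))
    return out


def _codon_at(seq: list[str], trip: tuple[int, int, int], strand: str) -> str:
    bases = seq[trip[0]], seq[trip[1]], seq[trip[2]]
    if strand == "H":
        return "".join(bases)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return "".join(comp[b] for b in bases)


def _write_sense_codon(b: _SeqBuilder, trip, strand: str, codon: str, lock: bool) -> None:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for p, ch in zip(trip, codon):
        b.seq[p] = ch if strand == "H" else comp[ch]
        if lock:
            b.locked.add(p)


def _destroy_internal_stops(b: _SeqBuilder, pcgs: Sequence[GeneFeature]) -> None:
    """Mutate non-terminal in-frame TAA/TAG codons away, respecting locks and
    genes whose frames overlap."""
    frames = {f.name: _sense_codon_positions(f) for f in pcgs}
    pos_to_genes: dict[int, list[str]] = {}
    for f in pcgs:
        for trip in frames[f.name]:
            for p in trip:
                pos_to_genes.setdefault(p, []).append(f.name)
    by_name = {f.name: f for f in pcgs}

    def codon_ok_everywhere(p: int) -> bool:
        for gname in pos_to_genes.get(p, []):
            g = by_name[gname]
            for trip in frames[gname]:
                if p in trip and _codon_at(b.seq, trip, g.strand) in STOPS \
                        and trip != frames[gname][-1]:
                    return False
        return True

    for _ in range(20):
        dirty = False
        for f in pcgs:
            trips = frames[f.name]
            for trip in trips[:-1]:
                if _codon_at(b.seq, trip, f.strand) not in STOPS:
                    continue
                fixed = False
                for idx in (2, 0, 1):
                    p = trip[idx]
                    if p in b.locked:
                        continue
                    old = b.seq[p]
                    for new in "CGAT":
                        if new == old:
                            continue
                        b.seq[p] = new
                        if _codon_at(b.seq, trip, f.strand) not in STOPS and \
                                codon_ok_everywhere(p):
                            fixed = True
                            break
                        b.seq[p] = old
                    if fixed:
                        break
                if not fixed:
                    raise GenomeValidationError(
                        f"could not clear stop codon in {f.name}"
                    )
                dirty = True
        if not dirty:
            return
    raise GenomeValidationError("stop-codon clearing did not converge")


def _break_long_orfs(b: _SeqBuilder, interval: tuple[int, int, str],
                     pcgs: Sequence[GeneFeature], max_codons: int = 40) -> None:
    """Insert sense stops into a region until no ORF reaches max_codons,
    without creating stops inside any overlapping PCG frame."""
    from .ends import longest_orf_codons

    start, end, strand = interval
    frames = {f.name: _sense_codon_positions(f) for f in pcgs}
    by_name = {f.name: f for f in pcgs}

    def safe_write_stop(pos1: int) -> bool:
        changed: list[tuple[int, str]] = []
        text = "TAA" if strand == "H" else "TTA"
        for i, ch in enumerate(text):
            p = (pos1 - 1 + i) % b.L
            if p in b.locked:
                for q, old in changed:
                    b.seq[q] = old
                return False
            changed.append((p, b.seq[p]))
            b.seq[p] = ch
        for f in pcgs:
            for trip in frames[f.name]:
                if any(p in trip for p, _ in changed):
                    if _codon_at(b.seq, trip, f.strand) in STOPS and \
                            trip != frames[f.name][-1]:
                        for q, old in changed:
                            b.seq[q] = old
                        return False
        for p, _ in changed:
            b.locked.add(p)
        return True

    for _ in range(30):
        seq = b.get(start, end - start + 1)
        if strand == "L":
            seq = revcomp(seq)
        if longest_orf_codons(seq) < max_codons:
            return
        # place a stop at a pseudo-random in-region position
        offsets = list(range(30, end - start - 30, 7))
        b.rng.shuffle(offsets)
        placed = False
        for off in offsets:
            if safe_write_stop(start + off):
                placed = True
                break
        if not placed:
            raise GenomeValidationError("could not break ORF in lncRNA region")
    raise GenomeValidationError("ORF breaking did not converge")


def _repair_composition(b: _SeqBuilder, pcgs: Sequence[GeneFeature],
                        counts: dict[str, int],
                        avoid: tuple[int, int, str] | None = None) -> None:
    """Swap bases at safe positions until exact target composition is restored."""
    frames = {f.name: _sense_codon_positions(f) for f in pcgs}
    pos_to_gene: dict[int, list[tuple[GeneFeature, tuple[int, int, int], bool]]] = {}
    for f in pcgs:
        trips = frames[f.name]
        for trip in trips:
            for p in trip:
                pos_to_gene.setdefault(p, []).append((f, trip, trip == trips[-1]))
    avoid_set = set()
    if avoid is not None:
        avoid_set = set(range(avoid[0] - 1, avoid[1]))

    def delta() -> dict[str, int]:
        cur = {x: 0 for x in "ACGT"}
        for ch in b.seq:
            cur[ch] += 1
        return {x: cur[x] - counts[x] for x in "ACGT"}

    d = delta()
    if all(v == 0 for v in d.values()):
        return
    order = np.arange(b.L)
    b.rng.shuffle(order)
    for p in order:
        p = int(p)
        if p in b.locked or p in avoid_set:
            continue
        surplus = b.seq[p]
        if d[surplus] <= 0:
            continue
        deficits = [x for x in "ACGT" if d[x] < 0]
        if not deficits:
            break
        for new in deficits:
            old = b.seq[p]
            b.seq[p] = new
            ok = True
            for f, trip, terminal in pos_to_gene.get(p, []):
                if not terminal and _codon_at(b.seq, trip, f.strand) in STOPS:
                    ok = False
                    break
            if ok:
                d[surplus] -= 1
                d[new] += 1
                break
            b.seq[p] = old
        if all(v == 0 for v in d.values()):
            return
    if not all(v == 0 for v in delta().values()):
        raise GenomeValidationError("composition repair failed")


@functools.lru_cache(maxsize=2)
def reference_arrangement_a() -> tuple[CircularGenome, tuple[GeneFeature, ...]]:
    """The synthetic arrangement-'A' reference mitogenome and its annotation.

    Deterministic: the sequence is built once from a fixed internal seed and
    cached.  See the module docstring for the imposed anatomy.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    feats = _feature_objects(ARRANGEMENT_A_GENES)
    b = _SeqBuilder(REFERENCE_LENGTH, rng, _BASE_COUNTS)

    pcgs = [f for f in feats if f.kind == "PCG"]
    for f in pcgs:
        trips = _sense_codon_positions(f)
        _write_sense_codon(b, trips[0], f.strand, "ATG", lock=True)
        _write_sense_codon(b, trips[-1], f.strand, "TAA", lock=True)

    # canonical-terminus sentinels (see _NONA_H): 'C' can never complete a
    # TAA/TAG stop, so these writes are frame-safe on both strands
    for pos in _NONA_H + _NONA_GENOMIC:
        b.write(pos, "C")

    # control-region structure and the shared unit-boundary motif
    for pos in _MOTIF_SITES:
        b.write(pos, SHARED_MOTIF)
    b.write(_CR_HAIRPIN_START, _HAIRPIN_ARM + _HAIRPIN_LOOP + revcomp(_HAIRPIN_ARM))
    hp_pos, arm, loop = _IGR_HAIRPIN
    b.write(hp_pos, arm + loop + revcomp(arm))

    _destroy_internal_stops(b, pcgs)
    _break_long_orfs(b, LNC_ATP6, pcgs)
    _repair_composition(b, pcgs, _BASE_COUNTS, avoid=LNC_ATP6)
    _assert_clean_frames(b, pcgs)

    genome = CircularGenome(id="synthA_mito", sequence="".join(b.seq))
    return genome, tuple(feats)


def _assert_clean_frames(b: _SeqBuilder, pcgs: Sequence[GeneFeature]) -> None:
    for f in pcgs:
        trips = _sense_codon_positions(f)
        if _codon_at(b.seq, trips[0], f.strand) != "ATG":
            raise GenomeValidationError(f"{f.name}: start codon lost")
        if _codon_at(b.seq, trips[-1], f.strand) not in STOPS:
            raise GenomeValidationError(f"{f.name}: stop codon lost")
        for trip in trips[1:-1]:
            if _codon_at(b.seq, trip, f.strand) in STOPS:
                raise GenomeValidationError(f"{f.name}: internal stop codon")


# ---------------------------------------------------------------------------
# Default programs
# ---------------------------------------------------------------------------

MTMUTS_APA_SITES = ((6746, 0.08), (6770, 0.08), (6911, 0.08),
                    (8761, 0.12), (8950, 0.20), (8977, 0.08))
MTMUTS_INTERNAL = InternalTranscript("mtMutS", five=6542, three=8950,
                                     strand="H", abundance=0.5)


def default_program(arrangement: str = "A") -> tuple[TranscriptionProgram, CircularGenome, tuple[GeneFeature, ...]]:
    """The ground-truth transcription program for a mitogenome arrangement.

    Arrangement 'A' carries the full soft-coral program (seven PCG units of
    cistron counts 1/2/3/3/3/1/1, six alternative mtMutS poly(A) sites, the
    antisense lncATP6); arrangement 'C' has the red-coral-style unit layout
    (ND1--CytB, COII--ATP8--ATP6--COIII, ND6--ND3--ND4L, ND2--ND5--ND4, COI).
    """
    if arrangement == "A":
        genome, feats = reference_arrangement_a()
        units = [
            UnitSpec(("COI",), "H", 1.0, utr5=4, utr3=3),
            UnitSpec(("rns",), "H", 1.0, polyadenylated=False, kind="rRNA"),
            UnitSpec(("ND1",), "H", 0.8),
            UnitSpec(("CytB", "ND6"), "H", 1.2, utr5=-6, utr3=8,
                     alt_five=((3683, 0.6), (3926, 0.25), (3970, 0.15))),
            UnitSpec(("ND3", "ND4L", "mtMutS"), "H", 0.6, utr5=31, utr3=0,
                     apa_sites=MTMUTS_APA_SITES),
            UnitSpec(("rnl",), "H", 1.0, polyadenylated=False, kind="rRNA"),
            UnitSpec(("ND2", "ND5", "ND4"), "H", 0.7, utr5=1, utr3=44),
            UnitSpec(("trnM",), "L", 1.5, polyadenylated=False, kind="tRNA"),
            UnitSpec(("COIII",), "L", 0.9),
            UnitSpec(("COII", "ATP8", "ATP6"), "L", 1.0, utr5=3, utr3=83),
        ]
        program = TranscriptionProgram(
            units=units,
            antisense=[AntisenseSpec(LNC_ATP6, abundance=0.3)],
            internal=[MTMUTS_INTERNAL],
        )
        return program, genome, feats
    if arrangement == "C":
        genome, feats = _reference_arrangement_c()
        units = [
            UnitSpec(("COI",), "H", 1.0, utr5=2, utr3=5),
            UnitSpec(("ND1", "CytB"), "H", 1.0, utr5=3, utr3=10),
            UnitSpec(("mtMutS",), "H", 0.4),
            UnitSpec(("rns",), "H", 1.0, polyadenylated=False, kind="rRNA"),
            UnitSpec(("ND2", "ND5", "ND4"), "H", 0.7, utr5=2, utr3=12),
            UnitSpec(("rnl",), "H", 1.0, polyadenylated=False, kind="rRNA"),
            UnitSpec(("trnM",), "L", 1.5, polyadenylated=False, kind="tRNA"),
            UnitSpec(("COII", "ATP8", "ATP6", "COIII"), "L", 1.0, utr5=4, utr3=20),
            UnitSpec(("ND6", "ND3", "ND4L"), "L", 0.8, utr5=6, utr3=9),
        ]
        program = TranscriptionProgram(units=units)
        return program, genome, feats
    raise GenomeValidationError(f"unknown arrangement {arrangement!r}")


_ARRANGEMENT_C_ORDER = (
    # (name, kind, strand, length); positions laid out left to right with
    # 30 nt IGRs (120 nt control region between ND6 and the wrap to COI)
    ("COI", "PCG", "H", 1557),
    ("ND1", "PCG", "H", 921),
    ("CytB", "PCG", "H", 1185),
    ("mtMutS", "PCG", "H", 2982),
    ("rns", "rRNA", "H", 1050),
    ("ND2", "PCG", "H", 1092),
    ("ND5", "PCG", "H", 1818),
    ("ND4", "PCG", "H", 1479),
    ("rnl", "rRNA", "H", 1953),
    ("trnM", "tRNA", "L", 71),
    ("COIII", "PCG", "L", 780),
    ("ATP6", "PCG", "L", 702),
    ("ATP8", "PCG", "L", 216),
    ("COII", "PCG", "L", 828),
    ("ND4L", "PCG", "L", 300),
    ("ND3", "PCG", "L", 357),
    ("ND6", "PCG", "L", 564),
)


@functools.lru_cache(maxsize=2)
def _reference_arrangement_c() -> tuple[CircularGenome, tuple[GeneFeature, ...]]:
    rng = np.random.default_rng(_REFERENCE_SEED + 1)
    igr = 30
    pos = 121  # control region occupies 1..120 (wrap IGR ND6--COI)
    table = []
    for name, kind, strand, length in _ARRANGEMENT_C_ORDER:
        table.append((name, kind, strand, pos, pos + length - 1))
        pos += length + igr
    L = table[-1][4] + 120  # the 120 nt control region closes the circle
    feats = _feature_objects(table)
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    draws = rng.choice(np.array(list("ACGT")), size=L,
                       p=[0.302, 0.165, 0.193, 0.34])
    for ch in draws:
        counts[str(ch)] += 1
    b = _SeqBuilder(L, rng, counts)
    pcgs = [f for f in feats if f.kind == "PCG"]
    for f in pcgs:
        trips = _sense_codon_positions(f)
        _write_sense_codon(b, trips[0], f.strand, "ATG", lock=True)
        _write_sense_codon(b, trips[-1], f.strand, "TAA", lock=True)
    b.write(20, SHARED_MOTIF)
    b.write(50, _HAIRPIN_ARM + _HAIRPIN_LOOP + revcomp(_HAIRPIN_ARM))
    _destroy_internal_stops(b, pcgs)
    genome = CircularGenome(id="synthC_mito", sequence="".join(b.seq))
    return genome, tuple(feats)


# ---------------------------------------------------------------------------
# Program -> concrete transcript species
# ---------------------------------------------------------------------------

def realize_species(
    program: TranscriptionProgram,
    genome: CircularGenome,
    features: Sequence[GeneFeature],
) -> list[TranscriptSpecies]:
    """Expand the program into concrete transcript species with weights.

    A unit with alternative poly(A) sites becomes one species per site plus
    the canonical full-length form carrying the residual weight; rRNA units
    are scaled by the rRNA multiplier.
    """
    by_name = {f.name: f for f in features}
    out: list[TranscriptSpecies] = []
    for u in program.units:
        first, last = by_name[u.genes[0]], by_name[u.genes[-1]]
        utr5 = u.utr5 or 0
        utr3 = u.utr3 or 0
        if u.strand == "H":
            start = first.start - utr5
            end = last.end + utr3
        else:
            end = first.end + utr5
            start = last.start - utr3
        weight = u.abundance * (program.rrna_multiplier if u.kind == "rRNA" else 1.0)
        name = "-".join(u.genes)
        apa_total = sum(w for _, w in u.apa_sites)
        if apa_total >= 1.0:
            raise GenomeValidationError(f"unit {name}: APA weights must sum to < 1")
        for pos, w in u.apa_sites:
            if u.strand == "H":
                out.append(TranscriptSpecies(f"{name}@pA{pos}", start, pos, "H",
                                             weight * w, u.polyadenylated, u.genes))
            else:
                out.append(TranscriptSpecies(f"{name}@pA{pos}", pos, end, "L",
                                             weight * w, u.polyadenylated, u.genes))
        out.append(TranscriptSpecies(name, start, end, u.strand,
                                     weight * (1.0 - apa_total), u.polyadenylated,
                                     u.genes))
    for a in program.antisense:
        s, e, st = a.interval
        out.append(TranscriptSpecies(f"lnc{_antisense_name(a, features)}", s, e, st,
                                     a.abundance, a.polyadenylated, None))
    for it in program.internal:
        s, e = (it.five, it.three) if it.strand == "H" else (it.three, it.five)
        out.append(TranscriptSpecies(f"{it.gene}-internal", s, e, it.strand,
                                     it.abundance, True, None))
    return out


def _antisense_name(a: AntisenseSpec, features: Sequence[GeneFeature]) -> str:
    from .linkage import circular_overlap

    s, e, st = a.interval
    best, best_ov = "RNA", 0
    for f in features:
        if f.strand == st:
            continue
        ov = circular_overlap((s, e), (f.start, f.end), 10 ** 9)
        if ov > best_ov:
            best, best_ov = f.name, ov
    return best


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _precursor_species(program, genome, features) -> list[TranscriptSpecies]:
    """Whole-strand unprocessed precursors spanning all unit boundaries
    between the two control-region edges."""
    cr_start, cr_end = CONTROL_REGION
    lo, hi = cr_end + 1, cr_start - 1
    out = []
    for strand in ("H", "L"):
        if any(f.strand == strand for f in features):
            out.append(TranscriptSpecies(f"precursor_{strand}", lo, hi, strand,
                                         0.0, False, None))
    return out


def simulate_reads(
    program: TranscriptionProgram,
    genome: CircularGenome,
    features: Sequence[GeneFeature],
    depth: float = 30.0,
    read_len: int = 50,
    frag_mean: float = 250.0,
    frag_sd: float = 40.0,
    seed: int = 0,
) -> SimulatedReadSet:
    """Simulate a strand-resolved paired-end read set with truth labels.

    Fragments are drawn from transcript species with probability
    proportional to weight x length (so per-base depth is proportional to
    weight); with probability ``readthrough_fraction`` a fragment comes from
    the unprocessed whole-strand precursor instead.  Fragments covering a
    polyadenylated species' 3' terminus carry an A-tail soft-clip.  ``depth``
    is the genome-wide mean per-base coverage aimed for.
    """
    rng = np.random.default_rng(seed)
    species = realize_species(program, genome, features)
    if depth <= 0:
        import warnings

        warnings.warn("depth <= 0: empty read set")
        return SimulatedReadSet([], [], species, read_len, depth, seed)
    precursors = _precursor_species(program, genome, features)
    strand_weight = {
        st: sum(s.weight * s.length for s in species if s.strand == st)
        for st in ("H", "L")
    }
    n_frags = int(round(depth * genome.length / (2 * read_len)))
    probs = np.array([s.weight * s.length for s in species], dtype=float)
    probs /= probs.sum()
    f_rt = program.readthrough_fraction
    frag_species = []
    for _ in range(n_frags):
        if f_rt > 0 and rng.random() < f_rt:
            tot = strand_weight["H"] + strand_weight["L"]
            st = "H" if rng.random() < strand_weight["H"] / tot else "L"
            frag_species.append(next(p for p in precursors if p.strand == st))
        else:
            frag_species.append(species[rng.choice(len(species), p=probs)])
    fragments: list[AlignedFragment] = []
    truth: list[str] = []
    for sp in frag_species:
        slen = sp.length
        flen = int(round(rng.normal(frag_mean, frag_sd)))
        flen = max(read_len, min(flen, slen))
        t0 = int(rng.integers(0, slen - flen + 1))
        # transcript-coordinate mate intervals
        m1 = (t0, min(t0 + read_len, t0 + flen) - 1)
        if flen > read_len:
            m2 = (max(t0 + flen - read_len, t0), t0 + flen - 1)
        else:
            m2 = None
        def to_genome(iv):
            a, bb = iv
            if sp.strand == "H":
                return (sp.start + a, sp.start + bb)
            return (sp.end - bb, sp.end - a)
        clip3 = None
        if sp.polyadenylated and t0 + flen == slen:
            tail = int(round(rng.normal(program.polya_len_mean, program.polya_len_sd)))
            clip3 = "A" * max(5, min(tail, read_len - 25))
        fragments.append(
            AlignedFragment(mate1=to_genome(m1),
                            mate2=to_genome(m2) if m2 else None,
                            strand=sp.strand, clip3=clip3)
        )
        truth.append(sp.name)
    return SimulatedReadSet(fragments, truth, species, read_len, depth, seed)


# ---------------------------------------------------------------------------
# SAM / FASTQ round trip
# ---------------------------------------------------------------------------

def write_sam(readset: SimulatedReadSet, genome: CircularGenome, path: str | Path) -> None:
    """Write the simulated fragments as a coordinate-unsorted SAM text file.

    Mate 1 is written on the transcript strand (an fr-secondstrand library);
    a poly(A) tail appears as a terminal soft-clip in reference orientation
    (A's on the right for H transcripts, T's on the left for L transcripts).
    """
    import pysam

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.id, "LN": genome.length}],
    })
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, (frag, name) in enumerate(zip(readset.fragments, readset.truth)):
            mates = frag.intervals()
            for mi, iv in enumerate(mates):
                a = pysam.AlignedSegment(header)
                a.query_name = f"frag{i:07d}"
                s, e = iv
                span = e - s + 1
                seq = genome.fetch(s, e)
                cigar = f"{span}M"
                # transcript-3'-most mate carries the tail clip
                is_three_mate = (mi == len(mates) - 1) if frag.strand == "H" else (
                    iv == min(mates, key=lambda x: x[0]))
                if frag.clip3 and is_three_mate:
                    if frag.strand == "H":
                        seq = seq + frag.clip3
                        cigar = f"{span}M{len(frag.clip3)}S"
                    else:
                        seq = revcomp(frag.clip3) + seq
                        cigar = f"{len(frag.clip3)}S{span}M"
                a.reference_id = 0
                a.reference_start = s - 1
                a.cigarstring = cigar
                a.query_sequence = seq
                a.mapping_quality = 60
                flag = 0
                if len(mates) == 2:
                    flag |= 0x1 | 0x2 | (0x40 if mi == 0 else 0x80)
                    other = mates[1 - mi]
                    a.next_reference_id = 0
                    a.next_reference_start = other[0] - 1
                    # mate1 on transcript strand, mate2 opposite
                    m_rev = (frag.strand == "L") ^ (mi == 1)
                    o_rev = (frag.strand == "L") ^ (mi == 0)
                    if m_rev:
                        flag |= 0x10
                    if o_rev:
                        flag |= 0x20
                else:
                    if frag.strand == "L":
                        flag |= 0x10
                a.flag = flag
                a.set_tag("XS", frag.strand)
                out.write(a)


def fragments_from_sam(path: str | Path, protocol: str = "unstranded") -> list[AlignedFragment]:
    """Re-pair SAM records into AlignedFragments (sense-oriented clip3)."""
    import pysam

    from .coverage import _record_strand

    pending: dict[str, tuple] = {}
    out: list[AlignedFragment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            iv = (rec.reference_start + 1, rec.reference_end)
            strand = _record_strand(rec, protocol)
            clip = None
            cig = rec.cigartuples or []
            if cig and cig[-1][0] == 4:  # right soft clip
                tail = rec.query_sequence[-cig[-1][1]:]
                if strand == "H":
                    clip = tail
            if cig and cig[0][0] == 4:  # left soft clip
                head = rec.query_sequence[: cig[0][1]]
                if strand == "L":
                    clip = revcomp(head)
            if not rec.is_paired:
                out.append(AlignedFragment(iv, None, strand, clip))
                continue
            if rec.query_name in pending:
                o_iv, o_strand, o_clip = pending.pop(rec.query_name)
                out.append(AlignedFragment(o_iv, iv, o_strand, clip or o_clip))
            else:
                pending[rec.query_name] = (iv, strand, clip)
    for name, (iv, strand, clip) in pending.items():
        out.append(AlignedFragment(iv, None, strand, clip))
    return out


def write_fastq(readset: SimulatedReadSet, genome: CircularGenome,
                path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, frag in enumerate(readset.fragments):
            mates = frag.intervals()
            for mi, iv in enumerate(mates):
                seq = genome.fetch(*iv)
                if frag.strand == "L":
                    seq = revcomp(seq)
                fh = f1 if mi == 0 else f2
                fh.write(f"@frag{i:07d}/{mi + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Junction-read simulation
# ---------------------------------------------------------------------------

def simulate_junction_reads(
    program: TranscriptionProgram,
    genome: CircularGenome,
    features: Sequence[GeneFeature],
    n_per_end: int = 1,
    flank: int = 35,
    error_rate: float = 0.0,
    seed: int = 0,
    weighted_total: int | None = None,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Circularized-RT junction reads [3' flank][A-tail][5' flank] with truth.

    By default every polyadenylated species (unit ends, APA variants,
    internal and antisense transcripts) yields ``n_per_end`` reads; with
    ``weighted_total`` the species of each read is instead drawn
    multinomially by abundance weight.
    """
    rng = np.random.default_rng(seed)
    species = [s for s in realize_species(program, genome, features)
               if s.polyadenylated and _unit_known(program, s)]
    reads: list[tuple[str, str]] = []
    truth: list[dict] = []

    def one_read(sp: TranscriptSpecies, idx: int) -> None:
        tail = max(8, int(round(rng.normal(program.polya_len_mean,
                                           program.polya_len_sd))))
        five_positions = _five_prime_choices(program, sp)
        pos5, _ = five_positions[rng.choice(len(five_positions),
                                            p=np.array([w for _, w in five_positions])
                                            / sum(w for _, w in five_positions))]
        seq5 = _sense_fetch(genome, sp.strand, pos5, flank, direction="down")
        pos3 = sp.three_prime()
        seq3 = _sense_fetch(genome, sp.strand, pos3, flank, direction="up")
        read = seq3 + "A" * tail + seq5
        if error_rate > 0:
            read = _mutate(read, error_rate, rng)
        reads.append((f"{sp.name}_j{idx}", read))
        truth.append({"species": sp.name, "three_prime": pos3,
                      "five_prime": pos5, "polya_len": tail,
                      "strand": sp.strand})

    if weighted_total is None:
        for sp in species:
            for k in range(n_per_end):
                one_read(sp, k)
    else:
        w = np.array([s.weight for s in species], dtype=float)
        w /= w.sum()
        for k in range(weighted_total):
            one_read(species[rng.choice(len(species), p=w)], k)
    return reads, truth


def _unit_known(program: TranscriptionProgram, sp: TranscriptSpecies) -> bool:
    if sp.source_unit is None:
        return True
    for u in program.units:
        if u.genes == sp.source_unit:
            return u.ends_known
    return True


def _five_prime_choices(program: TranscriptionProgram, sp: TranscriptSpecies):
    if sp.source_unit is not None:
        for u in program.units:
            if u.genes == sp.source_unit and u.alt_five:
                return list(u.alt_five)
    return [(sp.five_prime(), 1.0)]


def _sense_fetch(genome: CircularGenome, strand: str, pos: int, n: int,
                 direction: str) -> str:
    """n transcript-sense bases ending at (direction='up') or starting at
    (direction='down') genomic position pos."""
    L = genome.length
    if strand == "H":
        if direction == "up":
            start = ((pos - n) % L) + 1
            return genome.fetch(start, pos)
        end = ((pos + n - 2) % L) + 1
        return genome.fetch(pos, end)
    if direction == "up":
        end = ((pos + n - 2) % L) + 1
        return revcomp(genome.fetch(pos, end))
    start = ((pos - n) % L) + 1
    return revcomp(genome.fetch(start, pos))


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    out = list(read)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def write_junction_fasta(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Congener genome (two-genome comparison)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CongenerTruth:
    n_substitutions: int
    n_ambiguity_cols: int
    n_gap_cols: int
    n_columns: int


def congener_alignment(seed: int = _REFERENCE_SEED) -> tuple[CircularGenome, str, str, CongenerTruth]:
    """A synthetic congener of the reference plus their pairwise alignment.

    The congener is generated through a constructed alignment: 432
    substitution columns, 9 ambiguity (N) columns, 9 insertion and 21
    deletion columns (net 12 nt shorter), mirroring the divergence regime of
    two closely related soft-coral mitogenomes.  Returns (congener genome,
    reference row, congener row, truth).
    """
    genome, _ = reference_arrangement_a()
    rng = np.random.default_rng(seed)
    L = genome.length
    n_sub, n_amb, n_ins, n_del = 432, 9, 9, 21
    picks = rng.choice(L, size=n_sub + n_amb + n_del, replace=False)
    subs = set(int(p) for p in picks[:n_sub])
    ambs = set(int(p) for p in picks[n_sub : n_sub + n_amb])
    dels = set(int(p) for p in picks[n_sub + n_amb :])
    ins_after = sorted(int(p) for p in rng.choice(L - 1, size=n_ins, replace=False))
    ins_iter = iter(ins_after + [None])
    next_ins = next(ins_iter)
    row_a, row_b = [], []
    for p, base in enumerate(genome.sequence):
        if p in dels:
            row_a.append(base)
            row_b.append("-")
        elif p in ambs:
            row_a.append(base)
            row_b.append("N")
        elif p in subs:
            row_a.append(base)
            row_b.append(str(rng.choice([b for b in "ACGT" if b != base])))
        else:
            row_a.append(base)
            row_b.append(base)
        while next_ins is not None and next_ins == p:
            row_a.append("-")
            row_b.append(str(rng.choice(list("ACGT"))))
            next_ins = next(ins_iter)
    a, b = "".join(row_a), "".join(row_b)
    congener = CircularGenome(id="synthA_congener", sequence=b.replace("-", ""))
    truth = CongenerTruth(n_sub, n_amb, n_ins + n_del, len(a))
    return congener, a, b, truth


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_cq(
    true_ratios: dict[str, float],
    efficiency: float = 2.0,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    baseline: float = 24.0,
    reference: str = "ACTB",
):
    """Two-condition Cq table: each target's 'sample' abundance is
    ``true_ratios[target]``-fold its 'control' abundance; the reference gene
    is at ratio 1.  Cq = baseline - log_E(abundance) + Gaussian noise."""
    from .qpcr import QpcrWell

    if replicates < 2:
        raise GenomeValidationError("need >= 2 replicates")
    rng = np.random.default_rng(seed)
    wells = []
    log_e = math.log(efficiency)
    for target, fold in {**true_ratios, reference: 1.0}.items():
        for cond, abundance in (("sample", fold), ("control", 1.0)):
            for r in range(replicates):
                cq = baseline - math.log(abundance) / log_e + rng.normal(0, noise_sd)
                wells.append(QpcrWell(target, cond, r, cq, efficiency))
    return wells


def simulate_cq_abundances(
    abundances: dict[str, float],
    efficiency: float = 2.0,
    noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    baseline: float = 24.0,
):
    """Single-condition Cq table for amplicons measured on one cDNA pool
    (the RNase-H APA assay readout): Cq = baseline - log_E(abundance) + noise."""
    from .qpcr import QpcrWell

    rng = np.random.default_rng(seed)
    log_e = math.log(efficiency)
    wells = []
    for target, ab in abundances.items():
        for r in range(replicates):
            cq = baseline - math.log(ab) / log_e + rng.normal(0, noise_sd)
            wells.append(QpcrWell(target, "sample", r, cq, efficiency))
    return wells
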