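"""Transcript 5'/3' end resolution, UTR annotation, APA clustering and lncRNA calls.

Three evidence channels map mature transcript termini onto the genome:

* circularized-RT junction reads, in which self-ligation of a transcript
  places its 3' end, poly(A) tail and 5' end on one sequenced molecule;
* RACE reads, adapter-anchored at one terminus;
* poly(A)-bearing alignment soft-clips from ordinary RNA-seq reads.

Anchoring to the genome is exact-match (clone-derived, Sanger-quality
junction/RACE sequences justify no mismatch tolerance) over both strands of
the circular sequence.  Stop codons are TAA/TAG throughout (TGA encodes
tryptophan in invertebrate mitochondria).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .coverage import AlignedFragment, revcomp
from .genome import CircularGenome, GeneFeature, GenomeValidationError

STOP_CODONS = ("TAA", "TAG")
START_CODON = "ATG"


class EndResolutionError(ValueError):
    """A junction or RACE read could not be interpreted unambiguously."""


@dataclass(frozen=True)
class TranscriptEnd:
    position: int           # 1-based genomic coordinate of the terminal base
    kind: str               # five_prime | three_prime
    strand: str             # H | L
    method: str             # crtpcr | race | softclip
    polya_len: int | None = None
    support: int = 1

    def __post_init__(self) -> None:
        if self.polya_len is not None and self.kind != "three_prime":
            raise GenomeValidationError("polya_len is only meaningful on a 3' end")


@dataclass(frozen=True)
class ApaSite:
    representative_position: int
    member_positions: tuple[int, ...]
    support: int
    end_codon: str
    in_frame: bool


@dataclass(frozen=True)
class UtrAnnotation:
    unit_genes: tuple[str, ...]
    utr5_len: int | None
    utr3_len: int | None
    truncated5: bool = False
    truncated5_offset: int = 0


@dataclass(frozen=True)
class LncRnaCall:
    interval: tuple[int, int, str]
    antisense_of: str
    length: int
    polyadenylated: bool
    longest_orf_codons: int


# ---------------------------------------------------------------------------
# Exact circular anchoring
# ---------------------------------------------------------------------------

def _occurrences(haystack_doubled: str, needle: str, L: int) -> list[int]:
    """0-based circular start offsets (< L) of exact occurrences."""
    out = []
    start = 0
    while True:
        i = haystack_doubled.find(needle, start)
        if i == -1 or i >= L:
            break
        out.append(i)
        start = i + 1
    return out


def locate_sense_sequence(
    genome: CircularGenome, seq: str, anchor_k: int, anchor_side: str
) -> tuple[str, int]:
    """Map a transcript-sense sequence onto the circular genome exactly.

    ``anchor_side`` ('left' or 'right') selects which end of ``seq`` the
    k-mer anchor is taken from; the anchor is then extended maximally (the
    full sequence must match).  Returns (strand, offset0) where offset0 is
    the 0-based genomic offset of seq[0] on the H strand for strand 'H', or
    of revcomp(seq)[0] for strand 'L'.

    Raises EndResolutionError on ambiguous (multi-locus) anchors or no hit.
    """
    if len(seq) < anchor_k:
        raise EndResolutionError(f"flank shorter than anchor_k={anchor_k}")
    L = genome.length
    doubled = genome.sequence + genome.sequence[: max(len(seq), anchor_k) - 1]
    kmer = seq[:anchor_k] if anchor_side == "left" else seq[-anchor_k:]
    hits: list[tuple[str, int]] = []  # (strand, offset of seq[0] in its search space)
    for strand, query in (("H", seq), ("L", revcomp(seq))):
        km = kmer if strand == "H" else revcomp(kmer)
        # offset of the anchor k-mer within the H-sense query; revcomp flips
        # ends, so seq's 'right' anchor is the left end of revcomp(seq)
        if strand == "H":
            km_off = 0 if anchor_side == "left" else len(seq) - anchor_k
        else:
            km_off = 0 if anchor_side == "right" else len(query) - anchor_k
        for o in _occurrences(doubled, km, L):
            hits.append((strand, (o - km_off) % L))
    if not hits:
        raise EndResolutionError("anchor not found in genome")
    if len(hits) > 1:
        raise EndResolutionError(f"ambiguous anchor: {len(hits)} genomic loci")
    strand, off = hits[0]
    query = seq if strand == "H" else revcomp(seq)
    for i, base in enumerate(query):
        if genome.sequence[(off + i) % L] != base:
            raise EndResolutionError("anchor extension mismatch")
    return strand, off


def _sense_base(genome: CircularGenome, strand: str, pos: int) -> str:
    base = genome.sequence[(pos - 1) % genome.length]
    if strand == "H":
        return base
    return {"A": "T", "T": "A", "C": "G", "G": "C"}.get(base, "N")


def _extend_three_over_a(genome: CircularGenome, strand: str, pos: int) -> int:
    step = 1 if strand == "H" else -1
    while _sense_base(genome, strand, pos + step) == "A":
        pos += step
    return ((pos - 1) % genome.length) + 1


def _extend_five_over_a(genome: CircularGenome, strand: str, pos: int) -> int:
    step = 1 if strand == "H" else -1
    while _sense_base(genome, strand, pos - step) == "A":
        pos -= step
    return ((pos - 1) % genome.length) + 1


def _sense_positions(strand: str, off: int, seq_len: int, L: int) -> list[int]:
    """1-based genomic positions of each transcript-sense base."""
    if strand == "H":
        return [((off + i) % L) + 1 for i in range(seq_len)]
    # L strand: transcript base i sits at the far end of the revcomp match
    return [((off + seq_len - 1 - i) % L) + 1 for i in range(seq_len)]


# ---------------------------------------------------------------------------
# Circularized-RT junction reads
# ---------------------------------------------------------------------------

def resolve_crtpcr_junction(
    read: str,
    genome: CircularGenome,
    anchor_k: int = 15,
    min_polya: int = 5,
) -> tuple[TranscriptEnd, TranscriptEnd]:
    """Resolve one circularized-RT junction read into a (3', 5') end pair.

    The read has the transcript-sense layout [3' flank][A-tail][5' flank]:
    the longest A-run of length >= min_polya is the ligated poly(A) tail,
    the upstream flank's last genomic base is the transcript 3' end and the
    downstream flank's first genomic base is its 5' end.
    """
    read = read.upper()
    if len(read) < 2 * anchor_k + min_polya:
        raise EndResolutionError(
            f"read shorter than 2*anchor_k + min_polya = {2 * anchor_k + min_polya}"
        )
    runs = [m for m in re.finditer("A{%d,}" % min_polya, read)]
    # the tail must leave an anchorable flank on each side
    runs = [m for m in runs if m.start() >= anchor_k and len(read) - m.end() >= anchor_k]
    if not runs:
        raise EndResolutionError("no junction found: no poly(A) run with anchorable flanks")
    tail = max(runs, key=lambda m: m.end() - m.start())
    up, down = read[: tail.start()], read[tail.end() :]
    strand_u, off_u = locate_sense_sequence(genome, up, anchor_k, anchor_side="right")
    strand_d, off_d = locate_sense_sequence(genome, down, anchor_k, anchor_side="left")
    if strand_u != strand_d:
        raise EndResolutionError("strand conflict between 3' and 5' flanks")
    L = genome.length
    three_pos = _sense_positions(strand_u, off_u, len(up), L)[-1]
    five_pos = _sense_positions(strand_d, off_d, len(down), L)[0]
    # adenosines at the flank/tail boundary cannot be attributed from the read
    # alone; assign them maximally to the genome (transcripts are taken to end
    # on any genomic A's, the remainder being tail)
    three_pos = _extend_three_over_a(genome, strand_u, three_pos)
    five_pos = _extend_five_over_a(genome, strand_d, five_pos)
    polya = tail.end() - tail.start()
    return (
        TranscriptEnd(three_pos, "three_prime", strand_u, "crtpcr", polya_len=polya),
        TranscriptEnd(five_pos, "five_prime", strand_u, "crtpcr"),
    )


# ---------------------------------------------------------------------------
# RACE reads
# ---------------------------------------------------------------------------

def interpret_race_read(
    read: str,
    genome: CircularGenome,
    adapter: str,
    side: str,
    anchor_k: int = 15,
) -> TranscriptEnd:
    """Map a 5'- or 3'-RACE read to its transcript terminus.

    5' RACE reads carry the adapter as a prefix of the transcript-sense
    sequence; 3' RACE reads end with [3' flank][A-tail][adapter].
    """
    read, adapter = read.upper(), adapter.upper()
    if side not in ("five", "three"):
        raise EndResolutionError("side must be 'five' or 'three'")
    if side == "five":
        if not read.startswith(adapter):
            raise EndResolutionError("no adapter")
        insert = read[len(adapter) :]
        strand, off = locate_sense_sequence(genome, insert, anchor_k, anchor_side="left")
        pos = _sense_positions(strand, off, len(insert), genome.length)[0]
        return TranscriptEnd(pos, "five_prime", strand, "race")
    if not read.endswith(adapter):
        raise EndResolutionError("no adapter")
    insert = read[: len(read) - len(adapter)]
    m = re.search("A+$", insert)
    polya = (m.end() - m.start()) if m else 0
    insert = insert[: len(insert) - polya]
    strand, off = locate_sense_sequence(genome, insert, anchor_k, anchor_side="right")
    pos = _sense_positions(strand, off, len(insert), genome.length)[-1]
    if polya:
        pos = _extend_three_over_a(genome, strand, pos)
    return TranscriptEnd(pos, "three_prime", strand, "race", polya_len=polya or None)


# ---------------------------------------------------------------------------
# Poly(A) soft-clips from RNA-seq alignments
# ---------------------------------------------------------------------------

def call_polya_sites(
    fragments: Sequence[AlignedFragment],
    genome: CircularGenome,
    min_clip: int = 5,
    min_a_frac: float = 0.9,
) -> list[TranscriptEnd]:
    """3' ends from A-rich soft-clipped tails, aggregated by position.

    A fragment's ``clip3`` is already in transcript sense, so the adenine
    fraction test applies directly whichever strand the read mapped to.
    """
    counts: dict[tuple[int, str], list[int]] = {}
    for frag in fragments:
        clip = frag.clip3
        if clip is None or len(clip) < min_clip:
            continue
        a_frac = clip.upper().count("A") / len(clip)
        if a_frac < min_a_frac:
            continue
        key = (frag.three_prime_position(), frag.strand)
        counts.setdefault(key, []).append(len(clip))
    out = [
        TranscriptEnd(pos, "three_prime", strand, "softclip",
                      polya_len=max(lens), support=len(lens))
        for (pos, strand), lens in counts.items()
    ]
    return sorted(out, key=lambda e: (e.strand, e.position))


# ---------------------------------------------------------------------------
# APA clustering
# ---------------------------------------------------------------------------

def cluster_apa(
    ends: Sequence[TranscriptEnd],
    genome: CircularGenome,
    gene: GeneFeature,
    cluster_tol: int = 3,
) -> list[ApaSite]:
    """Single-linkage clustering of 3' ends with positional tolerance.

    The representative is the highest-support member (ties to the smaller
    position); its end codon is the sense-strand 3-mer ending at the
    representative, and in_frame tests whether the representative falls on a
    codon boundary of ``gene``'s reading frame.
    """
    if not ends:
        return []
    strands = {e.strand for e in ends}
    if len(strands) > 1:
        raise GenomeValidationError("APA clustering requires ends from a single strand")
    strand = strands.pop()
    L = genome.length
    ordered = sorted(ends, key=lambda e: e.position)
    clusters: list[list[TranscriptEnd]] = [[ordered[0]]]
    for e in ordered[1:]:
        if e.position - clusters[-1][-1].position <= cluster_tol:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    out = []
    for members in clusters:
        rep = max(members, key=lambda e: (e.support, -e.position))
        pos = rep.position
        if strand == "H":
            codon = genome.fetch(((pos - 3) % L) + 1, pos)
            in_frame = (pos - gene.start + 1) % 3 == 0
        else:
            codon = revcomp(genome.fetch(pos, ((pos + 1) % L) + 1))
            in_frame = (gene.end - pos + 1) % 3 == 0
        out.append(
            ApaSite(
                representative_position=pos,
                member_positions=tuple(e.position for e in members),
                support=sum(e.support for e in members),
                end_codon=codon,
                in_frame=in_frame,
            )
        )
    return out


# ---------------------------------------------------------------------------
# UTR annotation
# ---------------------------------------------------------------------------

def _signed_circular(delta: int, L: int) -> int:
    d = delta % L
    return d - L if d > L // 2 else d


def annotate_utrs(
    units,
    ends: Sequence[TranscriptEnd],
    features: Sequence[GeneFeature],
    genome: CircularGenome,
    max_assign: int = 300,
) -> list[UtrAnnotation]:
    """UTR lengths per transcription unit from mapped 5'/3' ends.

    utr5 is the distance from a mapped 5' end to the unit's first start
    codon; utr3 the distance from the unit's last stop codon to a mapped 3'
    end (pre-poly(A)).  A 5' end downstream of the start codon is reported
    with a truncated-5' flag rather than as an error; 3' ends upstream of
    the stop codon are APA territory and are not UTR records.  Alternative
    5' ends yield one record each.
    """
    by_name = {f.name: f for f in features}
    L = genome.length
    out: list[UtrAnnotation] = []
    for unit in units:
        first = by_name[unit.genes[0]]
        last = by_name[unit.genes[-1]]
        if unit.strand == "H":
            start_codon_pos, stop_pos = first.start, last.end
            utr5_of = lambda p: _signed_circular(start_codon_pos - p, L)
            utr3_of = lambda p: _signed_circular(p - stop_pos, L)
        else:
            start_codon_pos, stop_pos = first.end, last.start
            utr5_of = lambda p: _signed_circular(p - start_codon_pos, L)
            utr3_of = lambda p: _signed_circular(stop_pos - p, L)
        fives = sorted(
            (e for e in ends if e.kind == "five_prime" and e.strand == unit.strand
             and abs(utr5_of(e.position)) <= max_assign),
            key=lambda e: (-e.support, e.position),
        )
        threes = sorted(
            (e for e in ends if e.kind == "three_prime" and e.strand == unit.strand
             and 0 <= utr3_of(e.position) <= max_assign),
            key=lambda e: (-e.support, e.position),
        )
        utr3 = utr3_of(threes[0].position) if threes else None
        if not fives:
            if utr3 is not None:
                out.append(UtrAnnotation(tuple(unit.genes), None, utr3))
            continue
        for e in fives:
            d = utr5_of(e.position)
            if d >= 0:
                out.append(UtrAnnotation(tuple(unit.genes), d, utr3))
            else:
                out.append(
                    UtrAnnotation(tuple(unit.genes), None, utr3,
                                  truncated5=True, truncated5_offset=-d)
                )
    return out


# ---------------------------------------------------------------------------
# ORF scanning and lncRNA classification
# ---------------------------------------------------------------------------

def longest_orf_codons(seq: str) -> int:
    """Longest ATG-initiated open reading frame, in codons (ATG included,
    stop excluded), scanning all three frames of the given sense only."""
    seq = seq.upper()
    best = 0
    for frame in range(3):
        i = frame
        open_from: int | None = None
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if open_from is None:
                if codon == START_CODON:
                    open_from = i
            elif codon in STOP_CODONS:
                best = max(best, (i - open_from) // 3)
                open_from = None
            i += 3
        # an ORF still open at the end of the transcript has no stop; count it
        if open_from is not None:
            best = max(best, (len(seq) - open_from - (len(seq) - open_from) % 3) // 3)
    return best


def classify_lncrna(
    transcript_interval: tuple[int, int, str],
    polyadenylated: bool,
    genome: CircularGenome,
    features: Sequence[GeneFeature],
    orf_threshold: int = 50,
    min_antisense_overlap: float = 0.5,
) -> LncRnaCall | None:
    """Call a long noncoding antisense RNA, or return None.

    The call requires all four of: length > 200 nt, polyadenylation, no ORF
    of >= orf_threshold codons on the transcript's own sense, and at least
    min_antisense_overlap of the transcript overlapping an annotated gene on
    the opposite strand.
    """
    from .linkage import circular_overlap  # local import avoids a cycle

    start, end, strand = transcript_interval
    L = genome.length
    length = (end - start) % L + 1
    if length <= 200 or not polyadenylated:
        return None
    seq = genome.fetch(start, end)
    if strand == "L":
        seq = revcomp(seq)
    orf = longest_orf_codons(seq)
    if orf >= orf_threshold:
        return None
    best_gene, best_frac = None, 0.0
    for f in features:
        if f.strand == strand:
            continue
        frac = circular_overlap((start, end), (f.start, f.end), L) / length
        if frac > best_frac:
            best_gene, best_frac = f.name, frac
    if best_gene is None or best_frac < min_antisense_overlap:
        return None
    return LncRnaCall(
        interval=(start, end, strand),
        antisense_of=best_gene,
        length=length,
        polyadenylated=True,
        longest_orf_codons=orf,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def ends_to_tsv(ends: Sequence[TranscriptEnd], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tkind\tstrand\tmethod\tpolya_len\tsupport\n")
        for e in sorted(ends, key=lambda e: (e.position, e.kind)):
            pa = "" if e.polya_len is None else e.polya_len
            fh.write(f"{e.position}\t{e.kind}\t{e.strand}\t{e.method}\t{pa}\t{e.support}\n")


def apa_to_tsv(sites: Sequence[ApaSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tmembers\tsupport\tend_codon\tin_frame\n")
        for s in sites:
            fh.write(
                f"{s.representative_position}\t{','.join(map(str, s.member_positions))}\t"
                f"{s.support}\t{s.end_codon}\t{s.in_frame}\n"
            )
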