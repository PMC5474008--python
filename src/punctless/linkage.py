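"""Transcription-unit calling from IGR-spanning read pairs.

Read pairs whose mates fall in two adjacent same-strand genes (or single
reads crossing the whole intergenic region) are evidence that the two genes
are co-transcribed on one mature messenger.  Because RNA-seq libraries also
contain traces of unprocessed precursor RNA, an adjacency supported by only
a handful of pairs across a large coverage discontinuity is demoted to
precursor read-through rather than joined: a genuine mature polycistron is
one molecule, so its genes cannot differ 10-fold in depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage import AlignedFragment, CoverageProfile
from .genome import CircularGenome, GeneFeature, GenomeValidationError, KIND_TRNA, KIND_PCG


@dataclass(frozen=True)
class LinkageEvidence:
    """Spanning-fragment support for one same-strand adjacent gene pair."""

    gene_a: str
    gene_b: str
    strand: str
    n_spanning: int
    igr_median_depth: float
    flank_a_median: float
    flank_b_median: float

    @property
    def flank_depth_ratio(self) -> float:
        hi = max(self.flank_a_median, self.flank_b_median)
        lo = min(self.flank_a_median, self.flank_b_median)
        return hi / max(1.0, lo)

    @property
    def min_flank_median(self) -> float:
        return min(self.flank_a_median, self.flank_b_median)


@dataclass(frozen=True)
class TranscriptionUnit:
    """An ordered run of co-transcribed genes (5' to 3' in transcript order)."""

    genes: tuple[str, ...]
    strand: str
    status: str = "mature"  # mature | precursor_readthrough | ambiguous
    n_cistrons: int = 0

    def with_status(self, status: str) -> "TranscriptionUnit":
        return TranscriptionUnit(self.genes, self.strand, status, self.n_cistrons)


@dataclass(frozen=True)
class DemotedAdjacency:
    gene_a: str
    gene_b: str
    n_spanning: int
    flank_depth_ratio: float


@dataclass
class UnitCallResult:
    units: list[TranscriptionUnit]
    demoted: list[DemotedAdjacency] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Circular-interval helpers
# ---------------------------------------------------------------------------

def _unwrap(start: int, end: int, L: int) -> tuple[int, int]:
    """1-based inclusive circular interval -> 0-based [s, e) with e possibly > L."""
    s = start - 1
    e = end  # exclusive
    if e <= s:
        e += L
    return s, e


def circular_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> int:
    """Length of the largest contiguous overlap arc of two circular intervals
    (1-based inclusive; start > end denotes an origin-wrapping interval)."""
    sa, ea = _unwrap(*a, L)
    sb, eb = _unwrap(*b, L)
    best = 0
    for shift in (-L, 0, L):
        best = max(best, min(ea, eb + shift) - max(sa, sb + shift))
    return max(0, best)


def _feature_interval(f: GeneFeature) -> tuple[int, int]:
    return (f.start, f.end)


def _median_depth(profile: CoverageProfile, start: int, end: int, strand: str, L: int) -> float:
    depth = profile.depth(strand)
    s, e = _unwrap(start, end, L)
    idx = np.arange(s, e) % L
    return float(np.median(depth[idx])) if len(idx) else 0.0


# ---------------------------------------------------------------------------
# Adjacency enumeration
# ---------------------------------------------------------------------------

def adjacent_pairs(features: Sequence[GeneFeature]) -> list[tuple[GeneFeature, GeneFeature]]:
    """Consecutive feature pairs in circular genome order (including wrap-around)."""
    feats = sorted(features, key=lambda f: (f.start, f.end))
    return [(feats[i], feats[(i + 1) % len(feats)]) for i in range(len(feats))]


def collect_linkage(
    fragments: Sequence[AlignedFragment],
    features: Sequence[GeneFeature],
    genome: CircularGenome,
    profile: CoverageProfile | None = None,
    min_overlap: int = 1,
) -> list[LinkageEvidence]:
    """Count IGR-spanning fragments for every same-strand adjacent gene pair.

    A fragment spans the pair when one mate overlaps each gene by at least
    ``min_overlap`` nt (for single-end fragments: the one read overlaps both
    genes, i.e. crosses the entire IGR), on the pair's strand.
    """
    L = genome.length
    out: list[LinkageEvidence] = []
    for fa, fb in adjacent_pairs(features):
        if fa.strand != fb.strand:
            continue
        strand = fa.strand
        ia, ib = _feature_interval(fa), _feature_interval(fb)
        n = 0
        for frag in fragments:
            if frag.strand != strand:
                continue
            ivs = frag.intervals()
            if len(ivs) == 2:
                m1, m2 = ivs
                hit = (
                    circular_overlap(m1, ia, L) >= min_overlap
                    and circular_overlap(m2, ib, L) >= min_overlap
                ) or (
                    circular_overlap(m2, ia, L) >= min_overlap
                    and circular_overlap(m1, ib, L) >= min_overlap
                )
            else:
                (m1,) = ivs
                hit = (
                    circular_overlap(m1, ia, L) >= min_overlap
                    and circular_overlap(m1, ib, L) >= min_overlap
                )
            if hit:
                n += 1
        if profile is not None:
            flank_a = _median_depth(profile, fa.start, fa.end, strand, L)
            flank_b = _median_depth(profile, fb.start, fb.end, strand, L)
            # IGR span (may be zero-length when the genes abut or overlap)
            igr_start = fa.end % L + 1
            igr_end = (fb.start - 2) % L + 1
            gap = (fb.start - 1 - fa.end) % L if fb.start != fa.end + 1 else 0
            if 0 < gap < L // 2:
                igr_med = _median_depth(profile, igr_start, igr_end, strand, L)
            else:
                igr_med = min(flank_a, flank_b)
        else:
            flank_a = flank_b = igr_med = 0.0
        out.append(
            LinkageEvidence(fa.name, fb.name, strand, n, igr_med, flank_a, flank_b)
        )
    return out


# ---------------------------------------------------------------------------
# Unit calling
# ---------------------------------------------------------------------------

def call_units(
    linkage: Sequence[LinkageEvidence],
    features: Sequence[GeneFeature],
    min_support: int = 1,
    precursor_ratio: float = 10.0,
    precursor_max_support: int = 2,
    precursor_support_frac: float = 2.0,
) -> UnitCallResult:
    """Partition the annotated genes into transcription units.

    Adjacencies with n_spanning >= min_support are joined.  A joined
    adjacency is demoted to precursor read-through when its flank depth
    ratio is >= precursor_ratio (a single mature molecule cannot carry a
    10-fold abundance step) while its support does not exceed
    max(precursor_max_support, precursor_support_frac * min flank median) —
    i.e. the linkage is far weaker than co-transcription at the minority
    gene's own depth would produce.  Read-through between neighbours of
    similar abundance leaves no depth contradiction and is not decidable
    from coverage alone; such joins require orthogonal end evidence to
    refute.  tRNA genes are processing punctuation marks and always form
    their own units; adjacencies across strand switches are never joined.
    """
    feats = sorted(features, key=lambda f: (f.start, f.end))
    by_pair = {(e.gene_a, e.gene_b): e for e in linkage}
    joined: dict[tuple[str, str], bool] = {}
    demoted: list[DemotedAdjacency] = []
    for fa, fb in adjacent_pairs(feats):
        key = (fa.name, fb.name)
        if fa.strand != fb.strand:
            joined[key] = False
            continue
        ev = by_pair.get(key)
        if ev is None:
            raise GenomeValidationError(
                f"linkage evidence missing for same-strand adjacency {key}"
            )
        if fa.kind == KIND_TRNA or fb.kind == KIND_TRNA:
            joined[key] = False
            continue
        ok = ev.n_spanning >= min_support
        if ok:
            support_cap = max(precursor_max_support,
                              precursor_support_frac * ev.min_flank_median)
            if ev.flank_depth_ratio >= precursor_ratio and ev.n_spanning <= support_cap:
                ok = False
                demoted.append(
                    DemotedAdjacency(fa.name, fb.name, ev.n_spanning, ev.flank_depth_ratio)
                )
        joined[key] = ok

    # walk the circle, cutting at unjoined adjacencies
    n = len(feats)
    pairs = adjacent_pairs(feats)
    cut_after = [not joined[(a.name, b.name)] for a, b in pairs]  # cut between i and i+1
    if all(not c for c in cut_after):
        # fully circular join is degenerate; cut at the largest gap (wrap pair)
        cut_after[-1] = True
    # find unit start indices: i is a start when the adjacency before it is cut
    starts = [(i + 1) % n for i, c in enumerate(cut_after) if c]
    units: list[TranscriptionUnit] = []
    for s in sorted(starts):
        genes = [feats[s]]
        i = s
        while not cut_after[i]:
            i = (i + 1) % n
            genes.append(feats[i])
        strand = genes[0].strand
        ordered = genes if strand == "H" else list(reversed(genes))  # transcript 5'->3'
        units.append(
            TranscriptionUnit(
                genes=tuple(g.name for g in ordered),
                strand=strand,
                status="mature",
                n_cistrons=sum(1 for g in genes if g.kind == KIND_PCG),
            )
        )
    start_pos = {f.name: f.start for f in feats}
    units.sort(key=lambda u: min(start_pos[g] for g in u.genes))
    return UnitCallResult(units=units, demoted=demoted)


def classify_units(units: Sequence[TranscriptionUnit]) -> dict[str, int]:
    """Tally mono-/bi-/tricistronic units and PCG membership of polycistrons."""
    pcg_units = [u for u in units if u.n_cistrons > 0]
    summary = {
        "n_units": len(units),
        "n_pcg_units": len(pcg_units),
        "n_monocistronic": sum(1 for u in pcg_units if u.n_cistrons == 1),
        "n_bicistronic": sum(1 for u in pcg_units if u.n_cistrons == 2),
        "n_tricistronic": sum(1 for u in pcg_units if u.n_cistrons == 3),
        "n_polycistronic": sum(1 for u in pcg_units if u.n_cistrons >= 2),
        "pcgs_in_polycistrons": sum(u.n_cistrons for u in pcg_units if u.n_cistrons >= 2),
    }
    return summary


def units_to_gff3(
    units: Sequence[TranscriptionUnit],
    features: Sequence[GeneFeature],
    genome: CircularGenome,
    path,
) -> None:
    by_name = {f.name: f for f in features}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, u in enumerate(units, 1):
            spans = [by_name[g] for g in u.genes]
            start = min(f.start for f in spans)
            end = max(f.end for f in spans)
            strand = "+" if u.strand == "H" else "-"
            fh.write(
                f"{genome.id}\tpunctless\ttranscription_unit\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID=unit{i:02d};genes={','.join(u.genes)};status={u.status};"
                f"n_cistrons={u.n_cistrons}\n"
            )
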