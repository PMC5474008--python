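"""Strand-specific per-position read coverage on a circular genome.

Includes the log-scale normalization used for display of organelle RNA-seq
tracks (log(coverage+1)/log(max coverage+1)), detection of zero-coverage
segments (candidate control regions / unexpressed gaps) and of abrupt
coverage discontinuities (candidate processing sites / unit boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import CircularGenome, GeneFeature, GenomeValidationError

PROTOCOLS = ("unstranded", "fr-firststrand", "fr-secondstrand")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedFragment:
    """One sequenced cDNA fragment mapped to the genome.

    Mate intervals are 1-based inclusive; an interval with start > end wraps
    the origin.  ``strand`` is the strand of transcription (H/L), already
    resolved per the library protocol.  ``clip3`` is the soft-clipped tail at
    the fragment's transcript-3' side, given in transcript sense (so a
    poly(A) tail reads as A's regardless of mapping orientation).
    """

    mate1: tuple[int, int]
    mate2: tuple[int, int] | None
    strand: str
    clip3: str | None = None

    def intervals(self) -> list[tuple[int, int]]:
        out = [self.mate1]
        if self.mate2 is not None:
            out.append(self.mate2)
        return out

    def three_prime_position(self) -> int:
        """Genomic position of the fragment's transcript-3'-most aligned base."""
        ivs = self.intervals()
        if self.strand == "H":
            return max(e for _, e in ivs)
        return min(s for s, _ in ivs)


class CoverageProfile:
    """Per-position, per-strand read depth over a circular genome."""

    def __init__(self, genome_id: str, length: int,
                 depth_h: np.ndarray | None = None,
                 depth_l: np.ndarray | None = None) -> None:
        self.genome_id = genome_id
        self.length = length
        self.depth_h = np.zeros(length, dtype=np.int64) if depth_h is None else depth_h
        self.depth_l = np.zeros(length, dtype=np.int64) if depth_l is None else depth_l
        if len(self.depth_h) != length or len(self.depth_l) != length:
            raise GenomeValidationError("depth array length != genome length")

    def depth(self, strand: str | None = None) -> np.ndarray:
        if strand == "H":
            return self.depth_h
        if strand == "L":
            return self.depth_l
        return self.depth_h + self.depth_l

    def add_interval(self, start: int, end: int, strand: str) -> None:
        """Increment depth on a 1-based inclusive, possibly wrapping interval."""
        arr = self.depth_h if strand == "H" else self.depth_l
        if start <= end:
            arr[start - 1 : end] += 1
        else:
            arr[start - 1 :] += 1
            arr[:end] += 1

    @property
    def total_bases(self) -> int:
        return int(self.depth_h.sum() + self.depth_l.sum())


@dataclass
class NormalizedCoverage:
    """Log-normalized coverage in [0, 1] per strand.

    ``mean_level`` is the raw mean depth mapped onto the normalized scale;
    ``mean_normalized`` is the plain mean of the normalized values (both are
    reported because either convention is seen on published tracks).
    """

    values_h: np.ndarray
    values_l: np.ndarray
    mean_level: float
    mean_normalized: float


@dataclass(frozen=True)
class CoverageBreakpoint:
    position: int
    strand: str
    drop_ratio: float
    direction: str  # "rise" | "fall"


# ---------------------------------------------------------------------------
# Coverage computation
# ---------------------------------------------------------------------------

def _record_strand(rec, protocol: str) -> str:
    """Strand of transcription for one SAM record under the library protocol."""
    mapped_minus = rec.is_reverse
    read1_minus = mapped_minus if (not rec.is_paired or rec.is_read1) else not mapped_minus
    if protocol == "fr-firststrand":
        read1_minus = not read1_minus
    # unstranded: take the alignment strand of read1 at face value
    return "L" if read1_minus else "H"


def compute_coverage(
    alignments,
    genome: CircularGenome,
    protocol: str = "unstranded",
) -> CoverageProfile:
    """Per-position depth from SAM/BAM (path) or an iterable of AlignedFragment.

    Each aligned base increments the depth of its reference position on the
    strand of transcription; unmapped, secondary, duplicate and QC-fail
    records are skipped; alignment deletions do not increment and insertions
    have no reference position.  Reads crossing the origin wrap.
    """
    if protocol not in PROTOCOLS:
        raise GenomeValidationError(f"unknown protocol {protocol!r}")
    profile = CoverageProfile(genome.id, genome.length)
    if isinstance(alignments, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_duplicate or rec.is_qcfail:
                    continue
                ref_len = fh.get_reference_length(rec.reference_name)
                if ref_len != genome.length:
                    raise GenomeValidationError(
                        f"reference length {ref_len} != genome length {genome.length}"
                    )
                strand = _record_strand(rec, protocol)
                arr = profile.depth_h if strand == "H" else profile.depth_l
                for b0, b1 in rec.get_blocks():  # 0-based half-open, no deletions
                    arr[b0:b1] += 1
    else:
        for frag in alignments:
            for s, e in frag.intervals():
                profile.add_interval(s, e, frag.strand)
    return profile


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_log(profile: CoverageProfile) -> NormalizedCoverage:
    """log(depth+1)/log(max depth+1), base-invariant, in [0, 1].

    The maximum is taken over both strands so the two tracks share a scale;
    an all-zero profile normalizes to all zeros with a warning.
    """
    max_depth = int(max(profile.depth_h.max(initial=0), profile.depth_l.max(initial=0)))
    if max_depth == 0:
        warnings.warn("all-zero coverage profile; normalized track is all zeros")
        zeros = np.zeros(profile.length)
        return NormalizedCoverage(zeros, zeros.copy(), 0.0, 0.0)
    denom = np.log(max_depth + 1)
    vh = np.log(profile.depth_h + 1.0) / denom
    vl = np.log(profile.depth_l + 1.0) / denom
    mean_raw = float(profile.depth().mean())
    return NormalizedCoverage(
        values_h=vh,
        values_l=vl,
        mean_level=float(np.log(mean_raw + 1.0) / denom),
        mean_normalized=float(np.concatenate([vh, vl]).mean()),
    )


# ---------------------------------------------------------------------------
# Zero-coverage segments
# ---------------------------------------------------------------------------

def zero_coverage_segments(profile: CoverageProfile, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of zero combined-strand depth, merged across the origin.

    Returns 1-based inclusive (start, end) tuples; a wrapped segment has
    start > end.  Only runs of length >= min_len are reported.
    """
    if min_len < 1:
        raise GenomeValidationError("min_len must be >= 1")
    combined = profile.depth()
    L = profile.length
    zero = combined == 0
    if zero.all():
        return [(1, L)]
    if not zero.any():
        return []
    # find runs on the linear array
    padded = np.diff(np.r_[0, zero.astype(np.int8), 0])
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1  # inclusive 0-based
    runs = [(int(s), int(e)) for s, e in zip(starts, ends)]
    # merge wrap-around: run ending at L-1 with run starting at 0
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L - 1:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])
    out = []
    for s, e in runs:
        length = (e - s + 1) if s <= e else (L - s + e + 1)
        if length >= min_len:
            out.append((s + 1, e + 1))
    return out


# ---------------------------------------------------------------------------
# Breakpoints
# ---------------------------------------------------------------------------

def _rolling_medians(depth: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Circular flanking-window medians: left over [i-w, i-1], right over [i, i+w-1]."""
    L = len(depth)
    ext = np.r_[depth[-window:], depth, depth[: window - 1]]
    win = np.lib.stride_tricks.sliding_window_view(ext, window)
    med = np.median(win, axis=1)
    left = med[:L]           # window ending at i-1
    right = med[window:window + L]  # window starting at i
    return left, right


def find_breakpoints(
    profile: CoverageProfile,
    window: int = 50,
    min_ratio: float = 5.0,
    per_strand: bool = True,
) -> list[CoverageBreakpoint]:
    """Positions where flanking-window median depths differ by >= min_ratio.

    The ratio is max(flank medians) / max(1, min(flank medians)); contiguous
    candidate runs are deduplicated to their local ratio maximum (the centre
    of a tied plateau).  The median resists single-read spikes; the default
    window is about one read length.
    """
    if window < 5:
        raise GenomeValidationError("window must be >= 5")
    out: list[CoverageBreakpoint] = []
    strands = ("H", "L") if per_strand else (None,)
    for strand in strands:
        depth = profile.depth(strand).astype(float)
        if depth.max(initial=0) == 0:
            continue
        left, right = _rolling_medians(depth, window)
        ratio = np.maximum(left, right) / np.maximum(1.0, np.minimum(left, right))
        cand = np.flatnonzero(ratio >= min_ratio)
        if cand.size == 0:
            continue
        # group candidates separated by > window/2 into distinct events
        breaks = np.flatnonzero(np.diff(cand) > window // 2)
        groups = np.split(cand, breaks + 1)
        for g in groups:
            gmax = ratio[g].max()
            tied = g[ratio[g] >= gmax * (1 - 1e-12)]
            pos0 = int(tied[len(tied) // 2])
            direction = "fall" if left[pos0] > right[pos0] else "rise"
            out.append(
                CoverageBreakpoint(
                    position=pos0 + 1,
                    strand=strand if strand else "H",
                    drop_ratio=float(gmax),
                    direction=direction,
                )
            )
    return sorted(out, key=lambda b: (b.position, b.strand))


# ---------------------------------------------------------------------------
# Export and plotting
# ---------------------------------------------------------------------------

def coverage_to_tsv(profile: CoverageProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tdepth_H\tdepth_L\n")
        for i in range(profile.length):
            fh.write(f"{i + 1}\t{profile.depth_h[i]}\t{profile.depth_l[i]}\n")


def coverage_to_bedgraph(profile: CoverageProfile, path: str | Path, strand: str | None = None) -> None:
    depth = profile.depth(strand)
    with open(path, "w") as fh:
        start = 0
        for i in range(1, profile.length + 1):
            if i == profile.length or depth[i] != depth[start]:
                if depth[start] != 0:
                    fh.write(f"{profile.genome_id}\t{start}\t{i}\t{int(depth[start])}\n")
                start = i


def plot_coverage(
    profile: CoverageProfile,
    features: Sequence[GeneFeature],
    path: str | Path,
) -> None:
    """Normalized coverage track with gene blocks and a mean-level indicator."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = normalize_log(profile)
    x = np.arange(1, profile.length + 1)
    fig, ax = plt.subplots(figsize=(12, 3.2))
    ax.fill_between(x, norm.values_h, step="mid", alpha=0.7, label="H strand")
    ax.fill_between(x, -norm.values_l, step="mid", alpha=0.7, label="L strand")
    ax.axhline(norm.mean_level, ls="--", lw=0.8, color="k", label="mean level")
    colors = {"PCG": "tab:green", "rRNA": "tab:red", "tRNA": "tab:blue"}
    for f in features:
        y = -1.12 if f.strand == "L" else -1.05
        ax.plot([f.start, f.end], [y, y], lw=4, color=colors.get(f.kind, "gray"))
    ax.set_xlabel("genome position (nt)")
    ax.set_ylabel("log-normalized coverage")
    ax.set_ylim(-1.2, 1.05)
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
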