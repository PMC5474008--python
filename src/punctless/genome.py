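"""Annotated circular mitogenomes: loading, validation and descriptive arithmetic.

Coordinates are 1-based inclusive throughout the public API (matching how
positions are conventionally printed for organelle genomes); internal
circular arithmetic runs on a 0-based shadow index modulo the genome
length.  The heavy strand (H) is, by convention, the strand carrying most
protein-coding genes; the mapping from "+/-" to H/L is configurable and
defaults to "+" == H.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
AMBIGUOUS = IUPAC_DNA - set("ACGT")

KIND_PCG = "PCG"
KIND_RRNA = "rRNA"
KIND_TRNA = "tRNA"
VALID_KINDS = (KIND_PCG, KIND_RRNA, KIND_TRNA)


class GenomeValidationError(ValueError):
    """Raised when a genome or its annotation violates a structural invariant."""


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA sequence with 1-based coordinate helpers."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise GenomeValidationError(
                f"genome {self.id!r}: non-IUPAC residue(s) {sorted(bad)}"
            )
        if not seq:
            raise GenomeValidationError(f"genome {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive, possibly origin-wrapping span."""
        L = self.length
        if not (1 <= start <= L and 1 <= end <= L):
            raise GenomeValidationError(
                f"span {start}..{end} outside [1, {L}] on genome {self.id!r}"
            )
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene on a circular genome (1-based inclusive span)."""

    name: str
    kind: str
    strand: str
    start: int
    end: int
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise GenomeValidationError(f"{self.name}: unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise GenomeValidationError(f"{self.name}: strand must be H or L, got {self.strand!r}")

    def span_length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def validate(self, genome_length: int) -> None:
        L = genome_length
        if not (1 <= self.start <= L and 1 <= self.end <= L):
            raise GenomeValidationError(
                f"feature {self.name!r}: coordinates {self.start}..{self.end} outside [1, {L}]"
            )
        if not self.wraps_origin and self.end < self.start:
            raise GenomeValidationError(
                f"feature {self.name!r}: end < start without wraps_origin"
            )
        if self.span_length(L) < 3:
            raise GenomeValidationError(f"feature {self.name!r}: span shorter than 3 nt")

    def positions(self, genome_length: int) -> range | list[int]:
        """1-based positions covered by the feature, unwrapped."""
        if not self.wraps_origin:
            return range(self.start, self.end + 1)
        return list(range(self.start, genome_length + 1)) + list(range(1, self.end + 1))


@dataclass(frozen=True)
class IntergenicRegion:
    """Gap between consecutive features in circular genome order (length >= 0)."""

    left_gene: str
    right_gene: str
    start: int
    end: int
    length: int


@dataclass(frozen=True)
class GeneOverlap:
    left_gene: str
    right_gene: str
    length: int


@dataclass(frozen=True)
class AnnotationDiff:
    """Column-wise summary of a pairwise alignment of two genome versions."""

    variability_pct: float
    ambiguity_pct: float
    gap_pct: float

    def __post_init__(self) -> None:
        for v in (self.variability_pct, self.ambiguity_pct, self.gap_pct):
            if not (0.0 <= v <= 100.0):
                raise GenomeValidationError(f"percentage {v} outside [0, 100]")


# ---------------------------------------------------------------------------
# Loading and writing annotations
# ---------------------------------------------------------------------------

_GENBANK_KIND = {"CDS": KIND_PCG, "rRNA": KIND_RRNA, "tRNA": KIND_TRNA}


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "locus_tag", "label"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def load_annotation(
    path: str | Path,
    feature_table: str | Path | None = None,
    plus_is: str = "H",
) -> tuple[CircularGenome, list[GeneFeature]]:
    """Load a GenBank flat file, or a FASTA plus a TSV feature table.

    The TSV table has columns name, kind, strand, start, end (1-based
    inclusive; strand "+"/"-" or "H"/"L").  ``plus_is`` sets which
    mitogenome strand the "+" file strand denotes.
    """
    path = Path(path)
    if plus_is not in ("H", "L"):
        raise GenomeValidationError("plus_is must be 'H' or 'L'")
    minus_is = "L" if plus_is == "H" else "H"
    strand_map = {"+": plus_is, "-": minus_is, "H": "H", "L": "L", "1": plus_is, "-1": minus_is}

    features: list[GeneFeature] = []
    if feature_table is None:
        record = next(SeqIO.parse(str(path), "genbank"))
        genome = CircularGenome(id=record.id, sequence=str(record.seq))
        L = genome.length
        for feat in record.features:
            kind = _GENBANK_KIND.get(feat.type)
            if kind is None:
                continue
            name = _feature_name(feat)
            if name is None:
                continue
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
            wraps = end > L or start > end
            strand = plus_is if (feat.location.strand or 1) >= 0 else minus_is
            features.append(
                GeneFeature(name=name, kind=kind, strand=strand,
                            start=((start - 1) % L) + 1, end=((end - 1) % L) + 1,
                            wraps_origin=wraps)
            )
    else:
        record = next(SeqIO.parse(str(path), "fasta"))
        genome = CircularGenome(id=record.id, sequence=str(record.seq))
        L = genome.length
        for line in Path(feature_table).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\t|,", line)
            if parts[0].lower() == "name":
                continue
            if len(parts) < 5:
                raise GenomeValidationError(f"feature table row too short: {line!r}")
            name, kind, strand, start, end = parts[:5]
            if strand not in strand_map:
                raise GenomeValidationError(f"feature {name!r}: unknown strand {strand!r}")
            start_i, end_i = int(start), int(end)
            wraps = end_i < start_i
            features.append(
                GeneFeature(name=name, kind=kind, strand=strand_map[strand],
                            start=start_i, end=end_i, wraps_origin=wraps)
            )

    if not features:
        raise GenomeValidationError(f"{path}: no gene features found")
    names = [f.name for f in features]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise GenomeValidationError(f"duplicate feature name(s): {sorted(dupes)}")
    for f in features:
        f.validate(genome.length)
    features.sort(key=lambda f: (f.start, f.end))
    return genome, features


def write_annotation(genome: CircularGenome, features: Sequence[GeneFeature],
                     fasta_path: str | Path, table_path: str | Path) -> None:
    """Write the FASTA + TSV feature-table representation (round-trips with load)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(table_path, "w") as fh:
        fh.write("name\tkind\tstrand\tstart\tend\n")
        for f in features:
            fh.write(f"{f.name}\t{f.kind}\t{f.strand}\t{f.start}\t{f.end}\n")


# ---------------------------------------------------------------------------
# IGR / overlap table
# ---------------------------------------------------------------------------

def igr_table(
    genome: CircularGenome, features: Sequence[GeneFeature]
) -> tuple[list[IntergenicRegion], list[GeneOverlap]]:
    """Intergenic gaps and overlaps between consecutive features in circular order.

    Every consecutive pair (including the wrap-around pair) yields exactly
    one IGR of length >= 0, or one overlap entry of length >= 1; overlapping
    pairs are excluded from the IGR table and reported separately.
    """
    if len(features) < 2:
        return [], []
    L = genome.length
    feats = sorted(features, key=lambda f: (f.start, f.end))
    igrs: list[IntergenicRegion] = []
    overlaps: list[GeneOverlap] = []
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        cur_end0 = (cur.end - 1) + (L if cur.wraps_origin else 0)  # 0-based, may exceed L-1
        if i + 1 < len(feats):
            gap = (nxt.start - 1) - cur_end0 - 1
        else:  # wrap-around pair
            gap = (nxt.start - 1) + L - cur_end0 - 1
        if gap < 0:
            overlaps.append(GeneOverlap(cur.name, nxt.name, -gap))
        else:
            start = (cur_end0 + 1) % L + 1
            end = (cur_end0 + gap) % L + 1 if gap > 0 else start - 1
            if gap == 0:
                start, end = start, start - 1  # degenerate; length carries the information
            igrs.append(IntergenicRegion(cur.name, nxt.name, start, end, gap))
    return igrs, overlaps


def igr_occupancy_oracle(
    genome: CircularGenome, features: Sequence[GeneFeature]
) -> tuple[list[int], list[int]]:
    """Brute-force per-position occupancy computation of IGR and overlap lengths.

    Independent of igr_table: marks every covered position on the circle and
    measures the runs between consecutive feature ends/starts.  Returns the
    sorted multisets of IGR lengths and overlap lengths.
    """
    L = genome.length
    feats = sorted(features, key=lambda f: (f.start, f.end))
    igr_lens: list[int] = []
    ovl_lens: list[int] = []
    for i, cur in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        covered = set(p % L for p in range(cur.start - 1, cur.start - 1 + cur.span_length(L)))
        nxt_pos = [p % L for p in range(nxt.start - 1, nxt.start - 1 + nxt.span_length(L))]
        shared = [p for p in nxt_pos if p in covered]
        if shared:
            ovl_lens.append(len(shared))
        else:
            # walk forward from cur's end until nxt's start
            p = (cur.start - 1 + cur.span_length(L)) % L
            n = 0
            while p != (nxt.start - 1) % L:
                n += 1
                p = (p + 1) % L
            igr_lens.append(n)
    return sorted(igr_lens), sorted(ovl_lens)


# ---------------------------------------------------------------------------
# Composition and pairwise variability
# ---------------------------------------------------------------------------

def base_composition(genome: CircularGenome) -> dict[str, float]:
    """Percentages of A/C/G/T (of unambiguous bases) plus G+C and ambiguity count.

    Ambiguity codes are excluded from the four-base denominator and counted
    separately.  Reported values are exact; round to one decimal for display.
    """
    seq = genome.sequence
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    n_ambiguous = len(seq) - denom
    if denom == 0:
        raise GenomeValidationError("sequence contains no unambiguous bases")
    pct = {b: 100.0 * c / denom for b, c in counts.items()}
    pct["GC"] = pct["G"] + pct["C"]
    pct["n_ambiguous"] = float(n_ambiguous)
    return pct


def pairwise_variability(row_a: str, row_b: str) -> AnnotationDiff:
    """Column-wise divergence of a two-row alignment (gap character '-').

    variability = mismatches / columns that are gap- and ambiguity-free in
    both rows; ambiguity_pct and gap_pct are fractions of all alignment
    columns containing an ambiguity code or a gap, respectively.
    """
    if len(row_a) != len(row_b):
        raise GenomeValidationError(
            f"alignment rows differ in length ({len(row_a)} vs {len(row_b)})"
        )
    a, b = row_a.upper(), row_b.upper()
    n_cols = len(a)
    if n_cols == 0:
        raise GenomeValidationError("empty alignment")
    n_gap = n_amb = n_clean = n_mismatch = 0
    for ca, cb in zip(a, b):
        has_gap = ca == "-" or cb == "-"
        has_amb = ca in AMBIGUOUS or cb in AMBIGUOUS
        if has_gap:
            n_gap += 1
        if has_amb:
            n_amb += 1
        if not has_gap and not has_amb:
            n_clean += 1
            if ca != cb:
                n_mismatch += 1
    variability = 100.0 * n_mismatch / n_clean if n_clean else 0.0
    return AnnotationDiff(
        variability_pct=variability,
        ambiguity_pct=100.0 * n_amb / n_cols,
        gap_pct=100.0 * n_gap / n_cols,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def igr_table_to_tsv(igrs: Sequence[IntergenicRegion], overlaps: Sequence[GeneOverlap],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("left_gene\tright_gene\ttype\tstart\tend\tlength\n")
        for r in igrs:
            fh.write(f"{r.left_gene}\t{r.right_gene}\tIGR\t{r.start}\t{r.end}\t{r.length}\n")
        for o in overlaps:
            fh.write(f"{o.left_gene}\t{o.right_gene}\toverlap\t.\t.\t{o.length}\n")


def igr_table_to_bed(igrs: Sequence[IntergenicRegion], genome: CircularGenome,
                     path: str | Path) -> None:
    """BED is 0-based half-open; an IGR at 1-based s..e becomes (s-1, e)."""
    with open(path, "w") as fh:
        for r in igrs:
            if r.length == 0:
                continue
            if r.start <= r.end:
                fh.write(f"{genome.id}\t{r.start - 1}\t{r.end}\t{r.left_gene}--{r.right_gene}\n")
            else:  # wraps the origin: emit two records
                fh.write(f"{genome.id}\t{r.start - 1}\t{genome.length}\t{r.left_gene}--{r.right_gene}\n")
                fh.write(f"{genome.id}\t0\t{r.end}\t{r.left_gene}--{r.right_gene}\n")
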