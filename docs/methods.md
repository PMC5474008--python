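# Methods

This note documents the models, conventions, parameters and limitations of
`punctless`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and strands

All public coordinates are 1-based inclusive, matching how organelle genome
positions are conventionally printed; internal circular arithmetic runs on a
0-based index modulo the genome length *L*. An interval with `start > end`
wraps the origin. The heavy strand (H) is the strand carrying most
protein-coding genes; file strands "+"/"−" map to H/L through a configurable
convention defaulting to "+" == H. BED exports are converted to the 0-based
half-open BED standard at write time.

Stop codons are **TAA/TAG only** throughout (TGA encodes tryptophan in
invertebrate mitochondrial genetic codes); start codons are ATG. This applies
to ORF scanning, reading-frame checks and the synthetic sequence generator
alike.

## Coverage

Each aligned base of an accepted record (not unmapped, secondary, duplicate
or QC-fail) increments per-position depth on the strand of transcription.
Deletions contribute nothing; insertions have no reference position; reads
crossing the origin wrap. The strand of transcription is resolved per library
protocol (`fr-firststrand`, `fr-secondstrand`, `unstranded`); under
`unstranded` (the default) the alignment strand of read 1 is taken at face
value, which is exact for the bundled simulator and a documented assumption
for real unstranded libraries.

Display normalization is `log(c+1)/log(c_max+1)` with the maximum taken over
both strands; the value is base-invariant and order-isomorphic to raw depth.
Because the convention for the "mean level" indicator on such plots is
ambiguous, both the raw mean mapped onto the normalized scale and the mean of
normalized values are reported.

Coverage discontinuities are scored as the ratio of flanking-window
**medians** (window 50 nt ≈ one read length; medians resist single-read
spikes); candidate runs are deduplicated to the centre of the tied plateau of
maximal ratio, so a clean step edge reports within ±2 nt of the true
boundary.

## Unit calling and precursor discrimination

Fragments with one mate overlapping each of two adjacent same-strand genes
(≥ 1 nt), or a single read crossing the whole IGR, are collinearity evidence.
`min_support = 1` joins on any observed spanning pair — appropriate at the
very low mitochondrial read yields this method targets.

RNA-seq libraries always contain traces of unprocessed precursor, which can
fake collinearity across genuine unit boundaries. A mature polycistron is one
molecule, so its genes share abundance; an adjacency whose flank depths
differ ≥ 10-fold (`precursor_ratio`) while its spanning support does not
exceed `max(precursor_max_support = 2, precursor_support_frac = 2 × the
minority gene's median depth)` is demoted to precursor read-through. The
depth-scaled second term is this package's extension of a fixed support cap:
with a fixed cap of 2, a 1% read-through fraction at 30× coverage yields
≈ 0.8 expected spanning precursor fragments across a boundary such as
COI–12S, and Poisson(0.8) exceeds 2 in ≈ 5% of runs — an unacceptable false
merge rate. Scaling the cap by the minority-gene depth (which is what mature
co-transcription would produce) keeps the false merge probability below
10⁻⁴ per boundary while never demoting a genuinely co-transcribed pair,
whose flank ratio is ≈ 1 and fails the ratio condition first.

tRNA genes are processing punctuation and always form their own units;
adjacencies across strand switches are never joined; rRNA genes join only if
linked above threshold. Protein-coding units with no mapped transcript end
are reported with status `ambiguous` rather than forced to a boundary call.

A deliberate limitation: read-through between neighbours of **similar**
abundance (flank ratio ≈ 1) leaves no depth contradiction, so at a few-fold
per-gene coverage a 1% precursor fraction can spuriously join two
monocistronic neighbours. This is not decidable from coverage alone — an
IGR-coverage criterion was considered and rejected because 50 bp read blocks
make per-position depths strongly correlated, so a short mature within-unit
IGR goes median-zero at these depths about as often as a silent boundary IGR
gets touched by a single precursor read. Resolving such joins requires
orthogonal end evidence (junction/RACE), mirroring how boundary calls that
coverage could not settle are left undetermined rather than forced.

## Transcript ends

Junction reads have the transcript-sense layout `[3′ flank][A-tail][5′
flank]`. The longest A-run ≥ `min_polya = 5` with an anchorable flank on each
side is the tail; flanks are anchored by exact 15-mer search over both
strands of the circular sequence and extended maximally. Exact matching (no
mismatches) is appropriate for clone-derived Sanger-quality reads; ambiguous
(multi-locus) anchors, absent runs and strand conflicts raise typed errors
rather than guesses.

Adenosines at a flank/tail boundary cannot be attributed from the read alone.
The package adopts the **maximal genomic attribution** convention: the 3′ end
extends over any genomic A's adjacent to the tail (so a transcript may
legitimately end on …UAA), and symmetrically the 5′ end extends back over
genomic A's absorbed by the tail. The simulator guarantees its configured
termini are canonical under this rule (a non-A base is planted adjacent to
every configured end), which makes closed-loop recovery exact rather than
±1–2 nt.

UTRs are distances from the mapped 5′ end to the unit's first start codon and
from its last stop codon to the mapped 3′ end. A 5′ end *inside* the first
CDS is a first-class result (flag `truncated5` with its offset), not an
error. 3′ ends upstream of the stop are APA calls, not UTRs. Ends are
assigned to units within 300 nt of the relevant boundary; alternative 5′ ends
yield one record each.

APA clustering is single-linkage with tolerance 3 nt — near-identical ends
are merged conservatively while sites ≥ 10 nt apart stay distinct. The
representative is the highest-support member (ties to the smaller position);
`in_frame` tests whether the representative lies on a codon boundary of the
containing gene's frame.

The lncRNA rule is conjunctive: length > 200 nt, polyadenylated, longest
same-sense ORF < 50 codons (a package choice; "lacks ORFs" needs an
operational threshold), and ≥ 50% of the transcript antisense to an annotated
gene. Candidate intervals come from junction-read end pairs that do not
correspond to any same-strand annotated gene.

## Motifs and control regions

Stem-loops are perfect inverted repeats (Watson–Crick plus G·U wobble, i.e.
G–T in DNA space) with stem ≥ 6 bp and loop 3–30 nt, found by exhaustive
outward extension and deduplicated to the longest stem per start. This
replaces thermodynamic folding deliberately: the claim tested is structural
presence, not ΔG, and the parameters are exposed.

Shared motifs are exact k-mers (k = 15 down to 8) present in ≥ 3 IGRs,
reported maximally (a k-mer that is a substring of a longer reported hit with
the same IGR set is dropped). A Hamming-1 mode exists but is off by default,
since the motifs of interest are described as conserved across congeners.

A control region is called for an IGR meeting all four criteria (configurable
to ≥ 3): ≥ 90% of its positions at zero combined-strand depth (the 90%
allowance exists because mapped UTRs of the neighbouring units may
legitimately nibble a few bases off an otherwise silent region), a hairpin,
flanking genes on opposite strands, and a shared motif.

## qPCR

The expression ratio is `E_t^ΔCq_t / E_ref^ΔCq_ref` at replicate means, with
per-well efficiencies (as fluorescence-curve tools emit them) averaged per
amplicon; efficiency is validated to (1, 2]. Two SDs are reported because the
"±SD of technical triplicates" convention is ambiguous: a delta-method
propagation of replicate Cq SDs through the log-ratio, and the SD of
replicate-paired ratios. The randomization test permutes condition labels
within each gene, two-sided on the log ratio, with the plus-one correction
`p = (b+1)/(n+1)`.

Two statistical facts shape the tests. First, with 3+3 replicates a label
permutation has only C(6,3) = 20 distinct partitions, so the achievable
two-sided p floors near 0.05–0.1; the power test asserts detection at that
granularity floor rather than a nominally smaller α. Second, at per-well Cq
noise SD 0.1 with 3 replicates the log₂-ratio SD is √(4·0.01/3) = 0.1155
cycles, so a ±15% recovery band is a 1.745σ event captured with probability
0.919 per run — the recovery tests assert the bands and rates this noise
model actually guarantees (derivations in the test docstrings).

The RNase-H APA assay readout quantifies each amplicon of the
alternatively polyadenylated gene relative to the cleaved-off 3′-most
amplicon, normalized by the reference gene within each condition; the
reference is duplicated into both pseudo-conditions of the recast contrast so
it cancels exactly when efficiencies are equal.

## The synthetic study system

The generator's defaults *are* the study conditions; they are not tuned per
test. The arrangement-'A' reference is a deterministic construction (fixed
internal seed): exact base counts realise the published-style composition;
gene coordinates realise the IGR/overlap/length anatomy; every PCG gets an
ATG start, a TAA stop, and a stop-free interior on its own frame (including
both frames across the 13 nt ND5/ND4 overlap); an 11 nt motif is planted in
the control region and three unit-flanking IGRs, with a 12 bp-stem hairpin in
the control region; the antisense-RNA window inside *ATP6* is kept free of
≥ 40-codon same-sense ORFs without disturbing the *ATP6* frame; and a non-A
sentinel base flanks every configured transcript terminus (canonicality, see
above). A composition repair pass then restores the exact base counts using
only frame-safe positions, and a final validation asserts every invariant.

The transcription program encodes seven PCG units (cistron counts
1/2/3/3/3/1/1), two rRNA units at a 50× abundance multiplier, a tRNA unit,
six weighted alternative poly(A) sites plus an internal transcript within
*mtMutS*, alternative 5′ ends for the CytB–ND6 unit (one 6 nt inside the
CDS), a 212 nt antisense transcript within *ATP6*, and a 1% whole-strand
precursor read-through fraction. Read simulation draws fragments ∝ weight ×
length (so per-base depth ∝ weight), fragment length 250 ± 40 nt, 50 bp
mates, poly(A) tails 35 ± 5 nt appearing as soft-clips on 3′-terminal
fragments; identical seeds give identical outputs byte-for-byte. Default
problem sizes (depth 30, 20–50 discrimination replicates, 200–500 qPCR runs)
keep the full suite under a minute of compute while leaving the statistical
margins computed above.

A synthetic congener is generated *through* a constructed alignment — 432
substitution, 9 ambiguity, 9 insertion and 21 deletion columns on the
18,730 nt reference (net 12 nt shorter) — so column-wise divergence
(2.31% / 0.05% / 0.16%) is exact by construction. `pairwise_variability`
consumes any precomputed alignment; the aligner choice for real data is
external.

What the simulator does **not** model: sequencing errors are substitution-only
and off by default; RNA degradation kinetics, reverse-transcriptase template
switching (which produces false deletion isoforms in long genes), library GC
bias, and chimeric artefacts are absent. Passing recovery tests therefore
demonstrate correctness of the inference logic under clean evidence, not
robustness to artefact-laden libraries. Real-data caveats: precursor
discrimination assumes depth differences are expression, not mappability;
exact-match anchoring will reject ends on polymorphic sites unless the
mismatch-tolerant mode is enabled.

## Numerical and degenerate-input conventions

All-zero coverage normalizes to zeros with a warning; an all-zero alignment
produces an all-monocistronic report. Zero-length IGRs (abutting genes) are
retained in the IGR table with length 0; overlapping pairs are reported
separately and never as negative IGRs. A fully-joined circular chain of
adjacencies (degenerate) is cut at the wrap-around pair. Permutation p-values
use ≥-with-epsilon comparison (ties count as extreme, conservative). Reports
serialize with sorted keys; reruns with identical configuration are
byte-identical.
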