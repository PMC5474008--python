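"""End-to-end orchestration: genome -> coverage -> units -> ends -> motifs (-> qPCR).

The pipeline either simulates a ground-truth transcriptome or consumes real
inputs (annotated genome, SAM alignments, junction-read FASTA, Cq TSV), and
emits a machine-readable JSON report plus optional per-stage artifacts
(unit GFF3, end/APA TSVs, control-region JSON, coverage plot).  Reports are
deterministic: identical configuration gives byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import coverage as cov
from . import ends as ends_mod
from . import genome as genome_mod
from . import linkage as linkage_mod
from . import motifs as motifs_mod
from . import qpcr as qpcr_mod
from . import simulate as sim

log = logging.getLogger("punctless")


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults (unknown keys rejected)."""

    # input selection: simulate a ground-truth data set, or consume paths
    simulate: bool = True
    arrangement: str = "A"
    depth: float = 30.0
    read_len: int = 50
    seed: int = 42
    readthrough_fraction: float | None = None
    genome_path: str | None = None
    feature_table: str | None = None
    sam_path: str | None = None
    junction_fasta: str | None = None
    qpcr_tsv: str | None = None
    # module parameters
    protocol: str = "unstranded"
    min_support: int = 1
    precursor_ratio: float = 10.0
    precursor_max_support: int = 2
    precursor_support_frac: float = 2.0
    breakpoint_window: int = 50
    breakpoint_min_ratio: float = 5.0
    anchor_k: int = 15
    min_polya: int = 5
    min_clip: int = 5
    min_a_frac: float = 0.9
    cluster_tol: int = 3
    orf_threshold: int = 50
    min_antisense_overlap: float = 0.5
    motif_min_igrs: int = 3
    zero_frac: float = 0.9
    cr_min_criteria: int = 4
    qpcr_reference: str = "ACTB"
    # output
    outdir: str | None = None
    write_plot: bool = False

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise genome_mod.GenomeValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc

        return wrapper

    return deco


# ---------------------------------------------------------------------------
# Individual stages
# ---------------------------------------------------------------------------

@_stage("inputs")
def _load_inputs(config: RunConfig):
    if config.simulate:
        program, genome, feats = sim.default_program(config.arrangement)
        if config.readthrough_fraction is not None:
            program.readthrough_fraction = config.readthrough_fraction
        readset = sim.simulate_reads(
            program, genome, feats,
            depth=config.depth, read_len=config.read_len, seed=config.seed,
        )
        fragments = readset.fragments
        junction_reads, _ = sim.simulate_junction_reads(
            program, genome, feats, n_per_end=2, seed=config.seed + 1,
        )
        return genome, list(feats), fragments, junction_reads, None
    if not config.genome_path:
        raise genome_mod.GenomeValidationError("genome_path required when simulate=False")
    genome, feats = genome_mod.load_annotation(config.genome_path, config.feature_table)
    fragments = (
        sim.fragments_from_sam(config.sam_path, config.protocol)
        if config.sam_path else []
    )
    junction_reads = []
    if config.junction_fasta:
        from Bio import SeqIO

        junction_reads = [
            (rec.id, str(rec.seq))
            for rec in SeqIO.parse(config.junction_fasta, "fasta")
        ]
    wells = qpcr_mod.wells_from_tsv(config.qpcr_tsv) if config.qpcr_tsv else None
    return genome, feats, fragments, junction_reads, wells


@_stage("ends")
def _map_ends(junction_reads, genome, config: RunConfig):
    resolved, failures = [], []
    for name, seq in junction_reads:
        try:
            three, five = ends_mod.resolve_crtpcr_junction(
                seq, genome, anchor_k=config.anchor_k, min_polya=config.min_polya
            )
            resolved.append((name, three, five))
        except ends_mod.EndResolutionError as exc:
            failures.append((name, str(exc)))
    return resolved, failures


def _aggregate_ends(resolved, softclip_ends):
    """Merge junction-derived and soft-clip ends into support-counted records."""
    agg: dict[tuple, int] = {}
    extra: dict[tuple, int] = {}
    for _, three, five in resolved:
        for e in (three, five):
            key = (e.position, e.kind, e.strand, e.method, e.polya_len)
            agg[key] = agg.get(key, 0) + 1
    ends = [
        ends_mod.TranscriptEnd(pos, kind, strand, method, polya_len=pa, support=n)
        for (pos, kind, strand, method, pa), n in sorted(agg.items())
    ]
    return ends + list(softclip_ends)


@_stage("lncRNA")
def _lncrna_calls(resolved, genome, features, config: RunConfig):
    from .linkage import circular_overlap

    calls = []
    seen = set()
    for _, three, five in resolved:
        strand = three.strand
        if strand == "H":
            interval = (five.position, three.position, "H")
        else:
            interval = (three.position, five.position, "L")
        if interval in seen:
            continue
        seen.add(interval)
        s, e, st = interval
        length = (e - s) % genome.length + 1
        same_strand_ov = max(
            (circular_overlap((s, e), (f.start, f.end), genome.length) / length
             for f in features if f.strand == st),
            default=0.0,
        )
        if same_strand_ov >= 0.5:
            continue  # an ordinary mRNA/rRNA terminus pair, not a lncRNA candidate
        call = ends_mod.classify_lncrna(
            interval, polyadenylated=three.polya_len is not None,
            genome=genome, features=features,
            orf_threshold=config.orf_threshold,
            min_antisense_overlap=config.min_antisense_overlap,
        )
        if call is not None:
            calls.append(call)
    return calls


def _apa_by_gene(all_ends, features, genome, config: RunConfig):
    """Cluster 3' ends falling inside each gene's span (same strand)."""
    out = {}
    for f in features:
        inside = [
            e for e in all_ends
            if e.kind == "three_prime" and e.strand == f.strand
            and f.start <= e.position <= f.end
        ]
        if not inside:
            continue
        sites = ends_mod.cluster_apa(inside, genome, f, cluster_tol=config.cluster_tol)
        terminal = f.end if f.strand == "H" else f.start
        n_alt = sum(1 for s in sites if s.representative_position != terminal)
        out[f.name] = {"sites": sites, "n_sites": len(sites), "n_alternative": n_alt}
    return out


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full inference pipeline; returns the JSON-ready report."""
    genome, features, fragments, junction_reads, wells = _load_inputs(config)

    igrs, overlaps = genome_mod.igr_table(genome, features)
    comp = genome_mod.base_composition(genome)

    profile = cov.compute_coverage(fragments, genome, protocol=config.protocol)
    if profile.total_bases == 0:
        log.warning("zero coverage: no aligned fragments")
    breakpoints = cov.find_breakpoints(
        profile, window=config.breakpoint_window, min_ratio=config.breakpoint_min_ratio
    ) if profile.total_bases else []
    zero_segments = cov.zero_coverage_segments(profile, min_len=20) \
        if profile.total_bases else [(1, genome.length)]

    linkage = linkage_mod.collect_linkage(fragments, features, genome, profile)
    call = linkage_mod.call_units(
        linkage, features,
        min_support=config.min_support,
        precursor_ratio=config.precursor_ratio,
        precursor_max_support=config.precursor_max_support,
        precursor_support_frac=config.precursor_support_frac,
    )
    units = call.units
    summary = linkage_mod.classify_units(units)

    resolved, junction_failures = _map_ends(junction_reads, genome, config)
    softclip_ends = ends_mod.call_polya_sites(
        fragments, genome, min_clip=config.min_clip, min_a_frac=config.min_a_frac
    )
    all_ends = _aggregate_ends(resolved, softclip_ends)
    junction_ends = [e for e in all_ends if e.method == "crtpcr"]
    utrs = ends_mod.annotate_utrs(units, junction_ends, features, genome)
    apa = _apa_by_gene(all_ends, features, genome, config)
    lnc_calls = _lncrna_calls(resolved, genome, features, config)

    # units without any mapped end evidence stay calls of record but are
    # flagged ambiguous (their precise boundaries are undetermined)
    genes_with_ends = {g for u in utrs for g in u.unit_genes}
    units = [
        u if (u.n_cistrons == 0 or set(u.genes) & genes_with_ends)
        else u.with_status("ambiguous")
        for u in units
    ]

    cr_calls = motifs_mod.predict_control_region(
        igrs, profile, features, genome,
        motif_min_igrs=config.motif_min_igrs,
        zero_frac=config.zero_frac,
        min_criteria=config.cr_min_criteria,
    )

    qpcr_report = None
    if wells is not None:
        targets = sorted({w.target for w in wells} - {config.qpcr_reference})
        ratios = [
            qpcr_mod.relative_ratio(wells, t, config.qpcr_reference, seed=config.seed)
            for t in targets
        ]
        qpcr_report = [dataclasses.asdict(r) for r in ratios]

    report: dict[str, Any] = {
        "config": config.to_dict(),
        "genome": {
            "id": genome.id,
            "length": genome.length,
            "n_features": len(features),
            "composition_pct": {k: round(v, 1) for k, v in comp.items() if k != "n_ambiguous"},
            "n_igrs": len(igrs),
            "n_overlaps": len(overlaps),
            "max_igr": max((r.length for r in igrs), default=0),
            "min_igr": min((r.length for r in igrs), default=0),
        },
        "coverage": {
            "total_aligned_bases": profile.total_bases,
            "n_breakpoints": len(breakpoints),
            "zero_segments": [list(z) for z in zero_segments],
        },
        "units": [
            {"genes": list(u.genes), "strand": u.strand, "status": u.status,
             "n_cistrons": u.n_cistrons}
            for u in units
        ],
        "unit_summary": summary,
        "demoted_adjacencies": [
            {"gene_a": d.gene_a, "gene_b": d.gene_b, "n_spanning": d.n_spanning,
             "flank_depth_ratio": round(d.flank_depth_ratio, 2)}
            for d in call.demoted
        ],
        "ends": [
            {"position": e.position, "kind": e.kind, "strand": e.strand,
             "method": e.method, "polya_len": e.polya_len, "support": e.support}
            for e in all_ends
        ],
        "junction_failures": junction_failures,
        "utrs": [
            {"unit": list(u.unit_genes), "utr5": u.utr5_len, "utr3": u.utr3_len,
             "truncated5": u.truncated5, "truncated5_offset": u.truncated5_offset}
            for u in utrs
        ],
        "apa": {
            gene: {
                "n_sites": d["n_sites"],
                "n_alternative": d["n_alternative"],
                "representatives": [s.representative_position for s in d["sites"]],
                "in_frame": [s.in_frame for s in d["sites"]],
                "end_codons": [s.end_codon for s in d["sites"]],
            }
            for gene, d in sorted(apa.items())
        },
        "lncrna": [
            {"interval": list(c.interval), "antisense_of": c.antisense_of,
             "length": c.length, "longest_orf_codons": c.longest_orf_codons}
            for c in lnc_calls
        ],
        "control_region": [dataclasses.asdict(c) for c in cr_calls],
    }
    if qpcr_report is not None:
        report["qpcr"] = qpcr_report

    if config.outdir:
        _write_artifacts(config, report, genome, features, profile, units, all_ends, apa)
    return report


@_stage("artifacts")
def _write_artifacts(config, report, genome, features, profile, units, all_ends, apa):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    linkage_mod.units_to_gff3(units, features, genome, outdir / "units.gff3")
    ends_mod.ends_to_tsv(all_ends, outdir / "ends.tsv")
    for gene, d in apa.items():
        ends_mod.apa_to_tsv(d["sites"], outdir / f"apa_{gene}.tsv")
    igrs, overlaps = genome_mod.igr_table(genome, features)
    genome_mod.igr_table_to_tsv(igrs, overlaps, outdir / "igr.tsv")
    genome_mod.igr_table_to_bed(igrs, genome, outdir / "igr.bed")
    with open(outdir / "control_region.json", "w") as fh:
        json.dump(report["control_region"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    if config.write_plot:
        cov.plot_coverage(profile, features, outdir / "coverage.png")


def report_to_json(report: dict[str, Any]) -> str:
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
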