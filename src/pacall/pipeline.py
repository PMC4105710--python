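"""End-to-end orchestration: trim -> poly(A) -> ingest alignments ->
internal-priming filter -> cluster -> annotate -> miRNA loss -> signal QC.

The aligner is pluggable and external: the pipeline's contract is at the
SAM/BAM boundary. Reads surviving the poly(A) stage are matched to the
supplied alignments by read id (the synthetic generator emits truth
alignments so no aligner is needed for testing). All outputs are written
atomically; per-stage counts are reported as a TSV and a JSON run summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd
import pyfaidx

from . import annotation as ann
from . import clustering as clu
from . import mirna_loss as mir
from . import preprocess as pre
from . import priming_filter as pf
from . import signal_qc as sig
from .genomic_core import atomic_write, write_bed6

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "stage_report",
           "EXIT_MISSING_INPUT", "EXIT_MALFORMED", "EXIT_EMPTY"]

log = logging.getLogger(__name__)

EXIT_MISSING_INPUT = 3
EXIT_MALFORMED = 4
EXIT_EMPTY = 5


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's published settings."""

    # inputs
    reads: Optional[str] = None  # FASTQ
    alignment: Optional[str] = None  # SAM/BAM of clipped reads
    genome: Optional[str] = None  # FASTA
    gene_models: Optional[str] = None  # GFF3 or BED12
    mirna_sites: Optional[str] = None  # BED6, name = mirna|gene
    outdir: str = "pacall_out"
    # quality trimming / poly(A) detection
    min_q: int = 16
    window: int = 5
    min_a: int = 4
    min_steps: int = 7
    min_remaining: int = 20
    # internal priming
    astretch_k: int = 10
    max_mismatch: int = 2
    adjacency: int = 10
    # clustering / annotation
    max_dist: int = 25
    min_mapq: int = 10
    hcs_threshold: int = 5
    max_ext: int = 3000
    # signal QC
    upstream_n: int = 50
    motifs: tuple[str, ...] = ("AWTAAA",)
    tol: int = 25
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


@dataclass
class PipelineResult:
    clusters: list = field(default_factory=list)
    annotated: list = field(default_factory=list)
    loss_reports: list = field(default_factory=list)
    motif_fraction: Optional[float] = None
    counts: list = field(default_factory=list)  # (stage, count)
    kept_events: list = field(default_factory=list)
    discarded_events: list = field(default_factory=list)
    outdir: str = ""


def stage_report(counts: list[tuple[str, int]]) -> pd.DataFrame:
    """One row per stage with absolute count and fraction of previous stage."""
    rows = []
    prev = None
    for stage, n in counts:
        frac = "" if prev in (None, 0) else f"{n / prev:.4f}"
        rows.append({"stage": stage, "count": n, "fraction_of_previous": frac})
        prev = n
    return pd.DataFrame(rows, columns=["stage", "count", "fraction_of_previous"])


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in library order on the configured inputs.

    Raises ``FileNotFoundError`` for missing inputs and ``ValueError`` for
    malformed ones; an empty post-filter event set is reported with an empty
    (but complete) output bundle, flagged in the summary.
    """
    for label, path in (
        ("reads", config.reads), ("alignment", config.alignment),
        ("genome", config.genome), ("gene models", config.gene_models),
    ):
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"missing {label} input: {path}")
    os.makedirs(config.outdir, exist_ok=True)
    result = PipelineResult(outdir=config.outdir)
    counts: list[tuple[str, int]] = []

    # stage 1+2: quality trim, poly(A) detect + clip
    clipped: list[pre.Read] = []
    rejected: list[pre.Read] = []
    n_raw = 0
    for read in pre.read_fastq(config.reads):
        n_raw += 1
        trimmed = pre.trim_low_quality(read, min_q=config.min_q)
        call = pre.detect_polya(
            trimmed.seq, window=config.window, min_a=config.min_a,
            min_steps=config.min_steps,
        )
        if not call.is_positive:
            rejected.append(read)
            continue
        kept = pre.clip_polya(trimmed, call, min_remaining=config.min_remaining)
        if kept is None:
            rejected.append(read)
        else:
            clipped.append(kept)
    counts.append(("raw_reads", n_raw))
    counts.append(("polya_positive", len(clipped)))
    pre.write_fastq(clipped, os.path.join(config.outdir, "clipped.fastq"))

    # stage 3: unique alignments of surviving reads -> cleavage events
    keep_ids = {r.read_id for r in clipped}
    events = clu.extract_cleavage_coords(
        config.alignment, min_mapq=config.min_mapq, keep_ids=keep_ids
    )
    counts.append(("unique_alignments", len(events)))

    # stage 4+5: A-stretch scan and internal-priming filter
    genome = pyfaidx.Fasta(config.genome, as_raw=False, sequence_always_upper=True)
    stretches = pf.find_a_stretches(
        genome, k=config.astretch_k, max_mismatch=config.max_mismatch
    )
    write_bed6(pf.stretches_to_bed(stretches), os.path.join(config.outdir, "astretches.bed"))
    kept, discarded = pf.filter_internal_priming(
        events, stretches, adjacency=config.adjacency
    )
    result.kept_events, result.discarded_events = kept, discarded
    counts.append(("post_priming_filter", len(kept)))

    # stage 6: clustering
    clusters = clu.cluster_events(kept, max_dist=config.max_dist)
    result.clusters = clusters
    counts.append(("pa_clusters", len(clusters)))

    # stage 7: annotation
    models = ann.parse_gene_models(config.gene_models)
    annotated = ann.annotate_clusters(
        clusters, models, max_ext=config.max_ext, hcs_threshold=config.hcs_threshold
    )
    result.annotated = annotated
    clu.write_clusters_bed(clusters, os.path.join(config.outdir, "clusters.bed"))
    counts.append(("annotated_clusters", sum(1 for a in annotated if a.feature != ann.UNASSIGNED)))

    # stage 8: miRNA loss
    if config.mirna_sites and os.path.exists(config.mirna_sites):
        sites_by_gene, _ = mir.load_mirna_sites(config.mirna_sites, models)
        reports = [mir.lost_sites(a, sites_by_gene) for a in annotated]
        result.loss_reports = reports
        mir.write_loss_report(reports, os.path.join(config.outdir, "mirna_loss.tsv"))

    # stage 9: poly(A)-signal QC
    motif = config.motifs[0] if config.motifs else "AWTAAA"
    fraction, table = sig.motif_frequency(
        clusters, genome, motif=motif, n=config.upstream_n
    )
    result.motif_fraction = fraction
    sig.write_upstream_fasta(
        clusters, genome, os.path.join(config.outdir, "upstream.fa"), n=config.upstream_n
    )
    with atomic_write(os.path.join(config.outdir, "motif_report.tsv")) as fh:
        table.to_csv(fh, sep="\t", index=False)

    result.counts = counts
    with atomic_write(os.path.join(config.outdir, "stage_report.tsv")) as fh:
        stage_report(counts).to_csv(fh, sep="\t", index=False)
    summary = {
        "counts": {stage: n for stage, n in counts},
        "n_hcs": sum(1 for c in clusters if c.is_hcs(config.hcs_threshold)),
        "motif": motif,
        "motif_fraction": fraction,
        "empty_event_set": len(kept) == 0,
    }
    with atomic_write(os.path.join(config.outdir, "summary.json")) as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with atomic_write(os.path.join(config.outdir, "config.json")) as fh:
        fh.write(config.to_json() + "\n")
    if len(kept) == 0:
        log.warning("no cleavage events survive the internal-priming filter")
    return result
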