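"""Predicted miRNA binding sites lost under a given PA-site choice.

When a proximal PA site is used, the transcript loses every 3'UTR segment —
and every miRNA binding site — downstream of the cleavage position, so those
regulatory interactions no longer apply to the shortened isoform. Binding
sites are an input track (e.g. TargetScan/miRanda predictions exported as
BED6, one record per site with the name field ``mirna_id|gene_symbol``); a
site counts as lost for a cluster when it starts strictly downstream, in
transcript orientation, of the cluster's median coordinate. Sites straddling
the cleavage position are conservatively treated as retained.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .annotation import AnnotatedSite, GeneModel, UNASSIGNED
from .genomic_core import BedRecord, GenomicInterval, atomic_write, read_bed6

__all__ = ["MiRNASite", "LossReport", "load_mirna_sites", "lost_sites",
           "loss_report_table", "write_loss_report"]

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class MiRNASite:
    """One predicted miRNA binding site inside a gene's 3'UTR."""

    gene_symbol: str
    mirna_id: str
    interval: GenomicInterval


@dataclass
class LossReport:
    """Binding sites lost when the cluster's PA site is used."""

    site: AnnotatedSite
    lost: list[MiRNASite] = field(default_factory=list)
    unassigned: bool = False

    @property
    def n_lost(self) -> int:
        return len(self.lost)


def load_mirna_sites(
    source: Union[str, os.PathLike, Iterable[BedRecord]],
    models: Optional[Sequence[GeneModel]] = None,
) -> tuple[dict[str, list[MiRNASite]], dict[str, int]]:
    """Group binding sites by gene from BED6 with ``mirna|gene`` names.

    Records whose name lacks the ``|`` separator are skipped; duplicate
    identical records collapse to one (set semantics). When ``models`` is
    given, sites outside the gene's annotated 3'UTR span are ignored. Returns
    (sites_by_gene, counters) with counters ``malformed`` and
    ``outside_3utr``.
    """
    if isinstance(source, (str, os.PathLike)):
        records: Iterable[BedRecord] = read_bed6(source)
    else:
        records = source
    utr_spans: dict[str, list[GenomicInterval]] = {}
    if models is not None:
        for m in models:
            span = m.three_utr_span()
            if span is not None:
                utr_spans.setdefault(m.gene_symbol, []).append(span)
    seen: set[MiRNASite] = set()
    by_gene: dict[str, list[MiRNASite]] = {}
    counters = {"malformed": 0, "outside_3utr": 0}
    for rec in records:
        if "|" not in rec.name:
            counters["malformed"] += 1
            continue
        mirna_id, gene = rec.name.split("|", 1)
        if not mirna_id or not gene:
            counters["malformed"] += 1
            continue
        site = MiRNASite(gene, mirna_id, rec.interval())
        if site in seen:
            continue
        if models is not None:
            spans = utr_spans.get(gene, [])
            inside = any(
                s.chrom == site.interval.chrom
                and s.start <= site.interval.start
                and site.interval.end <= s.end
                for s in spans
            )
            if not inside:
                counters["outside_3utr"] += 1
                continue
        seen.add(site)
        by_gene.setdefault(gene, []).append(site)
    for sites in by_gene.values():
        sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.mirna_id))
    if counters["malformed"]:
        log.warning("skipped %d miRNA records with malformed names", counters["malformed"])
    return by_gene, counters


def lost_sites(
    site: AnnotatedSite, sites_by_gene: dict[str, list[MiRNASite]]
) -> LossReport:
    """Binding sites of the cluster's gene strictly downstream of its median.

    Plus strand: ``site.start > median``; minus strand: ``site.end <= median``
    (downstream runs toward lower coordinates, and a site whose half-open end
    is at or left of the median lies entirely downstream of it). Output is
    sorted by transcript-orientation position, most proximal first.
    """
    if site.gene_symbol == UNASSIGNED:
        return LossReport(site, unassigned=True)
    median = site.cluster.median_coord
    strand = site.cluster.strand
    candidates = sites_by_gene.get(site.gene_symbol, [])
    if strand == "+":
        lost = [s for s in candidates if s.interval.start > median]
        lost.sort(key=lambda s: s.interval.start)
    else:
        lost = [s for s in candidates if s.interval.end <= median]
        lost.sort(key=lambda s: -s.interval.end)
    return LossReport(site, lost=lost)


def loss_report_table(reports: Sequence[LossReport]) -> pd.DataFrame:
    """Tabulate loss reports: cluster id, gene, n_lost, joined miRNA ids."""
    rows = []
    for rep in reports:
        rows.append(
            {
                "cluster": rep.site.cluster.name,
                "gene_symbol": rep.site.gene_symbol,
                "feature": rep.site.feature,
                "n_lost": rep.n_lost,
                "lost_mirnas": ";".join(s.mirna_id for s in rep.lost),
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster", "gene_symbol", "feature", "n_lost", "lost_mirnas"]
    )


def write_loss_report(reports: Sequence[LossReport], path: Union[str, os.PathLike]) -> None:
    table = loss_report_table(reports)
    with atomic_write(path) as fh:
        table.to_csv(fh, sep="\t", index=False)
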