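"""Skipped-exon event definitions from GTF annotation.

Only annotated cassette exons are considered: an internal exon of a
multi-exon transcript is a candidate skipped exon, with the host gene's
full transcribed span (TSS to 3'UTR end, i.e. the gene interval) as the
cis-variant region.  Effective lengths default to junction-count mode
(two inclusion junctions, one skipping junction).
"""
from __future__ import annotations

from typing import Iterable

from .psi import SpliceEvent, DEFAULT_INCLUSION_LENGTH, DEFAULT_SKIP_LENGTH


def skipped_exon_events_from_gtf(path,
                                 inclusion_length: float = DEFAULT_INCLUSION_LENGTH,
                                 skip_length: float = DEFAULT_SKIP_LENGTH) -> list[SpliceEvent]:
    """Enumerate candidate skipped exons from a GTF file.

    One event per distinct internal exon interval per gene; the event id is
    ``gene:chrom:start-end``.  Uses an in-memory gffutils database; intended
    for annotation files of gene-panel scale.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            disable_infer_genes=True, disable_infer_transcripts=True)
    events: dict[str, SpliceEvent] = {}
    for gene in db.features_of_type("gene"):
        gene_name = gene.attributes.get("gene_id", [gene.id])[0]
        for tx in db.children(gene, featuretype="transcript"):
            exons = sorted(db.children(tx, featuretype="exon"), key=lambda e: e.start)
            if len(exons) < 3:
                continue
            for exon in exons[1:-1]:
                event_id = f"{gene_name}:{gene.seqid}:{exon.start}-{exon.end}"
                if event_id in events:
                    continue
                events[event_id] = SpliceEvent(
                    event_id=event_id,
                    host_gene=gene_name,
                    chrom=gene.seqid,
                    strand=gene.strand if gene.strand in "+-" else "+",
                    exon_start=exon.start,
                    exon_end=exon.end,
                    region_start=gene.start,
                    region_end=gene.end,
                    inclusion_length=inclusion_length,
                    skip_length=skip_length,
                )
    return list(events.values())


def write_event_table(events: Iterable[SpliceEvent], path) -> None:
    import pandas as pd

    rows = [{
        "event_id": ev.event_id, "host_gene": ev.host_gene, "chrom": ev.chrom,
        "strand": ev.strand, "exon_start": ev.exon_start, "exon_end": ev.exon_end,
        "region_start": ev.region_start, "region_end": ev.region_end,
        "inclusion_length": ev.inclusion_length, "skip_length": ev.skip_length,
    } for ev in events]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_event_table(path) -> list[SpliceEvent]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [SpliceEvent(
        event_id=r.event_id, host_gene=r.host_gene, chrom=str(r.chrom), strand=r.strand,
        exon_start=int(r.exon_start), exon_end=int(r.exon_end),
        region_start=int(r.region_start), region_end=int(r.region_end),
        inclusion_length=float(r.inclusion_length), skip_length=float(r.skip_length),
    ) for r in df.itertuples()]
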