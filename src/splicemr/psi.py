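"""Percent-spliced-in (PSI) quantification from junction read counts.

A skipped-exon event is quantified per sample as

    psi = (I / L_I) / (I / L_I + S / L_S)

where ``I`` and ``S`` are the junction reads supporting the inclusion and
exclusion (exon-skipping) isoforms and ``L_I``, ``L_S`` are the effective
lengths of the two isoforms.  In junction-count mode the inclusion isoform
is supported by two junctions and the exclusion isoform by one, hence the
default lengths 2 and 1.

Event eligibility for cis-genetic modeling requires, per event:
more than one SNV in the host gene's transcribed region, at least 100
support samples (genotyped, with I + S >= 10 junction reads), and an
interquartile range of psi over the support samples above 10%.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import GenotypePanel

DEFAULT_INCLUSION_LENGTH = 2.0
DEFAULT_SKIP_LENGTH = 1.0


@dataclass(frozen=True)
class SpliceEvent:
    """An annotated skipped exon.

    Genomic coordinates are 1-based closed intervals (GTF convention).
    ``region_start``/``region_end`` span the host gene's transcribed region
    from the TSS to the end of the 3'UTR; cis candidate variants are drawn
    from this interval.
    """

    event_id: str
    host_gene: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    region_start: int
    region_end: int
    inclusion_length: float = DEFAULT_INCLUSION_LENGTH
    skip_length: float = DEFAULT_SKIP_LENGTH

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.region_start <= self.exon_start <= self.exon_end <= self.region_end):
            raise ValueError(f"{self.event_id}: exon interval must lie within the transcribed region")
        if self.inclusion_length <= 0 or self.skip_length <= 0:
            raise ValueError(f"{self.event_id}: effective lengths must be positive")


@dataclass
class PsiMatrix:
    """Per-event, per-sample psi values plus the support mask.

    ``psi`` is events x samples with NaN where no junction reads were
    observed; ``support`` is a boolean frame of the same shape.
    """

    psi: pd.DataFrame
    support: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.support is None:
            self.support = pd.DataFrame(False, index=self.psi.index, columns=self.psi.columns)
        if not self.psi.index.equals(self.support.index) or not self.psi.columns.equals(self.support.columns):
            raise ValueError("psi and support must share index/columns")
        # support implies a defined psi
        bad = self.support.to_numpy() & np.isnan(self.psi.to_numpy())
        if bad.any():
            raise ValueError("support=True requires a defined psi value")

    def support_samples(self, event_id: str) -> pd.Index:
        row = self.support.loc[event_id]
        return row.index[row]


def compute_psi(inclusion: float, skip: float,
                inclusion_length: float = DEFAULT_INCLUSION_LENGTH,
                skip_length: float = DEFAULT_SKIP_LENGTH) -> float:
    """psi for one sample-event; NaN when no junction reads support either isoform."""
    if inclusion_length <= 0 or skip_length <= 0:
        raise ValueError("effective lengths must be positive")
    if inclusion < 0 or skip < 0:
        raise ValueError("junction read counts must be nonnegative")
    if inclusion + skip == 0:
        return float("nan")
    i_norm = inclusion / inclusion_length
    s_norm = skip / skip_length
    return i_norm / (i_norm + s_norm)


def compute_psi_table(counts: pd.DataFrame, events: Sequence[SpliceEvent]) -> pd.DataFrame:
    """Events x samples psi from a long junction-count table.

    ``counts`` has columns event_id, sample_id, IJC, SJC (rMATS JC naming).
    Per-event effective lengths come from the event annotations; events
    absent from the table yield all-NaN rows.
    """
    for col in ("event_id", "sample_id", "IJC", "SJC"):
        if col not in counts.columns:
            raise ValueError(f"junction-count table is missing column {col!r}")
    if (counts[["IJC", "SJC"]] < 0).to_numpy().any():
        raise ValueError("junction read counts must be nonnegative")
    lengths = {ev.event_id: (ev.inclusion_length, ev.skip_length) for ev in events}
    ijc = counts.pivot_table(index="event_id", columns="sample_id", values="IJC", aggfunc="sum")
    sjc = counts.pivot_table(index="event_id", columns="sample_id", values="SJC", aggfunc="sum")
    ijc = ijc.reindex(index=lengths.keys())
    sjc = sjc.reindex(index=lengths.keys(), columns=ijc.columns)
    l_i = np.array([lengths[e][0] for e in ijc.index])[:, None]
    l_s = np.array([lengths[e][1] for e in ijc.index])[:, None]
    i_norm = ijc.to_numpy(dtype=float) / l_i
    s_norm = sjc.to_numpy(dtype=float) / l_s
    total = i_norm + s_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, i_norm / total, np.nan)
    out = pd.DataFrame(psi, index=ijc.index, columns=ijc.columns)
    out.index.name = "event_id"
    out.columns.name = "sample_id"
    return out


def support_mask(counts: pd.DataFrame, genotyped: Iterable[str], min_reads: int = 10) -> pd.DataFrame:
    """Boolean events x samples mask of support samples.

    A sample supports an event iff it is genotyped and the total junction
    reads (inclusion + exclusion) reach ``min_reads`` (default 10,
    boundary inclusive).
    """
    genotyped = set(genotyped)
    total = counts.pivot_table(index="event_id", columns="sample_id",
                               values=["IJC", "SJC"], aggfunc="sum")
    tot = total["IJC"].fillna(0) + total["SJC"].fillna(0)
    mask = tot >= min_reads
    geno_cols = np.array([c in genotyped for c in mask.columns])
    out = mask & geno_cols[None, :]
    out.index.name = "event_id"
    out.columns.name = "sample_id"
    return out


def psi_matrix(counts: pd.DataFrame, events: Sequence[SpliceEvent],
               genotyped: Iterable[str], min_reads: int = 10) -> PsiMatrix:
    psi = compute_psi_table(counts, events)
    support = support_mask(counts, genotyped, min_reads=min_reads).reindex(
        index=psi.index, columns=psi.columns, fill_value=False)
    return PsiMatrix(psi=psi, support=support)


def iqr(values: np.ndarray) -> float:
    """Interquartile range with linear-interpolation quantiles."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


def filter_events(psi: PsiMatrix, events: Sequence[SpliceEvent], variants: GenotypePanel,
                  min_support: int = 100, min_iqr: float = 0.10,
                  min_variants: int = 2) -> list[str]:
    """Event ids passing all three eligibility criteria.

    (i) at least ``min_variants`` SNVs inside the transcribed region
    (default 2, i.e. "more than one"); (ii) support-sample count >=
    ``min_support``; (iii) IQR of psi over the support samples strictly
    above ``min_iqr``.
    """
    eligible = []
    for ev in events:
        if ev.event_id not in psi.psi.index:
            continue
        n_var = len(variants.variants_in_region(ev.chrom, ev.region_start, ev.region_end))
        if n_var < min_variants:
            continue
        sup = psi.support_samples(ev.event_id)
        if len(sup) < min_support:
            continue
        if not iqr(psi.psi.loc[ev.event_id, sup].to_numpy()) > min_iqr:
            continue
        eligible.append(ev.event_id)
    return eligible
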