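"""Assign peaks to genes by TSS-distance windows and classify genomic context.

A peak's anchor (summit if recorded, else region midpoint) is compared to
every TSS on the same chromosome; pairs within the outer window (default
10 kb) are emitted, flagged ``within_1kb`` when inside the inner window.
Signed distances are in gene orientation: negative means the anchor lies
5' (upstream) of the TSS.  Each peak's minimum-|distance| gene carries
``nearest=True`` (ties broken by gene id).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, Peak

__all__ = [
    "PeakAssignment",
    "tss_of",
    "anchor_of",
    "assign_peaks",
    "classify_location",
    "assignments_to_frame",
]

WINDOW_DEFAULT = 10_000
INNER_DEFAULT = 1_000

LOCATION_CLASSES = (
    "tss_overlap",
    "upstream_5prime",
    "downstream_3prime",
    "exon",
    "intron",
)


@dataclass(frozen=True)
class PeakAssignment:
    peak_id: str
    gene_id: str
    symbol: str
    signed_distance: int
    window_class: str  # within_1kb | within_10kb
    location_class: str
    nearest: bool


def tss_of(gene: GeneModel) -> int:
    """TSS position: body start on +, last covered base (end - 1) on -."""
    if gene.body.strand == "+":
        return gene.body.start
    if gene.body.strand == "-":
        return gene.body.end - 1
    raise ValueError(f"gene {gene.gene_id}: unstranded gene has no TSS")


def anchor_of(peak: Peak) -> int:
    """Anchor point: summit if present, else region midpoint."""
    if peak.summit_offset is not None:
        return peak.region.start + peak.summit_offset
    return (peak.region.start + peak.region.end) // 2


def classify_location(peak: Peak, gene: GeneModel) -> str:
    """Classify a peak already assigned to a gene.

    Precedence: tss_overlap (region contains the TSS) > exon (region
    overlaps any exon) > intron (region contained in the body) > the
    upstream/downstream flank of the anchor in gene orientation.  A region
    that straddles a body edge without touching an exon or the TSS is
    classed by the edge it crosses (5' edge wins if both).
    """
    tss = tss_of(gene)
    region = peak.region
    if region.chrom != gene.body.chrom:
        raise ValueError(
            f"peak {peak.peak_id} and gene {gene.gene_id} on different chromosomes"
        )
    if region.contains(tss):
        return "tss_overlap"
    if any(region.overlaps(exon) for exon in gene.exons):
        return "exon"
    if gene.body.contains_interval(region):
        return "intron"
    plus = gene.body.strand == "+"
    anchor = anchor_of(peak)
    if anchor < gene.body.start:
        return "upstream_5prime" if plus else "downstream_3prime"
    if anchor >= gene.body.end:
        return "downstream_3prime" if plus else "upstream_5prime"
    # anchor inside the body but region spills over an edge
    crosses_5p = region.start < gene.body.start if plus else region.end > gene.body.end
    return "upstream_5prime" if crosses_5p else "downstream_3prime"


def assign_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = WINDOW_DEFAULT,
    inner: int = INNER_DEFAULT,
) -> list[PeakAssignment]:
    """All (peak, gene) pairs with |anchor - TSS| <= window, chromosome-matched.

    A peak near several genes yields several assignments; exactly one per
    assigned peak is flagged nearest.
    """
    if window <= 0 or inner <= 0 or inner > window:
        raise ValueError(f"need 0 < inner <= window, got inner={inner} window={window}")
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.body.chrom].append(g)
    tss_arrays = {
        chrom: np.array([tss_of(g) for g in glist])
        for chrom, glist in by_chrom.items()
    }
    out: list[PeakAssignment] = []
    for peak in peaks:
        chrom = peak.region.chrom
        if chrom not in by_chrom:
            continue
        anchor = anchor_of(peak)
        glist = by_chrom[chrom]
        tss = tss_arrays[chrom]
        idx = np.flatnonzero(np.abs(anchor - tss) <= window)
        if len(idx) == 0:
            continue
        rows = []
        for i in idx:
            gene = glist[i]
            d = anchor - int(tss[i])
            if gene.body.strand == "-":
                d = -d
            rows.append(
                PeakAssignment(
                    peak_id=peak.peak_id,
                    gene_id=gene.gene_id,
                    symbol=gene.symbol,
                    signed_distance=d,
                    window_class="within_1kb" if abs(d) <= inner else "within_10kb",
                    location_class=classify_location(peak, gene),
                    nearest=False,
                )
            )
        best = min(
            range(len(rows)),
            key=lambda j: (abs(rows[j].signed_distance), rows[j].gene_id),
        )
        rows[best] = replace(rows[best], nearest=True)
        out.extend(rows)
    return out


def assignments_to_frame(assignments: Iterable[PeakAssignment]) -> pd.DataFrame:
    cols = [
        "peak_id",
        "gene_id",
        "symbol",
        "signed_distance",
        "window_class",
        "location_class",
        "nearest",
    ]
    return pd.DataFrame([a.__dict__ for a in assignments], columns=cols)


def summarize_assignments(assignments: Sequence[PeakAssignment]) -> dict[str, int]:
    """Funnel counts, reporting both peak-level and gene-level tallies.

    The two levels are both reported because 'n within 10 kb' can count
    either peaks or distinct genes, and the two differ on real data.
    """
    peaks_10kb = {a.peak_id for a in assignments}
    peaks_1kb = {a.peak_id for a in assignments if a.window_class == "within_1kb"}
    genes_10kb = {a.gene_id for a in assignments}
    genes_1kb = {a.gene_id for a in assignments if a.window_class == "within_1kb"}
    return {
        "assignments": len(assignments),
        "peaks_within_10kb": len(peaks_10kb),
        "peaks_within_1kb": len(peaks_1kb),
        "genes_within_10kb": len(genes_10kb),
        "genes_within_1kb": len(genes_1kb),
    }
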