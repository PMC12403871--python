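"""Transcript 3'-end (TEP) calling from Term-seq profiles and classification.

Candidates are local maxima of the 3'-end count track above a height
threshold; merged sites are classified relative to the annotation into:

* ``P`` primary        — strongest site within 300 nt downstream of a gene's
  3' end on the sense strand;
* ``S`` secondary      — weaker site competing in the same window;
* ``C`` cis-regulatory — inside a primary-TSS-derived 5'-UTR (premature
  3' ends of regulatory leaders such as riboswitches);
* ``A`` antisense      — inside a gene body on the antisense strand;
* ``N`` intergenic (orphan).

Precedence is P/S > C > A > N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .io_formats import EndCountProfile, GeneFeature, GenomeAnnotation
from .rnafold import FoldResult
from .sites import CalledSite, MergedSite, merge_sites
from .tss_mapper import TSSRecord, category_counts

__all__ = [
    "TEPRecord",
    "call_tep",
    "merge_sites",
    "classify_tep",
    "utr3_lengths",
    "utr5_intervals",
]

logger = logging.getLogger(__name__)

TEP_CATEGORIES = ("P", "S", "C", "A", "N")


@dataclass(frozen=True)
class TEPRecord:
    position: int  # 0-based position of the last transcribed base
    strand: str
    conditions: tuple[str, ...]
    height: float
    category: str
    assigned_gene: Optional[str] = None
    utr3_length: Optional[int] = None
    fold: Optional[FoldResult] = None
    shape: Optional[str] = None  # HS_U_RICH | HS_U_LACK | LS
    u_count: Optional[int] = None
    readthrough: Optional[float] = None
    constitutive: bool = False

    def __post_init__(self) -> None:
        if self.category not in TEP_CATEGORIES:
            raise ValueError(f"unknown TEP category {self.category!r}")
        if self.category in "PS" and self.assigned_gene is None:
            raise ValueError(f"category {self.category} requires an assigned gene")

    def to_row(self) -> dict:
        return {
            "position": self.position,
            "strand": self.strand,
            "category": self.category,
            "gene": self.assigned_gene or "",
            "conditions": ",".join(self.conditions),
            "height": self.height,
            "utr3": self.utr3_length if self.utr3_length is not None else "",
            "delta_g": round(self.fold.delta_g, 1) if self.fold else "",
            "structure": self.fold.structure if self.fold else "",
            "shape": self.shape or "",
            "u_count": self.u_count if self.u_count is not None else "",
            "readthrough": round(self.readthrough, 4)
            if self.readthrough is not None
            else "",
        }


def call_tep(
    termseq: EndCountProfile,
    min_height: float = 10.0,
    local_window: int = 2,
) -> list[CalledSite]:
    """Call 3'-end candidates: height >= min_height and local maximum
    within +/-local_window nt (ties keep the 3'-most position)."""
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    condition = termseq.meta.condition if termseq.meta else ""
    out: list[CalledSite] = []
    for pos, h in termseq.counts.items():
        if h < min_height:
            continue
        neighborhood = [
            (termseq[q], q) for q in range(pos - local_window, pos + local_window + 1)
        ]
        if h < max(v for v, _ in neighborhood):
            continue
        peers = [q for v, q in neighborhood if v == h]
        three_most = max(peers) if termseq.strand == "+" else min(peers)
        if pos != three_most:
            continue
        out.append(
            CalledSite(
                position=pos, strand=termseq.strand, height=float(h), condition=condition
            )
        )
    out.sort(key=lambda s: s.position)
    return out


def utr5_intervals(
    tss_records: Sequence[TSSRecord], annotation: GenomeAnnotation
) -> list[tuple[int, int, str]]:
    """Forward-coordinate half-open 5'-UTR intervals of primary TSSs."""
    genes = {g.gene_id: g for g in annotation.genes}
    out = []
    for rec in tss_records:
        if rec.category != "P":
            continue
        g = genes[rec.assigned_gene]
        if g.strand == "+":
            lo, hi = rec.position, g.start
        else:
            lo, hi = g.end, rec.position + 1
        if hi > lo:
            out.append((lo, hi, g.strand))
    return out


def _downstream_distance(gene: GeneFeature, pos: int) -> int:
    """Distance from the gene's 3' end to pos along the transcript strand."""
    return pos - gene.end if gene.strand == "+" else gene.start - 1 - pos


def classify_tep(
    sites: Sequence[MergedSite],
    annotation: GenomeAnnotation,
    tss_records: Sequence[TSSRecord] = (),
    downstream_window: int = 300,
    contig_id: Optional[str] = None,
) -> list[TEPRecord]:
    """Assign the five positional TEP categories to merged 3'-end sites."""
    if contig_id is None:
        contig_id = next(iter(annotation.sequences))
    genes = annotation.genes_on(contig_id)
    utrs = utr5_intervals(tss_records, annotation)

    assignment: dict[int, GeneFeature] = {}
    for i, site in enumerate(sites):
        eligible = []
        for g in genes:
            if g.strand != site.strand:
                continue
            d = _downstream_distance(g, site.position)
            if 0 <= d <= downstream_window:
                eligible.append((d, g.gene_id, g))
        if eligible:
            eligible.sort()
            assignment[i] = eligible[0][2]

    by_gene: dict[str, list[int]] = {}
    for i, g in assignment.items():
        by_gene.setdefault(g.gene_id, []).append(i)
    category: dict[int, str] = {}
    for gene_id, idxs in by_gene.items():
        idxs.sort(key=lambda i: (-sites[i].height, sites[i].position))
        category[idxs[0]] = "P"
        for i in idxs[1:]:
            category[i] = "S"

    records: list[TEPRecord] = []
    for i, site in enumerate(sites):
        if i in category:
            cat = category[i]
            gene: Optional[str] = assignment[i].gene_id
        else:
            gene = None
            if any(
                lo <= site.position < hi and strand == site.strand
                for lo, hi, strand in utrs
            ):
                cat = "C"
            elif any(
                g.strand != site.strand and g.start <= site.position < g.end
                for g in genes
            ):
                cat = "A"
            else:
                cat = "N"
        records.append(
            TEPRecord(
                position=site.position,
                strand=site.strand,
                conditions=site.conditions,
                height=site.height,
                category=cat,
                assigned_gene=gene,
                constitutive=site.constitutive,
            )
        )
    assert sum(category_counts(records, TEP_CATEGORIES).values()) == len(records)
    return records


def utr3_lengths(
    records: Sequence[TEPRecord],
    annotation: GenomeAnnotation,
    short_cutoff: int = 20,
    bin_width: int = 10,
) -> tuple[list[TEPRecord], dict]:
    """Attach 3'-UTR lengths to primary TEPs and summarize them.

    The 3'-UTR length is the distance from the assigned gene's stop position
    to the TEP on the sense strand.  The summary reports the median, the
    modal ``bin_width``-nt bin (as its inclusive [lo, hi] bounds) and the
    fraction of short UTRs below ``short_cutoff`` nt.
    """
    genes = {g.gene_id: g for g in annotation.genes}
    out: list[TEPRecord] = []
    lengths: list[int] = []
    for rec in records:
        if rec.category != "P":
            out.append(rec)
            continue
        utr3 = _downstream_distance(genes[rec.assigned_gene], rec.position)
        if utr3 < 0:
            raise ValueError(
                f"TEP at {rec.strand}{rec.position} upstream of gene 3' end: "
                "classification bug"
            )
        out.append(replace(rec, utr3_length=utr3))
        lengths.append(utr3)
    arr = np.array(lengths)
    if len(arr):
        hist = np.bincount(arr // bin_width)
        modal = int(np.argmax(hist))
        modal_bin = (modal * bin_width, modal * bin_width + bin_width - 1)
        summary = {
            "n": len(arr),
            "median_utr3": float(np.median(arr)),
            "modal_bin": modal_bin,
            "short_fraction": float(np.mean(arr < short_cutoff)),
            "histogram": hist.tolist(),
        }
    else:
        summary = {
            "n": 0,
            "median_utr3": float("nan"),
            "modal_bin": None,
            "short_fraction": float("nan"),
            "histogram": [],
        }
    return out, summary
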