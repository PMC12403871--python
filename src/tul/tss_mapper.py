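"""TSS calling from dRNA-seq 5'-end profiles and genomic classification.

A position is a TSS candidate when its 5'-end count in the TEX-treated
(enriched) library clears a height threshold, the pseudocounted
enriched/unenriched ratio clears an enrichment threshold, and the position
is a local maximum of the enriched track within +/-2 nt.  Candidates are
merged across conditions within +/-5 nt and classified against the gene
annotation into five categories:

* ``P`` primary   — the strongest site within the upstream window of a gene
  on its sense strand;
* ``S`` secondary — a weaker site competing for the same gene;
* ``I`` internal  — inside a gene body on the sense strand;
* ``A`` antisense — inside a gene body or its +/-100-nt flanks on the
  antisense strand;
* ``N`` intergenic (orphan) — everything else.

Precedence is P/S > I > A > N, so every site receives exactly one label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import EndCountProfile, GeneFeature, GenomeAnnotation, revcomp
from .sites import CalledSite, MergedSite, merge_sites

__all__ = [
    "TSSRecord",
    "call_tss",
    "merge_sites",
    "classify_tss",
    "utr5_and_leaderless",
    "base_composition",
    "category_counts",
]

logger = logging.getLogger(__name__)

TSS_CATEGORIES = ("P", "S", "I", "A", "N")


@dataclass(frozen=True)
class TSSRecord:
    position: int  # 0-based position of the +1 (first transcribed) base
    strand: str
    conditions: tuple[str, ...]
    height: float
    enrichment: float
    category: str
    assigned_gene: Optional[str] = None
    utr5_length: Optional[int] = None
    leaderless: Optional[bool] = None
    constitutive: bool = False

    def __post_init__(self) -> None:
        if self.category not in TSS_CATEGORIES:
            raise ValueError(f"unknown TSS category {self.category!r}")
        if self.category in "PSI" and self.assigned_gene is None:
            raise ValueError(f"category {self.category} requires an assigned gene")

    def to_row(self) -> dict:
        return {
            "position": self.position,
            "strand": self.strand,
            "category": self.category,
            "gene": self.assigned_gene or "",
            "conditions": ",".join(self.conditions),
            "height": self.height,
            "enrichment": round(self.enrichment, 3)
            if self.enrichment == self.enrichment
            else "",
            "utr5": self.utr5_length if self.utr5_length is not None else "",
            "leaderless": {True: "yes", False: "no", None: ""}[self.leaderless],
        }


def call_tss(
    enriched: EndCountProfile,
    unenriched: EndCountProfile,
    min_height: float = 10.0,
    min_enrichment: float = 2.0,
    pseudocount: float = 1.0,
    local_window: int = 2,
) -> list[CalledSite]:
    """Call TSS candidates on one strand of one condition.

    A position p qualifies iff ``enriched[p] >= min_height``,
    ``(enriched[p]+a)/(unenriched[p]+a) >= min_enrichment`` with pseudocount
    a, and ``enriched[p]`` is the maximum of the enriched track within
    +/-``local_window`` nt (ties keep only the 5'-most position).
    """
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    if min_enrichment < 1:
        raise ValueError("min_enrichment must be >= 1")
    if (enriched.contig_id, enriched.strand) != (unenriched.contig_id, unenriched.strand):
        raise ValueError("enriched/unenriched profiles must match contig and strand")
    condition = enriched.meta.condition if enriched.meta else ""
    out: list[CalledSite] = []
    for pos, h in enriched.counts.items():
        if h < min_height:
            continue
        ratio = (h + pseudocount) / (unenriched[pos] + pseudocount)
        if ratio < min_enrichment:
            continue
        neighborhood = [
            (enriched[q], q) for q in range(pos - local_window, pos + local_window + 1)
        ]
        best = max(n[0] for n in neighborhood)
        if h < best:
            continue
        peers = [q for v, q in neighborhood if v == h]
        five_most = min(peers) if enriched.strand == "+" else max(peers)
        if pos != five_most:
            continue
        out.append(
            CalledSite(
                position=pos,
                strand=enriched.strand,
                height=float(h),
                condition=condition,
                enrichment=float(ratio),
            )
        )
    out.sort(key=lambda s: s.position)
    return out


def _upstream_candidates(
    gene: GeneFeature, window: int
) -> tuple[int, int]:
    """Forward-coordinate half-open interval of 5'-UTR distances [0, window].

    The gene-start position itself is included so that leaderless starts
    (transcription initiating at the first codon, 5'-UTR length 0) classify
    as primary rather than internal.
    """
    if gene.strand == "+":
        return max(0, gene.start - window), gene.start + 1
    return gene.end - 1, gene.end + window


def classify_tss(
    sites: Sequence[MergedSite],
    annotation: GenomeAnnotation,
    upstream_window: int = 300,
    antisense_flank: int = 100,
    contig_id: Optional[str] = None,
) -> list[TSSRecord]:
    """Assign each merged site one of the five positional categories."""
    if contig_id is None:
        contig_id = next(iter(annotation.sequences))
    genes = annotation.genes_on(contig_id)

    # candidate P/S assignment: site in the sense-strand upstream window of
    # a gene; a site eligible for several genes goes to the nearer start
    assignment: dict[int, GeneFeature] = {}  # site index -> gene
    for i, site in enumerate(sites):
        eligible: list[tuple[int, str, GeneFeature]] = []
        for g in genes:
            if g.strand != site.strand:
                continue
            lo, hi = _upstream_candidates(g, upstream_window)
            if lo <= site.position < hi:
                dist = abs(site.position - g.five_prime())
                eligible.append((dist, g.gene_id, g))
        if eligible:
            eligible.sort()
            if len(eligible) > 1 and eligible[0][0] == eligible[1][0]:
                logger.info(
                    "site %s%d equidistant from %s and %s; assigned to %s",
                    site.strand,
                    site.position,
                    eligible[0][1],
                    eligible[1][1],
                    eligible[0][1],
                )
            assignment[i] = eligible[0][2]

    # within each gene, the strongest assigned site is primary
    by_gene: dict[str, list[int]] = {}
    for i, g in assignment.items():
        by_gene.setdefault(g.gene_id, []).append(i)
    category: dict[int, str] = {}
    for gene_id, idxs in by_gene.items():
        idxs.sort(key=lambda i: (-sites[i].height, sites[i].position))
        category[idxs[0]] = "P"
        for i in idxs[1:]:
            category[i] = "S"

    records: list[TSSRecord] = []
    for i, site in enumerate(sites):
        if i in category:
            cat = category[i]
            gene: Optional[str] = assignment[i].gene_id
        else:
            gene = None
            sense_body = [
                g
                for g in genes
                if g.strand == site.strand and g.start <= site.position < g.end
            ]
            if sense_body:
                cat = "I"
                gene = sense_body[0].gene_id
            elif any(
                g.strand != site.strand
                and g.start - antisense_flank <= site.position < g.end + antisense_flank
                for g in genes
            ):
                cat = "A"
            else:
                cat = "N"
        records.append(
            TSSRecord(
                position=site.position,
                strand=site.strand,
                conditions=site.conditions,
                height=site.height,
                enrichment=site.enrichment,
                category=cat,
                assigned_gene=gene,
                constitutive=site.constitutive,
            )
        )
    return records


def utr5_and_leaderless(
    records: Sequence[TSSRecord],
    annotation: GenomeAnnotation,
    leaderless_max: int = 10,
) -> tuple[list[TSSRecord], dict]:
    """Attach 5'-UTR lengths to P/S records and flag leaderless starts.

    The 5'-UTR length is the distance from the TSS (+1 base) to the start
    codon of the assigned gene on the sense strand; a transcript is
    leaderless when that distance is < ``leaderless_max`` nt (too short to
    hold a ribosome-binding site).
    """
    genes = {g.gene_id: g for g in annotation.genes}
    out: list[TSSRecord] = []
    lengths: list[int] = []
    n_leaderless = 0
    for rec in records:
        if rec.category not in ("P", "S"):
            out.append(rec)
            continue
        g = genes[rec.assigned_gene]
        utr5 = (
            g.start - rec.position if g.strand == "+" else rec.position - (g.end - 1)
        )
        if utr5 < 0:
            raise ValueError(
                f"TSS at {rec.strand}{rec.position} lies downstream of "
                f"{g.gene_id}'s start: classification bug"
            )
        leaderless = utr5 < leaderless_max
        out.append(replace(rec, utr5_length=utr5, leaderless=leaderless))
        lengths.append(utr5)
        n_leaderless += leaderless
    lengths_arr = np.array(lengths)
    summary = {
        "n": len(lengths),
        "median_utr5": float(np.median(lengths_arr)) if lengths else float("nan"),
        "n_leaderless": n_leaderless,
        "leader_fraction": 1 - n_leaderless / len(lengths) if lengths else float("nan"),
        "histogram": np.bincount(lengths_arr // 10).tolist() if lengths else [],
    }
    return out, summary


def base_composition(
    sites: Sequence, genome: str | GenomeAnnotation, flank: int = 2,
    contig_id: Optional[str] = None,
) -> pd.DataFrame:
    """Base frequencies at offsets -flank..+flank around sites (+1 = offset 0).

    Minus-strand windows are reverse-complemented so offsets read in
    transcript sense.  Sites too close to a contig edge are skipped (and
    logged); each returned row sums to 1.
    """
    if isinstance(genome, GenomeAnnotation):
        if contig_id is None:
            contig_id = next(iter(genome.sequences))
        seq = genome.sequences[contig_id].sequence
    else:
        seq = genome
    sites = list(sites)
    if not sites:
        raise ValueError("no sites given")
    offsets = range(-flank, flank + 1)
    counts = pd.DataFrame(0.0, index=list(offsets), columns=list("ACGT"))
    n_used = 0
    for s in sites:
        lo, hi = s.position - flank, s.position + flank
        if lo < 0 or hi >= len(seq):
            logger.info("site %s%d within %d nt of contig edge: skipped",
                        s.strand, s.position, flank)
            continue
        window = seq[lo : hi + 1]
        if s.strand == "-":
            window = revcomp(window)
        n_used += 1
        for off, base in zip(offsets, window):
            if base in "ACGT":
                counts.loc[off, base] += 1
    if n_used == 0:
        raise ValueError("all sites fell within flank of a contig edge")
    freq = counts.div(counts.sum(axis=1), axis=0)
    freq.index.name = "offset"
    return freq


def category_counts(records: Sequence, categories: Sequence[str] = TSS_CATEGORIES) -> dict[str, int]:
    """Counts per category; always a full partition of the input records."""
    records = list(records)
    counts = {c: 0 for c in categories}
    for r in records:
        counts[r.category] += 1
    assert sum(counts.values()) == len(records), "category partition violated"
    return counts
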