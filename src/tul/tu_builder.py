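"""Transcription-unit assembly from paired TSS/TEP lists.

Each TU spans a TSS and the nearest downstream TEP on the same strand,
subject to a maximum span and to not running past the gene block of the
next primary TSS.  TUs are categorized by the genes they fully contain
(monocistronic / polycistronic) or, when gene-free, by the class of their
endpoints (cis-regulatory when the 3' end falls in a 5'-UTR, intergenic
otherwise).  The functional-relatedness statistic compares the COG
homogeneity of genes co-transcribed in polycistronic TUs with randomly
drawn runs of neighboring same-strand genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneFeature, GenomeAnnotation
from .tep_mapper import TEPRecord
from .tss_mapper import TSSRecord

__all__ = [
    "TranscriptionUnit",
    "EnrichmentScore",
    "assemble_tus",
    "categorize_and_summarize",
    "functional_enrichment_score",
    "random_neighbor_baseline",
]

logger = logging.getLogger(__name__)

TU_CATEGORIES = ("monocistronic", "polycistronic", "cis_regulatory", "intergenic")


@dataclass(frozen=True)
class TranscriptionUnit:
    tss: TSSRecord
    tep: TEPRecord
    strand: str
    span: tuple[int, int]  # forward-coordinate half-open interval
    genes: tuple[str, ...]  # fully contained sense-strand genes, 5'->3'
    category: str
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in TU_CATEGORIES:
            raise ValueError(f"unknown TU category {self.category!r}")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def to_row(self) -> dict:
        return {
            "tss_position": self.tss.position,
            "tep_position": self.tep.position,
            "strand": self.strand,
            "category": self.category,
            "n_genes": len(self.genes),
            "genes": ",".join(self.genes),
            "conditions": ",".join(self.conditions),
        }


@dataclass(frozen=True)
class EnrichmentScore:
    score: float
    n_genes_with_cog: int
    n_categories: int


def _contained_genes(
    annotation: GenomeAnnotation, strand: str, lo: int, hi: int
) -> list[GeneFeature]:
    """Sense-strand genes fully inside [lo, hi), ordered 5'->3'."""
    inside = [
        g
        for g in annotation.genes
        if g.strand == strand and lo <= g.start and g.end <= hi
    ]
    inside.sort(key=lambda g: g.start, reverse=(strand == "-"))
    return inside


def assemble_tus(
    tss_list: Sequence[TSSRecord],
    tep_list: Sequence[TEPRecord],
    annotation: GenomeAnnotation,
    max_span: int = 15_000,
) -> list[TranscriptionUnit]:
    """Pair each TSS with its nearest downstream TEP and build TUs.

    Pairing walks each strand 5'->3'; a TSS takes the nearest same-strand
    TEP downstream of it within ``max_span`` that does not reach past the
    start of the next primary TSS's gene block.  Unpaired sites are logged.
    Per-condition duplicates are implicitly handled upstream (sites are
    already condition-merged); TUs whose endpoints both agree within ±5 nt
    are deduplicated here with unioned condition support.
    """
    genes = {g.gene_id: g for g in annotation.genes}
    tus: list[TranscriptionUnit] = []
    for strand in "+-":
        sign = 1 if strand == "+" else -1
        tss_here = sorted(
            (t for t in tss_list if t.strand == strand),
            key=lambda t: sign * t.position,
        )
        tep_here = sorted(
            (t for t in tep_list if t.strand == strand),
            key=lambda t: sign * t.position,
        )
        for idx, tss in enumerate(tss_here):
            # boundary: the next primary TSS's gene block must not be crossed
            limit = None
            for nxt in tss_here[idx + 1 :]:
                if nxt.category == "P" and nxt.assigned_gene:
                    g = genes[nxt.assigned_gene]
                    limit = g.five_prime()
                    break
            chosen: Optional[TEPRecord] = None
            for tep in tep_here:
                d = sign * (tep.position - tss.position)
                if d <= 0 or d > max_span:
                    continue
                if limit is not None and sign * (tep.position - limit) > 0:
                    continue
                chosen = tep
                break
            if chosen is None:
                logger.info("TSS %s%d left unpaired", strand, tss.position)
                continue
            if sign * (chosen.position - tss.position) <= 0:
                raise RuntimeError("TEP upstream of its TSS: pairing bug")
            lo, hi = sorted((tss.position, chosen.position))
            contained = _contained_genes(annotation, strand, lo, hi + 1)
            if contained:
                category = "monocistronic" if len(contained) == 1 else "polycistronic"
            elif chosen.category == "C":
                category = "cis_regulatory"
            elif tss.category == "N" or chosen.category == "N":
                category = "intergenic"
            else:
                category = "intergenic"
            conds = tuple(
                sorted(set(tss.conditions) | set(chosen.conditions))
            )
            tus.append(
                TranscriptionUnit(
                    tss=tss,
                    tep=chosen,
                    strand=strand,
                    span=(lo, hi + 1),
                    genes=tuple(g.gene_id for g in contained),
                    category=category,
                    conditions=conds,
                )
            )
    # merge TUs whose endpoints agree within ±5 nt (cross-condition duplicates)
    merged: list[TranscriptionUnit] = []
    for tu in sorted(tus, key=lambda t: (t.strand, t.span)):
        dup = next(
            (
                m
                for m in merged
                if m.strand == tu.strand
                and abs(m.tss.position - tu.tss.position) <= 5
                and abs(m.tep.position - tu.tep.position) <= 5
            ),
            None,
        )
        if dup is None:
            merged.append(tu)
        else:
            merged.remove(dup)
            keep, other = (dup, tu) if dup.tss.height >= tu.tss.height else (tu, dup)
            merged.append(
                TranscriptionUnit(
                    tss=keep.tss,
                    tep=keep.tep,
                    strand=keep.strand,
                    span=keep.span,
                    genes=keep.genes,
                    category=keep.category,
                    conditions=tuple(
                        sorted(set(keep.conditions) | set(other.conditions))
                    ),
                )
            )
    merged.sort(key=lambda t: (t.strand, t.span))
    return merged


def categorize_and_summarize(tus: Sequence[TranscriptionUnit]) -> dict:
    """Category counts (a partition of the TU list) and genes-per-TU stats."""
    counts = {c: 0 for c in TU_CATEGORIES}
    for tu in tus:
        counts[tu.category] += 1
    assert sum(counts.values()) == len(list(tus)), "TU category partition violated"
    poly_sizes = [len(t.genes) for t in tus if t.category == "polycistronic"]
    return {
        "counts": counts,
        "n_total": len(list(tus)),
        "median_genes_per_polycistronic": float(np.median(poly_sizes))
        if poly_sizes
        else float("nan"),
        "poly_sizes": sorted(poly_sizes),
    }


def functional_enrichment_score(
    gene_ids: Sequence[str],
    cog_map: dict[str, Optional[str]],
    mode: str = "literal",
) -> Optional[EnrichmentScore]:
    """COG functional-relatedness score of one gene set.

    ``literal`` mode: max genes in one COG category divided by the number of
    distinct categories present (can exceed 1 when all genes share one
    category).  ``per-gene`` mode divides by the number of COG-annotated
    genes instead, bounding the score at 1.  Genes without a COG category
    are excluded; returns None when none remain.
    """
    cats = [cog_map[g] for g in gene_ids if cog_map.get(g)]
    if not cats:
        return None
    counter = Counter(cats)
    max_count = max(counter.values())
    if mode == "literal":
        score = max_count / len(counter)
    elif mode == "per-gene":
        score = max_count / len(cats)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return EnrichmentScore(
        score=float(score), n_genes_with_cog=len(cats), n_categories=len(counter)
    )


def random_neighbor_baseline(
    annotation: GenomeAnnotation,
    tu_sizes: Sequence[int],
    observed_scores: Sequence[float],
    n_draws: int = 1000,
    seed: int = 0,
    mode: str = "literal",
    max_retries: int = 1000,
) -> dict:
    """Null distribution of enrichment scores from random neighbor runs.

    Each draw samples a TU size k from ``tu_sizes`` and a random gene, takes
    the run of k consecutive same-strand neighbors starting there, and
    scores it with the same formula; draws landing on strand breaks are
    resampled (bounded retries).  Returns the baseline scores and a
    two-sided Mann-Whitney U comparison against ``observed_scores``.
    """
    rng = np.random.default_rng(seed)
    genes = annotation.genes
    cog_map = {g.gene_id: g.cog_category for g in genes}
    sizes = list(tu_sizes)
    if not sizes or not genes:
        raise ValueError("need observed TU sizes and an annotated genome")
    baseline: list[float] = []
    for _ in range(n_draws):
        for _attempt in range(max_retries):
            k = int(rng.choice(sizes))
            start = int(rng.integers(0, len(genes)))
            run = genes[start : start + k]
            if len(run) < k or len({g.strand for g in run}) != 1:
                continue
            if len({g.contig_id for g in run}) != 1:
                continue
            es = functional_enrichment_score(
                [g.gene_id for g in run], cog_map, mode=mode
            )
            if es is None:
                continue
            baseline.append(es.score)
            break
        else:
            raise RuntimeError(
                "could not draw a same-strand neighbor run; annotation too sparse"
            )
    observed = [s for s in observed_scores if s == s]
    result: dict = {"baseline_scores": baseline, "n_draws": n_draws}
    if observed:
        mw = stats.mannwhitneyu(observed, baseline, alternative="two-sided")
        result.update(
            U=float(mw.statistic),
            p=float(mw.pvalue),
            observed_median=float(np.median(observed)),
            baseline_median=float(np.median(baseline)),
        )
    return result
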