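"""End-to-end orchestration: tracks in, classified sites and TUs out.

Replicates of one condition are pooled (summed) before site calling; the
per-condition candidate lists are then merged within ±5 nt into the total
site lists, classified, typed and assembled into TUs.  RNA-seq coverage is
normalized across replicates by median-of-ratios over gene-level counts
and averaged before readthrough estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import EndCountProfile, GenomeAnnotation
from .signal import gene_counts, size_factors
from .sites import merge_sites
from .tep_mapper import TEPRecord, call_tep, classify_tep, utr3_lengths
from .terminator_typing import readthrough_fraction, type_all
from .tss_mapper import TSSRecord, call_tss, classify_tss, utr5_and_leaderless
from .tu_builder import TranscriptionUnit, assemble_tus, categorize_and_summarize

__all__ = ["PipelineResult", "sum_profiles", "average_normalized_coverage", "analyze_study"]


def sum_profiles(profiles: Sequence[EndCountProfile]) -> EndCountProfile:
    """Pool replicate tracks position-wise (same contig/strand required)."""
    first = profiles[0]
    counts: dict[int, float] = {}
    for p in profiles:
        if (p.contig_id, p.strand) != (first.contig_id, first.strand):
            raise ValueError("cannot pool profiles from different contigs/strands")
        for pos, c in p.counts.items():
            counts[pos] = counts.get(pos, 0.0) + c
    return EndCountProfile(
        contig_id=first.contig_id,
        strand=first.strand,
        counts=counts,
        meta=first.meta,
        contig_length=first.contig_length,
    )


def average_normalized_coverage(
    replicate_pairs: Sequence[tuple[EndCountProfile, EndCountProfile]],
    annotation: GenomeAnnotation,
) -> tuple[EndCountProfile, EndCountProfile]:
    """Average replicate coverage pairs after median-of-ratios normalization.

    Size factors come from gene-body coverage sums; with a single replicate
    the input is returned unscaled.
    """
    if len(replicate_pairs) == 1:
        return replicate_pairs[0]
    named = {f"rep{i + 1}": pair for i, pair in enumerate(replicate_pairs)}
    counts = gene_counts(named, annotation)
    factors = size_factors(counts)
    out = []
    for strand_idx in (0, 1):
        first = replicate_pairs[0][strand_idx]
        acc: dict[int, float] = {}
        for name, pair in named.items():
            f = factors[name]
            for pos, c in pair[strand_idx].counts.items():
                acc[pos] = acc.get(pos, 0.0) + c / f
        avg = {pos: v / len(replicate_pairs) for pos, v in acc.items()}
        out.append(
            EndCountProfile(
                contig_id=first.contig_id,
                strand=first.strand,
                counts=avg,
                meta=first.meta,
                contig_length=first.contig_length,
            )
        )
    return out[0], out[1]


@dataclass
class PipelineResult:
    tss_records: list[TSSRecord]
    tep_records: list[TEPRecord]
    tus: list[TranscriptionUnit]
    utr5_summary: dict
    utr3_summary: dict
    readthrough_summary: dict
    hs_ls_threshold: float
    tu_summary: dict


def analyze_study(
    annotation: GenomeAnnotation,
    libraries: dict[tuple, EndCountProfile],
    conditions: Sequence[str],
    n_replicates: int,
    min_height: float = 10.0,
    min_enrichment: float = 2.0,
    merge_window: int = 5,
    hs_threshold: float | str = "median",
    readthrough_condition: Optional[str] = None,
) -> PipelineResult:
    """Run the full site→terminator→TU pipeline on a library dictionary.

    ``libraries`` is keyed ``(assay, condition, replicate, enriched, strand)``
    as produced by the simulator or assembled from bedGraph input.
    ``readthrough_condition`` selects the RNA-seq condition for readthrough
    estimation (default: last condition).
    """
    conditions = list(conditions)

    tss_per_cond = []
    tep_per_cond = []
    for cond in conditions:
        tss_sites = []
        tep_sites = []
        for strand in "+-":
            enr = sum_profiles(
                [libraries[("dRNA", cond, r, True, strand)] for r in range(1, n_replicates + 1)]
            )
            une = sum_profiles(
                [libraries[("dRNA", cond, r, False, strand)] for r in range(1, n_replicates + 1)]
            )
            tss_sites += call_tss(
                enr, une,
                min_height=min_height * n_replicates,
                min_enrichment=min_enrichment,
            )
            term = sum_profiles(
                [libraries[("Term", cond, r, None, strand)] for r in range(1, n_replicates + 1)]
            )
            tep_sites += call_tep(term, min_height=min_height * n_replicates)
        # pooled profiles inherit the condition label through their meta
        tss_per_cond.append(tss_sites)
        tep_per_cond.append(tep_sites)

    merged_tss = merge_sites(tss_per_cond, window=merge_window, all_conditions=conditions)
    merged_tep = merge_sites(
        tep_per_cond, window=merge_window, all_conditions=conditions, prefer="3prime"
    )

    tss_records = classify_tss(merged_tss, annotation)
    tss_records, utr5_summary = utr5_and_leaderless(tss_records, annotation)

    tep_records = classify_tep(merged_tep, annotation, tss_records)
    tep_records, utr3_summary = utr3_lengths(tep_records, annotation)
    tep_records, threshold = type_all(tep_records, annotation, threshold=hs_threshold)

    rt_cond = readthrough_condition or conditions[-1]
    pairs = [
        (
            libraries[("RNAseq-coverage", rt_cond, r, None, "+")],
            libraries[("RNAseq-coverage", rt_cond, r, None, "-")],
        )
        for r in range(1, n_replicates + 1)
    ]
    cov_plus, cov_minus = average_normalized_coverage(pairs, annotation)
    active = [r for r in tep_records if rt_cond in r.conditions]
    rt_records, rt_summary = readthrough_fraction(active, cov_plus, cov_minus)
    rt_by_pos = {(r.strand, r.position): r for r in rt_records}
    tep_records = [rt_by_pos.get((r.strand, r.position), r) for r in tep_records]

    tus = assemble_tus(tss_records, tep_records, annotation)
    tu_summary = categorize_and_summarize(tus)

    return PipelineResult(
        tss_records=tss_records,
        tep_records=tep_records,
        tus=tus,
        utr5_summary=utr5_summary,
        utr3_summary=utr3_summary,
        readthrough_summary=rt_summary,
        hs_ls_threshold=threshold,
        tu_summary=tu_summary,
    )
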