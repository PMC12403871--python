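"""Typing TEPs by upstream RNA structure, U-tract content and readthrough.

The 40-nt transcript window ending at each TEP is folded with the in-repo
MFE engine; TEPs split at a ΔG threshold (the data median by default, which
is how a highly/less-structured boundary is defined when folding engines
and energy tables differ) into highly structured (HS) and less structured
(LS).  HS TEPs are typed by the uridine count in the 10 nt immediately 3'
of the terminator stem: >=3 Us marks a canonical L-shaped (U-rich)
intrinsic terminator, fewer marks the I-shaped (U-lack) variant common in
high-GC genomes.  Termination strength is measured as the readthrough
fraction: mean normalized RNA-seq coverage downstream over upstream of the
TEP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EndCountProfile, GenomeAnnotation, revcomp
from .rnafold import FoldResult, fold_window
from .tep_mapper import TEPRecord

__all__ = [
    "fold_teps",
    "split_hs_ls",
    "type_u_content",
    "type_all",
    "positional_enrichment",
    "readthrough_fraction",
    "stem_loop_metrics",
    "upstream_window_seq",
    "shape_counts",
]

logger = logging.getLogger(__name__)

SHAPES = ("HS_U_RICH", "HS_U_LACK", "LS")


def _contig_seq(genome: str | GenomeAnnotation, contig_id: Optional[str]) -> str:
    if isinstance(genome, GenomeAnnotation):
        cid = contig_id or next(iter(genome.sequences))
        return genome.sequences[cid].sequence
    return genome


def upstream_window_seq(
    genome: str | GenomeAnnotation,
    position: int,
    strand: str,
    window: int = 40,
    contig_id: Optional[str] = None,
) -> str:
    """Transcript-sense sequence of the `window` nt ending at (and including)
    the 3'-end position; truncated at contig edges."""
    seq = _contig_seq(genome, contig_id)
    if strand == "+":
        lo = max(0, position - window + 1)
        return seq[lo : position + 1]
    hi = min(len(seq), position + window)
    return revcomp(seq[position : hi])


def fold_teps(
    records: Sequence[TEPRecord],
    genome: str | GenomeAnnotation,
    window: int = 40,
    contig_id: Optional[str] = None,
) -> list[TEPRecord]:
    """Fold the upstream window of every TEP and attach the result."""
    out = []
    for rec in records:
        seq = upstream_window_seq(genome, rec.position, rec.strand, window, contig_id)
        fold = fold_window(seq, expected_length=window)
        if fold.truncated:
            logger.info(
                "TEP %s%d window truncated to %d nt at contig edge",
                rec.strand, rec.position, len(seq),
            )
        out.append(replace(rec, fold=fold))
    return out


def split_hs_ls(
    records: Sequence[TEPRecord],
    threshold: float | str = "median",
) -> tuple[list[TEPRecord], float]:
    """Label TEPs HS (ΔG <= threshold) or LS (ΔG > threshold).

    ``threshold="median"`` uses the median of the record ΔG distribution —
    the definitional choice, since absolute ΔG depends on the energy table;
    a fixed kcal/mol value may be supplied instead.  Returns the labeled
    records and the threshold used.  HS records keep their shape for
    subsequent U-content typing; LS records are final.
    """
    records = list(records)
    if not records:
        raise ValueError("no TEP records to split")
    if any(r.fold is None for r in records):
        raise ValueError("all TEPs must be folded before the HS/LS split")
    dgs = np.array([r.fold.delta_g for r in records])
    thr = float(np.median(dgs)) if threshold == "median" else float(threshold)
    out = [
        replace(r, shape=None if r.fold.delta_g <= thr else "LS") for r in records
    ]
    return out, thr


def type_u_content(
    record: TEPRecord,
    genome: str | GenomeAnnotation,
    window: int = 10,
    min_u: int = 3,
    contig_id: Optional[str] = None,
) -> TEPRecord:
    """Type one HS TEP by the U count just 3' of its terminator stem.

    Counts U/T in the ``window`` nt immediately 3' of the stem's last paired
    base on the transcript strand; >= ``min_u`` gives HS_U_RICH, otherwise
    HS_U_LACK.  LS records pass through unchanged.
    """
    if record.shape == "LS":
        return record
    if record.fold is None or record.fold.hairpin3 is None:
        raise ValueError(
            f"HS TEP at {record.strand}{record.position} has no hairpin: "
            "inconsistent fold"
        )
    seq = _contig_seq(genome, contig_id)
    win_len = len(record.fold.structure)
    # stem_close_pos indexes the folded window (transcript sense, ending at TEP)
    offset_from_3p = win_len - 1 - record.fold.hairpin3.stem_close_pos
    if record.strand == "+":
        start = record.position - offset_from_3p + 1
        downstream = seq[start : start + window]
    else:
        end = record.position + offset_from_3p  # genomic pos of stem close
        downstream = revcomp(seq[max(0, end - window) : end])
    u_count = downstream.count("T") + downstream.count("U")
    label = "HS_U_RICH" if u_count >= min_u else "HS_U_LACK"
    return replace(record, shape=label, u_count=u_count)


def type_all(
    records: Sequence[TEPRecord],
    genome: str | GenomeAnnotation,
    threshold: float | str = "median",
    window: int = 10,
    min_u: int = 3,
    fold_window_nt: int = 40,
    contig_id: Optional[str] = None,
) -> tuple[list[TEPRecord], float]:
    """Fold, split and U-type a full TEP list in one pass."""
    folded = fold_teps(records, genome, window=fold_window_nt, contig_id=contig_id)
    split, thr = split_hs_ls(folded, threshold)
    out = [
        type_u_content(r, genome, window=window, min_u=min_u, contig_id=contig_id)
        if r.shape != "LS"
        else r
        for r in split
    ]
    return out, thr


def shape_counts(records: Sequence[TEPRecord]) -> dict[str, int]:
    counts = {s: 0 for s in SHAPES}
    for r in records:
        if r.shape is not None:
            counts[r.shape] += 1
    total = sum(1 for r in records if r.shape is not None)
    assert sum(counts.values()) == total, "shape partition violated"
    return counts


def positional_enrichment(
    records: Sequence[TEPRecord],
    genome: str | GenomeAnnotation,
    flank: int = 50,
    contig_id: Optional[str] = None,
) -> dict[str, pd.DataFrame]:
    """Per-shape base-frequency matrices at offsets -flank..+flank of the TEP.

    Minus-strand windows are reverse-complemented; empty shape classes are
    skipped with a warning.  Each returned row sums to 1.
    """
    seq = _contig_seq(genome, contig_id)
    out: dict[str, pd.DataFrame] = {}
    for shape in SHAPES:
        members = [r for r in records if r.shape == shape]
        if not members:
            logger.warning("no TEPs in shape class %s; skipped", shape)
            continue
        offsets = range(-flank, flank + 1)
        counts = pd.DataFrame(0.0, index=list(offsets), columns=list("ACGT"))
        used = 0
        for r in members:
            lo, hi = r.position - flank, r.position + flank
            if lo < 0 or hi >= len(seq):
                continue
            window = seq[lo : hi + 1]
            if r.strand == "-":
                window = revcomp(window)
            used += 1
            for off, base in zip(offsets, window):
                if base in "ACGT":
                    counts.loc[off, base] += 1
        if used == 0:
            logger.warning("all %s TEPs at contig edges; skipped", shape)
            continue
        freq = counts.div(counts.sum(axis=1), axis=0)
        freq.index.name = "offset"
        out[shape] = freq
    return out


def readthrough_fraction(
    records: Sequence[TEPRecord],
    coverage_plus: EndCountProfile,
    coverage_minus: EndCountProfile,
    up_window: int = 200,
    down_window: int = 200,
    outlier_pctile: float = 95.0,
) -> tuple[list[TEPRecord], dict]:
    """Readthrough fraction per TEP and per-shape summaries.

    fraction = mean coverage over (TEP, TEP+down] / mean over (TEP-up, TEP],
    oriented along the transcript strand.  Coverage should already be
    normalized across libraries.  TEPs with zero upstream signal are
    excluded (undefined ratio) and counted; per-class summaries drop
    fractions above the ``outlier_pctile`` of the pooled distribution.
    """
    cov = {"+": coverage_plus, "-": coverage_minus}
    out: list[TEPRecord] = []
    n_undefined = 0
    for rec in records:
        profile = cov[rec.strand]
        length = profile.contig_length or (max(profile.counts, default=0) + 1)
        if rec.strand == "+":
            up_range = range(max(0, rec.position - up_window + 1), rec.position + 1)
            down_range = range(rec.position + 1, min(length, rec.position + down_window + 1))
        else:
            up_range = range(rec.position, min(length, rec.position + up_window))
            down_range = range(max(0, rec.position - down_window), rec.position)
        if len(up_range) < up_window or len(down_range) < down_window:
            logger.info("TEP %s%d readthrough windows clipped at contig edge",
                        rec.strand, rec.position)
        if not len(up_range) or not len(down_range):
            n_undefined += 1
            out.append(rec)
            continue
        up_mean = float(np.mean([profile[p] for p in up_range]))
        down_mean = float(np.mean([profile[p] for p in down_range]))
        if up_mean == 0:
            n_undefined += 1
            out.append(rec)
            continue
        out.append(replace(rec, readthrough=down_mean / up_mean))

    defined = [r.readthrough for r in out if r.readthrough is not None]
    summary: dict = {"n_undefined": n_undefined, "per_class": {}}
    if defined:
        cutoff = float(np.percentile(defined, outlier_pctile))
        summary["outlier_cutoff"] = cutoff
        for shape in SHAPES:
            vals = [
                r.readthrough
                for r in out
                if r.shape == shape
                and r.readthrough is not None
                and r.readthrough <= cutoff
            ]
            if vals:
                summary["per_class"][shape] = {
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "mean": float(np.mean(vals)),
                }
    return out, summary


def stem_loop_metrics(records: Sequence[TEPRecord]) -> dict:
    """Stem/loop length distributions per shape class with pairwise
    two-sided Mann-Whitney comparisons (skipped below 3 structured members)."""
    per_class: dict[str, dict[str, list[int]]] = {}
    for shape in SHAPES:
        stems, loops = [], []
        for r in records:
            if r.shape != shape or r.fold is None or r.fold.hairpin3 is None:
                continue
            stems.append(r.fold.hairpin3.stem_length)
            loops.append(r.fold.hairpin3.loop_length)
        per_class[shape] = {"stem": stems, "loop": loops}
    comparisons: dict[str, dict] = {}
    names = list(per_class)
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            for metric in ("stem", "loop"):
                a, b = per_class[x][metric], per_class[y][metric]
                key = f"{x}_vs_{y}_{metric}"
                if len(a) < 3 or len(b) < 3:
                    comparisons[key] = {"skipped": True}
                    continue
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                comparisons[key] = {
                    "U": float(res.statistic),
                    "p": float(res.pvalue),
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                }
    return {"distributions": per_class, "comparisons": comparisons}
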