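"""Normalization, expression summaries and replicate-agreement statistics.

Library size factors use median-of-ratios: each library is compared to the
per-gene geometric mean across libraries and its factor is the median of
those ratios over genes with all-positive counts.  This is the standard
count-normalization estimator for sequencing libraries and is all that the
downstream readthrough/expression analyses need — no dispersion estimation
or differential testing happens here.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import EndCountProfile, GenomeAnnotation

__all__ = [
    "size_factors",
    "rpkm",
    "replicate_correlation",
    "replicate_correlation_genomewide",
    "gene_counts",
]


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per library (column).

    Parameters
    ----------
    matrix : DataFrame
        genes x libraries raw counts, all values >= 0, >= 2 columns.

    Returns
    -------
    Series of positive factors indexed like the columns.  Dividing each
    column by its factor puts libraries on a common scale.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two libraries")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    values = matrix.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every library")
    sub = values[positive]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def rpkm(count: float, gene_length: int, library_size: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / (gene_length / 1_000.0) / (library_size / 1_000_000.0)


def _binned(vec: np.ndarray, bin_size: int) -> np.ndarray:
    n = (len(vec) + bin_size - 1) // bin_size
    out = np.zeros(n)
    np.add.at(out, np.arange(len(vec)) // bin_size, vec)
    return out


def replicate_correlation(
    a: EndCountProfile,
    b: EndCountProfile,
    mode: str = "positions",
    bin_size: int = 100,
    log1p: bool = False,
) -> float:
    """Pearson correlation between two replicate tracks.

    ``mode="positions"`` correlates counts over the union of nonzero
    positions (zeros filled in); ``mode="binned"`` sums counts into
    ``bin_size``-nt bins over the whole contig first.  ``log1p`` applies
    log2(1+x) before correlating.  Raises on mismatched tracks or
    constant vectors (for which r is undefined).
    """
    if (a.contig_id, a.strand) != (b.contig_id, b.strand):
        raise ValueError("profiles must share contig and strand")
    if mode == "positions":
        union = sorted(set(a.counts) | set(b.counts))
        if len(union) < 2:
            raise ValueError("need >= 2 informative positions")
        x = np.array([a[p] for p in union], dtype=float)
        y = np.array([b[p] for p in union], dtype=float)
    elif mode == "binned":
        length = a.contig_length or (max(max(a.counts, default=0), max(b.counts, default=0)) + 1)
        xa = np.zeros(length)
        ya = np.zeros(length)
        for p, c in a.counts.items():
            xa[p] = c
        for p, c in b.counts.items():
            ya[p] = c
        x, y = _binned(xa, bin_size), _binned(ya, bin_size)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if log1p:
        x, y = np.log2(1 + x), np.log2(1 + y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant track")
    return float(stats.pearsonr(x, y).statistic)


def replicate_correlation_genomewide(
    rep_a: tuple[EndCountProfile, EndCountProfile],
    rep_b: tuple[EndCountProfile, EndCountProfile],
    log1p: bool = False,
) -> float:
    """Pearson r between replicates over both strands pooled.

    Takes (plus, minus) profile pairs for each replicate and correlates
    counts over the per-strand unions of nonzero positions concatenated —
    the genome-wide reproducibility figure of a library pair.
    """
    xs: list[float] = []
    ys: list[float] = []
    for a, b in zip(rep_a, rep_b):
        if (a.contig_id, a.strand) != (b.contig_id, b.strand):
            raise ValueError("replicate profiles must align by contig and strand")
        union = sorted(set(a.counts) | set(b.counts))
        xs.extend(a[p] for p in union)
        ys.extend(b[p] for p in union)
    x, y = np.asarray(xs), np.asarray(ys)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined")
    if log1p:
        x, y = np.log2(1 + x), np.log2(1 + y)
    return float(stats.pearsonr(x, y).statistic)


def gene_counts(
    profiles: dict[str, EndCountProfile] | list[tuple[str, EndCountProfile, EndCountProfile]],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Sum per-position counts over gene bodies into a genes x libraries table.

    ``profiles`` maps a library name to a strand pair ``(plus, minus)`` or a
    single profile; counts are taken from the gene's own strand.
    """
    table: dict[str, dict[str, float]] = {}
    items = profiles.items() if isinstance(profiles, dict) else [
        (name, (p, m)) for name, p, m in profiles
    ]
    for name, value in items:
        if isinstance(value, EndCountProfile):
            by_strand = {value.strand: value}
        else:
            by_strand = {v.strand: v for v in value}
        col: dict[str, float] = {}
        for g in annotation.genes:
            prof = by_strand.get(g.strand)
            if prof is None or prof.contig_id != g.contig_id:
                col[g.gene_id] = 0.0
                continue
            col[g.gene_id] = float(
                sum(c for p, c in prof.counts.items() if g.start <= p < g.end)
            )
        table[name] = col
    return pd.DataFrame(table)
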