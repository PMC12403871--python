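"""Synthetic high-GC genome and library simulator with planted ground truth.

The generator emulates the data structure of a bacterial transcriptome-
architecture study: a GC-rich genome carrying non-overlapping transcription
units (single genes and small operons) on both strands, each with a planted
TSS upstream of its first gene and a planted transcript 3' end (TEP)
downstream of its last gene.  TEP contexts come in three shapes:

* ``L`` — intrinsic L-shaped terminator: GC-only stem (8-12 bp), short loop
  (4-8 nt) and a >=4-nt U-tract; the TEP is the last U of the tract.
* ``I`` — I-shaped terminator: same stem-loop but the 10 nt following the
  stem are constrained to <3 Us.
* ``U`` — unstructured context: no planted hairpin, background sequence.

Libraries are sampled per condition x replicate: dRNA-seq 5'-end tracks as
an enriched/unenriched pair (the enriched library carries the full peak,
the unenriched one the peak divided by the TEX enrichment factor), Term-seq
3'-end tracks peaking at TEPs, and piecewise-constant RNA-seq coverage that
drops to a shape-dependent readthrough fraction downstream of each TEP.
Counts are Poisson around their means; everything is deterministic under a
fixed seed.

Shape classes and condition specificity are allocated by exact largest-
remainder proportions rather than per-TU coin flips, so the realized
composition of a simulated genome always matches the configured mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    EndCountProfile,
    GeneFeature,
    GenomeAnnotation,
    GenomeSequence,
    LibraryMeta,
    revcomp,
    write_endcounts_bedgraph,
    write_fasta,
    write_gff3,
)

__all__ = [
    "SimulationConfig",
    "PlantedSite",
    "PlantedTU",
    "TruthTable",
    "simulate_genome",
    "simulate_libraries",
    "simulate_study",
    "evaluate_recovery",
]

_COG_LETTERS = "CDEFGHIJKLMNOPQTUV"


class ConfigError(ValueError):
    """Simulation parameters that cannot produce a valid genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator (defaults are the reference setup)."""

    genome_length: int = 100_000
    gc_fraction: float = 0.65
    n_genes: int = 60
    conditions: tuple[str, ...] = ("NMS", "ANMS")
    constitutive_fraction: float = 0.75
    shape_mix: tuple[float, float, float] = (0.15, 0.35, 0.50)  # L, I, U
    tex_enrichment: float = 8.0
    background_rate: float = 0.2  # mean end counts per nt
    peak_height: float = 200.0  # mean end counts at a planted site
    readthrough_L: float = 0.05
    readthrough_I: float = 0.10
    readthrough_LS: float = 0.50
    n_replicates: int = 2
    seed: int = 1
    tss_purine_bias: float = 0.9
    operon_fraction: float = 0.4  # fraction of TUs with >=2 genes
    overdispersion: float = 0.0  # 0 => Poisson; >0 => negative binomial
    mean_expression: float = 50.0  # mean RNA-seq coverage within a TU
    # reproducible site-to-site peak-strength spread (lognormal sigma);
    # shared across conditions and replicates, as real site strengths are
    peak_height_sigma: float = 1.0
    leaderless_fraction: float = 0.05  # TUs with a <10-nt 5' UTR
    utr5_median: float = 63.0
    utr3_median: float = 85.0

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ConfigError("genome_length must be >= 10 kb")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ConfigError("gc_fraction must be in (0, 1)")
        for name in (
            "constitutive_fraction",
            "readthrough_L",
            "readthrough_I",
            "readthrough_LS",
            "tss_purine_bias",
            "operon_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if abs(sum(self.shape_mix) - 1.0) > 1e-9:
            raise ConfigError("shape_mix must sum to 1")
        if self.background_rate < 0 or self.peak_height < 0:
            raise ConfigError("rates must be >= 0")
        if self.tex_enrichment < 1:
            raise ConfigError("tex_enrichment must be >= 1")
        if self.n_replicates < 1 or self.n_genes < 1:
            raise ConfigError("n_replicates and n_genes must be >= 1")


@dataclass(frozen=True)
class PlantedSite:
    position: int
    strand: str
    conditions: tuple[str, ...]
    tu_id: str
    shape: Optional[str] = None  # TEPs: L | I | U
    stem_close_pos: Optional[int] = None  # genomic pos of planted stem 3' base


@dataclass(frozen=True)
class PlantedTU:
    tu_id: str
    strand: str
    tss: int
    tep: int
    gene_ids: tuple[str, ...]
    shape: str
    conditions: tuple[str, ...]
    readthrough: float
    cog_category: Optional[str]


@dataclass
class TruthTable:
    tss: list[PlantedSite]
    tep: list[PlantedSite]
    tus: list[PlantedTU]

    def sites(self, kind: str) -> list[PlantedSite]:
        return self.tss if kind == "tss" else self.tep


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of n items matching fractions as closely as possible."""
    raw = [n * f for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _terminator_sequence(rng: np.random.Generator, shape: str, gc: float
                         ) -> tuple[str, int, int]:
    """Transcript-sense terminator cassette for an L- or I-shaped TEP.

    Returns (sequence, stem_close_offset, tep_offset): offsets are 0-based
    indices into the returned sequence of the 3'-most paired stem base and
    of the transcript 3' end.
    """
    stem = rng.integers(8, 13)
    loop = rng.integers(4, 9)
    stem_seq = "".join(rng.choice(["G", "C"], size=stem))
    loop_seq = "".join(rng.choice(["A", "T"], size=loop))  # kept pair-poor
    # the C spacer insulates the hairpin: C cannot pair the U-tract, so the
    # planted stem cannot stack-extend into the tail when the genomic flank
    # happens to be A/G-rich (which would bury the U-tract inside the stem)
    spacer = "CCC"
    hairpin = spacer + stem_seq + loop_seq + revcomp(stem_seq)
    stem_close = len(hairpin) - 1
    if shape == "L":
        tail_len = int(rng.integers(4, 9))
        tail = "T" * tail_len
        # pad the U-count window neutrally; no G, so the spacer stays inert
        pad = "".join(rng.choice(["A", "C"], size=max(0, 10 - tail_len)))
        seq = hairpin + tail + pad
        tep = stem_close + tail_len
    elif shape == "I":
        # 10 nt after the stem with <3 Us, enforced by construction (<=2 Ts);
        # the first tail base is A so it cannot pair the spacer either
        n_t = int(rng.integers(0, 3))
        tail = list(rng.choice(["A", "C", "G"], size=10))
        for idx in rng.choice(9, size=n_t, replace=False):
            tail[idx + 1] = "T"
        tail[0] = "A"
        seq = hairpin + "".join(tail)
        tep = stem_close + 5
    else:
        raise ValueError(shape)
    return seq, stem_close, tep


@dataclass
class _TULayout:
    strand: str
    utr5: int
    gene_spans: list[tuple[int, int]]  # transcript coordinates
    utr3: int
    term_seq: Optional[str]
    term_offset: Optional[int]  # transcript coord of terminator start
    stem_close_t: Optional[int]
    tep_t: int  # transcript coord of the 3' end

    @property
    def transcript_length(self) -> int:
        return self.tep_t + 1


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthTable]:
    """Build the genome, annotation and planted-site truth table.

    Deterministic in ``config.seed``.  Raises :class:`ConfigError` when the
    requested genes cannot be placed without overlap.
    """
    rng = np.random.default_rng([config.seed, 0])
    genome = _random_dna(rng, config.genome_length, config.gc_fraction)

    # ---- lay out TUs in transcript frame -------------------------------
    layouts: list[_TULayout] = []
    genes_left = config.n_genes
    while genes_left > 0:
        if rng.random() < config.operon_fraction and genes_left >= 2:
            size = int(min(rng.integers(2, 5), genes_left))
        else:
            size = 1
        genes_left -= size
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < config.leaderless_fraction:
            utr5 = int(rng.integers(0, 10))
        else:
            utr5 = int(
                np.clip(rng.lognormal(math.log(config.utr5_median), 0.6), 10, 295)
            )
        spans = []
        t = utr5
        for k in range(size):
            glen = int(rng.integers(400, 901))
            spans.append((t, t + glen))
            t += glen + (int(rng.integers(20, 51)) if k + 1 < size else 0)
        utr3 = int(np.clip(rng.lognormal(math.log(config.utr3_median), 0.6), 10, 280))
        layouts.append(
            _TULayout(
                strand=strand,
                utr5=utr5,
                gene_spans=spans,
                utr3=utr3,
                term_seq=None,
                term_offset=None,
                stem_close_t=None,
                tep_t=t + utr3,
            )
        )

    n_tus = len(layouts)
    # exact shape allocation, shuffled over TUs
    shape_counts = _largest_remainder(n_tus, config.shape_mix)
    shapes = ["L"] * shape_counts[0] + ["I"] * shape_counts[1] + ["U"] * shape_counts[2]
    shapes = [shapes[i] for i in rng.permutation(n_tus)]
    # exact condition allocation: constitutive, then specific split evenly
    n_const = _largest_remainder(
        n_tus, [config.constitutive_fraction, 1 - config.constitutive_fraction]
    )[0]
    spec_counts = _largest_remainder(
        n_tus - n_const, [1 / len(config.conditions)] * len(config.conditions)
    )
    cond_sets: list[tuple[str, ...]] = [tuple(config.conditions)] * n_const
    for cond, k in zip(config.conditions, spec_counts):
        cond_sets.extend([(cond,)] * k)
    order = rng.permutation(n_tus)
    cond_sets = [cond_sets[i] for i in order]

    # attach terminator cassettes; the cassette ends define the TEP offset
    for layout, shape in zip(layouts, shapes):
        if shape in ("L", "I"):
            seq, stem_close, tep_off = _terminator_sequence(rng, shape, config.gc_fraction)
            gene_end = layout.gene_spans[-1][1]
            # TEP sits utr3 nt past the gene end; a cassette longer than the
            # UTR reaches back over the gene's final codons, as real
            # terminator hairpins may
            term_start = gene_end + layout.utr3 - tep_off
            layout.term_seq = seq
            layout.term_offset = term_start
            layout.stem_close_t = term_start + stem_close
            layout.tep_t = term_start + tep_off

    # ---- place TU blocks on the genome ---------------------------------
    edge_margin = 60
    post_margin = 350  # room for the readthrough tail and separation
    cursor = edge_margin
    placements: list[tuple[_TULayout, int]] = []  # (layout, tss genomic pos)
    for layout in layouts:
        need = edge_margin + layout.transcript_length + post_margin
        if cursor + need > config.genome_length - edge_margin:
            raise ConfigError(
                f"genome_length={config.genome_length} too short to place "
                f"{config.n_genes} genes without overlap"
            )
        if layout.strand == "+":
            tss = cursor + edge_margin
        else:
            tss = cursor + need - post_margin - 1
        placements.append((layout, tss))
        cursor += need

    def t2g(tss: int, strand: str, t: int) -> int:
        return tss + t if strand == "+" else tss - t

    def write_transcript(tss: int, strand: str, t0: int, seq: str) -> None:
        if strand == "+":
            genome[tss + t0 : tss + t0 + len(seq)] = np.frombuffer(
                seq.encode(), dtype="S1"
            )
        else:
            rc = revcomp(seq)
            lo = tss - (t0 + len(seq)) + 1
            genome[lo : lo + len(seq)] = np.frombuffer(rc.encode(), dtype="S1")

    genes: list[GeneFeature] = []
    tss_sites: list[PlantedSite] = []
    tep_sites: list[PlantedSite] = []
    tus: list[PlantedTU] = []
    rt_by_shape = {
        "L": config.readthrough_L,
        "I": config.readthrough_I,
        "U": config.readthrough_LS,
    }
    gene_counter = 0
    for idx, ((layout, tss), shape, conds) in enumerate(
        zip(placements, shapes, cond_sets)
    ):
        tu_id = f"TU{idx + 1:04d}"
        strand = layout.strand
        # initiating nucleotide: purine with configured bias
        if rng.random() < config.tss_purine_bias:
            plus1 = "A" if rng.random() < 0.5 else "G"
        else:
            plus1 = "C" if rng.random() < 0.5 else "T"
        write_transcript(tss, strand, 0, plus1)
        if layout.term_seq is not None:
            write_transcript(tss, strand, layout.term_offset, layout.term_seq)
        # shared COG for operons, random for singletons, some unannotated
        if len(layout.gene_spans) >= 2:
            cog: Optional[str] = str(rng.choice(list(_COG_LETTERS)))
        else:
            cog = (
                str(rng.choice(list(_COG_LETTERS)))
                if rng.random() < 0.85
                else None
            )
        gene_ids = []
        for a, b in layout.gene_spans:
            gene_counter += 1
            gid = f"gene{gene_counter:04d}"
            gene_ids.append(gid)
            ga, gb = t2g(tss, strand, a), t2g(tss, strand, b - 1)
            lo, hi = (ga, gb) if strand == "+" else (gb, ga)
            genes.append(
                GeneFeature(
                    gene_id=gid,
                    contig_id="chr",
                    start=lo,
                    end=hi + 1,
                    strand=strand,
                    cog_category=cog,
                )
            )
        tep_g = t2g(tss, strand, layout.tep_t)
        stem_g = (
            t2g(tss, strand, layout.stem_close_t)
            if layout.stem_close_t is not None
            else None
        )
        tss_sites.append(PlantedSite(tss, strand, conds, tu_id))
        tep_sites.append(
            PlantedSite(tep_g, strand, conds, tu_id, shape=shape, stem_close_pos=stem_g)
        )
        tus.append(
            PlantedTU(
                tu_id=tu_id,
                strand=strand,
                tss=tss,
                tep=tep_g,
                gene_ids=tuple(gene_ids),
                shape=shape,
                conditions=conds,
                readthrough=rt_by_shape[shape],
                cog_category=cog,
            )
        )

    sequence = GenomeSequence("chr", genome.tobytes().decode())
    annotation = GenomeAnnotation(sequences={"chr": sequence}, genes=genes)
    truth = TruthTable(tss=tss_sites, tep=tep_sites, tus=tus)
    return annotation, truth


# ---------------------------------------------------------------------------
# library simulation


def _noise(rng: np.random.Generator, mean, size=None, overdispersion: float = 0.0):
    """Poisson counts, or negative binomial when overdispersion > 0."""
    mean = np.asarray(mean, dtype=float)
    if overdispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / overdispersion
    p = r / (r + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(r, p, size=size if size is not None else mean.shape)
    return np.where(mean <= 0, 0, out)


def _to_profile(arr: np.ndarray, strand: str, meta: LibraryMeta, length: int
                ) -> EndCountProfile:
    nz = np.nonzero(arr)[0]
    counts = {int(p): float(arr[p]) for p in nz}
    return EndCountProfile(
        contig_id="chr", strand=strand, counts=counts, meta=meta, contig_length=length
    )


def simulate_libraries(
    annotation: GenomeAnnotation,
    truth: TruthTable,
    config: SimulationConfig,
) -> dict[tuple, EndCountProfile]:
    """Sample all end-count and coverage tracks.

    Returns a dict keyed by ``(assay, condition, replicate, enriched, strand)``
    with assay in {"dRNA", "Term", "RNAseq-coverage"} (enriched is None for
    non-dRNA assays).
    """
    rng = np.random.default_rng([config.seed, 1])
    L = annotation.contig_length("chr")
    bg, peak, tex = config.background_rate, config.peak_height, config.tex_enrichment
    ov = config.overdispersion

    # per-TU expression level and per-site peak strengths, drawn once and
    # shared across conditions/replicates (reproducible biology, not noise)
    levels = {
        tu.tu_id: float(
            rng.lognormal(math.log(config.mean_expression), 0.5)
        )
        for tu in truth.tus
    }
    sigma = config.peak_height_sigma
    tss_strength = {
        (s.strand, s.position): float(rng.lognormal(0.0, sigma)) for s in truth.tss
    }
    tep_strength = {
        (s.strand, s.position): float(rng.lognormal(0.0, sigma)) for s in truth.tep
    }

    out: dict[tuple, EndCountProfile] = {}
    for condition in config.conditions:
        tss_here = [s for s in truth.tss if condition in s.conditions]
        tep_here = [s for s in truth.tep if condition in s.conditions]
        tus_here = [t for t in truth.tus if condition in t.conditions]
        for rep in range(1, config.n_replicates + 1):
            for strand in "+-":
                strand_tss = [s.position for s in tss_here if s.strand == strand]
                strand_tep = [s.position for s in tep_here if s.strand == strand]

                enr = _noise(rng, np.full(L, bg), overdispersion=ov).astype(float)
                une = _noise(rng, np.full(L, bg), overdispersion=ov).astype(float)
                if strand_tss:
                    pos = np.array(strand_tss)
                    means = peak * np.array(
                        [tss_strength[(strand, p)] for p in strand_tss]
                    )
                    enr[pos] += _noise(rng, means, overdispersion=ov)
                    une[pos] += _noise(rng, means / tex, overdispersion=ov)
                term = _noise(rng, np.full(L, bg), overdispersion=ov).astype(float)
                if strand_tep:
                    pos = np.array(strand_tep)
                    means = peak * np.array(
                        [tep_strength[(strand, p)] for p in strand_tep]
                    )
                    term[pos] += _noise(rng, means, overdispersion=ov)

                mean_cov = np.full(L, bg, dtype=float)
                for tu in tus_here:
                    if tu.strand != strand:
                        continue
                    lam = levels[tu.tu_id]
                    lo, hi = sorted((tu.tss, tu.tep))
                    mean_cov[lo : hi + 1] += lam
                    if tu.strand == "+":
                        tail = slice(tu.tep + 1, min(L, tu.tep + 301))
                    else:
                        tail = slice(max(0, tu.tep - 300), tu.tep)
                    mean_cov[tail] += lam * tu.readthrough
                cov = _noise(rng, mean_cov, overdispersion=ov).astype(float)

                meta_e = LibraryMeta("dRNA", condition, rep, enriched=True)
                meta_u = LibraryMeta("dRNA", condition, rep, enriched=False)
                meta_t = LibraryMeta("Term", condition, rep)
                meta_c = LibraryMeta("RNAseq-coverage", condition, rep)
                out[("dRNA", condition, rep, True, strand)] = _to_profile(
                    enr, strand, meta_e, L
                )
                out[("dRNA", condition, rep, False, strand)] = _to_profile(
                    une, strand, meta_u, L
                )
                out[("Term", condition, rep, None, strand)] = _to_profile(
                    term, strand, meta_t, L
                )
                out[("RNAseq-coverage", condition, rep, None, strand)] = _to_profile(
                    cov, strand, meta_c, L
                )
    return out


def simulate_study(config: SimulationConfig):
    """One-call convenience: genome + truth + all library tracks."""
    annotation, truth = simulate_genome(config)
    libraries = simulate_libraries(annotation, truth, config)
    return annotation, truth, libraries


# ---------------------------------------------------------------------------
# recovery evaluation against the truth table


def evaluate_recovery(
    called: Sequence,
    planted: Sequence[PlantedSite],
    tolerance: int = 5,
    conditions: Optional[set[str]] = None,
) -> dict[str, float]:
    """Sensitivity/precision of called sites vs planted truth at ±tolerance nt.

    ``called`` items need ``position`` and ``strand`` attributes.  When
    ``conditions`` is given, only planted sites active in at least one of
    those conditions count as positives.
    """
    if conditions is not None:
        planted = [p for p in planted if set(p.conditions) & conditions]
    truth_by_strand: dict[str, np.ndarray] = {}
    for strand in "+-":
        truth_by_strand[strand] = np.array(
            sorted(p.position for p in planted if p.strand == strand)
        )
    n_hit = 0
    n_called_ok = 0
    for strand in "+-":
        tpos = truth_by_strand[strand]
        cpos = np.array(sorted(c.position for c in called if c.strand == strand))
        if len(tpos) and len(cpos):
            idx = np.searchsorted(cpos, tpos)
            for t, i in zip(tpos, idx):
                near = [cpos[k] for k in (i - 1, i) if 0 <= k < len(cpos)]
                if near and min(abs(t - c) for c in near) <= tolerance:
                    n_hit += 1
            idx = np.searchsorted(tpos, cpos)
            for c, i in zip(cpos, idx):
                near = [tpos[k] for k in (i - 1, i) if 0 <= k < len(tpos)]
                if near and min(abs(c - t) for t in near) <= tolerance:
                    n_called_ok += 1
    n_truth = sum(len(v) for v in truth_by_strand.values())
    n_called = len(called)
    return {
        "sensitivity": n_hit / n_truth if n_truth else float("nan"),
        "precision": n_called_ok / n_called if n_called else float("nan"),
        "n_planted": float(n_truth),
        "n_called": float(n_called),
    }


def write_study(outdir, annotation: GenomeAnnotation, truth: TruthTable,
                libraries: dict[tuple, EndCountProfile]) -> None:
    """Emit FASTA, GFF3, bedGraph pairs and truth TSVs to a directory."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(annotation.sequences, outdir / "genome.fasta")
    write_gff3(annotation, outdir / "annotation.gff3")
    for key, profile in libraries.items():
        assay, condition, rep, enriched, strand = key
        tag = {"dRNA": "drna", "Term": "term", "RNAseq-coverage": "rnaseq"}[assay]
        if assay == "dRNA":
            tag += "_enriched" if enriched else "_unenriched"
        sname = "plus" if strand == "+" else "minus"
        write_endcounts_bedgraph(
            profile, outdir / f"{tag}_{condition}_rep{rep}_{sname}.bedgraph"
        )
    pd.DataFrame(
        [
            {
                "position": s.position + 1,
                "strand": s.strand,
                "conditions": ",".join(s.conditions),
                "tu_id": s.tu_id,
            }
            for s in truth.tss
        ]
    ).to_csv(outdir / "truth_tss.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "position": s.position + 1,
                "strand": s.strand,
                "shape": s.shape,
                "conditions": ",".join(s.conditions),
                "tu_id": s.tu_id,
            }
            for s in truth.tep
        ]
    ).to_csv(outdir / "truth_tep.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "tu_id": t.tu_id,
                "strand": t.strand,
                "tss": t.tss + 1,
                "tep": t.tep + 1,
                "genes": ",".join(t.gene_ids),
                "shape": t.shape,
                "conditions": ",".join(t.conditions),
            }
            for t in truth.tus
        ]
    ).to_csv(outdir / "truth_tu.tsv", sep="\t", index=False)
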