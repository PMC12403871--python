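"""Readers/writers for the external formats the pipeline consumes and emits.

All coordinates are kept internally as 0-based half-open intervals on the
forward strand; minus-strand features carry a strand flag but use forward
coordinates.  Conversions to the 1-based conventions of GFF3 and site
tables happen only at the I/O boundary.  End-count tracks are exchanged as
strand-split bedGraph files (0-based half-open, one numeric value per
interval), one file per strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "GenomeSequence",
    "GeneFeature",
    "GenomeAnnotation",
    "LibraryMeta",
    "EndCountProfile",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_endcounts_bedgraph",
    "write_endcounts_bedgraph",
    "write_feature_table",
    "read_feature_table",
    "revcomp",
]


class FormatError(ValueError):
    """A malformed or internally inconsistent input file."""


_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_DNA = re.compile(r"^[ACGTN]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: an id and its DNA sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.contig_id!r} has empty sequence")
        if not _VALID_DNA.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(
                f"contig {self.contig_id!r} contains illegal characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An oriented gene on a contig, 0-based half-open [start, end)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cog_category: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Position of the first transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        """Position of the last transcribed base (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """Genome sequences plus genes sorted by (contig, start)."""

    sequences: dict[str, GenomeSequence]
    genes: list[GeneFeature]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig_id not in self.sequences:
                raise FormatError(f"gene {g.gene_id}: unknown contig {g.contig_id!r}")
            if g.end > len(self.sequences[g.contig_id]):
                raise FormatError(
                    f"gene {g.gene_id}: interval exceeds contig length"
                )
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))

    def contig_length(self, contig_id: str) -> int:
        return len(self.sequences[contig_id])

    def genes_on(self, contig_id: str, strand: Optional[str] = None) -> list[GeneFeature]:
        return [
            g
            for g in self.genes
            if g.contig_id == contig_id and (strand is None or g.strand == strand)
        ]


@dataclass(frozen=True)
class LibraryMeta:
    """Provenance of one end-count/coverage track."""

    assay: str  # "dRNA" | "Term" | "RNAseq-coverage"
    condition: str
    replicate: int
    enriched: Optional[bool] = None  # dRNA only: TEX-treated vs untreated


@dataclass
class EndCountProfile:
    """Per-position read-end counts (or coverage) for one strand of one library."""

    contig_id: str
    strand: str
    counts: dict[int, float]
    meta: Optional[LibraryMeta] = None
    contig_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError("strand must be + or -")
        for pos, c in self.counts.items():
            if c < 0:
                raise FormatError(f"negative count {c} at position {pos}")
            if pos < 0 or (self.contig_length is not None and pos >= self.contig_length):
                raise FormatError(f"position {pos} outside contig bounds")

    def total(self) -> float:
        return float(sum(self.counts.values()))

    def __getitem__(self, pos: int) -> float:
        return self.counts.get(pos, 0.0)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, GenomeSequence]:
    """Read a FASTA file into {contig_id: GenomeSequence}.

    Sequences are upper-cased and U is converted to T.  Duplicate ids,
    empty records and non-nucleotide characters raise :class:`FormatError`.
    """
    path = Path(path)
    records: dict[str, GenomeSequence] = {}
    current_id: Optional[str] = None
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper().replace("U", "T")
        if current_id in records:
            raise FormatError(f"duplicate contig id {current_id!r}")
        records[current_id] = GenomeSequence(current_id, seq)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_id = line[1:].split()[0]
                chunks = []
            else:
                if current_id is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
    _flush()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Mapping[str, GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid in sequences:
            seq = sequences[cid].sequence
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_COG_ATTR = re.compile(r"(?:^|;)\s*cog=([A-Z])\s*(?:;|$)", re.IGNORECASE)
_ID_ATTR = re.compile(r"(?:^|;)\s*(?:ID|locus_tag|gene_id)=([^;]+)", re.IGNORECASE)


def read_gff3(path, sequences: Mapping[str, GenomeSequence],
              feature_types: Sequence[str] = ("gene",)) -> GenomeAnnotation:
    """Read gene features from a GFF3 file (1-based inclusive → 0-based half-open).

    An optional ``cog=X`` attribute becomes the gene's COG category.  Strand
    "." is rejected for genes; coordinates are validated against *sequences*.
    """
    genes: list[GeneFeature] = []
    seen: set[str] = set()
    with open(Path(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 tab-separated fields")
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{ln}: end < start")
            if contig not in sequences:
                raise FormatError(f"{path}:{ln}: unknown contig {contig!r}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: gene strand must be + or -")
            m = _ID_ATTR.search(attrs)
            gene_id = m.group(1).strip() if m else f"feature_{ln}"
            if gene_id in seen:
                raise FormatError(f"{path}:{ln}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            mcog = _COG_ATTR.search(attrs)
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    cog_category=mcog.group(1).upper() if mcog else None,
                )
            )
    return GenomeAnnotation(sequences=dict(sequences), genes=genes)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, seq in annotation.sequences.items():
            fh.write(f"##sequence-region {cid} 1 {len(seq)}\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id}"
            if g.cog_category:
                attrs += f";cog={g.cog_category}"
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "tul",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph end-count tracks


def _read_one_bedgraph(path, strand: str, meta: Optional[LibraryMeta],
                       contig_length: Optional[int]) -> EndCountProfile:
    counts: dict[int, float] = {}
    contig_id: Optional[str] = None
    last_end_by_contig: dict[str, int] = {}
    intervals: list[tuple[int, int]] = []
    with open(Path(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 whitespace-separated fields")
            contig, start_s, end_s, value_s = parts
            if contig_id is None:
                contig_id = contig
            elif contig != contig_id:
                raise FormatError(f"{path}:{ln}: multiple contigs in one track file")
            start, end = int(start_s), int(end_s)
            value = float(value_s)
            if end <= start:
                raise FormatError(f"{path}:{ln}: empty or inverted interval")
            if value < 0:
                raise FormatError(f"{path}:{ln}: negative value {value}")
            intervals.append((start, end))
            if value == 0:
                continue
            for pos in range(start, end):
                if pos in counts:
                    raise FormatError(f"{path}:{ln}: overlapping intervals at {pos}")
                counts[pos] = value
    # overlap check also for zero-valued intervals
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise FormatError(f"{path}: overlapping intervals [{s1},{e1}) and [{s2},{e2})")
    if contig_id is None:
        raise FormatError(f"{path}: empty bedGraph")
    return EndCountProfile(
        contig_id=contig_id,
        strand=strand,
        counts=counts,
        meta=meta,
        contig_length=contig_length,
    )


def read_endcounts_bedgraph(
    path_plus,
    path_minus,
    meta: Optional[LibraryMeta] = None,
    contig_length: Optional[int] = None,
) -> tuple[EndCountProfile, EndCountProfile]:
    """Read a strand pair of bedGraph files into two sparse profiles."""
    plus = _read_one_bedgraph(path_plus, "+", meta, contig_length)
    minus = _read_one_bedgraph(path_minus, "-", meta, contig_length)
    if plus.contig_id != minus.contig_id:
        raise FormatError("strand files describe different contigs")
    return plus, minus


def write_endcounts_bedgraph(profile: EndCountProfile, path) -> None:
    """Write one strand's sparse counts as a bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        positions = sorted(profile.counts)
        i = 0
        while i < len(positions):
            j = i
            while (
                j + 1 < len(positions)
                and positions[j + 1] == positions[j] + 1
                and profile.counts[positions[j + 1]] == profile.counts[positions[i]]
            ):
                j += 1
            value = float(profile.counts[positions[i]])
            text = str(int(value)) if value.is_integer() else repr(value)
            fh.write(
                f"{profile.contig_id}\t{positions[i]}\t{positions[j] + 1}\t{text}\n"
            )
            i = j + 1


# ---------------------------------------------------------------------------
# Feature tables (TSS/TEP/TU records) — TSV, 1-based positions


def write_feature_table(records: Iterable, path) -> None:
    """Write site/TU records to TSV with 1-based positions.

    Records are dataclasses exposing ``to_row()`` → dict; the first column
    holding an internal 0-based position is shifted to 1-based on output.
    Column order is the row dict order of the first record.
    """
    rows = [r.to_row() for r in records]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["position", "strand"])
    for col in df.columns:
        if col in ("position", "tss_position", "tep_position"):
            df[col] = df[col].astype(int) + 1
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a written feature table back; positions return to 0-based."""
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col in ("position", "tss_position", "tep_position"):
            df[col] = df[col].astype(int) - 1
    return df
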