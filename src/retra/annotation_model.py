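"""Domain types for genomic annotation plus GTF/FASTA/BED readers and writers.

Coordinate convention: every interval in this package is 0-based half-open
``[start, end)``.  GTF records (1-based, end-inclusive) are converted at the
I/O boundary; BED records pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid models."""


class Source(str, Enum):
    ASSEMBLY = "assembly"
    ENSEMBL = "ensembl"
    REFSEQ = "refseq"
    NOVEL = "novel"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start: {self}")
        if self.end <= self.start:
            raise AnnotationError(f"end must exceed start: {self}")
        if self.strand not in STRANDS:
            raise AnnotationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (ignores strand)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron intervals of a multi-exon transcript.

    Two transcripts with an identical chain (same chrom, strand and intron
    coordinates) are treated as the same isoform.
    """

    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.introns)

    def __len__(self) -> int:
        return len(self.introns)

    def intron_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.introns)


@dataclass
class TranscriptModel:
    """A stranded exon-structured transcript.

    ``fpkm`` maps sample id -> abundance; an absent sample means *unknown*,
    not zero (threshold rules fail closed on unknown).
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    fpkm: dict[str, float] = field(default_factory=dict)
    source: Source = Source.ASSEMBLY
    cds: list[tuple[GenomicInterval, int]] | None = None  # (segment, phase)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1:
            raise AnnotationError(f"{self.transcript_id}: exons span several chromosomes {chroms}")
        if len(strands) > 1:
            raise AnnotationError(f"{self.transcript_id}: exons on mixed strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons {a} / {b}")
        for v in self.fpkm.values():
            if v < 0:
                raise AnnotationError(f"{self.transcript_id}: negative FPKM")
        if self.cds:
            for seg, _phase in self.cds:
                if not any(e.start <= seg.start and seg.end <= e.end for e in self.exons):
                    raise AnnotationError(
                        f"{self.transcript_id}: CDS segment {seg} outside exons"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_monoexon(self) -> bool:
        return len(self.exons) == 1

    @property
    def tss(self) -> int:
        """5'-most genomic base in transcript orientation."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def tts(self) -> int:
        """3'-most genomic base in transcript orientation."""
        return self.end - 1 if self.strand != "-" else self.start


def intron_chain(t: TranscriptModel) -> IntronChain:
    """Gaps between consecutive exons; empty for a mono-exon transcript."""
    introns = tuple(
        (a.end, b.start) for a, b in zip(t.exons, t.exons[1:])
    )
    return IntronChain(t.chrom, t.strand, introns)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: empty gene")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(f"{self.gene_id}: members on mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )


@dataclass
class Annotation:
    """A collection of gene models with unique gene and transcript ids."""

    genes: list[GeneModel] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        gids = [g.gene_id for g in self.genes]
        if len(gids) != len(set(gids)):
            raise AnnotationError("duplicate gene ids")
        tids = [t.transcript_id for t in self.transcripts()]
        if len(tids) != len(set(tids)):
            raise AnnotationError("duplicate transcript ids")

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self.genes:
            yield from g.transcripts

    def transcript_map(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts()}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise AnnotationError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path, sample: str | None = None, provenance: str = "") -> Annotation:
    """Read a GTF file (exon and optional CDS features) into an Annotation.

    FPKM attributes, when present, are stored under ``sample`` (defaults to
    the string ``"default"``).  1-based inclusive coordinates are converted
    to 0-based half-open.
    """
    sample = sample if sample is not None else "default"
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[tuple[GenomicInterval, int]]] = {}
    tx_gene: dict[str, str] = {}
    tx_fpkm: dict[str, float] = {}
    tx_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start_s, end_s, _score, strand, frame, attr_text = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: bad coordinates") from exc
            if end1 < start1:
                raise AnnotationError(f"line {lineno}: end < start")
            attrs = _parse_attributes(attr_text, lineno)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise AnnotationError(f"line {lineno}: missing gene_id/transcript_id")
            tid = attrs["transcript_id"]
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if tid not in tx_gene:
                tx_gene[tid] = attrs["gene_id"]
                tx_order.append(tid)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
                if "FPKM" in attrs:
                    tx_fpkm[tid] = float(attrs["FPKM"])
            else:
                phase = int(frame) if frame in ("0", "1", "2") else 0
                cds.setdefault(tid, []).append((iv, phase))

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in tx_order:
        if tid not in exons:
            continue
        gid = tx_gene[tid]
        fpkm = {sample: tx_fpkm[tid]} if tid in tx_fpkm else {}
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            exons=exons[tid],
            fpkm=fpkm,
            cds=sorted(cds[tid], key=lambda sp: sp[0].start) if tid in cds else None,
        )
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(t)
    return Annotation(
        genes=[GeneModel(gid, genes[gid]) for gid in gene_order],
        provenance=provenance,
    )


def write_gtf(annotation: Annotation, path) -> None:
    """Write the canonical dialect: one line per exon/CDS, sorted by
    (chrom, start), deterministic byte output."""
    records: list[tuple[str, int, str]] = []
    for g in annotation.genes:
        for t in g.transcripts:
            attr = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if len(t.fpkm) == 1:
                (value,) = t.fpkm.values()
                attr += f' FPKM "{value:g}";'
            for e in t.exons:
                line = (
                    f"{e.chrom}\tretra\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attr}"
                )
                records.append((e.chrom, e.start, line))
            for seg, phase in t.cds or []:
                line = (
                    f"{seg.chrom}\tretra\tCDS\t{seg.start + 1}\t{seg.end}\t.\t"
                    f"{seg.strand}\t{phase}\t{attr}"
                )
                records.append((seg.chrom, seg.start, line))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for _, _, line in records:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# FASTA / BED
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Sequence store, names -> upper-cased sequences."""
    store: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in store:
            raise AnnotationError(f"duplicate sequence name {rec.id!r}")
        store[rec.id] = str(rec.seq).upper()
    return store


def write_fasta(store: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in store.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = "."
    score: float | None = None


def read_bed(path) -> list[BedRecord]:
    """BED3+ reader; intervals are 0-based half-open as written."""
    out: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise AnnotationError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise AnnotationError(f"line {lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = fields[5] if len(fields) > 5 else "."
            out.append(BedRecord(GenomicInterval(chrom, start, end, strand), name, score))
    return out


def write_bed(records: Iterable[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t{score}\t{iv.strand}\n")


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals on one sequence, sorted and disjoint."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]
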