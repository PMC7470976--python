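"""Transcript-level comparison between annotations.

Match classes (precedence exact > contained > novel_isoform > other):

* exact — identical intron chain; for mono-exon queries, interval contained
  in an exon-overlapping reference transcript on the same strand;
* contained — the query chain is a contiguous sub-chain of a reference chain;
* novel_isoform — shares >= 1 intron with an exon-overlapping reference
  transcript;
* other — anything else (intergenic, antisense, ...).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .annotation_model import Annotation, TranscriptModel, intron_chain, merge_intervals


class MatchClass(str, Enum):
    EXACT = "="
    CONTAINED = "c"
    NOVEL_ISOFORM = "j"
    OTHER = "u"


@dataclass
class AnnotationSummary:
    n_genes: int
    n_transcripts: int
    transcribed_bases: int
    transcribed_ratio: float
    n_exons: int
    exon_bases: int
    exon_ratio: float


def _is_subchain(query: tuple, reference: tuple) -> bool:
    """True iff query introns appear as a contiguous run inside reference."""
    nq, nr = len(query), len(reference)
    if nq > nr:
        return False
    return any(reference[i : i + nq] == query for i in range(nr - nq + 1))


class _RefIndex:
    """Reference transcripts bucketed by (chrom, strand)."""

    def __init__(self, reference: Annotation):
        self.by_cs: dict[tuple[str, str], list[TranscriptModel]] = {}
        for t in reference.transcripts():
            self.by_cs.setdefault((t.chrom, t.strand), []).append(t)

    def candidates(self, q: TranscriptModel) -> list[TranscriptModel]:
        return [
            r
            for r in self.by_cs.get((q.chrom, q.strand), [])
            if r.start < q.end and q.start < r.end
        ]


def classify_transcript(
    query: TranscriptModel, reference: Annotation, _index: _RefIndex | None = None
) -> MatchClass:
    """Highest-precedence match class of ``query`` against ``reference``."""
    index = _index if _index is not None else _RefIndex(reference)
    candidates = index.candidates(query)

    def exon_overlap(r: TranscriptModel) -> bool:
        return any(
            e1.start < e2.end and e2.start < e1.end
            for e1 in query.exons
            for e2 in r.exons
        )

    if query.is_monoexon:
        for r in candidates:
            if exon_overlap(r) and r.start <= query.start and query.end <= r.end:
                return MatchClass.EXACT
        return MatchClass.OTHER

    q_chain = intron_chain(query).introns
    best = MatchClass.OTHER
    for r in candidates:
        if r.is_monoexon:
            continue
        r_chain = intron_chain(r).introns
        if r_chain == q_chain:
            return MatchClass.EXACT
        if _is_subchain(q_chain, r_chain):
            best = min(best, MatchClass.CONTAINED, key=_precedence)
        elif set(q_chain) & set(r_chain) and exon_overlap(r):
            best = min(best, MatchClass.NOVEL_ISOFORM, key=_precedence)
    return best


_ORDER = {MatchClass.EXACT: 0, MatchClass.CONTAINED: 1, MatchClass.NOVEL_ISOFORM: 2, MatchClass.OTHER: 3}


def _precedence(c: MatchClass) -> int:
    return _ORDER[c]


def classify_all(predicted: Annotation, reference: Annotation) -> dict[str, MatchClass]:
    index = _RefIndex(reference)
    return {
        t.transcript_id: classify_transcript(t, reference, index)
        for t in predicted.transcripts()
    }


def precision(
    predicted: Annotation,
    reference: Annotation,
    match: set[MatchClass] = frozenset({MatchClass.EXACT}),
) -> float:
    """Fraction of predicted transcripts whose match class is accepted."""
    labels = classify_all(predicted, reference)
    if not labels:
        raise ValueError("precision undefined for an empty prediction set")
    return sum(1 for c in labels.values() if c in match) / len(labels)


def summarize(a: Annotation, genome_length: int, distinct_exons: bool = True) -> AnnotationSummary:
    """Table-style dataset summary.

    Transcribed region = union of full transcript spans (introns included);
    exon region = union of exon intervals; both strand-blind, bases counted
    once.  Exon count is over distinct (chrom, start, end, strand) exons by
    default.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    spans: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    exon_keys: set[tuple] = set()
    n_exon_records = 0
    for t in a.transcripts():
        spans.setdefault(t.chrom, []).append((t.start, t.end))
        for e in t.exons:
            exons.setdefault(t.chrom, []).append((e.start, e.end))
            exon_keys.add((e.chrom, e.start, e.end, e.strand))
            n_exon_records += 1
    transcribed = sum(
        e - s for ivs in spans.values() for s, e in merge_intervals(ivs)
    )
    exonic = sum(e - s for ivs in exons.values() for s, e in merge_intervals(ivs))
    return AnnotationSummary(
        n_genes=a.n_genes,
        n_transcripts=a.n_transcripts,
        transcribed_bases=transcribed,
        transcribed_ratio=transcribed / genome_length,
        n_exons=len(exon_keys) if distinct_exons else n_exon_records,
        exon_bases=exonic,
        exon_ratio=exonic / genome_length,
    )


@dataclass
class IsoformDistribution:
    counts: dict[int, int]          # isoforms-per-gene -> number of genes
    multi_isoform_fraction: float
    mean_isoforms_multi: float | None  # None when no multi-isoform gene exists


def isoform_distribution(a: Annotation) -> IsoformDistribution:
    per_gene = [len(g.transcripts) for g in a.genes]
    if not per_gene:
        return IsoformDistribution({}, 0.0, None)
    counts = dict(sorted(Counter(per_gene).items()))
    multi = [n for n in per_gene if n >= 2]
    return IsoformDistribution(
        counts=counts,
        multi_isoform_fraction=len(multi) / len(per_gene),
        mean_isoforms_multi=sum(multi) / len(multi) if multi else None,
    )
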