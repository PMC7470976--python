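"""Alternative-splicing event classification between isoforms of a gene.

Pairs of isoforms are decomposed into variation bubbles — maximal regions
where their intron chains disagree, bounded by shared exon-boundary sites —
and each bubble is labeled with one of the seven canonical categories (SE,
IR, A5SS, A3SS, MXE, AFE, ALE) when it matches the corresponding structural
pattern, or "complex" otherwise.  Pure 5'/3'-end length differences are not
events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .annotation_model import Annotation, GeneModel, TranscriptModel, intron_chain

Introns = tuple[tuple[int, int], ...]


class EventType(str, Enum):
    SE = "SE"
    IR = "IR"
    A5SS = "A5SS"
    A3SS = "A3SS"
    AFE = "AFE"
    ALE = "ALE"
    MXE = "MXE"
    COMPLEX = "complex"


CANONICAL_TYPES = tuple(t for t in EventType if t is not EventType.COMPLEX)


@dataclass(frozen=True)
class ASEvent:
    type: EventType
    gene_id: str
    chrom: str
    strand: str
    region: tuple[int, int]          # bubble bounds (genomic)
    paths: tuple[Introns, Introns]   # intron structure of each variant, sorted

    @property
    def key(self) -> tuple:
        return (self.type, self.chrom, self.strand, self.region, self.paths)


def _sites(t: TranscriptModel) -> set[int]:
    out: set[int] = set()
    for e in t.exons:
        out.add(e.start)
        out.add(e.end)
    return out


def _bubble_type(i1: Introns, i2: Introns, strand: str, terminal: str | None) -> EventType:
    """Label one variation bubble.

    ``terminal`` is None for internal bubbles, "left"/"right" (genomic) for
    transcript-end bubbles; i1/i2 are the introns of each path inside the
    bubble (already known to differ).
    """
    n1, n2 = len(i1), len(i2)
    if terminal is None:
        if {n1, n2} == {0, 1}:
            return EventType.IR
        if {n1, n2} == {1, 2}:
            one, two = (i1, i2) if n1 == 1 else (i2, i1)
            if one[0][0] == two[0][0] and one[0][1] == two[-1][1] and len(two) == 2:
                return EventType.SE
            return EventType.COMPLEX
        if n1 == 1 and n2 == 1:
            (d1, a1), (d2, a2) = i1[0], i2[0]
            if a1 == a2 and d1 != d2:
                return EventType.A5SS if strand != "-" else EventType.A3SS
            if d1 == d2 and a1 != a2:
                return EventType.A3SS if strand != "-" else EventType.A5SS
            return EventType.COMPLEX
        if n1 == 2 and n2 == 2:
            if i1[0][0] == i2[0][0] and i1[1][1] == i2[1][1]:
                e1 = (i1[0][1], i1[1][0])
                e2 = (i2[0][1], i2[1][0])
                disjoint = e1[1] <= e2[0] or e2[1] <= e1[0]
                if disjoint and e1 != e2:
                    return EventType.MXE
            return EventType.COMPLEX
        return EventType.COMPLEX

    return EventType.COMPLEX


def _end_bubble_type(
    i1: Introns,
    i2: Introns,
    end1: tuple[int, int],
    end2: tuple[int, int],
    strand: str,
    terminal: str,
) -> EventType:
    """Label a transcript-end bubble.

    ``end1``/``end2`` are each path's terminal exon inside the bubble.
    Canonical shapes carry exactly one intron per path, sharing the splice
    site on the bubble's closed side; disjoint terminal exons give AFE/ALE,
    overlapping ones an alternative donor/acceptor site.
    """
    if len(i1) != 1 or len(i2) != 1:
        return EventType.COMPLEX
    (d1, a1), (d2, a2) = i1[0], i2[0]
    disjoint = end1[1] <= end2[0] or end2[1] <= end1[0]
    if terminal == "left" and a1 == a2 and d1 != d2:
        if disjoint:
            return EventType.AFE if strand != "-" else EventType.ALE
        return EventType.A5SS if strand != "-" else EventType.A3SS
    if terminal == "right" and d1 == d2 and a1 != a2:
        if disjoint:
            return EventType.ALE if strand != "-" else EventType.AFE
        return EventType.A3SS if strand != "-" else EventType.A5SS
    return EventType.COMPLEX


def classify_pair(
    t1: TranscriptModel, t2: TranscriptModel, include_complex: bool = True
) -> list[ASEvent]:
    """Variation bubbles between two isoforms, each labeled.

    Symmetric in its arguments up to path order.
    """
    if (t1.chrom, t1.strand) != (t2.chrom, t2.strand):
        raise ValueError("transcripts on different chrom/strand")
    chrom, strand = t1.chrom, t1.strand
    gene_id = t1.gene_id
    c1, c2 = intron_chain(t1).introns, intron_chain(t2).introns
    if c1 == c2:
        return []
    shared = sorted(_sites(t1) & _sites(t2))
    low, high = max(t1.start, t2.start), min(t1.end, t2.end)
    if low >= high:
        return []  # no overlap: no comparable structure
    events: list[ASEvent] = []

    bounds = [s for s in shared if low <= s <= high]
    # internal bubbles between adjacent shared sites
    for l, r in zip(bounds, bounds[1:]):
        i1 = tuple(iv for iv in c1 if l <= iv[0] and iv[1] <= r)
        i2 = tuple(iv for iv in c2 if l <= iv[0] and iv[1] <= r)
        if i1 == i2:
            continue
        etype = _bubble_type(i1, i2, strand, None)
        events.append(
            ASEvent(etype, gene_id, chrom, strand, (l, r), _ordered(i1, i2))
        )

    # transcript-end bubbles outside the shared-site range
    if bounds:
        c0 = bounds[0]
        if t1.start != t2.start and c0 > max(t1.start, t2.start):
            i1 = tuple(iv for iv in c1 if iv[1] <= c0)
            i2 = tuple(iv for iv in c2 if iv[1] <= c0)
            if i1 and i2 and i1 != i2:
                etype = _end_bubble_type(
                    i1, i2, (t1.start, i1[0][0]), (t2.start, i2[0][0]),
                    strand, "left",
                )
                events.append(
                    ASEvent(
                        etype, gene_id, chrom, strand,
                        (min(t1.start, t2.start), c0), _ordered(i1, i2),
                    )
                )
        cN = bounds[-1]
        if t1.end != t2.end and cN < max(t1.end, t2.end):
            i1 = tuple(iv for iv in c1 if iv[0] >= cN)
            i2 = tuple(iv for iv in c2 if iv[0] >= cN)
            if i1 and i2 and i1 != i2:
                etype = _end_bubble_type(
                    i1, i2, (i1[-1][1], t1.end), (i2[-1][1], t2.end),
                    strand, "right",
                )
                events.append(
                    ASEvent(
                        etype, gene_id, chrom, strand,
                        (cN, max(t1.end, t2.end)), _ordered(i1, i2),
                    )
                )
    if not include_complex:
        events = [e for e in events if e.type is not EventType.COMPLEX]
    return events


def _ordered(i1: Introns, i2: Introns) -> tuple[Introns, Introns]:
    return (i1, i2) if i1 <= i2 else (i2, i1)


def gene_events(
    g: GeneModel, include_complex: bool = True
) -> list[ASEvent]:
    """Union of events over all isoform pairs, deduplicated by event key."""
    seen: set[tuple] = set()
    out: list[ASEvent] = []
    ts = g.transcripts
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            for ev in classify_pair(ts[i], ts[j], include_complex=include_complex):
                if ev.key not in seen:
                    seen.add(ev.key)
                    out.append(ev)
    return out


@dataclass
class EventDistribution:
    counts: dict[EventType, int]
    percentages: dict[EventType, float]  # over the seven canonical types
    n_complex: int


def event_distribution(a: Annotation) -> EventDistribution:
    tally: Counter = Counter()
    for g in a.genes:
        if len(g.transcripts) < 2:
            continue
        for ev in gene_events(g):
            tally[ev.type] += 1
    canonical_total = sum(tally[t] for t in CANONICAL_TYPES)
    percentages = {
        t: (100.0 * tally[t] / canonical_total if canonical_total else 0.0)
        for t in CANONICAL_TYPES
        if tally[t]
    }
    return EventDistribution(
        counts={t: tally[t] for t in EventType if tally[t]},
        percentages=percentages,
        n_complex=tally[EventType.COMPLEX],
    )
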