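"""Position-anchored signal analyses.

TSS peak-coverage metaprofile, randomized anchor shuffling, TTS polyA hexamer
scan, canonical splice-signature tally, and TE/exon overlap fractions.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation_model import (
    Annotation,
    BedRecord,
    GenomicInterval,
    TranscriptModel,
    intron_chain,
    merge_intervals,
    revcomp,
)

log = logging.getLogger(__name__)

NON_TE_PATTERNS = re.compile(r"Low_complexity|Satellite|Simple_repeat", re.IGNORECASE)
POLYA_HEXAMERS = ("AATAAA", "ATTAAA")


@dataclass
class MetaProfile:
    anchor: str                 # "TSS" or "TTS"
    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int

    def __post_init__(self) -> None:
        assert len(self.offsets) == len(self.values)


@dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int
    strand: str


@dataclass(frozen=True)
class RepeatRecord:
    interval: GenomicInterval
    repeat_class: str

    @property
    def is_te(self) -> bool:
        return not NON_TE_PATTERNS.search(self.repeat_class)


def repeats_from_bed(records: Iterable[BedRecord]) -> list[RepeatRecord]:
    """BED name column carries the repeat class/family (e.g. 'SINE/Alu')."""
    return [RepeatRecord(r.interval, r.name) for r in records]


# ---------------------------------------------------------------------------
# TSS metaprofile
# ---------------------------------------------------------------------------

def expressed_tss_anchors(
    transcripts: Iterable[TranscriptModel],
    sample: str,
    min_fpkm: float = 0.5,
) -> list[Anchor]:
    """Unique (chrom, position, strand) TSSs of transcripts whose FPKM in
    ``sample`` is >= min_fpkm (the two printed forms of this filter disagree
    at exactly 0.5; >= keeps the boundary)."""
    seen: set[Anchor] = set()
    out: list[Anchor] = []
    for t in transcripts:
        if t.strand == ".":
            log.warning("%s: unstranded, skipped for TSS profiling", t.transcript_id)
            continue
        if sample not in t.fpkm or t.fpkm[sample] < min_fpkm:
            continue
        a = Anchor(t.chrom, t.tss, t.strand)
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out


def _peak_boundaries(peaks: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append((p.start, p.end))
    return {
        chrom: np.array(merge_intervals(ivs), dtype=np.int64).reshape(-1)
        for chrom, ivs in by_chrom.items()
    }


def tss_profile(
    transcripts: Iterable[TranscriptModel],
    sample: str,
    peaks: Sequence[GenomicInterval],
    flank: int = 10000,
    min_fpkm: float = 0.5,
    anchors: Sequence[Anchor] | None = None,
) -> MetaProfile:
    """Per-offset fraction of expressed-TSS windows whose base lies inside a
    peak; offsets run -flank..+flank in transcript orientation (minus-strand
    windows are flipped).  Coverage is binary per base."""
    if anchors is None:
        anchors = expressed_tss_anchors(transcripts, sample, min_fpkm)
    if not anchors:
        raise ValueError("no expressed TSS anchors")
    bounds = _peak_boundaries(peaks)
    offsets = np.arange(-flank, flank + 1)
    acc = np.zeros(len(offsets), dtype=np.float64)
    for a in anchors:
        positions = a.position + offsets if a.strand != "-" else a.position - offsets
        b = bounds.get(a.chrom)
        if b is None or len(b) == 0:
            continue
        inside = (np.searchsorted(b, positions, side="right") % 2) == 1
        acc += inside
    return MetaProfile("TSS", offsets, acc / len(anchors), len(anchors))


def shuffle_anchors(
    anchors: Sequence[Anchor],
    genome_lengths: Mapping[str, int],
    seed: int,
) -> list[Anchor]:
    """Uniform random position per anchor on its own chromosome, strand
    preserved; reproducible by seed."""
    rng = np.random.default_rng(seed)
    out = []
    for a in anchors:
        n = genome_lengths[a.chrom]
        out.append(Anchor(a.chrom, int(rng.integers(0, n)), a.strand))
    return out


# ---------------------------------------------------------------------------
# TTS polyA hexamer scan
# ---------------------------------------------------------------------------

@dataclass
class PolyAHit:
    transcript_id: str
    offset: int   # hexamer start, relative to the TTS (always negative)
    hexamer: str


def tts_polya_scan(
    transcripts: Iterable[TranscriptModel],
    genome: Mapping[str, str],
    window: int = 100,
    hexamers: Sequence[str] = POLYA_HEXAMERS,
) -> tuple[MetaProfile, list[PolyAHit]]:
    """Scan the ``window`` genomic bases upstream of each TTS (transcript
    orientation) for polyA hexamer start positions.

    The window covers offsets -window..-1 relative to the TTS base (offset
    0, excluded); profile value at offset o = fraction of transcripts with a
    hexamer starting there, fully inside the window."""
    offsets = np.arange(-window, 0)
    counts = np.zeros(window, dtype=np.float64)
    hits: list[PolyAHit] = []
    n = 0
    for t in transcripts:
        if t.strand == ".":
            log.warning("%s: unstranded, skipped for TTS scan", t.transcript_id)
            continue
        seq = genome[t.chrom]
        if t.strand != "-":
            lo = t.end - 1 - window
            if lo < 0:
                log.warning("%s: TTS window truncated at chromosome start", t.transcript_id)
                lo = 0
            upstream = seq[lo : t.end - 1]
        else:
            hi = t.start + 1 + window
            if hi > len(seq):
                log.warning("%s: TTS window truncated at chromosome end", t.transcript_id)
                hi = len(seq)
            upstream = revcomp(seq[t.start + 1 : hi])
        n += 1
        w = len(upstream)
        for hexamer in hexamers:
            at = upstream.find(hexamer)
            while at != -1:
                offset = at - w  # window base immediately before the TTS is -1
                if offset + 6 <= 0 and offset >= -window:
                    counts[offset + window] += 1
                    hits.append(PolyAHit(t.transcript_id, offset, hexamer))
                at = upstream.find(hexamer, at + 1)
    if n == 0:
        raise ValueError("no stranded transcripts to scan")
    return MetaProfile("TTS", offsets, counts / n, n), hits


# ---------------------------------------------------------------------------
# splice signatures
# ---------------------------------------------------------------------------

SIGNATURE_CLASSES = ("GT-AG", "GC-AG", "AT-AC", "other")


def splice_signature_stats(
    annotation: Annotation, genome: Mapping[str, str]
) -> tuple[Counter, dict[str, float]]:
    """Donor/acceptor dinucleotide tally over unique junctions,
    strand-corrected to transcript orientation."""
    seen: set[tuple] = set()
    tally: Counter = Counter()
    for t in annotation.transcripts():
        if t.is_monoexon:
            continue
        chain = intron_chain(t)
        seq = genome[t.chrom]
        for s, e in chain.introns:
            key = (t.chrom, s, e, t.strand)
            if key in seen:
                continue
            seen.add(key)
            if e > len(seq):
                raise ValueError(f"junction {key} beyond chromosome end")
            if t.strand != "-":
                donor, acceptor = seq[s : s + 2], seq[e - 2 : e]
            else:
                donor, acceptor = revcomp(seq[e - 2 : e]), revcomp(seq[s : s + 2])
            pair = f"{donor}-{acceptor}"
            tally[pair if pair in SIGNATURE_CLASSES else "other"] += 1
    total = sum(tally.values())
    fractions = {
        c: (tally.get(c, 0) / total if total else 0.0) for c in SIGNATURE_CLASSES
    }
    return tally, fractions


# ---------------------------------------------------------------------------
# TE overlap
# ---------------------------------------------------------------------------

def _overlap_with_union(
    exons: Sequence[GenomicInterval], union: Mapping[str, np.ndarray]
) -> int:
    total = 0
    for e in exons:
        b = union.get(e.chrom)
        if b is None or len(b) == 0:
            continue
        starts, ends = b[0::2], b[1::2]
        lo = np.minimum(ends, e.end)
        hi = np.maximum(starts, e.start)
        total += int(np.clip(lo - hi, 0, None).sum())
    return total


def te_overlap(
    classes: Mapping[str, Annotation | Sequence[TranscriptModel]],
    repeats: Sequence[RepeatRecord],
) -> tuple[dict[str, float], dict[str, dict[str, float]]]:
    """Per-class fraction of transcript bases covered by transposable
    elements, plus a per-family breakdown.

    Non-TE records (low complexity, satellites, simple repeats) are removed.
    Numerator: exon bases intersecting the merged TE union, summed over
    transcripts; denominator: total transcript length of the class.
    """
    te = [r for r in repeats if r.is_te]
    union = _peak_boundaries([r.interval for r in te])
    by_family: dict[str, list[GenomicInterval]] = defaultdict(list)
    for r in te:
        by_family[r.repeat_class].append(r.interval)
    family_union = {fam: _peak_boundaries(ivs) for fam, ivs in by_family.items()}

    fractions: dict[str, float] = {}
    per_family: dict[str, dict[str, float]] = {}
    for name, members in classes.items():
        ts = list(members.transcripts()) if isinstance(members, Annotation) else list(members)
        denom = sum(t.length for t in ts)
        if denom == 0:
            fractions[name] = 0.0
            per_family[name] = {}
            continue
        num = sum(_overlap_with_union(t.exons, union) for t in ts)
        fractions[name] = num / denom
        per_family[name] = {
            fam: sum(_overlap_with_union(t.exons, fu) for t in ts) / denom
            for fam, fu in sorted(family_union.items())
        }
    return fractions, per_family
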