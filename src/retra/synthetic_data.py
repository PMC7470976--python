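"""Deterministic, seeded generators for every input the toolkit consumes.

Each generator plants a known ground truth (splice signatures, ORFs, polyA
hexamers, AS events, expression design, conservation labels, evidence
labels) and records it, so every analysis operation can be closed-loop
tested at noise zero without external data.

Gene structures are built from a fixed relative template with a dedicated
locus per AS-event type, so that pairwise isoform comparison recovers the
planted canonical events exactly (cross-variant bubbles can only add
"complex" events, which the seven-way tally excludes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation_model import (
    Annotation,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    intron_chain,
    revcomp,
)
from .as_events import EventType
from .consolidation import ReplicateSet
from .expression_patterns import ExpressionMatrix
from .genomic_features import RepeatRecord
from .junction_conservation import Junction, JunctionContext, extract_junction_contexts

import pandas as pd

# relative exon template (plus-strand layout); each AS event type edits a
# dedicated, non-adjacent locus so planted events never interfere
_ALT_FIRST = (0, 120)
_EXONS = ((300, 500), (700, 900), (1120, 1320), (1380, 1580),
          (1640, 1840), (1900, 2100), (2160, 2360))
_MXE_ALT = (960, 1060)
_ALT_LAST = (2420, 2540)
_SLOT = 3000          # per-gene genomic footprint
_MARGIN = 200         # slot-internal offset
_MONO_EXON = (300, 800)

_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

TE_FAMILIES = ("LINE/L1", "SINE/Alu", "LTR/ERVL-MaLR", "DNA/hAT")
NON_TE_CLASSES = ("Simple_repeat", "Low_complexity", "Satellite")


@dataclass
class SyntheticTruth:
    seed: int
    genome: dict[str, str]
    annotation: Annotation
    labels: dict[str, str] = field(default_factory=dict)       # tid -> coding/noncoding
    planted_events: Counter = field(default_factory=Counter)   # EventType -> count
    polya_offsets: dict[str, int] = field(default_factory=dict)
    junction_signatures: dict[tuple, str] = field(default_factory=dict)
    hk_genes: set[str] = field(default_factory=set)
    hk_transcripts: set[str] = field(default_factory=set)
    switch_genes: set[str] = field(default_factory=set)
    conserved_junctions: dict[tuple, bool] = field(default_factory=dict)
    violation_expectations: dict[str, str] = field(default_factory=dict)


def make_genome(seed: int, n_chroms: int = 2, chrom_len: int = 50_000) -> dict[str, str]:
    """Uniform-composition random genome, deterministic by seed."""
    if chrom_len < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(bases[rng.integers(0, 4, chrom_len)])
        for i in range(n_chroms)
    }


# event template: variant exon list for each type, in plus-strand layout
def _variant_exons(etype: EventType) -> list[tuple[int, int]]:
    e = list(_EXONS)
    if etype is EventType.SE:
        return [e[0], e[1], e[3], e[4], e[5], e[6]]
    if etype is EventType.IR:
        return [e[0], e[1], e[2], (e[3][0], e[4][1]), e[5], e[6]]
    if etype is EventType.A3SS:
        return [e[0], e[1], e[2], e[3], e[4], (e[5][0] + 40, e[5][1]), e[6]]
    if etype is EventType.A5SS:
        return [e[0], e[1], e[2], e[3], e[4], (e[5][0], e[5][1] - 40), e[6]]
    if etype is EventType.MXE:
        return [e[0], _MXE_ALT, e[2], e[3], e[4], e[5], e[6]]
    if etype is EventType.AFE:
        return [_ALT_FIRST, e[1], e[2], e[3], e[4], e[5], e[6]]
    if etype is EventType.ALE:
        return [e[0], e[1], e[2], e[3], e[4], e[5], _ALT_LAST]
    raise ValueError(f"no template for {etype}")


_MIRROR = {
    EventType.A5SS: EventType.A3SS,
    EventType.A3SS: EventType.A5SS,
    EventType.AFE: EventType.ALE,
    EventType.ALE: EventType.AFE,
}


def _template_for(etype: EventType, strand: str) -> EventType:
    """Template (plus-strand layout) that yields ``etype`` on ``strand``."""
    if strand == "-" and etype in _MIRROR:
        return _MIRROR[etype]
    return etype


def make_annotation(
    genome: Mapping[str, str],
    seed: int,
    n_genes: int = 20,
    isoform_weights: Sequence[float] = (0.6, 0.2, 0.1, 0.1),
    gtag_fraction: float = 0.97,
    coding_fraction: float = 0.5,
    mono_fraction: float = 0.0,
    polya_prob: float = 1.0,
    polya_offset: int | tuple[int, int] = (-40, -10),
    event_types: Sequence[EventType] = tuple(t for t in EventType if t is not EventType.COMPLEX),
    both_strands: bool = True,
) -> SyntheticTruth:
    """Plant a truth annotation into ``genome``.

    ``isoform_weights[i]`` is the probability of a gene carrying i+1
    isoforms; each isoform beyond the first realizes one AS event cycled
    from ``event_types``.  Splice signatures: round(gtag_fraction * n)
    unique junctions get GT..AG, the rest GC..AG (exact when isoforms do
    not share splice sites).  Coding genes carry a planted >= 100-codon ORF
    with CDS records on their first isoform.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    seq: dict[str, list[str]] = {c: list(genome[c]) for c in chroms}
    capacity = {c: (len(genome[c]) - 2 * _MARGIN) // _SLOT for c in chroms}
    if sum(capacity.values()) < n_genes:
        raise ValueError(
            f"cannot pack {n_genes} genes into {sum(capacity.values())} slots"
        )

    truth = SyntheticTruth(seed=seed, genome={}, annotation=Annotation())
    genes: list[GeneModel] = []
    weights = np.asarray(isoform_weights, dtype=float)
    weights = weights / weights.sum()

    slot_iter = [
        (c, _MARGIN + k * _SLOT) for c in chroms for k in range(capacity[c])
    ]
    event_cycle = 0
    for gi in range(n_genes):
        chrom, base = slot_iter[gi]
        gid = f"SYNG.{gi + 1}"
        strand = "+" if (not both_strands or rng.random() < 0.5) else "-"
        is_mono = rng.random() < mono_fraction
        is_coding = (not is_mono) and rng.random() < coding_fraction

        transcripts: list[TranscriptModel] = []
        if is_mono:
            s, e = _MONO_EXON
            transcripts.append(
                TranscriptModel(
                    f"{gid}.1", gid,
                    [GenomicInterval(chrom, base + s, base + e, strand)],
                )
            )
        else:
            n_iso = int(rng.choice(len(weights), p=weights)) + 1
            n_iso = min(n_iso, len(event_types) + 1)
            exon_lists = [list(_EXONS)]
            for v in range(n_iso - 1):
                etype = event_types[event_cycle % len(event_types)]
                event_cycle += 1
                truth.planted_events[etype] += 1
                exon_lists.append(_variant_exons(_template_for(etype, strand)))
            for k, rel_exons in enumerate(exon_lists):
                exons = [
                    GenomicInterval(chrom, base + s, base + e, strand)
                    for s, e in rel_exons
                ]
                transcripts.append(TranscriptModel(f"{gid}.{k + 1}", gid, exons))

        for t in transcripts:
            truth.labels[t.transcript_id] = "coding" if is_coding else "noncoding"
        if is_coding:
            _plant_orf(seq[chrom], transcripts[0], rng)
        _plant_polya(seq, transcripts, truth, rng, polya_prob, polya_offset)
        genes.append(GeneModel(gid, transcripts))

    annotation = Annotation(genes=genes, provenance="synthetic-truth")
    _plant_splice_signatures(seq, annotation, gtag_fraction, rng, truth)
    truth.genome = {c: "".join(seq[c]) for c in chroms}
    truth.annotation = annotation
    return truth


def _write_spliced(seq: list[str], t: TranscriptModel, spliced: str) -> None:
    """Write ``spliced`` (transcript orientation, possibly shorter than the
    transcript) into the genome along the transcript's exons."""
    i = 0
    if t.strand != "-":
        for e in t.exons:
            n = min(len(e), len(spliced) - i)
            if n <= 0:
                break
            seq[e.start : e.start + n] = list(spliced[i : i + n])
            i += n
    else:
        for e in reversed(t.exons):
            n = min(len(e), len(spliced) - i)
            if n <= 0:
                break
            # transcript offsets i..i+n occupy the genomic right end of e
            seq[e.end - n : e.end] = list(revcomp(spliced[i : i + n]))
            i += n


def _plant_orf(seq: list[str], t: TranscriptModel, rng: np.random.Generator) -> None:
    """Plant an ATG + 119 stop-free codons + TAA starting at spliced
    position 9, and attach CDS records with phases."""
    n_codons = 120
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 1))
    orf = "ATG" + body + "TAA"
    start, end = 9, 9 + len(orf)  # spliced coordinates
    # genomic payload for [0, end): keep a random prefix before the ORF
    prefix = "".join(np.array(list("ACGT"))[rng.integers(0, 4, start)])
    _write_spliced(seq, t, prefix + orf)
    # CDS genomic segments with GTF-style frame
    segments: list[tuple[GenomicInterval, int]] = []
    exon_iter = t.exons if t.strand != "-" else list(reversed(t.exons))
    spliced_pos = 0
    cds_before = 0
    for e in exon_iter:
        ex_lo, ex_hi = spliced_pos, spliced_pos + len(e)
        lo, hi = max(ex_lo, start), min(ex_hi, end)
        if lo < hi:
            if t.strand != "-":
                g_lo = e.start + (lo - ex_lo)
                g_hi = e.start + (hi - ex_lo)
            else:
                g_hi = e.end - (lo - ex_lo)
                g_lo = e.end - (hi - ex_lo)
            phase = (3 - cds_before % 3) % 3
            segments.append(
                (GenomicInterval(e.chrom, g_lo, g_hi, e.strand), phase)
            )
            cds_before += hi - lo
        spliced_pos = ex_hi
    t.cds = sorted(segments, key=lambda sp: sp[0].start)


def _plant_polya(
    seq: dict[str, list[str]],
    transcripts: list[TranscriptModel],
    truth: SyntheticTruth,
    rng: np.random.Generator,
    prob: float,
    offset_spec: int | tuple[int, int],
) -> None:
    planted_at_tts: dict[int, int] = {}
    for t in transcripts:
        if rng.random() >= prob:
            truth.polya_offsets[t.transcript_id] = 0  # 0 = not planted
            continue
        tts = t.tts
        if tts in planted_at_tts:
            truth.polya_offsets[t.transcript_id] = planted_at_tts[tts]
            continue
        if isinstance(offset_spec, int):
            offset = offset_spec
        else:
            offset = int(rng.integers(offset_spec[0], offset_spec[1] + 1))
        s = seq[t.chrom]
        if t.strand != "-":
            pos = (t.end - 1) + offset
            s[pos : pos + 6] = list("AATAAA")
        else:
            pos = t.start - offset - 5
            s[pos : pos + 6] = list(revcomp("AATAAA"))
        planted_at_tts[tts] = offset
        truth.polya_offsets[t.transcript_id] = offset


def _plant_splice_signatures(
    seq: dict[str, list[str]],
    annotation: Annotation,
    gtag_fraction: float,
    rng: np.random.Generator,
    truth: SyntheticTruth,
) -> None:
    junctions: list[tuple] = []
    seen: set[tuple] = set()
    for t in annotation.transcripts():
        chain = intron_chain(t)
        for s, e in chain.introns:
            key = (t.chrom, s, e, t.strand)
            if key not in seen:
                seen.add(key)
                junctions.append(key)
    n = len(junctions)
    if n == 0:
        return
    n_gc = n - int(round(gtag_fraction * n))
    # prefer junctions with private splice sites for the non-canonical
    # signature, so overlapping variants cannot overwrite each other
    site_use: Counter = Counter()
    for chrom, s, e, strand in junctions:
        site_use[(chrom, s)] += 1
        site_use[(chrom, e)] += 1
    order = [junctions[i] for i in rng.permutation(n)]
    private = [
        k for k in order if site_use[(k[0], k[1])] == 1 and site_use[(k[0], k[2])] == 1
    ]
    shared = [k for k in order if k not in set(private)]
    gc_set = set((private + shared)[:n_gc])
    for key in junctions:
        chrom, s, e, strand = key
        donor, acceptor = ("GC", "AG") if key in gc_set else ("GT", "AG")
        if strand != "-":
            seq[chrom][s : s + 2] = list(donor)
            seq[chrom][e - 2 : e] = list(acceptor)
        else:
            seq[chrom][e - 2 : e] = list(revcomp(donor))
            seq[chrom][s : s + 2] = list(revcomp(acceptor))
    # record the effective signature from the final sequence (shared sites
    # can override the intent when n_gc exceeds the private junctions)
    for key in junctions:
        chrom, s, e, strand = key
        if strand != "-":
            sig = "".join(seq[chrom][s : s + 2]) + "-" + "".join(seq[chrom][e - 2 : e])
        else:
            sig = (
                revcomp("".join(seq[chrom][e - 2 : e]))
                + "-"
                + revcomp("".join(seq[chrom][s : s + 2]))
            )
        truth.junction_signatures[key] = sig


# ---------------------------------------------------------------------------
# replicate assemblies
# ---------------------------------------------------------------------------

VIOLATION_KINDS = ("subthreshold", "mono_3of4", "orphan", "superchain")


def make_replicate_assemblies(
    truth: SyntheticTruth,
    seed: int,
    n_reps: int = 4,
    dropout: float = 0.0,
    fpkm_law: tuple[float, float] = (0.5, 0.5),
    fpkm_offset: float = 1.01,
    planted_violations: Sequence[str] = (),
    condition: str = "cond1",
) -> ReplicateSet:
    """Per-replicate copies of the truth with seeded dropout and shifted
    log-normal FPKM (offset + lognormal, so noiseless runs stay above the
    support threshold).  ``planted_violations`` appends the documented edge
    cases on a free stretch of sequence; expected verdicts are recorded in
    ``truth.violation_expectations``."""
    rng = np.random.default_rng(seed)
    mu, sigma = fpkm_law

    def draw_fpkm() -> float:
        return float(fpkm_offset + rng.lognormal(mu, sigma))

    reps: list[list[TranscriptModel]] = [[] for _ in range(n_reps)]
    for t in truth.annotation.transcripts():
        for r in range(n_reps):
            if rng.random() < dropout:
                continue
            reps[r].append(
                TranscriptModel(
                    t.transcript_id, t.gene_id,
                    [GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in t.exons],
                    fpkm={f"rep{r + 1}": draw_fpkm()},
                )
            )

    if planted_violations:
        _plant_violations(truth, reps, planted_violations, n_reps)

    assemblies = []
    for r, ts in enumerate(reps):
        genes: dict[str, list[TranscriptModel]] = {}
        order: list[str] = []
        for t in ts:
            if t.gene_id not in genes:
                genes[t.gene_id] = []
                order.append(t.gene_id)
            genes[t.gene_id].append(t)
        assemblies.append(
            Annotation(
                genes=[GeneModel(g, genes[g]) for g in order],
                provenance=f"{condition}-rep{r + 1}",
            )
        )
    return ReplicateSet(condition, assemblies)


def _plant_violations(
    truth: SyntheticTruth,
    reps: list[list[TranscriptModel]],
    kinds: Sequence[str],
    n_reps: int,
) -> None:
    # place extras on the chromosome with the most free tail sequence
    used = {c: 0 for c in truth.genome}
    for t in truth.annotation.transcripts():
        used[t.chrom] = max(used[t.chrom], t.end)
    chrom = max(sorted(truth.genome), key=lambda c: len(truth.genome[c]) - used[c])
    base = used[chrom] + 1000
    if base + 4000 > len(truth.genome[chrom]):
        raise ValueError("no free sequence for planted violations")

    def tx(tid: str, rel_exons, fpkm: float, rep: int) -> TranscriptModel:
        return TranscriptModel(
            tid, tid + ".g",
            [GenomicInterval(chrom, base + s, base + e, "+") for s, e in rel_exons],
            fpkm={f"rep{rep + 1}": fpkm},
        )

    for kind in kinds:
        if kind == "subthreshold":
            for r in range(n_reps):
                reps[r].append(tx("VIOL.sub", ((0, 150), (300, 450)), 0.8, r))
            truth.violation_expectations["VIOL.sub"] = "dropped"
        elif kind == "mono_3of4":
            for r in range(n_reps - 1):
                reps[r].append(tx("VIOL.mono", ((600, 900),), 5.0, r))
            truth.violation_expectations["VIOL.mono"] = "dropped"
        elif kind == "orphan":
            reps[0].append(tx("VIOL.orphan", ((1100, 1250), (1400, 1550)), 5.0, 0))
            truth.violation_expectations["VIOL.orphan"] = "dropped"
        elif kind == "superchain":
            # B: 2-replicate supported novel; A: 1-replicate superchain
            b_exons = ((1700, 1850), (2000, 2150), (2300, 2450))
            a_exons = ((1650, 1850), (2000, 2150), (2300, 2450), (2600, 2750))
            for r in (0, 1):
                reps[r].append(tx("VIOL.chainB", b_exons, 5.0, r))
            reps[0].append(tx("VIOL.chainA", a_exons, 5.0, 0))
            truth.violation_expectations["VIOL.chainA"] = "rescued"
            truth.violation_expectations["VIOL.chainB"] = "dropped_superseded"
        else:
            raise ValueError(f"unknown violation kind {kind!r}")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def make_expression_matrix(
    truth: SyntheticTruth,
    seed: int,
    tissues: Sequence[str] = ("liver", "brain", "kidney", "testis"),
    stages: Sequence[str] = ("wk2", "wk6"),
    sexes: Sequence[str] = ("M", "F"),
    n_reps: int = 2,
    n_hk_genes: int = 5,
    n_switch_genes: int = 2,
    noise: float = 0.2,
) -> ExpressionMatrix:
    """Transcript-level FPKM matrix with planted housekeeping genes (all
    isoforms above threshold everywhere), tissue-specific genes (one home
    tissue each), and dominant-isoform switches among the housekeeping set.

    Switch genes flip their top isoform in the first tissue; all other genes
    keep a fixed isoform ranking, so the switch set is exactly recoverable.
    """
    rng = np.random.default_rng(seed)
    genes = truth.annotation.genes
    multi = [g for g in genes if len(g.transcripts) >= 2]
    if n_switch_genes > len(multi):
        raise ValueError("not enough multi-isoform genes to plant switches")
    switch_genes = [g.gene_id for g in multi[:n_switch_genes]]
    hk_ids = set(switch_genes)
    for g in genes:
        if len(hk_ids) >= max(n_hk_genes, len(switch_genes)):
            break
        hk_ids.add(g.gene_id)

    samples: list[str] = []
    meta_rows: list[dict] = []
    for tissue in tissues:
        for stage in stages:
            for sex in sexes:
                for rep in range(1, n_reps + 1):
                    sid = f"{tissue}_{stage}_{sex}_{rep}"
                    samples.append(sid)
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "tissue": tissue,
                            "stage": stage,
                            "sex": sex,
                            "replicate": rep,
                        }
                    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    home_tissue = {
        g.gene_id: tissues[int(rng.integers(0, len(tissues)))]
        for g in genes
        if g.gene_id not in hk_ids
    }

    rows: dict[str, np.ndarray] = {}
    for g in genes:
        is_hk = g.gene_id in hk_ids
        is_switch = g.gene_id in switch_genes
        for k, t in enumerate(sorted(g.transcripts, key=lambda t: t.transcript_id)):
            base_rank = max(8.0 - k, 1.0)
            values = np.zeros(len(samples))
            for j, sid in enumerate(samples):
                tissue = meta.loc[sid, "tissue"]
                if is_hk:
                    v = base_rank
                    if is_switch and k < 2:
                        # isoform 0 dominates in tissues[0], isoform 1 elsewhere
                        first = tissue == tissues[0]
                        v = 10.0 if (k == 0) == first else 3.0
                elif tissue == home_tissue[g.gene_id]:
                    v = base_rank
                else:
                    v = 0.0
                values[j] = v + rng.uniform(0, noise)
            rows[t.transcript_id] = values

    truth.hk_genes = set(hk_ids)
    truth.hk_transcripts = {
        t.transcript_id for g in genes if g.gene_id in hk_ids for t in g.transcripts
    }
    truth.switch_genes = set(switch_genes)
    values = pd.DataFrame(rows, index=samples).T
    return ExpressionMatrix(values, meta, level="transcript")


# ---------------------------------------------------------------------------
# homolog contexts / peaks / repeats / evidence tables
# ---------------------------------------------------------------------------

def make_homolog_contexts(
    truth: SyntheticTruth,
    seed: int,
    conserve_rate: float = 1.0,
    n_mutations: int = 5,
) -> dict[str, list[JunctionContext]]:
    """Homolog junction contexts per gene: identical fragments for conserved
    junctions (probability ``conserve_rate``), heavily mutated ones
    otherwise (``n_mutations`` substitutions force identity far below the
    80 % rejection threshold).  Labels land in
    ``truth.conserved_junctions``."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[JunctionContext]] = {}
    seen: set[tuple] = set()
    for t in truth.annotation.transcripts():
        if t.is_monoexon:
            continue
        for ctx in extract_junction_contexts(t, truth.genome):
            if ctx.junction.key in seen:
                continue
            seen.add(ctx.junction.key)
            conserved = bool(rng.random() < conserve_rate)
            frag = ctx.nt_fragment
            if not conserved:
                frag = _mutate(frag, n_mutations, rng)
            truth.conserved_junctions[ctx.junction.key] = conserved
            out.setdefault(t.gene_id, []).append(
                JunctionContext(ctx.junction, frag, peptide=None)
            )
    return out


def _mutate(frag: str, n: int, rng: np.random.Generator) -> str:
    chars = list(frag)
    positions = rng.choice(len(chars), size=min(n, len(chars)), replace=False)
    for p in positions:
        options = [b for b in "ACGT" if b != chars[p]]
        chars[p] = options[int(rng.integers(0, 3))]
    return "".join(chars)


def make_peaks(
    anchors: Sequence, halfwidth: int = 500
) -> list[GenomicInterval]:
    """Peak intervals centered at anchor positions (e.g. expressed TSSs)."""
    return [
        GenomicInterval(a.chrom, max(0, a.position - halfwidth), a.position + halfwidth)
        for a in anchors
    ]


def make_repeats(
    genome: Mapping[str, str],
    seed: int,
    n_te: int = 50,
    n_non_te: int = 20,
    length_range: tuple[int, int] = (100, 400),
) -> list[RepeatRecord]:
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    out: list[RepeatRecord] = []
    for i in range(n_te + n_non_te):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(length_range[0], length_range[1]))
        start = int(rng.integers(0, len(genome[chrom]) - length))
        if i < n_te:
            cls = TE_FAMILIES[int(rng.integers(0, len(TE_FAMILIES)))]
        else:
            cls = NON_TE_CLASSES[int(rng.integers(0, len(NON_TE_CLASSES)))]
        out.append(RepeatRecord(GenomicInterval(chrom, start, start + length), cls))
    return out


def make_evidence_tables(
    truth: SyntheticTruth,
    seed: int,
    out_dir,
    cutoff: float = 0.364,
    noise: float = 0.0,
    species_pool: Sequence[str] = ("MOUSE", "HUMAN", "RAT"),
) -> tuple[str, str, str]:
    """Write CPAT/domain/alignment-hit tables consistent with the planted
    coding labels (at noise 0); returns the three file paths.

    ``noise`` is the per-channel probability of flipping a channel's
    outcome, which pushes transcripts into the ambiguous verdict.
    """
    import os

    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    cpat_path = os.path.join(out_dir, "cpat.tsv")
    pfam_path = os.path.join(out_dir, "pfam.tsv")
    blast_path = os.path.join(out_dir, "blast.tsv")

    with open(cpat_path, "w") as cpat, open(pfam_path, "w") as pfam, open(
        blast_path, "w"
    ) as blast:
        cpat.write("transcript_id\tcoding_prob\n")
        pfam.write("transcript_id\tdomain\tevalue\n")
        for tid in sorted(truth.labels):
            coding = truth.labels[tid] == "coding"
            ch = [coding, coding, coding]
            for i in range(3):
                if rng.random() < noise:
                    ch[i] = not ch[i]
            score = cutoff + 0.3 if ch[0] else max(cutoff - 0.3, 0.01)
            cpat.write(f"{tid}\t{score:.4f}\n")
            if ch[1]:
                pfam.write(f"{tid}\tPF{int(rng.integers(0, 99999)):05d}\t1e-12\n")
            if ch[2]:
                species = species_pool[int(rng.integers(0, len(species_pool)))]
                sid = f"sp|P{int(rng.integers(0, 99999)):05d}|PROT_{species}"
                blast.write(
                    f"{tid}\t{sid}\t92.5\t110\t8\t0\t1\t330\t1\t110\t1e-20\t200\n"
                )
    return cpat_path, pfam_path, blast_path
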