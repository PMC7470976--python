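"""Replicate-support consolidation of per-replicate assemblies.

Implements the post-assembly rules that turn N replicate assemblies from one
biological condition into a condition transcriptome, plus the cross-set merge
and the combination with reference annotations:

* multi-exon transcripts: identical intron chain in >= min_reps replicates
  with FPKM strictly > fpkm_min;
* rescue: a single-replicate transcript whose intron set strictly contains
  the intron set of a supported novel transcript supersedes it;
* mono-exon transcripts: overlap cluster with a passing member in EVERY
  replicate, boundaries = extremes over all copies;
* length filter: retain only transcripts strictly longer than min_len bases.

All thresholds are strict inequalities.  FPKM carried through merges is the
per-sample maximum over merged members (carried, not re-estimated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .annotation_model import (
    Annotation,
    GeneModel,
    GenomicInterval,
    IntronChain,
    Source,
    TranscriptModel,
    intron_chain,
)

log = logging.getLogger(__name__)


class Verdict(str, Enum):
    RETAINED = "retained"
    RESCUED = "rescued"
    DROPPED = "dropped"
    DROPPED_SUPERSEDED = "dropped_superseded"


@dataclass
class SupportDecision:
    key: str
    support: int
    passing_fpkms: list[float]
    verdict: Verdict
    detail: str = ""


@dataclass
class ReplicateSet:
    condition: str
    assemblies: list[Annotation]

    def __post_init__(self) -> None:
        if len(self.assemblies) < 2:
            raise ValueError("a ReplicateSet needs at least 2 replicates")

    @property
    def n_reps(self) -> int:
        return len(self.assemblies)


def _chain_label(chain: IntronChain) -> str:
    introns = ",".join(f"{s}-{e}" for s, e in chain.introns)
    return f"{chain.chrom}{chain.strand}:{introns}"


def _passes(t: TranscriptModel, fpkm_min: float) -> bool:
    """Strict FPKM threshold; unknown FPKM fails closed."""
    if not t.fpkm:
        log.warning("%s: no FPKM attribute, counted as non-passing", t.transcript_id)
        return False
    return max(t.fpkm.values()) > fpkm_min


def filter_multiexon_support(
    rs: ReplicateSet, fpkm_min: float = 1.0, min_reps: int = 2
) -> tuple[list[TranscriptModel], list[SupportDecision]]:
    """Group multi-exon transcripts by identical intron chain; retain groups
    with members passing the FPKM cut in >= min_reps distinct replicates.

    The retained representative keeps the shared chain with the leftmost
    start / rightmost end observed over all group members.
    """
    groups: dict[tuple, list[tuple[int, TranscriptModel]]] = {}
    for rep_idx, asm in enumerate(rs.assemblies):
        for t in asm.transcripts():
            if t.is_monoexon:
                continue
            if t.strand == ".":
                log.warning("%s: unstranded, excluded from chain matching", t.transcript_id)
                continue
            groups.setdefault(intron_chain(t).key, []).append((rep_idx, t))

    retained: list[TranscriptModel] = []
    decisions: list[SupportDecision] = []
    for key in sorted(groups, key=repr):
        members = groups[key]
        passing_reps = {r for r, t in members if _passes(t, fpkm_min)}
        passing_fpkms = sorted(
            max(t.fpkm.values()) for _, t in members if _passes(t, fpkm_min)
        )
        chain = intron_chain(members[0][1])
        label = _chain_label(chain)
        if len(passing_reps) >= min_reps:
            retained.append(_chain_representative([t for _, t in members]))
            decisions.append(
                SupportDecision(label, len(passing_reps), passing_fpkms, Verdict.RETAINED)
            )
        else:
            decisions.append(
                SupportDecision(
                    label,
                    len(passing_reps),
                    passing_fpkms,
                    Verdict.DROPPED,
                    detail=f"support {len(passing_reps)} < {min_reps}",
                )
            )
    return retained, decisions


def _chain_representative(members: list[TranscriptModel]) -> TranscriptModel:
    """Merge same-chain transcripts: extreme outer boundaries, max FPKM."""
    first = members[0]
    start = min(t.start for t in members)
    end = max(t.end for t in members)
    exons = [GenomicInterval(e.chrom, e.start, e.end, e.strand) for e in first.exons]
    exons[0] = GenomicInterval(first.chrom, start, exons[0].end, first.strand)
    exons[-1] = GenomicInterval(first.chrom, exons[-1].start, end, first.strand)
    fpkm: dict[str, float] = {}
    for t in members:
        for sample, v in t.fpkm.items():
            fpkm[sample] = max(fpkm.get(sample, 0.0), v)
    return TranscriptModel(
        transcript_id=first.transcript_id,
        gene_id=first.gene_id,
        exons=exons,
        fpkm=fpkm,
        source=first.source,
    )


def singleton_multiexons(
    rs: ReplicateSet, fpkm_min: float = 1.0
) -> list[TranscriptModel]:
    """Multi-exon transcripts whose chain appears (passing) in exactly one
    replicate — the rescue rule's candidates."""
    groups: dict[tuple, list[tuple[int, TranscriptModel]]] = {}
    for rep_idx, asm in enumerate(rs.assemblies):
        for t in asm.transcripts():
            if t.is_monoexon or t.strand == ".":
                continue
            groups.setdefault(intron_chain(t).key, []).append((rep_idx, t))
    out = []
    for key in sorted(groups, key=repr):
        members = groups[key]
        passing = {r for r, t in members if _passes(t, fpkm_min)}
        seen = {r for r, _ in members}
        if len(seen) == 1 and len(passing) <= 1:
            out.append(_chain_representative([t for _, t in members]))
    return out


def rescue_superchain(
    singletons: list[TranscriptModel],
    supported_novel: list[TranscriptModel],
) -> tuple[list[TranscriptModel], list[TranscriptModel], list[SupportDecision]]:
    """One-pass rescue: a singleton A whose intron set is a proper superset of
    a supported novel B's intron set (same chrom+strand, strictly more exons)
    is rescued; B is superseded.

    Returns (rescued, superseded, decisions).
    """
    rescued: list[TranscriptModel] = []
    superseded: list[TranscriptModel] = []
    superseded_ids: set[str] = set()
    decisions: list[SupportDecision] = []
    for a in singletons:
        a_chain = intron_chain(a)
        a_set = a_chain.intron_set()
        hit = False
        for b in supported_novel:
            if (b.chrom, b.strand) != (a.chrom, a.strand):
                continue
            b_set = intron_chain(b).intron_set()
            if b_set < a_set:  # proper subset => A has strictly more exons
                hit = True
                if b.transcript_id in superseded_ids:
                    continue
                superseded.append(b)
                superseded_ids.add(b.transcript_id)
                decisions.append(
                    SupportDecision(
                        _chain_label(intron_chain(b)),
                        0,
                        [],
                        Verdict.DROPPED_SUPERSEDED,
                        detail=f"superseded by {a.transcript_id}",
                    )
                )
        if hit:
            rescued.append(a)
            decisions.append(
                SupportDecision(_chain_label(a_chain), 1, [], Verdict.RESCUED)
            )
    return rescued, superseded, decisions


def consolidate_monoexon(
    rs: ReplicateSet, fpkm_min: float = 1.0
) -> tuple[list[TranscriptModel], list[SupportDecision]]:
    """Single-linkage overlap clusters of mono-exon transcripts on the same
    chrom+strand; a cluster is retained iff every replicate contributes a
    member with FPKM strictly > fpkm_min.  Boundaries = extremes over all
    cluster members."""
    by_cs: dict[tuple[str, str], list[tuple[int, TranscriptModel]]] = {}
    for rep_idx, asm in enumerate(rs.assemblies):
        for t in asm.transcripts():
            if not t.is_monoexon:
                continue
            if t.strand == ".":
                log.warning("%s: unstranded mono-exon excluded", t.transcript_id)
                continue
            by_cs.setdefault((t.chrom, t.strand), []).append((rep_idx, t))

    retained: list[TranscriptModel] = []
    decisions: list[SupportDecision] = []
    for (chrom, strand) in sorted(by_cs):
        members = sorted(by_cs[(chrom, strand)], key=lambda rt: (rt[1].start, rt[1].end))
        cluster: list[tuple[int, TranscriptModel]] = []
        cluster_end = -1
        clusters: list[list[tuple[int, TranscriptModel]]] = []
        for rep_idx, t in members:
            if cluster and t.start < cluster_end:
                cluster.append((rep_idx, t))
                cluster_end = max(cluster_end, t.end)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster = [(rep_idx, t)]
                cluster_end = t.end
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            passing_reps = {r for r, t in cl if _passes(t, fpkm_min)}
            label = f"{chrom}{strand}:[{min(t.start for _, t in cl)},{max(t.end for _, t in cl)})"
            passing_fpkms = sorted(
                max(t.fpkm.values()) for _, t in cl if _passes(t, fpkm_min)
            )
            if len(passing_reps) == rs.n_reps:
                start = min(t.start for _, t in cl)
                end = max(t.end for _, t in cl)
                rep = cl[0][1]
                fpkm: dict[str, float] = {}
                for _, t in cl:
                    for sample, v in t.fpkm.items():
                        fpkm[sample] = max(fpkm.get(sample, 0.0), v)
                retained.append(
                    TranscriptModel(
                        transcript_id=rep.transcript_id,
                        gene_id=rep.gene_id,
                        exons=[GenomicInterval(chrom, start, end, strand)],
                        fpkm=fpkm,
                        source=rep.source,
                    )
                )
                decisions.append(
                    SupportDecision(label, len(passing_reps), passing_fpkms, Verdict.RETAINED)
                )
            else:
                decisions.append(
                    SupportDecision(
                        label,
                        len(passing_reps),
                        passing_fpkms,
                        Verdict.DROPPED,
                        detail=f"mono-exon support {len(passing_reps)}/{rs.n_reps}",
                    )
                )
    return retained, decisions


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _cluster_genes(transcripts: list[TranscriptModel], prefix: str = "GENE.") -> Annotation:
    """Single-linkage clustering by >=1 bp exonic overlap on the same strand.

    Gene ids are assigned ``{prefix}{n}`` in (chrom, start) order; if any
    cluster member carries a reference gene id (non-assembly source), that id
    is preserved for the cluster.
    """
    by_cs: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_cs.setdefault((t.chrom, t.strand), []).append(t)

    clusters: list[list[TranscriptModel]] = []
    for cs in sorted(by_cs):
        ts = sorted(by_cs[cs], key=lambda t: (t.start, t.end, t.transcript_id))
        parent = list(range(len(ts)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                if ts[j].start >= ts[i].end:
                    break  # sorted by start; no later span can overlap ts[i]
                if any(
                    e1.start < e2.end and e2.start < e1.end
                    for e1 in ts[i].exons
                    for e2 in ts[j].exons
                ):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups: dict[int, list[TranscriptModel]] = {}
        for i, t in enumerate(ts):
            groups.setdefault(find(i), []).append(t)
        clusters.extend(groups[r] for r in sorted(groups))

    clusters.sort(key=lambda cl: (cl[0].chrom, min(t.start for t in cl)))
    genes: list[GeneModel] = []
    used_ids: set[str] = set()
    counter = 1
    for cl in clusters:
        ref_ids = sorted(
            {t.gene_id for t in cl if t.source not in (Source.ASSEMBLY, Source.NOVEL)}
        )
        if ref_ids and ref_ids[0] not in used_ids:
            gid = ref_ids[0]
        else:
            gid = f"{prefix}{counter}"
            counter += 1
            while gid in used_ids:
                gid = f"{prefix}{counter}"
                counter += 1
        used_ids.add(gid)
        members = [
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=gid,
                exons=t.exons,
                fpkm=t.fpkm,
                source=t.source,
                cds=t.cds,
            )
            for t in cl
        ]
        genes.append(GeneModel(gid, members))
    return Annotation(genes=genes)


def merge_transcript_sets(sets: list[Annotation], gene_prefix: str = "MRG.") -> Annotation:
    """Collapse identical intron chains (extreme boundaries) and overlapping
    same-strand mono-exon transcripts (union interval); rebuild genes by
    exon-overlap clustering.  Associative and idempotent."""
    if not sets:
        raise ValueError("need at least one annotation")
    multi: dict[tuple, list[TranscriptModel]] = {}
    mono: list[TranscriptModel] = []
    for a in sets:
        for t in a.transcripts():
            if t.is_monoexon:
                mono.append(t)
            else:
                multi.setdefault(intron_chain(t).key, []).append(t)

    merged: list[TranscriptModel] = []
    for key in sorted(multi, key=repr):
        merged.append(_chain_representative(multi[key]))

    by_cs: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in mono:
        by_cs.setdefault((t.chrom, t.strand), []).append(t)
    for cs in sorted(by_cs):
        ts = sorted(by_cs[cs], key=lambda t: (t.start, t.end))
        cluster: list[TranscriptModel] = []
        cluster_end = -1
        for t in ts + [None]:  # type: ignore[list-item]
            if t is not None and cluster and t.start < cluster_end:
                cluster.append(t)
                cluster_end = max(cluster_end, t.end)
            else:
                if cluster:
                    chrom, strand = cs
                    start = min(x.start for x in cluster)
                    end = max(x.end for x in cluster)
                    fpkm: dict[str, float] = {}
                    for x in cluster:
                        for sample, v in x.fpkm.items():
                            fpkm[sample] = max(fpkm.get(sample, 0.0), v)
                    first = cluster[0]
                    merged.append(
                        TranscriptModel(
                            transcript_id=first.transcript_id,
                            gene_id=first.gene_id,
                            exons=[GenomicInterval(chrom, start, end, strand)],
                            fpkm=fpkm,
                            source=first.source,
                        )
                    )
                if t is not None:
                    cluster = [t]
                    cluster_end = t.end

    # de-duplicate transcript ids deterministically
    seen: set[str] = set()
    unique: list[TranscriptModel] = []
    for t in sorted(merged, key=lambda t: (t.chrom, t.start, t.end, t.transcript_id)):
        tid = t.transcript_id
        n = 1
        while tid in seen:
            n += 1
            tid = f"{t.transcript_id}~{n}"
        seen.add(tid)
        if tid != t.transcript_id:
            t = TranscriptModel(tid, t.gene_id, t.exons, t.fpkm, t.source, t.cds)
        unique.append(t)
    return _cluster_genes(unique, prefix=gene_prefix)


def build_condition_transcriptome(
    rs: ReplicateSet,
    min_len: int = 200,
    fpkm_min: float = 1.0,
    min_reps: int = 2,
    references: list[Annotation] | None = None,
) -> tuple[Annotation, list[SupportDecision]]:
    """Full per-condition pipeline: support filter, rescue, mono-exon rule,
    merge, then drop transcripts not strictly longer than min_len bases.

    ``references`` restrict the rescue rule to transcripts that are novel
    (chain/interval absent from every reference); with no references all
    assembled transcripts count as novel.
    """
    multi, decisions = filter_multiexon_support(rs, fpkm_min, min_reps)
    ref_chains: set[tuple] = set()
    for ref in references or []:
        for t in ref.transcripts():
            if not t.is_monoexon:
                ref_chains.add(intron_chain(t).key)
    supported_novel = [t for t in multi if intron_chain(t).key not in ref_chains]

    singles = singleton_multiexons(rs, fpkm_min)
    singles = [t for t in singles if intron_chain(t).key not in ref_chains]
    rescued, superseded, resc_dec = rescue_superchain(singles, supported_novel)
    decisions.extend(resc_dec)
    superseded_ids = {t.transcript_id for t in superseded}
    multi = [t for t in multi if t.transcript_id not in superseded_ids] + rescued

    mono, mono_dec = consolidate_monoexon(rs, fpkm_min)
    decisions.extend(mono_dec)

    pool = multi + mono
    if not pool:
        log.warning("condition %s: empty consolidated transcriptome", rs.condition)
        return Annotation(genes=[], provenance=rs.condition), decisions
    merged = merge_transcript_sets([_cluster_genes(pool)])

    kept: list[TranscriptModel] = []
    for t in merged.transcripts():
        if t.length > min_len:
            kept.append(t)
        else:
            decisions.append(
                SupportDecision(
                    t.transcript_id, 0, [], Verdict.DROPPED,
                    detail=f"length {t.length} <= {min_len}",
                )
            )
    out = _cluster_genes(kept) if kept else Annotation(genes=[])
    out.provenance = rs.condition
    return out, decisions


def combine_with_reference(
    novel: Annotation,
    references: list[Annotation],
    prefix: str = "RTRG.",
) -> Annotation:
    """Combine assembled transcripts with reference annotations.

    Reference transcripts keep their ids.  Assembled transcripts that match a
    reference transcript (identical intron chain; mono-exon: interval within
    an exon-overlapping same-strand reference transcript) are represented by
    the reference entry.  The rest are added as novel with generated ids
    ``{prefix}{gene}.{n}``; genes are rebuilt by exon-overlap clustering,
    reference gene ids win where present.
    """
    ref_transcripts: list[TranscriptModel] = []
    seen_tids: set[str] = set()
    ref_chains: set[tuple] = set()
    for ref in references:
        for t in ref.transcripts():
            if t.transcript_id in seen_tids:
                log.warning("duplicate reference transcript id %s; first wins", t.transcript_id)
                continue
            seen_tids.add(t.transcript_id)
            src = t.source if t.source != Source.ASSEMBLY else Source.ENSEMBL
            t = TranscriptModel(t.transcript_id, t.gene_id, t.exons, t.fpkm, src, t.cds)
            ref_transcripts.append(t)
            if not t.is_monoexon:
                ref_chains.add(intron_chain(t).key)

    def matches_reference(t: TranscriptModel) -> bool:
        if not t.is_monoexon:
            return intron_chain(t).key in ref_chains
        for r in references:
            for rt in r.transcripts():
                if (rt.chrom, rt.strand) != (t.chrom, t.strand):
                    continue
                exon_overlap = any(t.exons[0].overlap(e) > 0 for e in rt.exons)
                if exon_overlap and rt.start <= t.start and t.end <= rt.end:
                    return True
        return False

    additions = [
        t for t in novel.transcripts() if not matches_reference(t)
    ]
    additions = [
        TranscriptModel(t.transcript_id, t.gene_id, t.exons, t.fpkm, Source.NOVEL, t.cds)
        for t in additions
    ]
    combined = _cluster_genes(ref_transcripts + additions, prefix=prefix.rstrip(".") + ".")

    # regenerate novel transcript ids as {gene_id}.{n}
    genes: list[GeneModel] = []
    for g in combined.genes:
        members: list[TranscriptModel] = []
        n = 0
        for t in sorted(g.transcripts, key=lambda t: (t.start, t.end, t.transcript_id)):
            if t.source == Source.NOVEL:
                n += 1
                t = TranscriptModel(f"{g.gene_id}.{n}", t.gene_id, t.exons, t.fpkm, t.source, t.cds)
            members.append(t)
        genes.append(GeneModel(g.gene_id, members))
    return Annotation(genes=genes, provenance="combined")
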