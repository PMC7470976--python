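"""Consensus coding-potential classification from three evidence channels.

A transcript is coding with high confidence iff it simultaneously passes all
three tests (score above the configured cutoff, >= 1 domain hit, best protein
alignment with e-value below the threshold); noncoding with high confidence
iff it fails all three; everything else is ambiguous.  Unknown evidence fails
closed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable


@dataclass(frozen=True)
class ProteinHit:
    subject_id: str
    species: str
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("e-value must be positive")


@dataclass
class CodingEvidence:
    transcript_id: str
    score: float | None          # None = unknown (fails closed)
    cutoff: float
    has_domain: bool
    best_hit: ProteinHit | None

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")


class VerdictClass(str, Enum):
    CODING = "coding_high_confidence"
    NONCODING = "noncoding_high_confidence"
    AMBIGUOUS = "ambiguous"


@dataclass
class CodingVerdict:
    transcript_id: str
    verdict: VerdictClass
    passes: tuple[bool, bool, bool]  # (score, domain, alignment)
    score_known: bool = True


def classify(e: CodingEvidence, evalue_max: float = 1e-5) -> CodingVerdict:
    """Three-test consensus; strict comparisons throughout."""
    p_score = e.score is not None and e.score > e.cutoff
    p_domain = e.has_domain
    p_hit = e.best_hit is not None and e.best_hit.evalue < evalue_max
    passes = (p_score, p_domain, p_hit)
    if all(passes):
        verdict = VerdictClass.CODING
    elif not any(passes):
        verdict = VerdictClass.NONCODING
    else:
        verdict = VerdictClass.AMBIGUOUS
    return CodingVerdict(e.transcript_id, verdict, passes, score_known=e.score is not None)


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------

def _species_from_subject(subject_id: str) -> str:
    """UniProt-style ids carry the organism mnemonic after the last '_'
    (e.g. 'sp|P12345|ALBU_MOUSE' -> 'MOUSE')."""
    tail = subject_id.rsplit("|", 1)[-1]
    if "_" in tail:
        return tail.rsplit("_", 1)[-1]
    return "unknown"


def load_evidence(
    cpat_table,
    domain_table,
    hits_table,
    cutoff: float = 0.364,
) -> dict[str, CodingEvidence]:
    """Assemble per-transcript evidence from three tabular files.

    * cpat_table — TSV with header, columns ``transcript_id`` and
      ``coding_prob``;
    * domain_table — TSV with header whose first column is the transcript id;
      any row means the transcript has >= 1 domain hit;
    * hits_table — 12-column tabular alignment format (qseqid sseqid pident
      length mismatch gapopen qstart qend sstart send evalue bitscore), an
      optional 13th column naming the subject species.

    A transcript missing from a table gets that channel as unknown/fail.
    The best hit is the row with the lowest e-value.
    """
    scores: dict[str, float] = {}
    with open(cpat_table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            id_col = header.index("transcript_id")
            score_col = header.index("coding_prob")
        except ValueError as exc:
            raise ValueError(f"{cpat_table}: need transcript_id and coding_prob columns") from exc
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                scores[fields[id_col]] = float(fields[score_col])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{cpat_table}: unparseable row {lineno}") from exc

    domains: set[str] = set()
    with open(domain_table) as fh:
        fh.readline()  # header
        for line in fh:
            if line.strip():
                domains.add(line.split("\t")[0].strip())

    hits: dict[str, ProteinHit] = {}
    with open(hits_table) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"{hits_table}: row {lineno} has fewer than 12 columns")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{hits_table}: unparseable row {lineno}") from exc
            species = fields[12] if len(fields) > 12 else _species_from_subject(sid)
            hit = ProteinHit(sid, species, evalue, pident)
            if qid not in hits or hit.evalue < hits[qid].evalue:
                hits[qid] = hit

    out: dict[str, CodingEvidence] = {}
    for tid in sorted(set(scores) | domains | set(hits)):
        out[tid] = CodingEvidence(
            transcript_id=tid,
            score=scores.get(tid),
            cutoff=cutoff,
            has_domain=tid in domains,
            best_hit=hits.get(tid),
        )
    return out


def classify_all(
    evidence: dict[str, CodingEvidence], evalue_max: float = 1e-5
) -> dict[str, CodingVerdict]:
    return {tid: classify(e, evalue_max) for tid, e in sorted(evidence.items())}


def species_tally(evidence: Iterable[CodingEvidence]) -> Counter:
    """Histogram of best-hit subject species."""
    return Counter(e.best_hit.species for e in evidence if e.best_hit is not None)


# ---------------------------------------------------------------------------
# ORF scan (stand-in scorer for synthetic evidence)
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(sequence: str) -> tuple[int, int, int] | None:
    """Longest ATG..stop open reading frame over the three forward frames.

    Returns (start, end, n_codons) with ``end`` past the stop codon and
    ``n_codons`` excluding the stop; ties broken by leftmost start.  None when
    no complete ORF exists.
    """
    seq = sequence.upper()
    best: tuple[int, int, int] | None = None
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                n_codons = (i - start) // 3
                if best is None or n_codons > best[2] or (
                    n_codons == best[2] and start < best[0]
                ):
                    best = (start, i + 3, n_codons)
                start = None
    return best
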