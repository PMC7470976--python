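"""Cross-species splice-junction conservation testing.

A junction context is the spliced +/-k exonic bases around one splice
junction (default k=6, 12 nt), strand-corrected to transcript orientation,
with an optional in-frame peptide when the junction lies inside an annotated
CDS.  Contexts are compared with a built-in Needleman-Wunsch/Gotoh global
aligner (affine gaps; nucleotide or protein scoring) and rejected when

* more than one gap column occurs in the alignment,
* nucleotide identity < 80 %,
* protein identity < 80 % or protein similarity < 90 %.

Protein similarity uses five residue groups only — aliphatic I,L,V;
aromatic F,Y,W,H; positive H,K,R; negative D,E; tiny A,C,T,S,G — residues
outside every group are similar only to themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .annotation_model import Annotation, TranscriptModel, revcomp

RESIDUE_GROUPS = (
    frozenset("ILV"),    # aliphatic
    frozenset("FYWH"),   # aromatic
    frozenset("HKR"),    # positive
    frozenset("DE"),     # negative
    frozenset("ACTSG"),  # tiny
)

_NT_MATRIX = substitution_matrices.load("NUC.4.4")
_AA_MATRIX = substitution_matrices.load("BLOSUM62")
_NEG_INF = float("-inf")


def residues_similar(a: str, b: str) -> bool:
    return a == b or any(a in g and b in g for g in RESIDUE_GROUPS)


@dataclass(frozen=True)
class Junction:
    """Splice junction keyed by genomic coordinates.

    ``donor`` is the last exonic base of the genomic-left exon, ``acceptor``
    the first exonic base of the genomic-right exon (0-based); transcript
    orientation is handled at sequence extraction.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if self.acceptor <= self.donor + 1:
            raise ValueError(f"degenerate junction {self}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.donor, self.acceptor, self.strand)

    @property
    def intron(self) -> tuple[int, int]:
        return (self.donor + 1, self.acceptor)


@dataclass
class JunctionContext:
    junction: Junction
    nt_fragment: str
    peptide: str | None = None
    truncated: bool = False
    edge_fallback: bool = False  # junction within 2 nt of a CDS edge

    @property
    def in_cds(self) -> bool:
        return self.peptide is not None


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float       # % of columns with identical residues
    similarity: float     # protein mode: % identical or co-grouped columns
    gap_columns: int
    mode: str

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# global alignment (Needleman-Wunsch with affine gaps, Gotoh)
# ---------------------------------------------------------------------------

def _check_alphabet(seq: str, matrix, mode: str) -> None:
    alphabet = set(matrix.alphabet)
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise AlignmentError(f"invalid {mode} character {ch!r} at position {pos}")


def global_align(
    a: str,
    b: str,
    mode: str = "nucleotide",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment; a gap of length L costs
    ``gap_open + L * gap_extend``.

    Tie-breaking is deterministic: diagonal is preferred over a gap in the
    second sequence ("up"), which is preferred over a gap in the first
    ("left"), both for the dynamic program and the traceback.
    """
    if not a or not b:
        raise AlignmentError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    matrix = _NT_MATRIX if mode == "nucleotide" else _AA_MATRIX
    _check_alphabet(a, matrix, mode)
    _check_alphabet(b, matrix, mode)
    n, m = len(a), len(b)
    go, ge = gap_open, gap_extend

    # state matrices: M diagonal, X gap in b (consumes a), Y gap in a
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(go + i * ge)
    for j in range(1, m + 1):
        Y[0][j] = -(go + j * ge)

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = matrix[ai, b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] - (go + ge),
                X[i - 1][j] - ge,
                Y[i - 1][j] - (go + ge),
            )
            Y[i][j] = max(
                M[i][j - 1] - (go + ge),
                X[i][j - 1] - (go + ge),
                Y[i][j - 1] - ge,
            )

    # traceback, preference M (diagonal) > X (up) > Y (left)
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: ({"M": M, "X": X, "Y": Y}[st][i][j], st == "M", st == "X"))
    score = {"M": M, "X": X, "Y": Y}[state][i][j]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = matrix[a[i - 1], b[j - 1]]
            prev = M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]
            target = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = ("M", "X", "Y")[_argmax_pref(prev, target)]
        elif state == "X":
            opts = (
                M[i - 1][j] - (go + ge),
                X[i - 1][j] - ge,
                Y[i - 1][j] - (go + ge),
            )
            target = X[i][j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            state = ("M", "X", "Y")[_argmax_pref(opts, target)] if (i, j) != (0, 0) else "M"
        else:
            opts = (
                M[i][j - 1] - (go + ge),
                X[i][j - 1] - (go + ge),
                Y[i][j - 1] - ge,
            )
            target = Y[i][j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            state = ("M", "X", "Y")[_argmax_pref(opts, target)] if (i, j) != (0, 0) else "M"

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return _result(aligned_a, aligned_b, score, mode)


def _argmax_pref(options: Sequence[float], target: float) -> int:
    """First option (preference order) matching the achieved score."""
    for k, v in enumerate(options):
        if abs(v - target) < 1e-9:
            return k
    return max(range(len(options)), key=lambda k: options[k])


def _result(aligned_a: str, aligned_b: str, score: float, mode: str) -> AlignmentResult:
    columns = len(aligned_a)
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    gaps = sum(1 for x, y in zip(aligned_a, aligned_b) if x == "-" or y == "-")
    identity = 100.0 * matches / columns
    if mode == "protein":
        similar = sum(
            1
            for x, y in zip(aligned_a, aligned_b)
            if x != "-" and y != "-" and residues_similar(x, y)
        )
        similarity = 100.0 * similar / columns
    else:
        similarity = identity
    return AlignmentResult(aligned_a, aligned_b, score, identity, similarity, gaps, mode)


# ---------------------------------------------------------------------------
# context extraction
# ---------------------------------------------------------------------------

def transcript_junctions(t: TranscriptModel) -> list[Junction]:
    return [
        Junction(t.chrom, a.end - 1, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def _cds_offsets(t: TranscriptModel) -> tuple[list[tuple[int, int]], int] | None:
    """CDS segments in genomic order plus total CDS length."""
    if not t.cds:
        return None
    segs = sorted(((seg.start, seg.end) for seg, _ in t.cds))
    return segs, sum(e - s for s, e in segs)


def extract_junction_contexts(
    t: TranscriptModel, genome: Mapping[str, str], k: int = 6
) -> list[JunctionContext]:
    """One context per junction of a multi-exon transcript.

    The nucleotide fragment is the last k exonic bases of the upstream exon
    plus the first k of the downstream exon, in transcript orientation
    (minus-strand fragments are reverse-complemented, sides swapped).  The
    peptide covers the codon-padded -k..+k window and is present only for
    junctions inside the annotated CDS, at least 2 nt from its edges.
    """
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} missing from genome")
    seq = genome[t.chrom]
    contexts: list[JunctionContext] = []
    cds_info = _cds_offsets(t)
    for idx, (left, right) in enumerate(zip(t.exons, t.exons[1:])):
        junction = Junction(t.chrom, left.end - 1, right.start, t.strand)
        l_take = min(k, len(left))
        r_take = min(k, len(right))
        frag = seq[left.end - l_take : left.end] + seq[right.start : right.start + r_take]
        truncated = l_take < k or r_take < k
        if t.strand == "-":
            frag = revcomp(frag)
        peptide, edge_fallback = _junction_peptide(t, seq, left.end, cds_info, k)
        contexts.append(
            JunctionContext(junction, frag, peptide, truncated, edge_fallback)
        )
    return contexts


def _junction_peptide(
    t: TranscriptModel,
    seq: str,
    intron_start: int,
    cds_info: tuple[list[tuple[int, int]], int] | None,
    k: int,
) -> tuple[str | None, bool]:
    if cds_info is None:
        return None, False
    segs, total = cds_info
    upstream = sum(e - s for s, e in segs if e <= intron_start)
    # offset of the junction along the spliced CDS in transcript orientation
    p = upstream if t.strand != "-" else total - upstream
    if p <= 0 or p >= total:
        return None, False  # junction outside the CDS
    if p < 2 or total - p < 2:
        return None, True  # too close to a CDS edge: nucleotide fallback
    cds_seq = "".join(seq[s:e] for s, e in segs)
    if t.strand == "-":
        cds_seq = revcomp(cds_seq)
    lo = max(0, ((p - k) // 3) * 3)
    hi = min(total, -((-(p + k)) // 3) * 3)
    window = cds_seq[lo:hi]
    window = window[: (len(window) // 3) * 3]
    if not window:
        return None, True
    return str(Seq(window).translate()), False


# ---------------------------------------------------------------------------
# conservation testing
# ---------------------------------------------------------------------------

@dataclass
class ConservationCall:
    conserved: bool
    best: AlignmentResult | None
    reason: str  # empty when conserved


def _reject_reason(r: AlignmentResult, max_gap_columns: int) -> str:
    if r.gap_columns > max_gap_columns:
        return "gaps"
    if r.mode == "nucleotide":
        if r.identity < 80.0:
            return "nt_identity"
    else:
        if r.identity < 80.0:
            return "protein_identity"
        if r.similarity < 90.0:
            return "protein_similarity"
    return ""


def test_junction_conservation(
    q: JunctionContext,
    homolog_contexts: Sequence[JunctionContext],
    mode: str = "auto",
    max_gap_columns: int = 1,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> ConservationCall:
    """Conserved iff >= 1 homolog context alignment survives every rejection
    rule.  In ``auto`` mode each homolog is aligned in protein mode when both
    contexts carry a peptide, in nucleotide mode otherwise."""
    if not homolog_contexts:
        return ConservationCall(False, None, "no homolog junctions")
    best_pass: AlignmentResult | None = None
    best_fail: AlignmentResult | None = None
    fail_reason = ""
    for h in homolog_contexts:
        if mode == "auto":
            use = "protein" if (q.peptide and h.peptide) else "nucleotide"
        else:
            use = mode
        if use == "protein" and not (q.peptide and h.peptide):
            use = "nucleotide"
        qa = q.peptide if use == "protein" else q.nt_fragment
        ha = h.peptide if use == "protein" else h.nt_fragment
        r = global_align(qa, ha, mode=use, gap_open=gap_open, gap_extend=gap_extend)
        reason = _reject_reason(r, max_gap_columns)
        if not reason:
            if best_pass is None or r.score > best_pass.score:
                best_pass = r
        elif best_fail is None or r.score > best_fail.score:
            best_fail = r
            fail_reason = reason
    if best_pass is not None:
        return ConservationCall(True, best_pass, "")
    return ConservationCall(False, best_fail, fail_reason)


@dataclass
class ConservationReport:
    rows: list[dict] = field(default_factory=list)
    conserved_fraction: float = 0.0


def conservation_report(
    annotation: Annotation,
    genome: Mapping[str, str],
    homolog_map: Mapping[str, Sequence[JunctionContext]],
    mode: str = "auto",
    k: int = 6,
) -> ConservationReport:
    """Per-junction conservation table over all multi-exon transcripts.

    ``homolog_map`` maps gene id -> junction contexts of the homologous gene.
    Junctions are deduplicated by genomic key; a junction with no mapped
    homolog counts as not conserved.
    """
    rows: list[dict] = []
    seen: set[tuple] = set()
    n_conserved = 0
    for t in annotation.transcripts():
        if t.is_monoexon:
            continue
        for ctx in extract_junction_contexts(t, genome, k=k):
            if ctx.junction.key in seen:
                continue
            seen.add(ctx.junction.key)
            call = test_junction_conservation(
                ctx, homolog_map.get(t.gene_id, ()), mode=mode
            )
            if call.conserved:
                n_conserved += 1
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "junction": ctx.junction.key,
                    "mode": call.best.mode if call.best else "none",
                    "identity": call.best.identity if call.best else float("nan"),
                    "similarity": call.best.similarity if call.best else float("nan"),
                    "conserved": call.conserved,
                    "reason": call.reason,
                }
            )
    fraction = n_conserved / len(rows) if rows else 0.0
    return ConservationReport(rows=rows, conserved_fraction=fraction)
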