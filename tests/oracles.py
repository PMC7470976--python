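"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here re-derives expected results directly from the stated rules,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

from retra.annotation_model import GenomicInterval, TranscriptModel
from retra.as_events import ASEvent, EventType

# ---------------------------------------------------------------------------
# consolidation rules, restated naively
# ---------------------------------------------------------------------------

def chain_of(t: TranscriptModel) -> tuple:
    introns = tuple(
        (t.exons[i].end, t.exons[i + 1].start) for i in range(len(t.exons) - 1)
    )
    return (t.exons[0].chrom, t.exons[0].strand, introns)


def brute_multiexon_support(assemblies, fpkm_min=1.0, min_reps=2):
    """chain key -> (retained?, support count, (min start, max end))."""
    by_chain = defaultdict(list)
    for rep, asm in enumerate(assemblies):
        for t in asm.transcripts():
            if len(t.exons) >= 2 and t.strand != ".":
                by_chain[chain_of(t)].append((rep, t))
    out = {}
    for chain, members in by_chain.items():
        reps_passing = set()
        for rep, t in members:
            if t.fpkm and max(t.fpkm.values()) > fpkm_min:
                reps_passing.add(rep)
        retained = len(reps_passing) >= min_reps
        bounds = (
            min(t.exons[0].start for _, t in members),
            max(t.exons[-1].end for _, t in members),
        )
        out[chain] = (retained, len(reps_passing), bounds)
    return out


def brute_rescue(singleton_chains, supported_chains):
    """Return (rescued singleton chains, superseded supported chains).

    A singleton rescues iff its intron set is a proper superset of some
    supported chain's intron set on the same chrom+strand.
    """
    rescued, superseded = set(), set()
    for s in singleton_chains:
        s_set = set(s[2])
        for b in supported_chains:
            if (s[0], s[1]) != (b[0], b[1]):
                continue
            b_set = set(b[2])
            if b_set < s_set:
                rescued.add(s)
                superseded.add(b)
    return rescued, superseded


def brute_monoexon(assemblies, fpkm_min=1.0):
    """Connected components (overlap, same chrom+strand) of mono-exon
    transcripts; component retained iff every replicate contributes a
    passing member.  Returns set of retained (chrom, strand, start, end)."""
    items = []
    n_reps = len(assemblies)
    for rep, asm in enumerate(assemblies):
        for t in asm.transcripts():
            if len(t.exons) == 1 and t.strand != ".":
                e = t.exons[0]
                passing = bool(t.fpkm) and max(t.fpkm.values()) > fpkm_min
                items.append((e.chrom, e.strand, e.start, e.end, rep, passing))
    # BFS over the all-pairs overlap graph
    adj = defaultdict(set)
    for i, a in enumerate(items):
        for j, b in enumerate(items):
            if i < j and a[0] == b[0] and a[1] == b[1] and a[2] < b[3] and b[2] < a[3]:
                adj[i].add(j)
                adj[j].add(i)
    seen = set()
    retained = set()
    for i in range(len(items)):
        if i in seen:
            continue
        comp = {i}
        stack = [i]
        while stack:
            k = stack.pop()
            for nb in adj[k]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        reps_passing = {items[k][4] for k in comp if items[k][5]}
        if len(reps_passing) == n_reps:
            retained.add(
                (
                    items[i][0],
                    items[i][1],
                    min(items[k][2] for k in comp),
                    max(items[k][3] for k in comp),
                )
            )
    return retained


def brute_merge_keys(annotations):
    """Expected transcript keys after merging: one per distinct multi-exon
    chain (with extreme bounds) and one per mono-exon overlap component."""
    chains = defaultdict(list)
    monos = []
    for a in annotations:
        for t in a.transcripts():
            if len(t.exons) >= 2:
                chains[chain_of(t)].append((t.exons[0].start, t.exons[-1].end))
            else:
                e = t.exons[0]
                monos.append((e.chrom, e.strand, e.start, e.end))
    keys = set()
    for chain, bounds in chains.items():
        keys.add((chain, min(b[0] for b in bounds), max(b[1] for b in bounds)))
    # mono components
    adj = defaultdict(set)
    for i, a in enumerate(monos):
        for j, b in enumerate(monos):
            if i < j and a[0] == b[0] and a[1] == b[1] and a[2] < b[3] and b[2] < a[3]:
                adj[i].add(j)
                adj[j].add(i)
    seen = set()
    for i in range(len(monos)):
        if i in seen:
            continue
        comp = {i}
        stack = [i]
        while stack:
            k = stack.pop()
            for nb in adj[k]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        keys.add(
            (
                (monos[i][0], monos[i][1], ()),
                min(monos[k][2] for k in comp),
                max(monos[k][3] for k in comp),
            )
        )
    return keys


# ---------------------------------------------------------------------------
# alignment score oracle (independent Gotoh, score only)
# ---------------------------------------------------------------------------

def nw_score_oracle(a, b, matrix, gap_open=10.0, gap_extend=0.5):
    """Affine-gap global alignment score; gap of length L costs
    gap_open + L * gap_extend."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    prev = {
        (0, "M"): 0.0,
    }
    # full tables, dict-based on purpose (different shape from the package)
    M = {(0, 0): 0.0}
    X = {}
    Y = {}
    for i in range(1, n + 1):
        X[(i, 0)] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[(0, j)] = -(gap_open + j * gap_extend)

    def get(d, key):
        return d.get(key, NEG)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[(i, j)] = s + max(
                get(M, (i - 1, j - 1)), get(X, (i - 1, j - 1)), get(Y, (i - 1, j - 1))
            )
            X[(i, j)] = max(
                get(M, (i - 1, j)) - gap_open - gap_extend,
                get(X, (i - 1, j)) - gap_extend,
                get(Y, (i - 1, j)) - gap_open - gap_extend,
            )
            Y[(i, j)] = max(
                get(M, (i, j - 1)) - gap_open - gap_extend,
                get(X, (i, j - 1)) - gap_open - gap_extend,
                get(Y, (i, j - 1)) - gap_extend,
            )
    return max(get(M, (n, m)), get(X, (n, m)), get(Y, (n, m)))


# ---------------------------------------------------------------------------
# bitmap / per-base oracles
# ---------------------------------------------------------------------------

def bitmap_union_size(intervals):
    """Number of distinct bases covered by (chrom, start, end) intervals."""
    covered = set()
    for chrom, s, e in intervals:
        covered.update((chrom, p) for p in range(s, e))
    return len(covered)


def bitmap_tss_profile(anchors, peaks, flank):
    """Per-offset coverage fraction via explicit base membership."""
    peak_bases = set()
    for p in peaks:
        peak_bases.update((p.chrom, x) for x in range(p.start, p.end))
    width = 2 * flank + 1
    acc = [0.0] * width
    for a in anchors:
        for idx, off in enumerate(range(-flank, flank + 1)):
            pos = a.position + off if a.strand != "-" else a.position - off
            if (a.chrom, pos) in peak_bases:
                acc[idx] += 1
    return [v / len(anchors) for v in acc]


def bitmap_te_fraction(transcripts, te_intervals):
    te_bases = set()
    for iv in te_intervals:
        te_bases.update((iv.chrom, p) for p in range(iv.start, iv.end))
    num = 0
    denom = 0
    for t in transcripts:
        for e in t.exons:
            denom += e.end - e.start
            num += sum(1 for p in range(e.start, e.end) if (e.chrom, p) in te_bases)
    return num / denom if denom else 0.0


# ---------------------------------------------------------------------------
# transcript comparison oracle
# ---------------------------------------------------------------------------

def brute_match_class(query: TranscriptModel, reference) -> str:
    """Direct all-pairs classification, restating the precedence rules."""
    refs = [
        r
        for r in reference.transcripts()
        if r.chrom == query.chrom and r.strand == query.strand
        and r.start < query.end and query.start < r.end
    ]

    def exons_overlap(x, y):
        return any(
            e1.start < e2.end and e2.start < e1.end for e1 in x.exons for e2 in y.exons
        )

    if len(query.exons) == 1:
        for r in refs:
            if exons_overlap(query, r) and r.start <= query.start and query.end <= r.end:
                return "="
        return "u"
    qc = chain_of(query)[2]
    best = "u"
    rank = {"=": 0, "c": 1, "j": 2, "u": 3}
    for r in refs:
        if len(r.exons) == 1:
            continue
        rc = chain_of(r)[2]
        if rc == qc:
            return "="
        label = "u"
        for i in range(len(rc) - len(qc) + 1):
            if rc[i : i + len(qc)] == qc:
                label = "c"
                break
        if label == "u" and set(qc) & set(rc) and exons_overlap(query, r):
            label = "j"
        if rank[label] < rank[best]:
            best = label
    return best


# ---------------------------------------------------------------------------
# AS event structural predicates
# ---------------------------------------------------------------------------

def _span_exonic(t: TranscriptModel, lo: int, hi: int) -> bool:
    return any(e.start <= lo and hi <= e.end for e in t.exons)


def _has_intron(t: TranscriptModel, intron) -> bool:
    return intron in set(chain_of(t)[2])


def event_satisfies_predicate(ev: ASEvent, t1: TranscriptModel, t2: TranscriptModel) -> bool:
    """Check an emitted event label against its structural definition."""
    p1, p2 = ev.paths
    l, r = ev.region
    strand = ev.strand
    transcripts = (t1, t2)

    def owner(path):
        for t in transcripts:
            if set(path) <= set(chain_of(t)[2]):
                return t
        return None

    if ev.type is EventType.IR:
        short, long_ = (p1, p2) if len(p1) < len(p2) else (p2, p1)
        if len(short) != 0 or len(long_) != 1:
            return False
        intron = long_[0]
        # one path has the intron; the other is exonic across it
        t_with = owner(long_)
        t_without = t1 if t_with is t2 else t2
        return (
            t_with is not None
            and _has_intron(t_with, intron)
            and _span_exonic(t_without, intron[0], intron[1])
        )
    if ev.type is EventType.SE:
        one, two = (p1, p2) if len(p1) == 1 else (p2, p1)
        if len(one) != 1 or len(two) != 2:
            return False
        (d, a) = one[0]
        (d1, x), (y, a1) = two
        skipped_ok = d1 == d and a1 == a and x < y
        t_two = owner(two)
        return skipped_ok and t_two is not None and _span_exonic(t_two, x, y)
    if ev.type in (EventType.A5SS, EventType.A3SS):
        if len(p1) != 1 or len(p2) != 1:
            return False
        (d1, a1), (d2, a2) = p1[0], p2[0]
        donor_side_differs = (d1 != d2) and (a1 == a2)
        acceptor_side_differs = (d1 == d2) and (a1 != a2)
        if strand != "-":
            expect_donor = ev.type is EventType.A5SS
        else:
            expect_donor = ev.type is EventType.A3SS
        return donor_side_differs if expect_donor else acceptor_side_differs
    if ev.type is EventType.MXE:
        if len(p1) != 2 or len(p2) != 2:
            return False
        if p1[0][0] != p2[0][0] or p1[1][1] != p2[1][1]:
            return False
        e1 = (p1[0][1], p1[1][0])
        e2 = (p2[0][1], p2[1][0])
        return (e1[1] <= e2[0] or e2[1] <= e1[0]) and e1 != e2
    if ev.type in (EventType.AFE, EventType.ALE):
        if len(p1) != 1 or len(p2) != 1:
            return False
        (d1, a1), (d2, a2) = p1[0], p2[0]
        genomic_left_end = (ev.type is EventType.AFE) == (strand != "-")
        if genomic_left_end:
            if a1 != a2 or d1 == d2:
                return False
            ends = sorted({t1.start, t2.start})
            exon_a = (min(t1.start, t2.start), min(d1, d2))
            exon_b = (max(t1.start, t2.start), max(d1, d2))
            # terminal exons disjoint and the region reaches a transcript start
            return exon_a[1] <= exon_b[0] and l == min(t1.start, t2.start)
        else:
            if d1 != d2 or a1 == a2:
                return False
            exon_a = (min(a1, a2), min(t1.end, t2.end))
            exon_b = (max(a1, a2), max(t1.end, t2.end))
            return exon_a[1] <= exon_b[0] and r == max(t1.end, t2.end)
    if ev.type is EventType.COMPLEX:
        return True  # no structural claim
    return False


# ---------------------------------------------------------------------------
# ORF brute force
# ---------------------------------------------------------------------------

def brute_longest_orf(seq: str):
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in stops:
                cand = (i, j + 3, (j - i) // 3)
                if (
                    best is None
                    or cand[2] > best[2]
                    or (cand[2] == best[2] and cand[0] < best[0])
                ):
                    best = cand
                break
            j += 3
    return best


# ---------------------------------------------------------------------------
# small-instance builders
# ---------------------------------------------------------------------------

def make_transcript(tid, chain=None, exon=None, chrom="chr1", strand="+",
                    fpkm=None, gene=None, pad=10):
    """Build a transcript from an intron chain (or a single exon interval)."""
    if chain:
        exons = [GenomicInterval(chrom, chain[0][0] - pad, chain[0][0], strand)]
        for (a, b), (c, d) in zip(chain, chain[1:]):
            exons.append(GenomicInterval(chrom, b, c, strand))
        exons.append(GenomicInterval(chrom, chain[-1][1], chain[-1][1] + pad, strand))
    else:
        exons = [GenomicInterval(chrom, exon[0], exon[1], strand)]
    return TranscriptModel(
        tid, gene or tid + ".g", exons,
        fpkm={} if fpkm is None else {"s": fpkm},
    )


def all_chains(grid, max_introns):
    """Every intron chain with 1..max_introns introns over a sorted site grid."""
    out = []
    for k in range(1, max_introns + 1):
        for sites in itertools.combinations(grid, 2 * k):
            out.append(tuple((sites[2 * i], sites[2 * i + 1]) for i in range(k)))
    return out
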