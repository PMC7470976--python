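import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from retra.annotation_model import GenomicInterval, TranscriptModel, revcomp
from retra.junction_conservation import (
    AlignmentError,
    JunctionContext,
    Junction,
    conservation_report,
    extract_junction_contexts,
    global_align,
    residues_similar,
)
from retra.junction_conservation import test_junction_conservation as conservation_call
from retra import synthetic_data as sd

from oracles import nw_score_oracle

NT = substitution_matrices.load("NUC.4.4")
AA = substitution_matrices.load("BLOSUM62")


class TestGlobalAlign:
    def test_self_alignment(self):
        r = global_align("GTAAGT", "GTAAGT")
        assert r.identity == 100.0 and r.gap_columns == 0

    def test_residue_groups_hand_case(self):
        r = global_align("ILVK", "LLVR", mode="protein")
        assert r.identity == pytest.approx(50.0)
        assert r.similarity == pytest.approx(100.0)

    def test_invalid_character(self):
        with pytest.raises(AlignmentError, match="position 2"):
            global_align("AC!T", "ACGT")

    def test_empty_sequence(self):
        with pytest.raises(AlignmentError):
            global_align("", "ACGT")

    def test_exhaustive_two_letter_len5(self):
        seqs = ["".join(p) for L in range(1, 6) for p in itertools.product("AC", repeat=L)]
        for a in seqs:
            for b in seqs:
                got = global_align(a, b).score
                exp = nw_score_oracle(a, b, NT)
                assert got == pytest.approx(exp), (a, b)

    def test_random_longer_pairs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(300):
            a = "".join(bases[rng.integers(0, 4, int(rng.integers(6, 13)))])
            b = "".join(bases[rng.integers(0, 4, int(rng.integers(6, 13)))])
            assert global_align(a, b).score == pytest.approx(nw_score_oracle(a, b, NT))

    def test_protein_similarity_at_least_identity(self, rng):
        aas = np.array(list("ARNDCQEGHILKMFPSTWYV"))
        for _ in range(100):
            a = "".join(aas[rng.integers(0, 20, int(rng.integers(3, 10)))])
            b = "".join(aas[rng.integers(0, 20, int(rng.integers(3, 10)))])
            r = global_align(a, b, mode="protein")
            assert r.similarity >= r.identity

    def test_reversal_score_symmetry(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            a = "".join(bases[rng.integers(0, 4, 10)])
            b = "".join(bases[rng.integers(0, 4, 10)])
            assert global_align(a, b).score == pytest.approx(
                global_align(a[::-1], b[::-1]).score
            )

    def test_determinism(self):
        r1 = global_align("ACGTACGTACGT", "ACGTCGTACGT")
        r2 = global_align("ACGTACGTACGT", "ACGTCGTACGT")
        assert (r1.aligned_a, r1.aligned_b) == (r2.aligned_a, r2.aligned_b)


class TestGlobalAlignHypothesis:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    dna = st.text(alphabet="ACGT", min_size=1, max_size=10)

    @given(dna, dna)
    @settings(max_examples=150, deadline=None)
    def test_score_matches_oracle(self, a, b):
        assert global_align(a, b).score == pytest.approx(nw_score_oracle(a, b, NT))

    @given(dna, dna)
    @settings(max_examples=100, deadline=None)
    def test_identity_bounds_and_symmetric_score(self, a, b):
        r = global_align(a, b)
        assert 0.0 <= r.identity <= 100.0
        assert r.score == pytest.approx(global_align(b, a).score)


class TestResidueGroups:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("I", "L", True),   # aliphatic
            ("F", "H", True),   # aromatic
            ("H", "K", True),   # positive (H in two groups)
            ("D", "E", True),   # negative
            ("A", "G", True),   # tiny
            ("M", "L", False),  # M is in no group
            ("N", "Q", False),  # unlisted residues only match themselves
            ("M", "M", True),
        ],
    )
    def test_pairs(self, a, b, expected):
        assert residues_similar(a, b) is expected


class TestContextExtraction:
    def _genome(self):
        return {"chr1": "ACGTACGTGTAAGTACGTAGCTAGCTAGACGTACGTACGT" * 10}

    def test_plus_strand_fragment(self):
        g = {"chr1": "AAGGTTCCXXXXTTCCAAGG".replace("X", "G")}
        t = TranscriptModel(
            "t", "g",
            [GenomicInterval("chr1", 0, 8, "+"), GenomicInterval("chr1", 12, 20, "+")],
        )
        (ctx,) = extract_junction_contexts(t, g)
        assert ctx.nt_fragment == g["chr1"][2:8] + g["chr1"][12:18]

    def test_minus_strand_is_revcomp(self):
        g = self._genome()
        exons = [GenomicInterval("chr1", 10, 30, "+"), GenomicInterval("chr1", 100, 130, "+")]
        t_plus = TranscriptModel("p", "g", exons)
        t_minus = TranscriptModel(
            "m", "g", [GenomicInterval("chr1", e.start, e.end, "-") for e in exons]
        )
        (cp,) = extract_junction_contexts(t_plus, g)
        (cm,) = extract_junction_contexts(t_minus, g)
        assert cm.nt_fragment == revcomp(cp.nt_fragment)

    def test_short_exon_truncated(self):
        g = self._genome()
        t = TranscriptModel(
            "t", "g",
            [GenomicInterval("chr1", 10, 13, "+"), GenomicInterval("chr1", 100, 130, "+")],
        )
        (ctx,) = extract_junction_contexts(t, g)
        assert ctx.truncated and len(ctx.nt_fragment) == 9

    def test_no_cds_no_peptide(self):
        g = self._genome()
        t = TranscriptModel(
            "t", "g",
            [GenomicInterval("chr1", 10, 30, "+"), GenomicInterval("chr1", 100, 130, "+")],
        )
        (ctx,) = extract_junction_contexts(t, g)
        assert ctx.peptide is None and not ctx.in_cds

    def test_planted_cds_has_peptide(self, small_truth):
        coding = [
            t
            for t in small_truth.annotation.transcripts()
            if t.cds and not t.is_monoexon
        ]
        assert coding
        t = coding[0]
        contexts = extract_junction_contexts(t, small_truth.genome)
        in_cds = [c for c in contexts if c.in_cds]
        assert in_cds, "planted ORF spans at least one junction"
        for c in in_cds:
            assert len(c.peptide) >= 4

    def test_missing_chrom(self):
        t = TranscriptModel(
            "t", "g",
            [GenomicInterval("nope", 10, 30, "+"), GenomicInterval("nope", 100, 130, "+")],
        )
        with pytest.raises(KeyError):
            extract_junction_contexts(t, {"chr1": "ACGT"})


def _ctx(frag, peptide=None):
    return JunctionContext(Junction("chr1", 99, 200, "+"), frag, peptide)


class TestConservationRules:
    def test_identical_conserved(self):
        call = conservation_call(_ctx("GTAAGTACGTAC"), [_ctx("GTAAGTACGTAC")])
        assert call.conserved and call.best.identity == 100.0

    def test_two_gap_columns_rejected(self):
        # two inserted bases force >= 2 gap columns
        call = conservation_call(
            _ctx("AAAACCCCGGGG"), [_ctx("AAAACCCCGGGGTT")]
        )
        assert not call.conserved and call.reason == "gaps"

    def test_75_percent_identity_rejected(self):
        q = "AAAACCCCGGGG"
        h = "TAAACCTCGGTG"  # 3 substitutions, gapless optimum: 9/12 = 75%
        call = conservation_call(_ctx(q), [_ctx(h)])
        assert not call.conserved and call.reason == "nt_identity"
        assert call.best.identity == pytest.approx(75.0)

    def test_protein_similarity_rejected(self):
        q = "A" * 20
        h = "A" * 17 + "KKK"  # identity 85 >= 80, similarity 85 < 90
        call = conservation_call(
            _ctx("X", peptide=q), [_ctx("X", peptide=h)], mode="protein"
        )
        assert not call.conserved and call.reason == "protein_similarity"
        assert call.best.similarity == pytest.approx(85.0)

    def test_no_homologs(self):
        call = conservation_call(_ctx("GTAAGTACGTAC"), [])
        assert not call.conserved and call.reason == "no homolog junctions"

    def test_monotone_in_homolog_set(self):
        q = _ctx("GTAAGTACGTAC")
        bad = _ctx("TTTTTTTTTTTT")
        good = _ctx("GTAAGTACGTAC")
        assert not conservation_call(q, [bad]).conserved
        assert conservation_call(q, [bad, good]).conserved


class TestConservationReport:
    def test_all_identical_fraction_one(self, small_truth):
        homologs = sd.make_homolog_contexts(small_truth, 3, conserve_rate=1.0)
        rep = conservation_report(small_truth.annotation, small_truth.genome, homologs)
        assert rep.conserved_fraction == 1.0

    def test_empty_map_fraction_zero(self, small_truth):
        rep = conservation_report(small_truth.annotation, small_truth.genome, {})
        assert rep.conserved_fraction == 0.0

    def test_planted_rate_recovered_per_junction(self, small_truth):
        homologs = sd.make_homolog_contexts(small_truth, 17, conserve_rate=0.6)
        by_key = {
            c.junction.key: c for ctxs in homologs.values() for c in ctxs
        }
        seen = set()
        for t in small_truth.annotation.transcripts():
            if t.is_monoexon:
                continue
            for ctx in extract_junction_contexts(t, small_truth.genome):
                key = ctx.junction.key
                if key in seen:
                    continue
                seen.add(key)
                call = conservation_call(ctx, [by_key[key]])
                assert call.conserved == small_truth.conserved_junctions[key], key

    def test_gene_level_report_close_to_planted_rate(self, small_truth):
        # testing against every homolog junction of the gene can only add
        # conserved calls; the fraction stays within binomial error
        homologs = sd.make_homolog_contexts(small_truth, 17, conserve_rate=0.6)
        rep = conservation_report(small_truth.annotation, small_truth.genome, homologs)
        n = len(rep.rows)
        sd3 = 3 * (0.6 * 0.4 / n) ** 0.5
        assert abs(rep.conserved_fraction - 0.6) <= sd3 + 0.05
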