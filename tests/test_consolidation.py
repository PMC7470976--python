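import numpy as np
import pytest

from retra.annotation_model import Annotation, GeneModel, intron_chain
from retra.consolidation import (
    ReplicateSet,
    Verdict,
    build_condition_transcriptome,
    combine_with_reference,
    consolidate_monoexon,
    filter_multiexon_support,
    merge_transcript_sets,
    rescue_superchain,
    singleton_multiexons,
)
from retra import synthetic_data as sd

from oracles import (
    all_chains,
    brute_merge_keys,
    brute_monoexon,
    brute_multiexon_support,
    brute_rescue,
    chain_of,
    make_transcript,
)


def _annotation(transcripts):
    genes = {}
    order = []
    for t in transcripts:
        if t.gene_id not in genes:
            genes[t.gene_id] = []
            order.append(t.gene_id)
        genes[t.gene_id].append(t)
    return Annotation(genes=[GeneModel(g, genes[g]) for g in order])


def _random_replicate_set(rng, n_reps=4, max_tx=6, grid=(100, 150, 220, 300, 380, 450)):
    """Random small instance over a shared chain universe."""
    chains = all_chains(grid, 3)
    assemblies = []
    for r in range(n_reps):
        n = int(rng.integers(0, max_tx + 1))
        ts = []
        for i in range(n):
            strand = "+" if rng.random() < 0.8 else "-"
            fpkm = float(rng.choice([0.5, 0.9, 1.0, 1.01, 2.0, 5.0]))
            if rng.random() < 0.3:
                s = int(rng.choice(grid))
                ts.append(
                    make_transcript(
                        f"r{r}t{i}", exon=(s, s + int(rng.integers(50, 400))),
                        strand=strand, fpkm=fpkm,
                    )
                )
            else:
                chain = chains[int(rng.integers(0, len(chains)))]
                ts.append(
                    make_transcript(f"r{r}t{i}", chain=chain, strand=strand, fpkm=fpkm)
                )
        assemblies.append(_annotation(ts) if ts else Annotation())
    return ReplicateSet("rand", assemblies)


class TestMultiexonSupport:
    def test_retained_two_reps(self):
        reps = [
            _annotation([make_transcript("a", chain=((100, 200),), fpkm=2.0)]),
            _annotation([make_transcript("b", chain=((100, 200),), fpkm=3.0)]),
            Annotation(),
            Annotation(),
        ]
        retained, decisions = filter_multiexon_support(ReplicateSet("c", reps))
        assert len(retained) == 1
        assert decisions[0].verdict is Verdict.RETAINED

    def test_strict_threshold(self):
        reps = [
            _annotation([make_transcript("a", chain=((100, 200),), fpkm=1.0)]),
            _annotation([make_transcript("b", chain=((100, 200),), fpkm=0.9)]),
            Annotation(),
            Annotation(),
        ]
        retained, decisions = filter_multiexon_support(ReplicateSet("c", reps))
        assert retained == []
        assert decisions[0].verdict is Verdict.DROPPED

    def test_boundaries_are_extremes(self):
        reps = [
            _annotation([make_transcript("a", chain=((100, 200),), fpkm=2.0, pad=10)]),
            _annotation([make_transcript("b", chain=((100, 200),), fpkm=2.0, pad=30)]),
        ]
        retained, _ = filter_multiexon_support(ReplicateSet("c", reps))
        (t,) = retained
        assert (t.start, t.end) == (70, 230)

    def test_missing_fpkm_fails_closed(self):
        reps = [
            _annotation([make_transcript("a", chain=((100, 200),))]),
            _annotation([make_transcript("b", chain=((100, 200),), fpkm=2.0)]),
        ]
        retained, _ = filter_multiexon_support(ReplicateSet("c", reps))
        assert retained == []

    def test_oracle_equivalence_random(self, rng):
        for _ in range(150):
            rs = _random_replicate_set(rng)
            expected = brute_multiexon_support(rs.assemblies)
            retained, _ = filter_multiexon_support(rs)
            got = {
                intron_chain(t).key: (t.start, t.end) for t in retained
            }
            exp = {
                chain: bounds
                for chain, (keep, _, bounds) in expected.items()
                if keep
            }
            assert got == exp


class TestRescue:
    def test_canonical_rescue(self):
        a = make_transcript("A", chain=((100, 160), (220, 280), (340, 400)))
        b = make_transcript("B", chain=((100, 160), (220, 280)))
        rescued, superseded, decisions = rescue_superchain([a], [b])
        assert [t.transcript_id for t in rescued] == ["A"]
        assert [t.transcript_id for t in superseded] == ["B"]
        verdicts = {d.verdict for d in decisions}
        assert verdicts == {Verdict.RESCUED, Verdict.DROPPED_SUPERSEDED}

    def test_not_a_superset(self):
        a = make_transcript("A", chain=((100, 160), (340, 400)))
        b = make_transcript("B", chain=((100, 160), (220, 280)))
        rescued, superseded, _ = rescue_superchain([a], [b])
        assert rescued == [] and superseded == []

    def test_equal_chain_is_not_proper_superset(self):
        a = make_transcript("A", chain=((100, 160),))
        b = make_transcript("B", chain=((100, 160),))
        rescued, superseded, _ = rescue_superchain([a], [b])
        assert rescued == [] and superseded == []

    def test_strand_mismatch_ignored(self):
        a = make_transcript("A", chain=((100, 160), (220, 280)), strand="-")
        b = make_transcript("B", chain=((100, 160),))
        rescued, superseded, _ = rescue_superchain([a], [b])
        assert rescued == [] and superseded == []

    def test_oracle_equivalence_random(self, rng):
        chains = all_chains((100, 150, 220, 300, 380, 450), 3)
        for _ in range(200):
            singles = [
                make_transcript(f"s{i}", chain=chains[int(rng.integers(0, len(chains)))])
                for i in range(int(rng.integers(0, 4)))
            ]
            supported = [
                make_transcript(f"b{i}", chain=chains[int(rng.integers(0, len(chains)))])
                for i in range(int(rng.integers(0, 4)))
            ]
            rescued, superseded, _ = rescue_superchain(singles, supported)
            exp_rescued, exp_super = brute_rescue(
                {chain_of(t) for t in singles}, {chain_of(t) for t in supported}
            )
            assert {chain_of(t) for t in rescued} == exp_rescued
            assert {chain_of(t) for t in superseded} == exp_super


class TestMonoexon:
    def test_all_four_reps_boundaries(self):
        spans = [(100, 300), (120, 310), (110, 305), (100, 320)]
        reps = [
            _annotation([make_transcript(f"m{r}", exon=span, fpkm=2.0)])
            for r, span in enumerate(spans)
        ]
        retained, _ = consolidate_monoexon(ReplicateSet("c", reps))
        (t,) = retained
        assert (t.start, t.end) == (100, 320)

    def test_three_of_four_dropped(self):
        reps = [
            _annotation([make_transcript(f"m{r}", exon=(100, 300), fpkm=2.0)])
            for r in range(3)
        ] + [Annotation()]
        retained, decisions = consolidate_monoexon(ReplicateSet("c", reps))
        assert retained == []
        assert decisions[0].verdict is Verdict.DROPPED

    def test_oracle_equivalence_random(self, rng):
        for _ in range(150):
            rs = _random_replicate_set(rng)
            retained, _ = consolidate_monoexon(rs)
            got = {(t.chrom, t.strand, t.start, t.end) for t in retained}
            assert got == brute_monoexon(rs.assemblies)


class TestMerge:
    def test_same_chain_extreme_bounds(self):
        a = _annotation([make_transcript("a", chain=((100, 200),), pad=10)])
        b = _annotation([make_transcript("b", chain=((100, 200),), pad=20)])
        merged = merge_transcript_sets([a, b])
        (t,) = list(merged.transcripts())
        assert (t.start, t.end) == (80, 220)

    def test_monoexon_union(self):
        a = _annotation([make_transcript("a", exon=(0, 150))])
        b = _annotation([make_transcript("b", exon=(100, 250))])
        merged = merge_transcript_sets([a, b])
        (t,) = list(merged.transcripts())
        assert (t.start, t.end) == (0, 250)

    def test_associativity_random(self, rng):
        for _ in range(60):
            sets = [_random_replicate_set(rng, n_reps=3).assemblies for _ in range(1)][0]
            a, b, c = sets
            left = merge_transcript_sets([merge_transcript_sets([a, b]), c])
            flat = merge_transcript_sets([a, b, c])
            key = lambda ann: {
                (intron_chain(t).key, t.start, t.end) for t in ann.transcripts()
            }
            assert key(left) == key(flat)

    def test_idempotence(self, rng):
        rs = _random_replicate_set(rng)
        merged = merge_transcript_sets(rs.assemblies)
        again = merge_transcript_sets([merged])
        key = lambda ann: {
            (intron_chain(t).key, t.start, t.end) for t in ann.transcripts()
        }
        assert key(merged) == key(again)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(100):
            rs = _random_replicate_set(rng)
            merged = merge_transcript_sets(rs.assemblies)
            got = {(intron_chain(t).key, t.start, t.end) for t in merged.transcripts()}
            assert got == brute_merge_keys(rs.assemblies)


class TestConditionPipeline:
    def test_length_filter_strict(self):
        # mono-exon of exactly 201 vs 200 bases, present in all replicates
        reps_ok = [
            _annotation([make_transcript(f"a{r}", exon=(0, 201), fpkm=5.0)])
            for r in range(4)
        ]
        reps_short = [
            _annotation([make_transcript(f"b{r}", exon=(0, 200), fpkm=5.0)])
            for r in range(4)
        ]
        out_ok, _ = build_condition_transcriptome(ReplicateSet("c", reps_ok))
        out_short, _ = build_condition_transcriptome(ReplicateSet("c", reps_short))
        assert out_ok.n_transcripts == 1
        assert out_short.n_transcripts == 0

    def test_singleton_absent(self):
        reps = [
            _annotation(
                [
                    make_transcript("keep", chain=((100, 200), (300, 400)), fpkm=5.0, pad=60),
                    make_transcript("orphan", chain=((700, 800),), fpkm=5.0, pad=120),
                ]
            )
        ] + [
            _annotation(
                [make_transcript(f"k{r}", chain=((100, 200), (300, 400)), fpkm=5.0, pad=60)]
            )
            for r in range(3)
        ]
        out, _ = build_condition_transcriptome(ReplicateSet("c", reps))
        chains = {intron_chain(t).introns for t in out.transcripts()}
        assert ((700, 800),) not in chains
        assert ((100, 200), (300, 400)) in chains

    def test_noiseless_truth_recovery(self, small_truth):
        rs = sd.make_replicate_assemblies(small_truth, seed=7)
        out, _ = build_condition_transcriptome(rs)
        truth_keys = {
            (intron_chain(t).key, t.start, t.end)
            for t in small_truth.annotation.transcripts()
        }
        out_keys = {
            (intron_chain(t).key, t.start, t.end) for t in out.transcripts()
        }
        assert out_keys == truth_keys

    def test_monotone_in_fpkm_min(self, rng):
        for _ in range(20):
            rs = _random_replicate_set(rng)
            lo, _ = filter_multiexon_support(rs, fpkm_min=1.0)
            hi, _ = filter_multiexon_support(rs, fpkm_min=2.0)
            assert {intron_chain(t).key for t in hi} <= {
                intron_chain(t).key for t in lo
            }


class TestCombineWithReference:
    def _ref(self):
        return _annotation(
            [
                make_transcript("ENS1", chain=((100, 200), (300, 400)), gene="ENSG1"),
                make_transcript("ENS2", exon=(1000, 1400), gene="ENSG2"),
            ]
        )

    def test_matching_chain_uses_reference_id(self):
        novel = _annotation([make_transcript("n1", chain=((100, 200), (300, 400)))])
        out = combine_with_reference(novel, [self._ref()])
        tids = {t.transcript_id for t in out.transcripts()}
        assert tids == {"ENS1", "ENS2"}

    def test_non_matching_gets_generated_id(self):
        novel = _annotation([make_transcript("n1", chain=((5000, 5100),))])
        out = combine_with_reference(novel, [self._ref()])
        new = [t for t in out.transcripts() if t.transcript_id.startswith("RTRG.")]
        assert len(new) == 1

    def test_counting_invariant(self, rng):
        ref = self._ref()
        ref_chains = {chain_of(t)[2] for t in ref.transcripts() if len(t.exons) > 1}
        chains = all_chains((100, 200, 300, 400, 5000, 5100), 2)
        for _ in range(30):
            picks = [
                chains[int(rng.integers(0, len(chains)))]
                for _ in range(int(rng.integers(1, 5)))
            ]
            picks = list(dict.fromkeys(picks))
            novel = _annotation(
                [make_transcript(f"n{i}", chain=c) for i, c in enumerate(picks)]
            )
            out = combine_with_reference(novel, [ref])
            expected_new = sum(1 for c in picks if c not in ref_chains)
            assert out.n_transcripts == ref.n_transcripts + expected_new
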