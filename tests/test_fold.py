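"""Tests for the RNA folding application: grammar, partition function,
algebras and the Pareto fold."""

from __future__ import annotations

import math

import numpy as np
import pytest

from paretodp.engine import (
    check_monotone,
    counting_algebra,
    enumerate_candidates,
    evaluate,
    product_pareto,
)
from paretodp.fold import (
    FOLD_SIGNATURE,
    FoldGrammar,
    FoldModel,
    RNASequence,
    dot_bracket,
    energy_algebra,
    fold_pareto,
    mea_algebra,
    partition_pairprobs,
    structure_pairs,
)
from paretodp.pareto import OrderSpec
from paretodp.synth import SyntheticSpec, generate_sequences

from conftest import PARETO_COMBOS, naive_front

MODEL = FoldModel()


def random_seqs(n, length, seed, gc=0.5):
    return generate_sequences(
        SyntheticSpec(n_sequences=n, min_length=length, max_length=length,
                      gc_content=gc, seed=seed)
    )


def enum_structures(seq: RNASequence, model: FoldModel = MODEL):
    grammar = FoldGrammar(model)
    return enumerate_candidates(grammar, seq.residues)


def quantize(psi):
    """Round psi to multiples of 2^-20: sums of such values are exact in
    double precision, making DP-vs-enumeration comparisons order-independent."""
    return np.round(psi * 2**20) / 2**20


def score_structure(pairs, psi, model: FoldModel = MODEL):
    """Independent re-scoring of a structure from its pair set alone."""
    energy = 0.0
    mea = 0.0
    for (i, j) in pairs:
        energy += model.pair_energy
        if (i + 1, j - 1) in pairs:
            energy += model.stack_energy
        mea += float(psi[i, j])
    return energy, mea


class TestSequence:
    def test_parse_normalizes(self):
        s = RNASequence.parse("x", "acgt")
        assert s.residues == "ACGU"

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError, match="non-RNA"):
            RNASequence.parse("x", "ACGX")


class TestSearchSpace:
    def test_aaaa_single_open_chain(self):
        assert len(enum_structures(RNASequence.parse("s", "AAAA"))) == 1

    def test_gaaac_two_structures(self):
        cands = enum_structures(RNASequence.parse("s", "GAAAC"))
        assert len(cands) == 2
        pair_sets = {structure_pairs(c) for c in cands}
        assert pair_sets == {frozenset(), frozenset({(0, 4)})}

    def test_count_equals_enumeration_on_random_12mers(self):
        grammar = FoldGrammar(MODEL)
        for seq in random_seqs(8, 12, seed=5):
            count = evaluate(grammar, counting_algebra(FOLD_SIGNATURE), seq.residues)
            assert count == [len(enum_structures(seq))]

    def test_structures_satisfy_invariants(self):
        for seq in random_seqs(4, 10, seed=6):
            for cand in enum_structures(seq):
                pairs = structure_pairs(cand)
                positions = [p for ij in pairs for p in ij]
                assert len(positions) == len(set(positions))  # non-sharing
                for (i, j) in pairs:
                    assert j - i > MODEL.minloop
                    assert seq.residues[i] + seq.residues[j] in MODEL.pair_rule
                    for (k, l) in pairs:  # non-crossing
                        assert not (i < k < j < l)

    def test_no_lonely_pairs_flag(self):
        model = FoldModel(no_lonely_pairs=True)
        for seq in random_seqs(4, 12, seed=7, gc=0.8):
            lonely_free = {
                frozenset(structure_pairs(c))
                for c in enumerate_candidates(FoldGrammar(model), seq.residues)
            }
            # oracle: filter the unrestricted space for helices of length >= 2
            expected = set()
            for c in enum_structures(seq):
                pairs = structure_pairs(c)
                if all(
                    (i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs
                    for (i, j) in pairs
                ):
                    expected.add(frozenset(pairs))
            assert lonely_free == expected


class TestPartition:
    def test_aaaa_all_zero(self):
        psi = partition_pairprobs(RNASequence.parse("s", "AAAA"), MODEL)
        assert not psi.any()

    def test_gaaac_equal_weights_half(self):
        model = FoldModel(pair_energy=0.0, stack_energy=0.0)
        psi = partition_pairprobs(RNASequence.parse("s", "GAAAC"), model)
        assert psi[0, 4] == pytest.approx(0.5)
        assert psi[4, 0] == pytest.approx(0.5)

    def test_matches_enumeration_on_random_10mers(self):
        for seq in random_seqs(5, 10, seed=8, gc=0.7):
            psi = partition_pairprobs(seq, MODEL)
            n = len(seq)
            weights = np.zeros((n, n))
            z = 0.0
            for cand in enum_structures(seq):
                pairs = structure_pairs(cand)
                e, _ = score_structure(pairs, psi)
                w = math.exp(-MODEL.beta * e)
                z += w
                for (i, j) in pairs:
                    weights[i, j] += w
            expected = (weights + weights.T) / z
            assert np.max(np.abs(psi - expected)) < 1e-9

    def test_row_sums_bounded(self):
        for seq in random_seqs(3, 12, seed=9, gc=0.8):
            psi = partition_pairprobs(seq, MODEL)
            assert (psi >= 0).all()
            assert (psi.sum(axis=1) <= 1 + 1e-12).all()


class TestAlgebras:
    def test_open_chain_scores_zero(self):
        seq = RNASequence.parse("s", "AAAA")
        psi = partition_pairprobs(seq, MODEL)
        grammar = FoldGrammar(MODEL)
        assert evaluate(grammar, energy_algebra(MODEL), seq.residues) == [0.0]
        assert evaluate(grammar, mea_algebra(psi), seq.residues) == [0.0]

    def test_gaaac_mea_is_single_pair_prob(self):
        seq = RNASequence.parse("s", "GAAAC")
        psi = partition_pairprobs(seq, MODEL)
        best = evaluate(FoldGrammar(MODEL), mea_algebra(psi), seq.residues)
        assert best == [pytest.approx(float(psi[0, 4]))]

    def test_single_objective_optima_match_enumeration(self):
        grammar = FoldGrammar(MODEL)
        for seq in random_seqs(5, 12, seed=10, gc=0.7):
            psi = partition_pairprobs(seq, MODEL)
            scored = [
                score_structure(structure_pairs(c), psi)
                for c in enum_structures(seq)
            ]
            e_alg, m_alg = energy_algebra(MODEL), mea_algebra(psi)
            assert evaluate(grammar, e_alg, seq.residues) == [
                pytest.approx(min(s[0] for s in scored))
            ]
            assert evaluate(grammar, m_alg, seq.residues) == [
                pytest.approx(max(s[1] for s in scored))
            ]

    def test_algebras_strictly_monotone(self):
        seq = RNASequence.parse("s", "GGGAAACCC")
        psi = partition_pairprobs(seq, MODEL)

        def terms(rng, symbol, pos):
            i = int(rng.integers(0, 4))
            return ("GACU"[i], i)

        assert check_monotone(energy_algebra(MODEL), term_sampler=terms).ok
        assert check_monotone(mea_algebra(psi), term_sampler=terms).ok

    def test_psi_shape_mismatch_rejected(self):
        seq = RNASequence.parse("s", "GAAAC")
        with pytest.raises(ValueError, match="match"):
            fold_pareto(seq, MODEL, psi=np.zeros((3, 3)))


class TestFoldPareto:
    def test_aaaa_front_is_origin(self):
        result = fold_pareto(RNASequence.parse("s", "AAAA"), MODEL)
        assert result.coords() == [(0.0, 0.0)]
        assert result.entries[0].structure == "...."

    def test_oracle_equality_on_random_12mers(self):
        orders = OrderSpec("min", "max")
        for seq in random_seqs(6, 12, seed=12, gc=0.7):
            psi = quantize(partition_pairprobs(seq, MODEL))
            scored = [
                score_structure(structure_pairs(c), psi)
                for c in enum_structures(seq)
            ]
            expected = naive_front(scored, orders)
            for strategy, variant in PARETO_COMBOS:
                result = fold_pareto(seq, MODEL, strategy, variant, psi=psi)
                assert set(result.coords()) == expected, (seq.id, strategy, variant)

    def test_witness_consistency(self):
        for seq in random_seqs(4, 12, seed=13, gc=0.8):
            result = fold_pareto(seq, MODEL)
            for entry in result.entries:
                e, m = score_structure(entry.pairs, result.psi)
                assert e == entry.energy
                assert m == pytest.approx(entry.mea)
                assert entry.structure == dot_bracket(entry.pairs, len(seq))

    def test_orientation_flip_gives_same_front(self):
        seq = random_seqs(1, 12, seed=14, gc=0.8)[0]
        psi = quantize(partition_pairprobs(seq, MODEL))
        result = fold_pareto(seq, MODEL, psi=psi)
        # carrier = -energy: negate the constants, not the carried values
        pe, se = MODEL.pair_energy, MODEL.stack_energy
        neg_fns = {
            "nil": lambda: 0.0,
            "unp": lambda t, x: x,
            "split": lambda x, y: x + y,
            "pair": lambda l, x, r: x - pe,
            "stack": lambda l, x, r: x - pe - se,
        }
        from paretodp.engine import EvaluationAlgebra, choice_max

        neg_alg = EvaluationAlgebra(
            "negE", FOLD_SIGNATURE, neg_fns, choice_max, "max"
        )
        prod = product_pareto(neg_alg, mea_algebra(psi), "eager")
        flipped = evaluate(FoldGrammar(MODEL), prod, seq.residues)
        assert {(-p[0], p[1]) for p in flipped} == set(result.coords())

    def test_front_size_bounded_by_distinct_energies(self):
        for seq in random_seqs(4, 12, seed=15, gc=0.8):
            psi = partition_pairprobs(seq, MODEL)
            energies = {
                score_structure(structure_pairs(c), psi)[0]
                for c in enum_structures(seq)
            }
            result = fold_pareto(seq, MODEL, psi=psi)
            assert len(result) <= len(energies)

    def test_length_bound_enforced(self):
        seq = RNASequence.parse("s", "AC" * 30)
        with pytest.raises(ValueError, match="bound"):
            fold_pareto(seq, MODEL, max_length=10)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fold_pareto(RNASequence("e", ""), MODEL)

    def test_front_size_study_bounded_by_harmonic(self):
        # qualitative: mean front size stays below the harmonic-law
        # expectation applied to the folding-space size (no numeric target)
        from paretodp.engine import counting_algebra
        from paretodp.pareto import harmonic

        grammar = FoldGrammar(MODEL)
        counter = counting_algebra(FOLD_SIGNATURE)
        sizes, bounds = [], []
        for seq in random_seqs(15, 16, seed=16, gc=0.7):
            count = evaluate(grammar, counter, seq.residues)[0]
            sizes.append(len(fold_pareto(seq, MODEL)))
            bounds.append(harmonic(count))
        assert np.mean(sizes) <= np.mean(bounds)
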