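"""Base-pair detection, pseudoknot order assignment, dot-bracket I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_max_noncrossing, random_matching
from rnaentangle.secondary import (
    BasePair,
    SecondaryStructure,
    SecondaryStructureError,
    assign_pseudoknot_orders,
    detect_canonical_pairs,
    parse_extended_dotbracket,
    to_extended_dotbracket,
)
from rnaentangle.synthetic import FixtureSpec, generate_fixture, rigid_transform


def author_pairs(model, pairs):
    order = [r.res_num for r in model.iter_residues()]
    return sorted((order[p.i], order[p.j]) for p in pairs)


class TestDetector:
    def test_recovers_ideal_hairpin_pairs_exactly(self, clean_hairpin):
        model, truth = clean_hairpin
        pairs = detect_canonical_pairs(model)
        assert author_pairs(model, pairs) == sorted((i, j) for i, j, _ in truth.pairs)
        assert all(p.pair_class == "WC-GC" for p in pairs)

    def test_broken_pair_fails_distance_gate(self, clean_hairpin):
        model, truth = clean_hairpin
        work = generate_fixture(FixtureSpec("clean_hairpin", loop_size=8))[0]
        i, j, _ = truth.pairs[0]  # deepest stem pair
        victim = work.residue_by_number(j)
        for atom in victim.atoms.values():
            atom.coords = atom.coords + np.array([0.0, 0.0, -15.0])
        pairs = detect_canonical_pairs(work)
        assert len(pairs) == len(truth.pairs) - 1
        assert (i, j) not in author_pairs(work, pairs)

    def test_detection_invariant_under_rigid_motion(self, knotlike):
        model, _ = knotlike
        ref = author_pairs(model, assign_pseudoknot_orders(detect_canonical_pairs(model)))
        for seed in (11, 12, 13):
            moved = rigid_transform(model, seed)
            got = author_pairs(moved, assign_pseudoknot_orders(detect_canonical_pairs(moved)))
            assert got == ref

    def test_each_residue_has_at_most_one_partner(self, knotlike):
        model, _ = knotlike
        pairs = detect_canonical_pairs(model)
        used = [p.i for p in pairs] + [p.j for p in pairs]
        assert len(used) == len(set(used))


class TestOrderAssignment:
    def test_nested_pairs_are_all_core(self):
        pairs = [BasePair(1, 10), BasePair(2, 9), BasePair(3, 8)]
        out = assign_pseudoknot_orders(pairs)
        assert [p.order for p in out] == [0, 0, 0]

    def test_single_crossing_forces_one_pseudoknot(self):
        out = assign_pseudoknot_orders([BasePair(1, 5), BasePair(3, 8)])
        orders = {p.as_tuple: p.order for p in out}
        assert orders == {(1, 5): 0, (3, 8): 1}

    def test_knotlike_layering_puts_crossing_helix_at_order_one(self, knotlike):
        model, truth = knotlike
        pairs = assign_pseudoknot_orders(detect_canonical_pairs(model))
        order_map = {}
        nums = [r.res_num for r in model.iter_residues()]
        for p in pairs:
            order_map[(nums[p.i], nums[p.j])] = p.order
        assert order_map == {(i, j): k for i, j, k in truth.pairs}

    def test_core_layer_is_maximum_against_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_pairs = int(rng.integers(1, 13))
            tuples = random_matching(rng, 40, n_pairs)
            out = assign_pseudoknot_orders([BasePair(i, j) for i, j in tuples])
            core = [p for p in out if p.order == 0]
            assert len(core) == brute_force_max_noncrossing(tuples)

    def test_layers_are_mutually_noncrossing(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tuples = random_matching(rng, 60, int(rng.integers(2, 20)))
            out = assign_pseudoknot_orders([BasePair(i, j) for i, j in tuples])
            by_order = {}
            for p in out:
                by_order.setdefault(p.order, []).append(p.as_tuple)
            for layer in by_order.values():
                for a in range(len(layer)):
                    for b in range(a + 1, len(layer)):
                        (i1, j1), (i2, j2) = layer[a], layer[b]
                        assert not (i1 < i2 < j1 < j2 or i2 < i1 < j2 < j1)

    def test_preset_crossing_within_order_rejected(self):
        bad = [BasePair(1, 5, order=0), BasePair(3, 8, order=0)]
        with pytest.raises(SecondaryStructureError):
            assign_pseudoknot_orders(bad)


class TestDotBracket:
    def _ss(self, n, pairs):
        return SecondaryStructure(
            sequence="N" * n, chain_lengths=[n], chain_ids=["A"], pairs=pairs)

    def test_hairpin_renders_to_parentheses(self):
        ss = self._ss(10, [BasePair(0, 9, order=0), BasePair(1, 8, order=0),
                           BasePair(2, 7, order=0)])
        assert to_extended_dotbracket(ss, with_headers=False) == "(((....)))"

    def test_pseudoknot_uses_second_alphabet(self):
        ss = self._ss(10, [BasePair(1, 5, order=0), BasePair(3, 8, order=1)])
        assert to_extended_dotbracket(ss, with_headers=False) == ".(.[.)..]."

    def test_parse_simple_and_crossing(self):
        ss = parse_extended_dotbracket("(((...)))")
        assert sorted(p.as_tuple for p in ss.pairs) == [(0, 8), (1, 7), (2, 6)]
        ss2 = parse_extended_dotbracket("([)]")
        assert {(p.i, p.j): p.order for p in ss2.pairs} == {(0, 2): 0, (1, 3): 1}

    def test_unbalanced_raises_with_position(self):
        with pytest.raises(SecondaryStructureError):
            parse_extended_dotbracket("((")
        with pytest.raises(SecondaryStructureError):
            parse_extended_dotbracket("())")

    def test_order_beyond_alphabets_rejected(self):
        ss = self._ss(4, [BasePair(0, 3, order=30)])
        with pytest.raises(SecondaryStructureError):
            to_extended_dotbracket(ss)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_round_trip_random_structures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        tuples = random_matching(rng, n, int(rng.integers(1, max(2, n // 3))))
        pairs = assign_pseudoknot_orders([BasePair(i, j) for i, j in tuples])
        ss = self._ss(n, pairs)
        text = to_extended_dotbracket(ss)
        back = parse_extended_dotbracket(text)
        assert sorted((p.i, p.j, p.order) for p in back.pairs) == \
               sorted((p.i, p.j, p.order) for p in pairs)

    def test_per_chain_blocks(self):
        ss = SecondaryStructure(sequence="GGGCCC", chain_lengths=[3, 3],
                                chain_ids=["A", "B"],
                                pairs=[BasePair(0, 5, order=0), BasePair(1, 4, order=0),
                                       BasePair(2, 3, order=0)])
        text = to_extended_dotbracket(ss)
        assert text.splitlines() == [">A", "GGG", "(((", ">B", "CCC", ")))"]
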