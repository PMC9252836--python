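"""Per-level decomposition into loops, dinucleotide steps, single strands."""

import numpy as np
import pytest

from conftest import make_linear_model, random_matching
from rnaentangle.elements import AnalysisOptions, ElementError, build_elements, enumerate_levels
from rnaentangle.secondary import (
    BasePair,
    assign_pseudoknot_orders,
    parse_extended_dotbracket,
    secondary_structure_from_model,
)


def decompose(db: str, **opt_kwargs):
    model = make_linear_model("A" * len(db))
    ss = parse_extended_dotbracket(db)
    ss = secondary_structure_from_model(model, ss.pairs)
    opts = AnalysisOptions(**opt_kwargs)
    return model, ss, opts


def kinds(eset):
    return sorted(e.kind for e in eset.all_elements)


def test_hairpin_with_dangles_decomposition():
    model, ss, opts = decompose("..(((....)))..")
    eset = build_elements(model, ss, 0, opts)
    loops = [e for e in eset.closed if e.kind == "L"]
    steps = [e for e in eset.closed if e.kind == "D"]
    strands = eset.open
    assert len(loops) == 1 and len(steps) == 2 and len(strands) == 2
    assert loops[0].residues == list(range(4, 10))
    assert sorted(s.residues[0] for s in strands) == [0, 12]


def test_all_unpaired_is_one_single_strand():
    model, ss, opts = decompose("." * 12)
    eset = build_elements(model, ss, 0, opts)
    assert not eset.closed
    assert len(eset.open) == 1 and len(eset.open[0].residues) == 12


def test_internal_loop_and_multibranch_are_loops():
    # internal loop between two helices and a two-way junction
    model, ss, opts = decompose("((..((....))..))")
    eset = build_elements(model, ss, 0, opts)
    loops = [e for e in eset.closed if e.kind == "L"]
    assert len(loops) == 2  # the internal loop and the inner hairpin loop


def test_helix_of_n_pairs_yields_n_minus_1_steps():
    model, ss, opts = decompose("((((....))))")
    eset = build_elements(model, ss, 0, opts)
    assert sum(1 for e in eset.closed if e.kind == "D") == 3


def test_step_requires_strict_adjacency_across_bulge():
    # bulge between the two pairs -> no D step
    model, ss, opts = decompose("(.(....))")
    eset = build_elements(model, ss, 0, opts)
    assert sum(1 for e in eset.closed if e.kind == "D") == 0
    # the bulged region forms a loop instead
    assert sum(1 for e in eset.closed if e.kind == "L") == 2


def test_level_k_treats_other_orders_as_unpaired(knotlike):
    model, truth = knotlike
    from rnaentangle.secondary import detect_canonical_pairs
    pairs = assign_pseudoknot_orders(detect_canonical_pairs(model))
    ss = secondary_structure_from_model(model, pairs)
    opts = AnalysisOptions()
    nums = [r.res_num for r in model.iter_residues()]
    level1 = build_elements(model, ss, 1, opts)
    strands = sorted(tuple(nums[i] for i in (min(s.residues), max(s.residues)))
                     for s in level1.open)
    assert (1, 31) in strands  # the 5'-end strand exists only at level 1
    loops = [e for e in level1.closed if e.kind == "L"]
    assert len(loops) == 1
    assert (nums[min(loops[0].residues)], nums[max(loops[0].residues)]) == (33, 49)


def test_oversized_loops_are_discarded_to_open_set():
    db = "(" + "." * 20 + ")"
    model, ss, opts = decompose(db, max_loop_length=10)
    eset = build_elements(model, ss, 0, opts)
    assert not eset.closed
    assert any(len(s.residues) == 20 for s in eset.open)


def test_isolated_pair_filter_only_shrinks_closed_set():
    db = "((..))..(.....)"
    model, ss, opts = decompose(db)
    with_iso = build_elements(model, ss, 0, AnalysisOptions())
    without_iso = build_elements(model, ss, 0, AnalysisOptions(ignore_isolated_pairs=True))
    assert len(without_iso.closed) <= len(with_iso.closed)
    # the lone pair closes a loop only when isolated pairs are kept
    assert len(with_iso.closed) - len(without_iso.closed) == 1


def test_step_count_matches_bruteforce_helix_finder():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(10, 60))
        tuples = random_matching(rng, n, int(rng.integers(1, n // 3)))
        pairs = assign_pseudoknot_orders([BasePair(i, j) for i, j in tuples])
        model = make_linear_model("A" * n)
        ss = secondary_structure_from_model(model, pairs)
        for level in enumerate_levels(ss):
            eset = build_elements(model, ss, level, AnalysisOptions(max_loop_length=10 ** 6))
            level_pairs = {p.as_tuple for p in pairs if p.order == level}
            expected = sum(1 for (i, j) in level_pairs if (i + 1, j - 1) in level_pairs)
            assert sum(1 for e in eset.closed if e.kind == "D") == expected


def test_closed_boundaries_are_simple_cycles():
    model, ss, opts = decompose("((..((....))..((...))..))")
    eset = build_elements(model, ss, 0, opts)
    for e in eset.closed:
        assert len(e.residues) == len(set(e.residues))


def test_level_zero_identical_with_or_without_pseudoknot_option():
    db = "..(((....)))..."
    model, ss, opts = decompose(db)
    accept = build_elements(model, ss, 0, AnalysisOptions(pseudoknots="accept"))
    ignore = build_elements(model, ss, 0, AnalysisOptions(pseudoknots="ignore"))
    assert [e.element_id for e in accept.all_elements] == \
           [e.element_id for e in ignore.all_elements]


def test_enumerate_levels():
    model = make_linear_model("A" * 12)
    pairs = assign_pseudoknot_orders(
        [BasePair(0, 6), BasePair(3, 9), BasePair(4, 11)])
    ss = secondary_structure_from_model(model, pairs)
    assert ss.max_order == 2
    assert enumerate_levels(ss, AnalysisOptions()) == [0, 1, 2]
    assert enumerate_levels(ss, AnalysisOptions(pseudoknots="ignore")) == [0]
    assert enumerate_levels(ss, AnalysisOptions(order_cap=1)) == [0, 1]
    flat = secondary_structure_from_model(model, [])
    assert enumerate_levels(flat, AnalysisOptions()) == [0]


def test_level_above_max_order_raises():
    model, ss, opts = decompose("(((...)))")
    with pytest.raises(ElementError):
        build_elements(model, ss, 2, opts)
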