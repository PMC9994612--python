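"""Signed circular order algebra: canonical forms, distances, patterns,
displaced blocks."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitorder.gene_order import (GROUND_PATTERN, SignedGeneOrder,
                                 adjacency_set, breakpoint_distance,
                                 canonicalize, circular_equal,
                                 cluster_patterns, displaced_blocks,
                                 extract_order, reflect_flip, rotate)
from mitorder.rearrangement import apply_translocation
from mitorder.synthetic import SimulationConfig, simulate_history
from mitorder.vocab import ALL_GENES


def _order(tokens, taxon="t"):
    return SignedGeneOrder(taxon=taxon, genes=tuple(tokens))


small_orders = st.builds(
    lambda names, signs: _order(tuple(
        (n, s) for n, s in zip(names, signs))),
    st.lists(st.sampled_from(ALL_GENES[:10]), min_size=3, max_size=8,
             unique=True),
    st.lists(st.sampled_from([1, -1]), min_size=8, max_size=8))


# --- extraction -----------------------------------------------------------

def test_extracted_order_contains_derived_runs(chishuiense_order):
    s = str(chishuiense_order)
    # the rearranged trnH block and the relocated trnQ/CR region
    assert "trnE,-trnH,-trnF,-nad5,-nad4,-nad4L" in s
    assert "-rrnL,-trnV,-trnQ,-rrnS,CR,trnI" in s


def test_extraction_round_trips_through_simulation(sim_genome):
    ann, order, _, _ = sim_genome
    assert extract_order(ann).genes == order.genes


def test_missing_genes_are_recorded(wushanense_order):
    assert wushanense_order.missing == frozenset({"trnI"})


# --- canonicalization -----------------------------------------------------

def test_canonicalize_constant_on_rotations():
    want = canonicalize(GROUND_PATTERN).genes
    for i in range(0, len(GROUND_PATTERN), 5):
        rotated = _order(rotate(GROUND_PATTERN.genes, i))
        assert canonicalize(rotated).genes == want


def test_canonicalize_constant_under_reflection():
    reflected = _order(reflect_flip(GROUND_PATTERN.genes))
    assert canonicalize(reflected).genes == canonicalize(GROUND_PATTERN).genes


def test_canonicalize_idempotent(chishuiense_order):
    once = canonicalize(chishuiense_order)
    assert canonicalize(once).genes == once.genes


def test_canonicalize_requires_cox1():
    with pytest.raises(ValueError, match="cox1"):
        canonicalize(_order(("trnA", "trnC", "trnD")))


@given(small_orders, st.integers(0, 7), st.integers(0, 7))
def test_random_rotations_share_a_canonical_form(order, i, j):
    a = _order(rotate(order.genes, i))
    b = _order(rotate(order.genes, j))
    assert circular_equal(a.genes, b.genes)
    if "cox1" in order.names():
        assert canonicalize(a).genes == canonicalize(b).genes


# --- breakpoint distance --------------------------------------------------

def test_identical_orders_have_distance_zero(chishuiense_order):
    assert breakpoint_distance(chishuiense_order, chishuiense_order) == 0
    rotated = _order(rotate(chishuiense_order.genes, 11), taxon="rot")
    assert breakpoint_distance(chishuiense_order, rotated) == 0


def test_single_gene_inversion_in_five_gene_circle_breaks_two_adjacencies():
    a = _order(("cox1", "trnA", "trnC", "trnD", "trnE"))
    b = _order(("cox1", "trnA", "-trnC", "trnD", "trnE"))
    assert breakpoint_distance(a, b) == 2


def test_distance_against_adjacency_set_oracle(chishuiense_order):
    # independent set-difference computation on the shared gene set
    a, b = GROUND_PATTERN, chishuiense_order
    common = a.gene_set() & b.gene_set()
    ra, rb = a.restrict(common), b.restrict(common)
    expected = len(adjacency_set(ra.genes) - adjacency_set(rb.genes))
    assert breakpoint_distance(a, b) == expected


def test_empty_intersection_is_an_error():
    a = _order(("cox1", "trnA"))
    b = _order(("cox2", "trnC"))
    with pytest.raises(ValueError, match="no genes"):
        breakpoint_distance(a, b)


@given(st.data())
def test_breakpoint_distance_is_a_pseudometric(data):
    """Symmetry and the triangle inequality on random signed orders over a
    common gene set."""
    names = data.draw(st.lists(st.sampled_from(ALL_GENES[:8]), min_size=3,
                               max_size=8, unique=True))

    def draw_order(label):
        perm = data.draw(st.permutations(names))
        signs = data.draw(st.lists(st.sampled_from([1, -1]),
                                   min_size=len(names),
                                   max_size=len(names)))
        return _order(tuple((n, s) for n, s in zip(perm, signs)), label)

    x, y, z = draw_order("x"), draw_order("y"), draw_order("z")
    dxy = breakpoint_distance(x, y)
    assert dxy == breakpoint_distance(y, x)
    assert dxy <= breakpoint_distance(x, z) + breakpoint_distance(z, y)
    assert breakpoint_distance(x, x) == 0
    if circular_equal(x.genes, y.genes):
        assert dxy == 0


# --- pattern grouping -----------------------------------------------------

def test_two_identical_plus_one_distinct_gives_two_groups():
    a = _order(("cox1", "trnA", "trnC"), "a")
    b = _order(rotate(a.genes, 1), "b")
    c = _order(("cox1", "trnC", "trnA"), "c")
    groups = cluster_patterns([a, b, c])
    assert [len(g.members) for g in groups] == [2, 1]
    assert groups[0].label == "I" and groups[1].label == "II"
    assert groups[0].members == ("a", "b")


def test_sinopotamon_fixtures_share_one_pattern(chishuiense_order,
                                                wushanense_order):
    groups = cluster_patterns([chishuiense_order, wushanense_order])
    assert len(groups) == 1
    assert set(groups[0].members) == {"Sinopotamon_chishuiense",
                                      "Sinopotamon_wushanense"}


def test_simulated_orders_group_by_history():
    """Ten orders drawn from three distinct histories form three groups."""
    histories = []
    for seed in (11, 22, 33):
        order, _ = simulate_history(SimulationConfig(seed=seed, events=2))
        histories.append(order)
    # ensure the three are actually distinct arrangements
    assert not circular_equal(histories[0].genes, histories[1].genes)
    assert not circular_equal(histories[0].genes, histories[2].genes)
    assert not circular_equal(histories[1].genes, histories[2].genes)
    orders = []
    for i in range(10):
        src = histories[i % 3]
        orders.append(_order(rotate(src.genes, 3 * i), taxon=f"taxon{i}"))
    groups = cluster_patterns(orders)
    assert len(groups) == 3
    assert sorted(len(g.members) for g in groups) == [3, 3, 4]


# --- displaced blocks -----------------------------------------------------

def test_three_blocks_separate_ground_pattern_from_sinopotamon(
        chishuiense_order):
    dec = displaced_blocks(GROUND_PATTERN, chishuiense_order)
    assert not dec.budget_exceeded
    assert sorted(str(b) for b in dec.displaced_blocks) == [
        "trnH", "trnM-nad2-trnW-trnC-trnY", "trnQ"]
    assert circular_equal(dec.replay().genes, chishuiense_order.genes)


def test_identical_orders_need_no_blocks():
    dec = displaced_blocks(GROUND_PATTERN, GROUND_PATTERN)
    assert dec.n_displaced == 0 and not dec.budget_exceeded


def test_single_transposition_yields_one_block():
    moved = apply_translocation(GROUND_PATTERN, ("trnG", "nad3", "trnA"),
                                after="cob")
    dec = displaced_blocks(GROUND_PATTERN, moved)
    assert dec.n_displaced == 1
    assert dec.displaced_blocks[0].names() == ("trnG", "nad3", "trnA")
    assert circular_equal(dec.replay().genes, moved.genes)


def test_budget_exceeded_is_explicit():
    order, _ = simulate_history(SimulationConfig(seed=5, events=6))
    dec = displaced_blocks(GROUND_PATTERN, order, max_blocks=1)
    if dec.budget_exceeded:
        assert dec.displaced_blocks == ()
    else:  # a 6-event history may still reduce to one displaced block
        assert dec.n_displaced <= 1


@given(st.integers(0, 30))
def test_replay_reconstructs_simulated_translocations(seed):
    cfg = SimulationConfig(seed=seed, events=2, kind_weights={
        "translocation": 1.0})
    order, _ = simulate_history(cfg)
    dec = displaced_blocks(GROUND_PATTERN, order)
    if not dec.budget_exceeded:
        assert circular_equal(dec.replay().genes, order.genes)
        assert dec.n_displaced <= 2
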