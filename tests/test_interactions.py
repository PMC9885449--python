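"""Duplicate-preserving interaction similarity and the filtered map scan."""

from fractions import Fraction
from itertools import combinations_with_replacement

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapcompare.interactions import (
    FilterCriteria,
    IdentifierMultiset,
    compare_maps,
    interaction_multiset,
    list_intersect,
    similarity,
)
from mapcompare.synthetic import MapConfig, SyntheticConfig, generate

from conftest import make_map


def mset(*ids, reaction_id="r", map_id="m"):
    return IdentifierMultiset(reaction_id=reaction_id, map_id=map_id, ids=tuple(ids))


def brute_force_similarity(a: tuple, b: tuple) -> float:
    """Independent oracle: direct occurrence counting, no shared code with
    the implementation's set-based path."""
    if not a or not b:
        return 0.0
    n_ab = 0
    for x in a:
        for y in b:
            if x == y:
                n_ab += 1
                break
    n_ba = 0
    for y in b:
        for x in a:
            if y == x:
                n_ba += 1
                break
    return (n_ab * n_ba) / (len(a) * len(b))


# -- multiset construction --------------------------------------------------


def test_multiset_concatenates_in_participant_order(tiny_map):
    ms = interaction_multiset(tiny_map.reactions[0], tiny_map)
    # E1=[P12345], E2 homodimer [P12345,P12345], E3 unannotated
    assert ms.ids == ("P12345", "P12345", "P12345")
    assert ms.n == 3


def test_multiset_all_unannotated():
    m = make_map(
        "m",
        {"E1": [], "E2": []},
        {"R1": [("E1", "reactant"), ("E2", "product")]},
    )
    ms = interaction_multiset(m.reactions[0], m)
    assert ms.ids == () and ms.n == 0


def test_multiset_homodimer_sole_participant():
    m = make_map("m", {"E1": ["P11111", "P11111"]}, {"R1": [("E1", "reactant")]})
    assert interaction_multiset(m.reactions[0], m).ids == ("P11111", "P11111")


def test_multiset_first_id_only_flag():
    m = make_map(
        "m",
        {"E1": ["P11111", "P22222"]},  # heteromeric complex
        {"R1": [("E1", "reactant")]},
    )
    assert interaction_multiset(m.reactions[0], m).ids == ("P11111", "P22222")
    assert interaction_multiset(m.reactions[0], m, first_id_only=True).ids == (
        "P11111",
    )


# -- the ∘ operator and similarity ------------------------------------------


def test_list_intersect_is_asymmetric():
    a = mset("P1AAAA", "P1AAAA", "P2AAAA")
    b = mset("P1AAAA", "P3AAAA")
    assert list_intersect(a, b).ids == ("P1AAAA", "P1AAAA")
    assert list_intersect(b, a).ids == ("P1AAAA",)


def test_list_intersect_identity_and_disjoint():
    a = mset("P1AAAA", "P2AAAA", "P1AAAA")
    assert list_intersect(a, a).ids == a.ids
    d = mset("P9AAAA")
    assert list_intersect(a, d).ids == ()
    assert list_intersect(d, a).ids == ()


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (("P1", "P1", "P2"), ("P1", "P3"), Fraction(1, 3)),
        (("P1", "P1"), ("P1",), Fraction(1)),  # equal supports give 1
        (("P1", "P2"), ("P1", "P2"), Fraction(1)),
        (("P1",), ("P2",), Fraction(0)),
        ((), ("P1",), Fraction(0)),
        ((), (), Fraction(0)),
    ],
)
def test_similarity_hand_evaluated(a, b, expected):
    pad = lambda ids: tuple(f"{x}AAAA" for x in ids)
    got = similarity(mset(*pad(a)), mset(*pad(b)))
    assert got == pytest.approx(float(expected))
    assert got == similarity(mset(*pad(b)), mset(*pad(a)))


def test_similarity_exhaustive_against_brute_force():
    """All multiset pairs over a 5-accession alphabet, lengths <= 4."""
    alphabet = ["P1AAAA", "P2AAAA", "P3AAAA", "P4AAAA", "P5AAAA"]
    multisets = [
        combo
        for length in range(5)
        for combo in combinations_with_replacement(alphabet, length)
    ]
    assert len(multisets) == 126
    for a in multisets:
        for b in multisets:
            got = similarity(mset(*a), mset(*b))
            assert got == brute_force_similarity(a, b), (a, b)


@given(
    a=st.lists(st.sampled_from("ABCDE"), max_size=6),
    b=st.lists(st.sampled_from("ABCDE"), max_size=6),
)
@settings(deadline=None, max_examples=300)
def test_similarity_properties(a, b):
    pa = [f"P{x}AAAA" for x in a]
    pb = [f"P{x}AAAA" for x in b]
    ma, mb = mset(*pa), mset(*pb)
    s = similarity(ma, mb)
    assert 0.0 <= s <= 1.0
    assert s == similarity(mb, ma)
    if a:
        assert similarity(ma, ma) == 1.0
    oa, ob = list_intersect(ma, mb), list_intersect(mb, ma)
    assert oa.n <= ma.n and ob.n <= mb.n
    assert (oa.n == 0 and ob.n == 0) == (not set(pa) & set(pb))


# -- map-level comparison ---------------------------------------------------


def test_compare_maps_disjoint_is_empty():
    a = make_map("a", {"E1": ["P1AAAA"] * 3}, {"R1": [("E1", "reactant")] * 3})
    b = make_map("b", {"F1": ["P2AAAA"] * 3}, {"S1": [("F1", "reactant")] * 3})
    assert compare_maps(a, b) == []


def test_compare_maps_verbatim_copy_retained():
    elements = {"E1": ["P1AAAA"], "E2": ["P2AAAA"], "E3": ["P3AAAA"]}
    reactions = {
        "R1": [("E1", "reactant"), ("E2", "modifier"), ("E3", "product")]
    }
    a = make_map("a", elements, reactions)
    b = make_map("b", elements, reactions)
    (rec,) = compare_maps(a, b)
    assert rec.similarity == 1.0
    assert rec.overlap_a == rec.overlap_b == 3


def test_compare_maps_rejects_same_map(tiny_map):
    with pytest.raises(ValueError):
        compare_maps(tiny_map, tiny_map)


def test_compare_maps_threshold_is_exact_at_cutoff():
    # overlap product / length product == exactly 7/10
    a = make_map(
        "a",
        {"E1": ["P1AAAA"], "E2": ["P2AAAA"], "E3": ["P3AAAA"],
         "E4": ["P4AAAA"], "E5": ["P5AAAA"]},
        {"R1": [("E1", "reactant"), ("E2", "reactant"), ("E3", "reactant"),
                ("E4", "reactant"), ("E5", "product")]},
    )
    b = make_map(
        "b",
        {"F1": ["P1AAAA"], "F2": ["P2AAAA"], "F3": ["P3AAAA"],
         "F4": ["P6AAAA"]},
        {"S1": [("F1", "reactant"), ("F2", "reactant"), ("F3", "reactant"),
                ("F4", "product")]},
    )
    # n(A)=5, n(B)=4, overlaps 3 and 3 -> 9/20 = 0.45 < 0.7: filtered
    assert compare_maps(a, b) == []
    # at min_similarity = 0.45 exactly, the pair must be retained
    recs = compare_maps(a, b, FilterCriteria(min_similarity=0.45))
    assert len(recs) == 1 and recs[0].similarity == pytest.approx(0.45)


def test_compare_maps_filter_monotonicity(synthetic_triple):
    _, maps, _ = synthetic_triple
    m1, m2 = maps[0], maps[1]
    base = compare_maps(m1, m2, FilterCriteria(min_similarity=0.0, min_overlap=1))
    keys = lambda recs: {(r.reaction_a, r.reaction_b) for r in recs}
    prev = keys(base)
    for ms in (0.3, 0.7, 0.9):
        cur = keys(compare_maps(m1, m2, FilterCriteria(min_similarity=ms,
                                                       min_overlap=1)))
        assert cur <= prev
        prev = cur
    prev = keys(base)
    for mo in (2, 3, 5):
        cur = keys(compare_maps(m1, m2, FilterCriteria(min_similarity=0.0,
                                                       min_overlap=mo)))
        assert cur <= prev
        prev = cur


def test_compare_maps_matches_brute_force_scan(synthetic_triple):
    """Filtered scan agrees with an exhaustive all-pairs oracle."""
    _, maps, _ = synthetic_triple
    m2, m3 = maps[1], maps[2]
    crit = FilterCriteria()
    recs = compare_maps(m2, m3, crit)
    expected = set()
    for ra in m2.reactions:
        ma = interaction_multiset(ra, m2)
        for rb in m3.reactions:
            mb = interaction_multiset(rb, m3)
            s = brute_force_similarity(ma.ids, mb.ids)
            oa = list_intersect(ma, mb).n
            ob = list_intersect(mb, ma).n
            if s >= 0.7 and oa >= 3 and ob >= 3:
                expected.add((ra.reaction_id, rb.reaction_id))
    assert {(r.reaction_a, r.reaction_b) for r in recs} == expected


def test_planted_pair_recovery_small():
    cfg = SyntheticConfig(
        seed=5,
        universe_size=1500,
        maps=(
            MapConfig("a", n_proteins=300, n_reactions=150, duplicate_prob=0.15),
            MapConfig("b", n_proteins=250, n_reactions=150, duplicate_prob=0.0),
        ),
        pairwise_shared={("a", "b"): 120},
        planted_similar={("a", "b"): 10},
    )
    maps, truth = generate(cfg)
    recs = compare_maps(maps[0], maps[1])
    assert {(r.reaction_a, r.reaction_b) for r in recs} == set(
        truth.planted_pair_ids[("a", "b")]
    )
    for r in recs:
        assert r.similarity >= 0.7
        assert r.overlap_a >= 3 and r.overlap_b >= 3
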