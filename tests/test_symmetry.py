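"""Unit and property tests for symmetry detection and group machinery."""

import math
from fractions import Fraction

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from selsym import (
    Permutation,
    SymmetryGroup,
    apply_permutation,
    build_chain,
    class_moran,
    directed_cycle_moran,
    is_symmetry,
    island_moran,
    site_orbits,
    star_moran_db,
    symmetry_group,
    undirected_cycle_moran,
    verify_transition_preservation,
    well_mixed_moran,
    wright_fisher,
)


def random_perm(draw_n=4):
    return st.permutations(list(range(draw_n))).map(lambda i: Permutation(tuple(i)))


class TestPermutation:
    def test_rejects_non_bijections(self):
        with pytest.raises(ValueError):
            Permutation((0, 0, 1))

    @given(random_perm())
    def test_inverse_composes_to_identity(self, sigma):
        assert sigma.compose(sigma.inverse()).is_identity()
        assert sigma.inverse().compose(sigma).is_identity()

    def test_cycle_notation_is_one_based_with_fixed_points(self):
        rot2 = Permutation.from_cycles(6, [(0, 2, 4), (1, 3, 5)])
        assert rot2.cycle_string() == "(1 3 5)(2 4 6)"
        assert Permutation.identity(3).cycle_string() == "(1)(2)(3)"

    def test_from_cycles_one_based_matches_zero_based(self):
        a = Permutation.from_cycles(5, [(1, 3, 5)], one_based=True)
        b = Permutation.from_cycles(5, [(0, 2, 4)])
        assert a == b


class TestApplyPermutation:
    def test_identity_fixes_every_state(self):
        x = (1, 0, 1)
        assert apply_permutation(x, Permutation.identity(3)) == x

    def test_explicit_three_cycle(self):
        # sigma(0)=1, sigma(1)=2, sigma(2)=0; result_g = x_{sigma(g)}
        sigma = Permutation((1, 2, 0))
        assert apply_permutation((1, 0, 0), sigma) == (0, 0, 1)

    @given(
        st.lists(st.integers(0, 1), min_size=4, max_size=4).map(tuple),
        random_perm(),
        random_perm(),
    )
    def test_right_action_composition_law(self, x, sigma, tau):
        # (x sigma) tau = x (sigma o tau)
        lhs = apply_permutation(apply_permutation(x, sigma), tau)
        rhs = apply_permutation(x, sigma.compose(tau))
        assert lhs == rhs


class TestIsSymmetry:
    def test_identity_is_always_a_symmetry(self, wm3, star5):
        for proc in (wm3, star5):
            assert is_symmetry(proc, Permutation.identity(proc.n))

    def test_rotation_by_two_on_the_undirected_cycle(self):
        proc = undirected_cycle_moran(8)
        rot2 = Permutation(tuple((g + 2) % 8 for g in range(8)))
        assert is_symmetry(proc, rot2)

    def test_hub_leaf_swap_is_not_a_star_symmetry(self, star5):
        swap = Permutation((1, 0, 2, 3, 4))
        assert not is_symmetry(star5, swap)

    def test_reflection_fails_on_the_directed_cycle(self):
        proc = directed_cycle_moran(5)
        refl = Permutation(tuple((-g) % 5 for g in range(5)))
        assert not is_symmetry(proc, refl)

    def test_size_mismatch_raises(self, wm3):
        with pytest.raises(ValueError):
            is_symmetry(wm3, Permutation.identity(4))


GROUP_ORDER_CASES = [
    (lambda: well_mixed_moran(4), math.factorial(4)),
    (lambda: wright_fisher(3), math.factorial(3)),
    (lambda: well_mixed_moran(4, r=Fraction(2)), math.factorial(4)),
    (lambda: directed_cycle_moran(5), 5),
    (lambda: undirected_cycle_moran(6), 12),
    (lambda: undirected_cycle_moran(8), 16),
    (lambda: star_moran_db(5), math.factorial(4)),
    (lambda: class_moran((2, 3)), math.factorial(2) * math.factorial(3)),
    (lambda: island_moran(2, 2), math.factorial(2) * math.factorial(2) ** 2),
]


@pytest.mark.parametrize(
    "make, order",
    GROUP_ORDER_CASES,
    ids=[
        "well_mixed_4",
        "wright_fisher_3",
        "well_mixed_4_selective",
        "directed_cycle_5",
        "undirected_cycle_6",
        "undirected_cycle_8",
        "star_5",
        "class_2_3",
        "island_2x2",
    ],
)
def test_detected_group_orders_match_population_structure(make, order):
    group = symmetry_group(make())
    assert group.order == order
    # group axioms hold: identity, closure, inverses
    SymmetryGroup(group.elements, check=True)


class TestGenerators:
    def test_closure_of_generators_recovers_the_rotation_group(self):
        proc = directed_cycle_moran(6)
        rot1 = Permutation(tuple((g + 1) % 6 for g in range(6)))
        assert symmetry_group(proc, [rot1]) == symmetry_group(proc)

    def test_invalid_generator_is_named_in_the_error(self, star5):
        bad = Permutation((1, 0, 2, 3, 4))
        with pytest.raises(ValueError, match="not a symmetry"):
            symmetry_group(star5, [bad])

    def test_brute_force_size_limit(self):
        proc = well_mixed_moran(4)
        with pytest.raises(ValueError, match="brute-force"):
            symmetry_group(proc, max_n=3)


class TestSiteOrbits:
    def test_full_symmetric_group_is_transitive(self, wm3_group):
        orbs = site_orbits(wm3_group)
        assert orbs.transitive
        assert orbs.orbits == [[0, 1, 2]]

    def test_star_splits_into_hub_and_leaves(self, star5_group):
        orbs = site_orbits(star5_group)
        assert not orbs.transitive
        assert orbs.orbits == [[0], [1, 2, 3, 4]]

    def test_trivial_group_gives_singletons(self):
        orbs = site_orbits(SymmetryGroup.trivial(4))
        assert orbs.orbits == [[0], [1], [2], [3]]
        assert not orbs.transitive

    def test_class_model_orbits_recover_the_class_partition(self):
        group = symmetry_group(class_moran((2, 3)))
        orbs = site_orbits(group)
        assert orbs.orbits == [[0, 1], [2, 3, 4]]


class TestTransitionPreservation:
    @pytest.mark.parametrize(
        "make",
        [
            lambda: well_mixed_moran(4),
            lambda: well_mixed_moran(3, r=Fraction(3, 2), u=Fraction(1, 10)),
            lambda: directed_cycle_moran(5),
            lambda: star_moran_db(5),
            lambda: island_moran(2, 2),
        ],
        ids=["well_mixed_4", "well_mixed_3_sel_mut", "directed_cycle_5", "star_5", "island_2x2"],
    )
    def test_every_detected_symmetry_preserves_transitions(self, make):
        proc = make()
        group = symmetry_group(proc)
        P = build_chain(proc)
        report = verify_transition_preservation(P, group)
        assert report.ok
        assert report.checked > 0

    def test_two_step_transitions_are_preserved_too(self, wm3, wm3_group):
        report = verify_transition_preservation(build_chain(wm3), wm3_group, steps=2)
        assert report.ok

    def test_trivial_group_is_vacuously_preserved(self, wm3):
        report = verify_transition_preservation(build_chain(wm3), SymmetryGroup.trivial(3))
        assert report.ok


class TestGraphAutomorphismOracle:
    """For neutral graph-based models the symmetry group must equal the
    automorphism group of the graph, computed independently by networkx."""

    @pytest.mark.parametrize(
        "graph, make",
        [
            (nx.cycle_graph(5), lambda: undirected_cycle_moran(5)),
            (nx.star_graph(4), lambda: star_moran_db(5)),
        ],
        ids=["cycle_5", "star_5"],
    )
    def test_detected_group_equals_graph_automorphisms(self, graph, make):
        matcher = nx.algorithms.isomorphism.GraphMatcher(graph, graph)
        autos = {
            Permutation(tuple(m[g] for g in range(graph.number_of_nodes())))
            for m in matcher.isomorphisms_iter()
        }
        detected = symmetry_group(make())
        assert detected.elements == frozenset(autos)
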