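"""Unit tests for orbit enumeration, lumping and Burnside/Polya counting."""

import math
from fractions import Fraction

import pytest

from selsym import (
    Permutation,
    StructureSpec,
    SymmetryGroup,
    build_chain,
    build_reduced_chain,
    count_directed_cycle,
    count_reduced_states,
    cycle_count,
    make_structure_group,
    star_moran_db,
    state_count_bounds,
    state_orbits,
    symmetry_group,
    well_mixed_moran,
)
from selsym.reduction import LumpabilityError


def cyclic(n):
    return make_structure_group(StructureSpec("cyclic", n=n))


def symmetric(n):
    return make_structure_group(StructureSpec("symmetric", n=n))


class TestStateOrbits:
    def test_full_symmetric_group_orbits_are_allele_counts(self):
        orbs = state_orbits(symmetric(4))
        assert len(orbs) == 5
        assert sorted(o.allele_count for o in orbs) == [0, 1, 2, 3, 4]
        for o in orbs:
            assert o.size == math.comb(4, o.allele_count)
            assert all(sum(m) == o.allele_count for m in o.members)

    def test_trivial_group_gives_singletons(self):
        orbs = state_orbits(SymmetryGroup.trivial(3))
        assert len(orbs) == 8
        assert all(o.size == 1 for o in orbs)

    def test_cyclic_group_on_five_sites_has_eight_orbits(self):
        assert len(state_orbits(cyclic(5))) == 8

    def test_representative_is_minimal_and_ordering_deterministic(self):
        from selsym.process_core import state_index

        orbs = state_orbits(cyclic(4))
        reps = [state_index(o.representative) for o in orbs]
        assert reps == sorted(reps)
        for o in orbs:
            assert state_index(o.representative) == min(state_index(m) for m in o.members)

    def test_three_allele_orbits(self):
        # necklaces with 3 colours on 4 beads under rotation: (1/4)(3^4+3+3^2+3) = 24
        orbs = state_orbits(cyclic(4), num_alleles=3)
        assert len(orbs) == 24


class TestReducedChain:
    def test_well_mixed_reduces_to_the_classical_birth_death_chain(self, wm3, wm3_group):
        P = build_chain(wm3)
        chain = build_reduced_chain(P, state_orbits(wm3_group))
        assert chain.R == 4
        assert [o.allele_count for o in chain.orbits] == [0, 1, 2, 3]
        # classical neutral Moran on {0..3}: from k=1, up/down each k(n-k)/n^2
        assert chain.entries[1][2] == Fraction(2, 9)
        assert chain.entries[1][0] == Fraction(2, 9)
        assert chain.entries[1][1] == Fraction(5, 9)
        for row in chain.entries:
            assert sum(row) == 1

    def test_reduced_absorption_matches_full_chain(self, wm3, wm3_group):
        from selsym import fixation_probabilities

        chain = build_reduced_chain(build_chain(wm3), state_orbits(wm3_group))
        # absorption into the all-1 orbit, solved on the 2 transient orbits
        a, b = chain.entries[1], chain.entries[2]
        # rho1 = a0*0 + a1*rho1 + a2*rho2 + a3*1, similarly rho2
        denom = (1 - a[1]) * (1 - b[2]) - a[2] * b[1]
        rho1 = (a[3] * (1 - b[2]) + a[2] * b[3]) / denom
        rho = fixation_probabilities(wm3)
        assert rho1 == rho.single_mutant(0)

    def test_wrong_partition_is_caught_by_the_lumpability_check(self):
        # star process lumped with cyclic orbits: rotations are not
        # symmetries of the star, so row sums differ within an orbit
        proc = star_moran_db(4)
        P = build_chain(proc)
        with pytest.raises(LumpabilityError, match="not lumpable"):
            build_reduced_chain(P, state_orbits(cyclic(4)))

    def test_partition_must_cover_the_state_space(self, wm3, star5_group):
        with pytest.raises(ValueError, match="cover"):
            build_reduced_chain(build_chain(wm3), state_orbits(symmetric(4))[:2])


class TestCycleCount:
    @pytest.mark.parametrize("shift, expected", [(1, 1), (2, 2), (3, 3)])
    def test_rotations_of_the_six_cycle(self, shift, expected):
        rot = Permutation(tuple((g + shift) % 6 for g in range(6)))
        dec = cycle_count(rot)
        assert dec.count == expected

    def test_rotation_by_two_gives_the_two_odd_even_cycles(self):
        rot = Permutation(tuple((g + 2) % 6 for g in range(6)))
        assert set(map(frozenset, cycle_count(rot).cycles)) == {
            frozenset({0, 2, 4}),
            frozenset({1, 3, 5}),
        }

    def test_identity_has_n_cycles(self):
        assert cycle_count(Permutation.identity(7)).count == 7

    @pytest.mark.parametrize("n", range(1, 13))
    def test_rotation_cycle_count_is_gcd(self, n):
        for j in range(1, n + 1):
            rot = Permutation(tuple((g + j) % n for g in range(n)))
            assert cycle_count(rot).count == math.gcd(n, j)


class TestBurnsideCounts:
    @pytest.mark.parametrize("n", range(1, 9))
    def test_full_symmetric_group_counts_allele_numbers(self, n):
        assert count_reduced_states(symmetric(n)) == n + 1

    def test_star_group_counts_hub_times_leaf_occupancy(self):
        group = make_structure_group(StructureSpec("star", n=5))
        assert count_reduced_states(group) == 10  # 2n at n=5

    def test_class_group_counts_products(self):
        group = make_structure_group(StructureSpec("class_partition", sizes=(2, 3)))
        assert count_reduced_states(group) == (2 + 1) * (3 + 1)

    def test_trivial_group_counts_all_states(self):
        assert count_reduced_states(SymmetryGroup.trivial(3)) == 8

    def test_burnside_equals_brute_force_orbit_enumeration(self):
        specs = [
            StructureSpec("symmetric", n=5),
            StructureSpec("class_partition", sizes=(2, 3)),
            StructureSpec("block_partition", block_count=2, block_size=2),
            StructureSpec("dihedral", n=7),
            StructureSpec("cyclic", n=8),
            StructureSpec("star", n=6),
        ]
        for spec in specs:
            group = make_structure_group(spec)
            for m in (2, 3):
                assert count_reduced_states(group, m) == len(state_orbits(group, num_alleles=m))

    def test_non_group_input_fails_the_divisibility_check(self):
        bad = SymmetryGroup(
            [Permutation((0, 1, 2)), Permutation((1, 0, 2)), Permutation((1, 2, 0))],
            check=False,
        )
        with pytest.raises(ValueError, match="not divisible"):
            count_reduced_states(bad)

    def test_detected_process_group_count_matches_its_orbit_partition(self, star5_group):
        assert count_reduced_states(star5_group) == len(state_orbits(star5_group))


class TestDirectedCycleCount:
    @pytest.mark.parametrize("n, expected", [(1, 2), (2, 3), (5, 8), (6, 14)])
    def test_known_necklace_counts(self, n, expected):
        assert count_directed_cycle(n) == expected

    @pytest.mark.parametrize("n", range(1, 11))
    def test_gcd_formula_matches_burnside_on_the_rotation_group(self, n):
        assert count_directed_cycle(n) == count_reduced_states(cyclic(n))
        assert count_directed_cycle(n, 3) == count_reduced_states(cyclic(n), 3)

    @pytest.mark.parametrize("n", [2, 3, 5, 7, 11])
    def test_prime_size_closed_form(self, n):
        assert count_directed_cycle(n) == 2 + (2**n - 2) // n

    def test_reflections_merge_orbits(self):
        dihedral6 = make_structure_group(StructureSpec("dihedral", n=6))
        assert count_reduced_states(dihedral6) == 13
        assert count_directed_cycle(6) == 14


class TestBounds:
    @pytest.mark.parametrize("n", range(1, 9))
    def test_full_symmetry_pins_both_bounds_at_n_plus_one(self, n):
        b = state_count_bounds(n, math.factorial(n))
        assert b.lower == b.upper == n + 1

    @pytest.mark.parametrize("n", range(1, 9))
    def test_no_symmetry_pins_both_bounds_at_two_to_the_n(self, n):
        b = state_count_bounds(n, 1)
        assert b.lower == b.upper == 2**n

    def test_prime_cycle_bounds_coincide(self):
        b = state_count_bounds(5, 5)
        assert b.lower == b.upper == 8

    def test_star_bounds_bracket_but_do_not_pin(self):
        b = state_count_bounds(5, 24)
        assert b.lower == 6
        assert b.upper == 22  # 2 + n(n-1) at prime n
        assert b.contains(10)

    def test_bounds_hold_for_every_structure_group(self):
        specs = [
            StructureSpec("symmetric", n=6),
            StructureSpec("class_partition", sizes=(2, 3)),
            StructureSpec("class_partition", sizes=(1, 2, 3)),
            StructureSpec("block_partition", block_count=2, block_size=3),
            StructureSpec("block_partition", block_count=3, block_size=2),
            StructureSpec("dihedral", n=8),
            StructureSpec("cyclic", n=9),
            StructureSpec("star", n=7),
        ]
        for spec in specs:
            group = make_structure_group(spec)
            R = count_reduced_states(group)
            b = state_count_bounds(group.n, group.order)
            assert b.contains(R), f"{spec}: R={R} outside [{b.lower}, {b.upper}]"

    def test_bounds_are_exact_rationals(self):
        b = state_count_bounds(5, 7)
        assert isinstance(b.lower, Fraction) and isinstance(b.upper, Fraction)
        assert b.lower == 2 + Fraction(30, 7)


class TestReducedDynamics:
    def test_lifted_stationary_distribution_matches_orbit_sums(self):
        """The reduced chain of a mutating symmetric model must carry the
        orbit-summed stationary mass of the full chain."""
        from selsym import stationary_distribution
        from selsym.process_core import state_index

        proc = well_mixed_moran(3, u=Fraction(1, 10))
        group = symmetry_group(proc)
        P = build_chain(proc)
        orbits = state_orbits(group)
        chain = build_reduced_chain(P, orbits)
        pi = stationary_distribution(P)
        orbit_mass = [sum(pi.pi[state_index(m)] for m in o.members) for o in orbits]
        # orbit_mass must be stationary for the reduced chain
        for j in range(chain.R):
            assert sum(orbit_mass[i] * chain.entries[i][j] for i in range(chain.R)) == orbit_mass[j]
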