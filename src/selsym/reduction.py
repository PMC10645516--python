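"""Orbit reduction of the selection chain and Burnside/Polya counting.

Two states are equivalent when some symmetry carries one to the other;
the equivalence classes are the orbits of the group's right action on
{0,1}^n.  Because symmetries preserve transition probabilities, the
chain is strongly lumpable over this partition: summing each row over a
target orbit gives the same value for every member of the source orbit,
and the quotient ("reduced") chain on orbits is again Markov.

The number of orbits R is computed without enumeration by Burnside's
lemma, R = (1/S) * sum_sigma m^{c(sigma)}, where c(sigma) is the number
of cycles of sigma and m the number of alleles, and is bracketed — from
the group order alone — by

    max(n + 1, 2 + (2^n - 2)/S)  <=  R  <=
        2 + (1/S) * sum_{k=1}^{n-1} C(n, k) * gcd(S, k! (n-k)!).

For the rotation group of the directed n-cycle the Burnside sum closes
to the classical binary-necklace count (1/n) * sum_j 2^{gcd(n, j)}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .markov import TransitionMatrix
from .process_core import FLOAT_TOL, State, all_states, state_index
from .symmetry import Permutation, SymmetryGroup, apply_permutation

__all__ = [
    "StateOrbit",
    "ReducedChain",
    "CycleDecomposition",
    "StateCountBounds",
    "state_orbits",
    "build_reduced_chain",
    "cycle_count",
    "count_reduced_states",
    "count_directed_cycle",
    "state_count_bounds",
    "ORBIT_MAX_N",
]

ORBIT_MAX_N = 12


@dataclass(frozen=True)
class StateOrbit:
    """One equivalence class [x] = {x sigma} of states under the group."""

    members: frozenset[State]
    representative: State
    allele_counts: tuple[int, ...]  # count of each allele value, shared by members

    @property
    def allele_count(self) -> int:
        """Number of 1 alleles (binary shorthand for allele_counts[1])."""
        return self.allele_counts[1]

    @property
    def size(self) -> int:
        return len(self.members)

    def label(self) -> str:
        return "".join(str(a) for a in self.representative)


def state_orbits(
    group: SymmetryGroup, n: int | None = None, num_alleles: int = 2, *, max_n: int = ORBIT_MAX_N
) -> list[StateOrbit]:
    """All orbits of the right action on allele assignments, ordered by
    the state index of their (minimal-index) representative."""
    if n is None:
        n = group.n
    if n != group.n:
        raise ValueError(f"n = {n} does not match the group's site count {group.n}")
    if n > max_n:
        raise ValueError(f"orbit enumeration over {num_alleles}^{n} states refused (limit n={max_n})")
    elems = list(group.elements)
    seen: set[State] = set()
    orbits: list[StateOrbit] = []
    for x in all_states(n, num_alleles):
        if x in seen:
            continue
        members = frozenset(apply_permutation(x, sigma) for sigma in elems)
        seen.update(members)
        rep = min(members, key=lambda s: state_index(s, num_alleles))
        counts = tuple(sum(1 for a in rep if a == v) for v in range(num_alleles))
        for m in members:
            if tuple(sum(1 for a in m if a == v) for v in range(num_alleles)) != counts:
                raise AssertionError("orbit members disagree on allele counts")
        orbits.append(StateOrbit(members=members, representative=rep, allele_counts=counts))
    return orbits


class LumpabilityError(ValueError):
    """Raised when row sums over a target orbit differ within a source
    orbit — the partition was not built from true symmetries."""


@dataclass
class ReducedChain:
    """The quotient chain on state orbits (rows/columns in orbit order)."""

    orbits: list[StateOrbit]
    entries: list[list]

    @property
    def R(self) -> int:
        return len(self.orbits)

    def orbit_index_of_state(self, x: State) -> int:
        for k, orb in enumerate(self.orbits):
            if x in orb.members:
                return k
        raise ValueError(f"state {x} not covered by the orbit partition")

    def to_csv(self) -> str:
        lines = ["orbit," + ",".join(o.label() for o in self.orbits)]
        for o, row in zip(self.orbits, self.entries):
            lines.append(o.label() + "," + ",".join(str(v) for v in row))
        return "\n".join(lines) + "\n"


def build_reduced_chain(P: TransitionMatrix, orbits: list[StateOrbit]) -> ReducedChain:
    """Lump the chain over the orbit partition.

    entry([x], [y]) = sum_{z in [y]} P(x -> z), evaluated at the orbit
    representative.  Before returning, the strong-lumpability condition
    is verified for every member of every source orbit; a violation
    indicates the partition did not come from true symmetries.
    """
    covered = set()
    for orb in orbits:
        covered.update(orb.members)
    if len(covered) != P.size:
        raise ValueError("orbit partition does not cover the state space")
    orbit_of: dict[int, int] = {}
    for k, orb in enumerate(orbits):
        for x in orb.members:
            orbit_of[state_index(x)] = k
    R = len(orbits)
    zero = Fraction(0) if P.exact else 0.0
    entries = []
    for k, orb in enumerate(orbits):
        sums_per_member: list[list] = []
        for x in orb.members:
            sums = [zero] * R
            for j, p in P.rows[state_index(x)].items():
                sums[orbit_of[j]] += p
            sums_per_member.append(sums)
        ref = sums_per_member[0]
        members = list(orb.members)
        for mi, sums in enumerate(sums_per_member[1:], start=1):
            for t in range(R):
                a, b = ref[t], sums[t]
                same = a == b if P.exact else abs(float(a) - float(b)) <= FLOAT_TOL
                if not same:
                    raise LumpabilityError(
                        f"orbit {orb.label()} is not lumpable: members "
                        f"{members[0]} and {members[mi]} give row sums {a} vs {b} "
                        f"onto orbit {orbits[t].label()}"
                    )
        rep_sums = [zero] * R
        for j, p in P.rows[state_index(orb.representative)].items():
            rep_sums[orbit_of[j]] += p
        entries.append(rep_sums)
    return ReducedChain(orbits=orbits, entries=entries)


@dataclass(frozen=True)
class CycleDecomposition:
    """Disjoint cycles of a permutation and their count c(sigma)."""

    cycles: tuple[tuple[int, ...], ...]

    @property
    def count(self) -> int:
        return len(self.cycles)


def cycle_count(sigma: Permutation) -> CycleDecomposition:
    """Cycle decomposition of a site permutation; sites g, h share a
    cycle iff g = sigma^k(h) for some power k."""
    return CycleDecomposition(cycles=tuple(tuple(c) for c in sigma.cycles()))


def count_reduced_states(group: SymmetryGroup, num_alleles: int = 2) -> int:
    """Burnside count of state orbits: R = (1/S) sum_sigma m^{c(sigma)}."""
    if num_alleles < 1:
        raise ValueError("need at least one allele type")
    S = group.order
    total = sum(num_alleles ** cycle_count(sigma).count for sigma in group.elements)
    R, rem = divmod(total, S)
    if rem:
        raise ValueError(
            f"Burnside sum {total} is not divisible by the group order {S}; "
            "the element set is not a group"
        )
    return R


def count_directed_cycle(n: int, num_alleles: int = 2) -> int:
    """Orbit count under rotations of the n-cycle (the necklace count):
    R = (1/n) sum_{j=1}^{n} m^{gcd(n, j)}.  Rotating by j vertices has
    gcd(n, j) cycles."""
    if n < 1:
        raise ValueError("n must be positive")
    total = sum(num_alleles ** math.gcd(n, j) for j in range(1, n + 1))
    R, rem = divmod(total, n)
    assert rem == 0, "necklace sum must be divisible by n"
    return R


@dataclass(frozen=True)
class StateCountBounds:
    """Exact rational lower/upper bounds on the reduced state count."""

    lower: Fraction
    upper: Fraction

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"lower bound {self.lower} exceeds upper bound {self.upper}")

    def contains(self, R: int) -> bool:
        return self.lower <= R <= self.upper


def state_count_bounds(n: int, S: int) -> StateCountBounds:
    """Bounds on the binary orbit count from n and the group order alone.

    lower = max(n + 1, 2 + (2^n - 2)/S): one orbit per possible number
    of 1 alleles, and reduction by at most a factor S outside the two
    single-allele states.  upper = 2 + (1/S) sum_k C(n,k) gcd(S, k!(n-k)!):
    the least reduction achievable among states with k alleles of type 1.
    Returned unrounded; R is an integer, so comparisons stay exact.
    """
    if n < 1 or S < 1:
        raise ValueError("need n >= 1 and S >= 1")
    lower = max(Fraction(n + 1), 2 + Fraction(2**n - 2, S))
    upper = Fraction(2) + Fraction(
        sum(
            math.comb(n, k) * math.gcd(S, math.factorial(k) * math.factorial(n - k))
            for k in range(1, n)
        ),
        S,
    )
    return StateCountBounds(lower=lower, upper=upper)
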