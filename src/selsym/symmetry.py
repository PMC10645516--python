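"""Symmetries of a selection process: detection, group closure, orbits.

A symmetry is a permutation sigma of the sites such that, for every
state x and every replacement event (alpha, U),

    p_x(alpha, U) = p_{x sigma}(sigma^-1 o alpha o sigma, sigma^-1(U)),

where x sigma denotes the permuted state with (x sigma)_g = x_{sigma(g)}.
The symmetries of a process form a group under composition; the group
acts on sites on the left (g -> sigma(g)) and on states on the right
(x -> x sigma), and every symmetry preserves the transition
probabilities of the selection Markov chain: P(x -> y) =
P(x sigma -> y sigma).

Conventions.  compose(sigma, tau)(g) = sigma(tau(g)), which together
with the right state action gives (x sigma) tau = x (sigma o tau).
Cycle notation is printed 1-based with fixed points shown, matching the
usual display of site labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .markov import TransitionMatrix
from .process_core import FLOAT_TOL, ZERO_TOL, SelectionProcess, State, all_states, state_index

__all__ = [
    "Permutation",
    "SymmetryGroup",
    "apply_permutation",
    "is_symmetry",
    "symmetry_group",
    "site_orbits",
    "verify_transition_preservation",
    "PreservationReport",
    "BRUTE_FORCE_MAX_N",
]

BRUTE_FORCE_MAX_N = 8  # n! candidates; 8! = 40320 is the practical ceiling


@dataclass(frozen=True)
class Permutation:
    """A bijection of the n sites, stored as its image vector."""

    image: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.image)
        if sorted(self.image) != list(range(n)):
            raise ValueError(f"image {self.image} is not a permutation of 0..{n - 1}")

    @classmethod
    def identity(cls, n: int) -> "Permutation":
        return cls(tuple(range(n)))

    @classmethod
    def from_cycles(cls, n: int, cycles: Sequence[Sequence[int]], *, one_based: bool = False) -> "Permutation":
        """Build from disjoint cycles, e.g. [(0, 2, 4), (1, 3)]."""
        image = list(range(n))
        seen: set[int] = set()
        for cyc in cycles:
            cyc = [c - 1 for c in cyc] if one_based else list(cyc)
            if seen.intersection(cyc):
                raise ValueError("cycles are not disjoint")
            seen.update(cyc)
            for i, g in enumerate(cyc):
                image[g] = cyc[(i + 1) % len(cyc)]
        return cls(tuple(image))

    @property
    def n(self) -> int:
        return len(self.image)

    def __call__(self, g: int) -> int:
        return self.image[g]

    def compose(self, other: "Permutation") -> "Permutation":
        """(self o other)(g) = self(other(g))."""
        if self.n != other.n:
            raise ValueError("size mismatch")
        return Permutation(tuple(self.image[other.image[g]] for g in range(self.n)))

    def inverse(self) -> "Permutation":
        inv = [0] * self.n
        for g, h in enumerate(self.image):
            inv[h] = g
        return Permutation(tuple(inv))

    def cycles(self) -> list[list[int]]:
        """Disjoint cycles (fixed points included), each starting at its
        minimal site, ordered by that minimum."""
        seen: set[int] = set()
        out: list[list[int]] = []
        for start in range(self.n):
            if start in seen:
                continue
            cyc = [start]
            seen.add(start)
            g = self.image[start]
            while g != start:
                cyc.append(g)
                seen.add(g)
                g = self.image[g]
            out.append(cyc)
        return out

    def cycle_string(self) -> str:
        """1-based disjoint-cycle display, fixed points shown."""
        return "".join("(" + " ".join(str(g + 1) for g in cyc) + ")" for cyc in self.cycles())

    def is_identity(self) -> bool:
        return all(self.image[g] == g for g in range(self.n))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Permutation{self.cycle_string()}"


def apply_permutation(x: Sequence[int], sigma: Permutation) -> State:
    """The right action of sigma on a state: result_g = x_{sigma(g)}."""
    x = tuple(x)
    if len(x) != sigma.n:
        raise ValueError(f"state length {len(x)} != permutation size {sigma.n}")
    return tuple(x[sigma.image[g]] for g in range(sigma.n))


class SymmetryGroup:
    """A set of permutations closed under composition and inverse."""

    def __init__(self, elements: Iterable[Permutation], *, check: bool = True):
        elems = frozenset(elements)
        if not elems:
            raise ValueError("a group needs at least the identity")
        n = next(iter(elems)).n
        if any(p.n != n for p in elems):
            raise ValueError("mixed permutation sizes")
        if check:
            if Permutation.identity(n) not in elems:
                raise ValueError("group must contain the identity")
            for p in elems:
                if p.inverse() not in elems:
                    raise ValueError(f"group not closed under inverse: {p.cycle_string()}")
            for p in elems:
                for q in elems:
                    if p.compose(q) not in elems:
                        raise ValueError(
                            f"group not closed under composition: "
                            f"{p.cycle_string()} o {q.cycle_string()}"
                        )
        self.elements = elems
        self.n = n

    @property
    def order(self) -> int:
        return len(self.elements)

    @classmethod
    def trivial(cls, n: int) -> "SymmetryGroup":
        return cls([Permutation.identity(n)], check=False)

    @classmethod
    def generated_by(cls, generators: Iterable[Permutation]) -> "SymmetryGroup":
        """Closure of the generators under composition (finite, so this
        also closes under inverse)."""
        gens = list(generators)
        if not gens:
            raise ValueError("need at least one generator")
        n = gens[0].n
        elems = {Permutation.identity(n)}
        frontier = list(elems)
        while frontier:
            new: list[Permutation] = []
            for p in frontier:
                for g in gens:
                    q = g.compose(p)
                    if q not in elems:
                        elems.add(q)
                        new.append(q)
            frontier = new
        return cls(elems, check=False)

    def __contains__(self, p: Permutation) -> bool:
        return p in self.elements

    def __iter__(self):
        return iter(sorted(self.elements, key=lambda p: p.image))

    def __eq__(self, other) -> bool:
        return isinstance(other, SymmetryGroup) and self.elements == other.elements

    def __hash__(self) -> int:
        return hash(self.elements)

    def to_json(self) -> list[list[int]]:
        return [list(p.image) for p in self]

    def cycle_strings(self) -> list[str]:
        return [p.cycle_string() for p in self]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SymmetryGroup(n={self.n}, order={self.order})"


# ---------------------------------------------------------------------------
# The symmetry test
# ---------------------------------------------------------------------------


def _probs_equal(p, q, exact: bool) -> bool:
    if exact:
        return p == q
    p, q = float(p), float(q)
    return abs(p - q) <= FLOAT_TOL * max(1.0, abs(p), abs(q))


def is_symmetry(process: SelectionProcess, sigma: Permutation) -> bool:
    """Test the defining probability-preservation condition.

    For every state x and support event (alpha, U) of x, the event
    (sigma^-1 o alpha o sigma, sigma^-1(U)) must carry the same
    probability in state x sigma, and the two supports must correspond
    exactly (no unmatched event on either side).
    """
    if sigma.n != process.n:
        raise ValueError(f"permutation size {sigma.n} != site count {process.n}")
    sg = sigma.image
    inv = sigma.inverse().image
    exact = process.exact
    for x in all_states(process.n):
        ev_x = process.event_table(x)
        ev_xs = process.event_table(apply_permutation(x, sigma))
        if exact and len(ev_x) != len(ev_xs):
            return False
        matched = 0
        for (alpha, U), p in ev_x.items():
            if not exact and float(p) < ZERO_TOL:
                continue
            # beta = sigma^-1 o alpha o sigma ; V = sigma^-1(U)
            beta = tuple(inv[alpha[sg[g]]] for g in range(process.n))
            V = frozenset(inv[u] for u in U)
            q = ev_xs.get((beta, V))
            if q is None or not _probs_equal(p, q, exact):
                return False
            matched += 1
        if not exact:
            significant = sum(1 for p in ev_xs.values() if float(p) >= ZERO_TOL)
            if matched != significant:
                return False
    return True


def symmetry_group(
    process: SelectionProcess,
    generators: Sequence[Permutation] | None = None,
    *,
    max_n: int = BRUTE_FORCE_MAX_N,
) -> SymmetryGroup:
    """The symmetry group of a process.

    Without generators, brute-forces all n! permutations (n <= max_n;
    the underlying decision problem contains graph automorphism, so no
    efficient general search is attempted).  With generators, each is
    verified and the group returned is their closure, which the group
    property guarantees is contained in the full symmetry group.
    """
    if generators is not None:
        for g in generators:
            if not is_symmetry(process, g):
                raise ValueError(f"supplied generator {g.cycle_string()} is not a symmetry")
        return SymmetryGroup.generated_by(generators)
    n = process.n
    if n > max_n:
        raise ValueError(
            f"brute-force search over {n}! permutations refused for n > {max_n}; "
            "supply generators instead"
        )
    found = [
        Permutation(img)
        for img in itertools.permutations(range(n))
        if is_symmetry(process, Permutation(img))
    ]
    return SymmetryGroup(found, check=False)


@dataclass
class SiteOrbits:
    """Partition of sites into equivalence classes under the group action."""

    orbits: list[list[int]]
    transitive: bool

    def orbit_of(self, g: int) -> list[int]:
        for orb in self.orbits:
            if g in orb:
                return orb
        raise ValueError(f"site {g} not covered")


def site_orbits(group: SymmetryGroup) -> SiteOrbits:
    """Orbits of the left action g -> sigma(g); two sites are equivalent
    iff some symmetry maps one to the other."""
    n = group.n
    seen: set[int] = set()
    orbits: list[list[int]] = []
    for g in range(n):
        if g in seen:
            continue
        orb = sorted({p(g) for p in group.elements})
        orbits.append(orb)
        seen.update(orb)
    return SiteOrbits(orbits=orbits, transitive=len(orbits) == 1)


@dataclass
class PreservationReport:
    """Outcome of checking P(x -> y) = P(x sigma -> y sigma) everywhere."""

    steps: int
    checked: int = 0
    violations: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_transition_preservation(
    P: TransitionMatrix, group: SymmetryGroup, *, steps: int = 1
) -> PreservationReport:
    """Check transition-probability preservation for every group element.

    With steps=m the check runs on the m-step matrix P^m, confirming
    that multi-step dynamics are preserved as well.  Returns a report
    listing any violating (sigma, x, y) triple.
    """
    if P.n != group.n:
        raise ValueError("transition matrix and group have different site counts")
    M = P.power(steps) if steps > 1 else P
    states = all_states(P.n)
    report = PreservationReport(steps=steps)
    for sigma in group:
        perm_index = [state_index(apply_permutation(x, sigma)) for x in states]
        inv_index = [0] * M.size
        for j, pj in enumerate(perm_index):
            inv_index[pj] = j
        for i in range(M.size):
            row = M.rows[i]
            prow = M.rows[perm_index[i]]
            cols = set(row) | {inv_index[c] for c in prow}
            for j in cols:
                p = row.get(j, 0)
                q = prow.get(perm_index[j], 0)
                report.checked += 1
                if not _probs_equal(p, q, M.exact):
                    report.violations.append((sigma.cycle_string(), i, j))
    return report
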