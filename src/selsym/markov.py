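"""The selection Markov chain on {0,1}^n and its derived quantities.

From a selection process, each time step samples a replacement event
(alpha, U) and forms the next state by inheritance-with-flip: a site
outside U copies the allele of its parent alpha(g); a site in U copies
the opposite allele.  This induces a Markov chain on the 2^n population
states, from which fixation (absorption) probabilities and stationary
distributions are computed here by exact linear algebra whenever the
process uses rational probabilities.

States are indexed by index(x) = sum_g x_g * 2^g (site 0 least
significant); the transition matrix is stored sparsely as one dict per
row, which keeps exact rational arithmetic cheap for the sparse chains
produced by Moran-type models.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .process_core import (
    DEFAULT_CHAIN_MAX_N,
    FLOAT_TOL,
    MutationSet,
    ParentageMap,
    SelectionProcess,
    State,
    all_states,
    state_from_index,
    state_index,
)

__all__ = [
    "TransitionMatrix",
    "FixationVector",
    "StationaryDistribution",
    "next_state",
    "build_chain",
    "fixation_probabilities",
    "stationary_distribution",
]


def next_state(x: Sequence[int], alpha: Sequence[int], U: Iterable[int]) -> State:
    """Apply one replacement event: x'_g = x_{alpha(g)}, flipped on U."""
    x = tuple(x)
    n = len(x)
    alpha = tuple(alpha)
    if len(alpha) != n:
        raise ValueError(f"parentage map length {len(alpha)} != state length {n}")
    U = frozenset(U)
    if any(not (0 <= a < n) for a in alpha) or any(not (0 <= g < n) for g in U):
        raise IndexError("site index out of range")
    return tuple(1 - x[alpha[g]] if g in U else x[alpha[g]] for g in range(n))


class TransitionMatrix:
    """Row-stochastic transition matrix over all 2^n states.

    Rows are stored as sparse {column: probability} dicts in state-index
    order.  Entries are exact Fractions for exact processes.
    """

    def __init__(self, n: int, rows: list[dict[int, Fraction | float]], *, exact: bool = True):
        self.n = n
        self.size = 2**n
        if len(rows) != self.size:
            raise ValueError(f"expected {self.size} rows, got {len(rows)}")
        self.rows = rows
        self.exact = exact
        for i, row in enumerate(rows):
            total = sum(row.values())
            if exact:
                if total != 1:
                    raise ValueError(f"row {i} sums to {total}, not 1")
            elif abs(float(total) - 1.0) > FLOAT_TOL:
                raise ValueError(f"row {i} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"row {i} has a negative entry")

    def prob(self, i: int, j: int) -> Fraction | float:
        """P(x -> y) by state index."""
        return self.rows[i].get(j, Fraction(0) if self.exact else 0.0)

    def matmul(self, other: "TransitionMatrix") -> "TransitionMatrix":
        """Exact sparse product; used for m-step transition checks."""
        if self.n != other.n:
            raise ValueError("size mismatch")
        rows: list[dict[int, Fraction | float]] = []
        for i in range(self.size):
            acc: dict[int, Fraction | float] = {}
            for k, p in self.rows[i].items():
                for j, q in other.rows[k].items():
                    acc[j] = acc.get(j, 0) + p * q
            rows.append(acc)
        return TransitionMatrix(self.n, rows, exact=self.exact and other.exact)

    def power(self, m: int) -> "TransitionMatrix":
        if m < 1:
            raise ValueError("power must be >= 1")
        out = self
        for _ in range(m - 1):
            out = out.matmul(self)
        return out

    def to_dense(self) -> np.ndarray:
        """Dense float copy (for numeric work and export)."""
        P = np.zeros((self.size, self.size))
        for i, row in enumerate(self.rows):
            for j, p in row.items():
                P[i, j] = float(p)
        return P

    def to_csv(self) -> str:
        """Dense CSV with state bitstrings (site 1 leftmost) as headers."""
        labels = ["".join(str(a) for a in state_from_index(i, self.n)) for i in range(self.size)]
        lines = ["state," + ",".join(labels)]
        for i, row in enumerate(self.rows):
            vals = [str(row.get(j, 0)) for j in range(self.size)]
            lines.append(labels[i] + "," + ",".join(vals))
        return "\n".join(lines) + "\n"

    def to_coo_text(self) -> str:
        """Sparse coordinate text: 'source target probability' per line."""
        lines = []
        for i, row in enumerate(self.rows):
            for j in sorted(row):
                lines.append(f"{i} {j} {row[j]}")
        return "\n".join(lines) + "\n"


def build_chain(process: SelectionProcess, *, max_n: int = DEFAULT_CHAIN_MAX_N) -> TransitionMatrix:
    """Assemble the selection Markov chain M(G, p).

    P(x -> y) sums the probabilities of all support events of x whose
    application lands in y.
    """
    n = process.n
    if n > max_n:
        raise ValueError(f"n = {n} exceeds the chain size limit {max_n} (2^n states)")
    rows: list[dict[int, Fraction | float]] = []
    for x in all_states(n):
        row: dict[int, Fraction | float] = {}
        for (alpha, U), p in process.event_table(x).items():
            j = state_index(next_state(x, alpha, U))
            row[j] = row.get(j, 0) + p
        rows.append(row)
    return TransitionMatrix(n, rows, exact=process.exact)


@dataclass
class FixationVector:
    """Absorption probability into the all-1 state, per state index."""

    n: int
    rho: list

    def __post_init__(self) -> None:
        size = 2**self.n
        if len(self.rho) != size:
            raise ValueError("rho has wrong length")
        if self.rho[0] != 0 or self.rho[size - 1] != 1:
            raise ValueError("rho must be 0 at the all-0 state and 1 at the all-1 state")

    def at_state(self, x: Sequence[int]):
        return self.rho[state_index(x)]

    def single_mutant(self, g: int):
        """rho of the state with allele 1 only at site g."""
        return self.rho[1 << g]


@dataclass
class StationaryDistribution:
    """The unique stationary distribution pi of an ergodic-enough chain."""

    n: int
    pi: list

    def at_state(self, x: Sequence[int]):
        return self.pi[state_index(x)]


# ---------------------------------------------------------------------------
# Exact linear algebra over Fractions
# ---------------------------------------------------------------------------


def _solve_exact(A: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Gaussian elimination with partial (first-nonzero) pivoting."""
    m = len(A)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(m):
        pivot = next((r for r in range(col, m) if M[r][col] != 0), None)
        if pivot is None:
            raise np.linalg.LinAlgError("singular system")
        M[col], M[pivot] = M[pivot], M[col]
        pv = M[col][col]
        M[col] = [v / pv for v in M[col]]
        for r in range(m):
            if r != col and M[r][col] != 0:
                factor = M[r][col]
                M[r] = [vr - factor * vc for vr, vc in zip(M[r], M[col])]
    return [M[i][m] for i in range(m)]


def _nullspace_exact(A: list[list[Fraction]]) -> list[list[Fraction]]:
    """Basis of the nullspace of a square rational matrix (RREF back-substitution)."""
    m = len(A)
    ncols = len(A[0])
    M = [row[:] for row in A]
    pivots: list[int] = []
    r = 0
    for col in range(ncols):
        pivot = next((i for i in range(r, m) if M[i][col] != 0), None)
        if pivot is None:
            continue
        M[r], M[pivot] = M[pivot], M[r]
        pv = M[r][col]
        M[r] = [v / pv for v in M[r]]
        for i in range(m):
            if i != r and M[i][col] != 0:
                f = M[i][col]
                M[i] = [vi - f * vc for vi, vc in zip(M[i], M[r])]
        pivots.append(col)
        r += 1
        if r == m:
            break
    free = [c for c in range(ncols) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * ncols
        v[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            v[pc] = -M[i][fc]
        basis.append(v)
    return basis


def fixation_probabilities(process: SelectionProcess) -> FixationVector:
    """Absorption probabilities into the all-1 state, for mutation-free chains.

    Solves the linear system rho(x) = sum_y P(x -> y) rho(y) on the
    transient states with rho(all-0) = 0, rho(all-1) = 1.  Requires the
    process to be mutation-free; the fixation axiom guarantees the two
    single-allele states are the only recurrent ones, which makes the
    system non-singular.
    """
    n = process.n
    for x in process.states():
        for (alpha, U), _ in process.event_table(x).items():
            if U:
                raise ValueError(
                    "fixation probabilities are defined for mutation-free processes; "
                    f"state {x} has an event with mutation set {sorted(U)}"
                )
    P = build_chain(process)
    size = 2**n
    zero_idx, one_idx = 0, size - 1
    transient = [i for i in range(size) if i not in (zero_idx, one_idx)]
    pos = {s: k for k, s in enumerate(transient)}
    exact = process.exact
    zero = Fraction(0) if exact else 0.0
    one = Fraction(1) if exact else 1.0
    A = [[zero] * len(transient) for _ in transient]
    b = [zero] * len(transient)
    for k, i in enumerate(transient):
        A[k][k] += one
        for j, p in P.rows[i].items():
            if j == one_idx:
                b[k] += p
            elif j != zero_idx:
                A[k][pos[j]] -= p
    try:
        if exact:
            sol = _solve_exact(A, b)
        else:
            sol = list(np.linalg.solve(np.array(A, dtype=float), np.array(b, dtype=float)))
    except np.linalg.LinAlgError:
        raise ValueError(
            "absorption system is singular: some state cannot reach fixation "
            "(the fixation axiom fails for this process)"
        ) from None
    rho = [zero] * size
    rho[one_idx] = one
    for k, i in enumerate(transient):
        rho[i] = sol[k]
        if not (-FLOAT_TOL <= float(sol[k]) <= 1 + FLOAT_TOL):
            raise ValueError(f"absorption probability {sol[k]} outside [0, 1]")
    return FixationVector(n, rho)


def stationary_distribution(P: TransitionMatrix) -> StationaryDistribution:
    """The unique probability vector pi with pi P = pi.

    Uniqueness is verified by checking that the nullspace of P^T - I is
    one-dimensional; chains with absorbing states (e.g. mutation-free
    processes) fail this check and raise.
    """
    size = P.size
    if P.exact:
        A = [[Fraction(0)] * size for _ in range(size)]
        for i, row in enumerate(P.rows):
            for j, p in row.items():
                A[j][i] += Fraction(p)
        for i in range(size):
            A[i][i] -= 1
        basis = _nullspace_exact(A)
        if len(basis) != 1:
            raise ValueError(
                f"stationary distribution is not unique: null space of P^T - I has "
                f"dimension {len(basis)} (expected 1); the chain is reducible or absorbing"
            )
        v = basis[0]
        total = sum(v)
        if total == 0:
            raise ValueError("degenerate null vector")
        pi = [x / total for x in v]
        if any(x < 0 for x in pi):
            pi = [-x for x in pi]
        if any(x < 0 for x in pi):
            raise ValueError("null vector is not sign-definite; no valid stationary distribution")
    else:
        dense = P.to_dense()
        A = dense.T - np.eye(size)
        u, s, vt = np.linalg.svd(A)
        null_dim = int(np.sum(s < 1e-10))
        if null_dim != 1:
            raise ValueError(
                f"stationary distribution is not unique: null space of P^T - I has "
                f"dimension {null_dim} (expected 1)"
            )
        v = vt[-1]
        pi_arr = v / v.sum()
        if np.any(pi_arr < -FLOAT_TOL):
            raise ValueError("no non-negative stationary vector found")
        pi = [float(max(x, 0.0)) for x in pi_arr]
    return StationaryDistribution(P.n, pi)
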