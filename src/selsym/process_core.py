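"""Core domain types for finite two-allele selection processes.

A selection process is a pair (G, p): a finite set of genetic sites
(indexed 0..n-1) together with, for every population state x in {0,1}^n,
a joint probability distribution over replacement events.  A replacement
event is a pair (alpha, U): a parentage map ``alpha`` (site g inherits
its allele from site alpha(g)) and a mutation set ``U`` (sites whose
inherited allele is flipped).  All standard finite-population models —
Moran, Wright–Fisher, graph-structured, class-structured, island — can
be expressed in this form, which is what the constructors below do.

Update-rule conventions for the built-in models
-----------------------------------------------
The model families are classical; their microscopic details (whether a
site may replace itself, how death and birth are ordered) vary across
the literature, so the exact rules used here are fixed and documented:

``well_mixed_moran``
    One site dies, chosen uniformly over all n sites (self-replacement
    allowed); the parent is drawn over all sites proportional to fitness
    (r for allele 1, 1 for allele 0).  alpha is the identity except
    alpha(dead) = parent.
``wright_fisher``
    Every site independently draws its parent proportional to fitness;
    the support therefore contains all n^n parentage maps (capped at
    n <= 6 unless ``allow_large=True``).
``graph_moran_db``
    Death–birth on a weighted (di)graph: the dying site is uniform over
    all sites; the parent is drawn among in-neighbours of the dying site
    with probability proportional to edge weight x fitness.
``graph_moran_bd``
    Birth–death: the parent is drawn over all sites proportional to
    fitness; the offspring replaces an out-neighbour of the parent
    chosen proportional to edge weight.
``directed_cycle_moran`` / ``undirected_cycle_moran`` / ``star_moran_db``
    Death–birth on the corresponding graph (sites 0..n-1 around the
    cycle; site 0 is the star's hub).
``class_moran``
    Sites are grouped into classes of given sizes (consecutive index
    blocks).  The dying site is uniform; the parent is drawn over all
    sites with weight W[class(parent)][class(dead)] x fitness, where W
    is the class-to-class parent-weight matrix (default: 1 within a
    class, 1/2 across classes, which breaks cross-class symmetry).
``island_moran``
    m islands of k sites each.  The dying site is uniform; with
    probability 1 - mig the parent is drawn within the dying site's
    island (proportional to fitness), with probability mig it is drawn
    among all sites of the other islands.  mig must be strictly between
    0 and 1 so that ancestry can spread everywhere.

Mutation is iid per site with probability u, applied after replacement,
so p_x(alpha, U) = p_x(alpha) * u^|U| * (1-u)^(n-|U|).

Probabilities are exact ``fractions.Fraction`` values whenever the model
parameters are rational; symmetry detection and lumpability checks are
equality tests, and exact arithmetic removes false negatives.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "State",
    "ParentageMap",
    "MutationSet",
    "ReplacementEvent",
    "SelectionProcess",
    "ProcessDiagnostics",
    "all_states",
    "state_index",
    "state_from_index",
    "make_model",
    "enumerate_support",
    "validate_process",
    "well_mixed_moran",
    "wright_fisher",
    "graph_moran_db",
    "graph_moran_bd",
    "directed_cycle_moran",
    "undirected_cycle_moran",
    "star_moran_db",
    "class_moran",
    "island_moran",
    "explicit_table",
    "BUILTIN_MODELS",
]

# A population state: allele (0 or 1) per site.  A parentage map: entry g
# holds alpha(g), the site g inherits from; it need not be a bijection.
State = tuple[int, ...]
ParentageMap = tuple[int, ...]
MutationSet = frozenset[int]

Prob = Union[Fraction, float]

FLOAT_TOL = 1e-9  # relative tolerance for float-mode probability checks
ZERO_TOL = 1e-15  # float probabilities below this count as absent

WRIGHT_FISHER_MAX_N = 6
DEFAULT_CHAIN_MAX_N = 12


def all_states(n: int, num_alleles: int = 2) -> list[State]:
    """All allele assignments over ``n`` sites, in state-index order.

    The state index is sum_g x_g * num_alleles**g (site 0 least
    significant); this bijection is used across the whole package.
    """
    states = []
    for i in range(num_alleles**n):
        states.append(state_from_index(i, n, num_alleles))
    return states


def state_index(x: Sequence[int], num_alleles: int = 2) -> int:
    return sum(int(a) * num_alleles**g for g, a in enumerate(x))


def state_from_index(i: int, n: int, num_alleles: int = 2) -> State:
    x = []
    for _ in range(n):
        i, a = divmod(i, num_alleles)
        x.append(a)
    return tuple(x)


@dataclass(frozen=True)
class ReplacementEvent:
    """One support atom (alpha, U) with its probability."""

    alpha: ParentageMap
    mutated: MutationSet
    prob: Prob

    def __post_init__(self) -> None:
        n = len(self.alpha)
        if any(not (0 <= a < n) for a in self.alpha):
            raise ValueError(f"parentage map {self.alpha} has out-of-range entries")
        if any(not (0 <= g < n) for g in self.mutated):
            raise ValueError(f"mutation set {sorted(self.mutated)} not a subset of sites")
        if not self.prob > 0:
            raise ValueError("event probability must be positive")


EventKey = tuple[ParentageMap, MutationSet]
SupportTable = dict[State, dict[EventKey, Prob]]


class SelectionProcess:
    """A selection process (G, p) with explicitly enumerated support.

    Parameters
    ----------
    n:
        Number of sites.
    support:
        For every state, a mapping from (alpha, U) to its probability.
        Probabilities must be positive and sum to one per state.
    exact:
        Whether probabilities are exact rationals.  Inferred from the
        table when omitted.
    name, site_labels:
        Display metadata; site labels default to 1-based numbers.
    """

    def __init__(
        self,
        n: int,
        support: SupportTable,
        *,
        exact: bool | None = None,
        name: str = "explicit",
        site_labels: Sequence[str] | None = None,
        validate: bool = True,
    ) -> None:
        if n < 1:
            raise ValueError("site count must be at least 1")
        self.n = n
        self.name = name
        self.site_labels = (
            list(site_labels) if site_labels is not None else [str(g + 1) for g in range(n)]
        )
        if len(self.site_labels) != n:
            raise ValueError("site_labels length must equal n")
        states = all_states(n)
        missing = [x for x in states if x not in support]
        if missing:
            raise ValueError(f"support missing for state {missing[0]} (and possibly others)")
        if exact is None:
            exact = all(
                isinstance(p, Rational) for ev in support.values() for p in ev.values()
            )
        self.exact = bool(exact)
        self._support: SupportTable = {}
        for x in states:
            events = support[x]
            if not events:
                raise ValueError(f"state {x} has empty support")
            clean: dict[EventKey, Prob] = {}
            for (alpha, mutated), p in events.items():
                ReplacementEvent(tuple(alpha), frozenset(mutated), p)  # validates
                clean[(tuple(alpha), frozenset(mutated))] = p
            self._support[x] = clean
        if validate:
            self._check_normalization()

    # -- basic accessors -------------------------------------------------

    def states(self) -> list[State]:
        return all_states(self.n)

    def events(self, x: State) -> list[ReplacementEvent]:
        """The aggregated support of state ``x`` as a sorted event list."""
        x = tuple(x)
        if len(x) != self.n:
            raise ValueError(f"state length {len(x)} != site count {self.n}")
        if x not in self._support:
            raise ValueError(f"state {x} is not a valid binary state")
        items = sorted(
            self._support[x].items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
        )
        return [ReplacementEvent(a, u, p) for (a, u), p in items]

    def event_table(self, x: State) -> Mapping[EventKey, Prob]:
        """Raw {(alpha, U): prob} mapping for state ``x`` (read-only use)."""
        return self._support[tuple(x)]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        mode = "exact" if self.exact else "float"
        return f"SelectionProcess({self.name!r}, n={self.n}, {mode})"

    # -- validation ------------------------------------------------------

    def _check_normalization(self) -> None:
        for x, events in self._support.items():
            total = sum(events.values())
            if self.exact:
                if total != 1:
                    raise ValueError(f"probabilities in state {x} sum to {total}, not 1")
            elif abs(float(total) - 1.0) > FLOAT_TOL:
                raise ValueError(f"probabilities in state {x} sum to {total}, not 1")


@dataclass
class ProcessDiagnostics:
    """Findings of :func:`validate_process`; never raises."""

    n: int
    probability_deviation: dict[int, float] = field(default_factory=dict)
    malformed: list[str] = field(default_factory=list)
    fixation_axiom_holds: bool | None = None

    @property
    def ok(self) -> bool:
        return (
            not self.probability_deviation
            and not self.malformed
            and self.fixation_axiom_holds is not False
        )


# ---------------------------------------------------------------------------
# Model constructors
# ---------------------------------------------------------------------------


def _as_rational(value, name: str) -> Fraction | float:
    """Exact Fraction for int/Fraction/str inputs, float passthrough."""
    if isinstance(value, bool):
        raise ValueError(f"{name} must be a number")
    if isinstance(value, Rational):
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, float):
        return value
    raise ValueError(f"{name} must be rational or float, got {type(value).__name__}")


def _check_params(n: int, r, u) -> tuple[Fraction | float, Fraction | float]:
    if n < 1:
        raise ValueError("site count n must be positive")
    r = _as_rational(r, "r")
    u = _as_rational(u, "u")
    if not r > 0:
        raise ValueError(f"fitness r must be positive, got {r}")
    if not (0 <= u <= 1):
        raise ValueError(f"mutation probability u must lie in [0, 1], got {u}")
    return r, u


def _fitness(x: State, r) -> list:
    one = Fraction(1) if isinstance(r, Rational) else 1.0
    return [r if a == 1 else one for a in x]


def _with_mutation(base: dict[ParentageMap, Prob], n: int, u) -> dict[EventKey, Prob]:
    """Expand map marginals into (alpha, U) events with iid mutation."""
    if u == 0:
        return {(alpha, frozenset()): q for alpha, q in base.items()}
    events: dict[EventKey, Prob] = {}
    sites = range(n)
    for k in range(n + 1):
        for subset in itertools.combinations(sites, k):
            w = u**k * (1 - u) ** (n - k)
            if w == 0:
                continue
            U = frozenset(subset)
            for alpha, q in base.items():
                events[(alpha, U)] = q * w
    return events


def _identity_except(n: int, dead: int, parent: int) -> ParentageMap:
    alpha = list(range(n))
    alpha[dead] = parent
    return tuple(alpha)


def _moran_support_from_parent_weights(
    n: int, u, parent_weight
) -> SupportTable:
    """Generic death–birth support: dead uniform, parent ~ given weights.

    ``parent_weight(x, dead)`` returns the (unnormalised) weight of each
    candidate parent for the given dying site in state ``x``.
    """
    support: SupportTable = {}
    inv_n = Fraction(1, n)
    for x in all_states(n):
        base: dict[ParentageMap, Prob] = {}
        for dead in range(n):
            weights = parent_weight(x, dead)
            total = sum(weights)
            if total == 0:
                raise ValueError(
                    f"site {dead + 1} has no possible parent in state {x} "
                    "(isolated vertex under death-birth updating)"
                )
            for parent, w in enumerate(weights):
                if w == 0:
                    continue
                alpha = _identity_except(n, dead, parent)
                p = inv_n * w / total
                base[alpha] = base.get(alpha, 0) + p
        support[x] = _with_mutation(base, n, u)
    return support


def well_mixed_moran(n: int, r=1, u=0) -> SelectionProcess:
    """Well-mixed Moran model: uniform death, fitness-proportional birth."""
    r, u = _check_params(n, r, u)

    def weight(x: State, dead: int):
        return _fitness(x, r)

    support = _moran_support_from_parent_weights(n, u, weight)
    return SelectionProcess(n, support, name=f"well_mixed_moran(n={n})")


def wright_fisher(n: int, r=1, u=0, *, allow_large: bool = False) -> SelectionProcess:
    """Haploid Wright–Fisher model: all sites resample parents at once."""
    r, u = _check_params(n, r, u)
    if n > WRIGHT_FISHER_MAX_N and not allow_large:
        raise ValueError(
            f"Wright-Fisher support has n^n = {n**n} maps; "
            f"n <= {WRIGHT_FISHER_MAX_N} unless allow_large=True"
        )
    support: SupportTable = {}
    for x in all_states(n):
        w = _fitness(x, r)
        total = sum(w)
        probs = [wi / total for wi in w]
        base: dict[ParentageMap, Prob] = {}
        for alpha in itertools.product(range(n), repeat=n):
            base[alpha] = math.prod((probs[a] for a in alpha), start=Fraction(1))
        support[x] = _with_mutation(base, n, u)
    return SelectionProcess(n, support, name=f"wright_fisher(n={n})")


def _adjacency(graph, n: int | None = None):
    """Coerce a graph argument to a square weight matrix of Fractions."""
    try:
        import networkx as nx

        if isinstance(graph, nx.Graph):  # covers DiGraph too
            nodes = sorted(graph.nodes())
            idx = {v: i for i, v in enumerate(nodes)}
            m = len(nodes)
            A = [[Fraction(0)] * m for _ in range(m)]
            directed = graph.is_directed()
            for a, b, data in graph.edges(data=True):
                w = _as_rational(data.get("weight", 1), "edge weight")
                A[idx[a]][idx[b]] = w
                if not directed:
                    A[idx[b]][idx[a]] = w
            return A
    except ImportError:  # pragma: no cover
        pass
    arr = np.asarray(graph, dtype=object)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"adjacency size {arr.shape[0]} != n = {n}")
    return [[_as_rational(v, "edge weight") for v in row] for row in arr.tolist()]


def graph_moran_db(graph, r=1, u=0) -> SelectionProcess:
    """Death–birth Moran model on a weighted (di)graph.

    Edge i->j with weight w means i can parent j; the dying site is
    uniform and its parent is drawn among in-neighbours proportional to
    weight x fitness.
    """
    A = _adjacency(graph)
    n = len(A)
    r, u = _check_params(n, r, u)

    def weight(x: State, dead: int):
        f = _fitness(x, r)
        return [A[i][dead] * f[i] for i in range(n)]

    support = _moran_support_from_parent_weights(n, u, weight)
    return SelectionProcess(n, support, name=f"graph_moran_db(n={n})")


def graph_moran_bd(graph, r=1, u=0) -> SelectionProcess:
    """Birth–death Moran model: fitness-proportional birth, then the
    offspring replaces an out-neighbour chosen proportional to weight."""
    A = _adjacency(graph)
    n = len(A)
    r, u = _check_params(n, r, u)
    out_totals = [sum(A[i]) for i in range(n)]
    if any(t == 0 for t in out_totals):
        bad = out_totals.index(0)
        raise ValueError(f"site {bad + 1} has no out-neighbours (offspring has nowhere to go)")
    support: SupportTable = {}
    for x in all_states(n):
        f = _fitness(x, r)
        W = sum(f)
        base: dict[ParentageMap, Prob] = {}
        for parent in range(n):
            for dead in range(n):
                if A[parent][dead] == 0:
                    continue
                alpha = _identity_except(n, dead, parent)
                p = (f[parent] / W) * (A[parent][dead] / out_totals[parent])
                base[alpha] = base.get(alpha, 0) + p
        support[x] = _with_mutation(base, n, u)
    return SelectionProcess(n, support, name=f"graph_moran_bd(n={n})")


def _cycle_matrix(n: int, directed: bool):
    A = [[Fraction(0)] * n for _ in range(n)]
    for g in range(n):
        A[g][(g + 1) % n] = Fraction(1)
        if not directed:
            A[(g + 1) % n][g] = Fraction(1)
    return A


def directed_cycle_moran(n: int, r=1, u=0) -> SelectionProcess:
    """Death–birth Moran model on the directed n-cycle (edges g -> g+1)."""
    if n < 2:
        raise ValueError("cycle needs at least 2 sites")
    proc = graph_moran_db(_cycle_matrix(n, directed=True), r=r, u=u)
    proc.name = f"directed_cycle_moran(n={n})"
    return proc


def undirected_cycle_moran(n: int, r=1, u=0) -> SelectionProcess:
    """Death–birth Moran model on the undirected n-cycle."""
    if n < 3:
        raise ValueError("undirected cycle needs at least 3 sites")
    proc = graph_moran_db(_cycle_matrix(n, directed=False), r=r, u=u)
    proc.name = f"undirected_cycle_moran(n={n})"
    return proc


def star_moran_db(n: int, r=1, u=0) -> SelectionProcess:
    """Death–birth Moran model on the star graph; site 0 is the hub."""
    if n < 3:
        raise ValueError("star needs at least 3 sites")
    A = [[Fraction(0)] * n for _ in range(n)]
    for leaf in range(1, n):
        A[0][leaf] = Fraction(1)
        A[leaf][0] = Fraction(1)
    proc = graph_moran_db(A, r=r, u=u)
    proc.name = f"star_moran_db(n={n})"
    return proc


def class_moran(sizes: Sequence[int], weights=None, r=1, u=0) -> SelectionProcess:
    """Moran model with class structure (sex, caste, role...).

    Sites are grouped into consecutive classes of the given sizes.  The
    dying site is uniform; the parent is drawn over all sites with
    weight ``weights[class(parent)][class(dead)]`` times fitness.  The
    default weight matrix (1 on the diagonal, 1/2 off) makes sites
    within a class interchangeable but classes distinguishable.
    """
    sizes = [int(s) for s in sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("class sizes must be positive")
    n = sum(sizes)
    k = len(sizes)
    r, u = _check_params(n, r, u)
    if weights is None:
        weights = [
            [Fraction(1) if i == j else Fraction(1, 2) for j in range(k)] for i in range(k)
        ]
    else:
        weights = [[_as_rational(w, "class weight") for w in row] for row in weights]
        if len(weights) != k or any(len(row) != k for row in weights):
            raise ValueError("class weight matrix must be k x k")
    cls = []
    for j, s in enumerate(sizes):
        cls.extend([j] * s)

    def weight(x: State, dead: int):
        f = _fitness(x, r)
        return [weights[cls[i]][cls[dead]] * f[i] for i in range(n)]

    support = _moran_support_from_parent_weights(n, u, weight)
    return SelectionProcess(n, support, name=f"class_moran(sizes={tuple(sizes)})")


def island_moran(islands: int, island_size: int, migration=Fraction(1, 10), r=1, u=0) -> SelectionProcess:
    """Moran model on identical islands coupled by migration.

    The dying site is uniform over all m*k sites.  With probability
    1 - migration the parent is drawn within the dying site's island
    (fitness-proportional); with probability migration it comes from the
    other islands.  migration must be in (0, 1) so every site's ancestry
    can reach every other site.
    """
    m, ksize = int(islands), int(island_size)
    if m < 2 or ksize < 1:
        raise ValueError("need at least 2 islands of positive size")
    n = m * ksize
    r, u = _check_params(n, r, u)
    mig = _as_rational(migration, "migration")
    if not (0 < mig < 1):
        raise ValueError(f"migration rate must lie strictly in (0, 1), got {mig}")
    isle = [g // ksize for g in range(n)]

    def weight(x: State, dead: int):
        f = _fitness(x, r)
        home = [i for i in range(n) if isle[i] == isle[dead]]
        away = [i for i in range(n) if isle[i] != isle[dead]]
        home_total = sum(f[i] for i in home)
        away_total = sum(f[i] for i in away)
        w = [Fraction(0)] * n if isinstance(mig, Rational) else [0.0] * n
        for i in home:
            w[i] = (1 - mig) * f[i] / home_total
        for i in away:
            w[i] = mig * f[i] / away_total
        return w

    support = _moran_support_from_parent_weights(n, u, weight)
    return SelectionProcess(n, support, name=f"island_moran({m}x{ksize})")


def explicit_table(n: int, table: SupportTable, *, exact: bool | None = None) -> SelectionProcess:
    """Wrap a user-supplied per-state event table as a process."""
    return SelectionProcess(n, table, exact=exact, name="explicit_table")


BUILTIN_MODELS = {
    "well_mixed_moran": well_mixed_moran,
    "wright_fisher": wright_fisher,
    "graph_moran_db": graph_moran_db,
    "graph_moran_bd": graph_moran_bd,
    "directed_cycle_moran": directed_cycle_moran,
    "undirected_cycle_moran": undirected_cycle_moran,
    "star_moran_db": star_moran_db,
    "class_moran": class_moran,
    "island_moran": island_moran,
    "explicit_table": explicit_table,
}


def make_model(spec: Mapping) -> SelectionProcess:
    """Build a process from a model descriptor mapping.

    The descriptor holds ``model`` (a built-in name) plus that model's
    parameters: ``n``, ``r``, ``u``, ``graph``, ``sizes``/``weights``
    (classes), ``islands``/``island_size``/``migration``, or ``table``.
    """
    spec = dict(spec)
    try:
        name = spec.pop("model")
    except KeyError:
        raise ValueError("model descriptor needs a 'model' key") from None
    try:
        ctor = BUILTIN_MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; known models: {sorted(BUILTIN_MODELS)}"
        ) from None
    return ctor(**spec)


def enumerate_support(process: SelectionProcess, x: Iterable[int]) -> list[ReplacementEvent]:
    """Aggregated support of state ``x``: distinct (alpha, U) with positive
    probability, microscopic duplicates merged, probabilities summing to 1."""
    return process.events(tuple(x))


def validate_process(process: SelectionProcess, *, check_axiom: bool = True) -> ProcessDiagnostics:
    """Diagnostic sweep over the process; reports findings, never raises."""
    report = ProcessDiagnostics(n=process.n)
    for x in process.states():
        events = process.event_table(x)
        total = sum(events.values())
        dev = float(total - 1)
        tol = 0 if process.exact else FLOAT_TOL
        if abs(dev) > tol:
            report.probability_deviation[state_index(x)] = dev
        for (alpha, mutated), p in events.items():
            if len(alpha) != process.n:
                report.malformed.append(f"state {x}: alpha {alpha} has wrong length")
            if not p > 0:
                report.malformed.append(f"state {x}: event ({alpha}, {set(mutated)}) has prob {p}")
    if check_axiom:
        from .axioms import check_fixation_axiom

        holds, _ = check_fixation_axiom(process)
        report.fixation_axiom_holds = holds
    return report
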