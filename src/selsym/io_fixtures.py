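"""Config parsing, analysis reports, and synthetic process fixtures.

Model descriptors are JSON or YAML mappings with a ``model`` key naming
a built-in family plus its parameters, or ``structure`` naming a
structure kind for the group constructors.  Explicit tables list every
state as a bitstring (site 1 leftmost) with its replacement events;
probabilities may be rational strings ("3/16") and round-trip exactly.
Site indices in files and reports are 1-based; everything internal is
0-based.

The synthetic generators produce fixtures for testing the symmetry
machinery: ``random_process`` draws a reproducible process with exact
rational probabilities that is guaranteed to satisfy the fixation axiom
(a uniform well-mixed replacement component is mixed in), and
``symmetrize_process`` averages any process over a permutation group,
which makes every element of that group a symmetry of the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from random import Random
from typing import Sequence

from .axioms import FixationWitness, check_fixation_axiom
from .process_core import (
    EventKey,
    Prob,
    SelectionProcess,
    State,
    SupportTable,
    all_states,
    make_model,
    state_index,
)
from .structures import StructureSpec
from .symmetry import Permutation, SymmetryGroup, site_orbits, symmetry_group

__all__ = [
    "read_model_spec",
    "parse_model_spec",
    "process_to_table_spec",
    "read_graph",
    "symmetrize_process",
    "random_process",
    "AnalysisReport",
    "analyze_process",
]


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


def _prob_from_text(value) -> Prob:
    if isinstance(value, str):
        return Fraction(value)
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return value
    raise ValueError(f"cannot parse probability {value!r}")


def _state_from_bitstring(s: str, n: int) -> State:
    if len(s) != n or any(c not in "01" for c in s):
        raise ValueError(f"state bitstring {s!r} is not a length-{n} binary string")
    return tuple(int(c) for c in s)


def _table_from_spec(spec: dict) -> SelectionProcess:
    try:
        n = int(spec["n"])
        listed = spec["table"]
    except KeyError as e:
        raise ValueError(f"explicit table spec needs key {e}") from None
    table: SupportTable = {}
    for bits, events in listed.items():
        x = _state_from_bitstring(str(bits), n)
        row: dict[EventKey, Prob] = {}
        for ev in events:
            alpha = tuple(int(a) - 1 for a in ev["alpha"])  # files are 1-based
            U = frozenset(int(g) - 1 for g in ev.get("U", []))
            p = _prob_from_text(ev["p"])
            key = (alpha, U)
            if key in row:
                raise ValueError(f"state {bits}: duplicate event {ev['alpha']}, {ev.get('U', [])}")
            row[key] = p
        table[x] = row
    return SelectionProcess(n, table, name="explicit_table")


def parse_model_spec(spec: dict) -> SelectionProcess | StructureSpec:
    """Build a process or structure spec from an already-parsed mapping."""
    if not isinstance(spec, dict):
        raise ValueError("model spec must be a mapping")
    if "structure" in spec:
        kw = {k: v for k, v in spec.items() if k != "structure"}
        if "sizes" in kw:
            kw["sizes"] = tuple(kw["sizes"])
        return StructureSpec(kind=spec["structure"], **kw)
    if spec.get("model") == "explicit_table":
        return _table_from_spec(spec)
    spec = dict(spec)
    if isinstance(spec.get("graph"), str):
        spec["graph"] = read_graph(spec["graph"], directed=spec.pop("directed", False))
    for key in ("r", "u", "migration"):
        if isinstance(spec.get(key), str):
            spec[key] = Fraction(spec[key])
    return make_model(spec)


def read_model_spec(path: str | Path) -> SelectionProcess | StructureSpec:
    """Read a JSON or YAML model descriptor from disk."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        spec = yaml.safe_load(text)
    else:
        spec = json.loads(text)
    return parse_model_spec(spec)


def process_to_table_spec(process: SelectionProcess) -> dict:
    """Serialise a process as an explicit-table descriptor (lossless for
    exact processes: probabilities become rational strings)."""
    table = {}
    for x in all_states(process.n):
        bits = "".join(str(a) for a in x)
        events = []
        for ev in process.events(x):
            p = str(ev.prob) if isinstance(ev.prob, Fraction) else float(ev.prob)
            events.append(
                {
                    "alpha": [a + 1 for a in ev.alpha],
                    "U": sorted(g + 1 for g in ev.mutated),
                    "p": p,
                }
            )
        table[bits] = events
    return {"model": "explicit_table", "n": process.n, "table": table}


def read_graph(path: str | Path, *, directed: bool = False):
    """Read a graph as 'i j weight' edge-list lines (1-based vertices) or
    a square adjacency CSV; returns a weight matrix of Fractions."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty graph file")
    if "," in lines[0]:
        rows = [[Fraction(v.strip()) for v in ln.split(",")] for ln in lines]
        if any(len(r) != len(rows) for r in rows):
            raise ValueError(f"{path}: adjacency CSV is not square")
        return rows
    edges = []
    for ln in lines:
        parts = ln.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}: bad edge line {ln!r}")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        w = Fraction(parts[2]) if len(parts) == 3 else Fraction(1)
        edges.append((i, j, w))
    n = 1 + max(max(i, j) for i, j, _ in edges)
    A = [[Fraction(0)] * n for _ in range(n)]
    for i, j, w in edges:
        A[i][j] = w
        if not directed:
            A[j][i] = w
    return A


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def symmetrize_process(process: SelectionProcess, group: SymmetryGroup) -> SelectionProcess:
    """Average the support over a permutation group.

    The result assigns p'_x(alpha, U) = (1/S) sum_sigma
    p_{x sigma}(sigma^-1 o alpha o sigma, sigma^-1(U)); by construction
    every element of the group is a symmetry of the returned process.
    """
    if group.n != process.n:
        raise ValueError("group and process have different site counts")
    n = process.n
    S = group.order
    inv_S = Fraction(1, S) if process.exact else 1.0 / S
    support: SupportTable = {}
    for x in all_states(n):
        acc: dict[EventKey, Prob] = {}
        for sigma in group.elements:
            y = tuple(x[sigma.image[g]] for g in range(n))
            sg = sigma.image
            for (beta, V), p in process.event_table(y).items():
                # event (beta, V) of x sigma corresponds to
                # alpha = sigma o beta o sigma^-1, U = sigma(V) in x
                alpha = [0] * n
                for g in range(n):
                    alpha[sg[g]] = sg[beta[g]]
                U = frozenset(sg[v] for v in V)
                key = (tuple(alpha), U)
                acc[key] = acc.get(key, 0) + p * inv_S
        support[x] = acc
    return SelectionProcess(n, support, exact=process.exact, name=f"symmetrized({process.name})")


def random_process(
    n: int,
    seed: int,
    *,
    extra_maps: int = 3,
    mutation: bool = False,
    backbone_weight: Fraction = Fraction(1, 4),
) -> SelectionProcess:
    """A reproducible random selection process with exact probabilities.

    A uniform single-replacement backbone (weight ``backbone_weight``,
    spread over all n^2 (dying, parent) choices) guarantees the fixation
    axiom; the remaining mass goes to ``extra_maps`` random parentage
    maps per state with random rational weights (and, if ``mutation``,
    random mutation sets).  The same seed always yields the same table.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not (0 < backbone_weight <= 1):
        raise ValueError("backbone_weight must lie in (0, 1]")
    rng = Random(seed)
    support: SupportTable = {}
    pair_mass = backbone_weight / (n * n)
    for x in all_states(n):
        acc: dict[EventKey, Prob] = {}
        for dead in range(n):
            for parent in range(n):
                alpha = list(range(n))
                alpha[dead] = parent
                key = (tuple(alpha), frozenset())
                acc[key] = acc.get(key, 0) + pair_mass
        rest = 1 - backbone_weight
        if rest > 0 and extra_maps > 0:
            weights = [rng.randint(1, 20) for _ in range(extra_maps)]
            total = sum(weights)
            for w in weights:
                alpha = tuple(rng.randrange(n) for _ in range(n))
                if mutation:
                    U = frozenset(g for g in range(n) if rng.random() < 0.3)
                else:
                    U = frozenset()
                key = (alpha, U)
                acc[key] = acc.get(key, 0) + rest * Fraction(w, total)
        elif rest > 0:
            raise ValueError("extra_maps must be positive when backbone_weight < 1")
        support[x] = acc
    return SelectionProcess(n, support, name=f"random_process(n={n}, seed={seed})")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Aggregated analysis of one process: group, orbits, counts, bounds."""

    model: str
    n: int
    group_order: int
    group_cycles: list[str]
    site_orbits: list[list[int]]  # 1-based site labels
    transitive: bool
    orbit_count: int
    bounds: tuple[str, str]
    lumpable: bool
    fixation_axiom: bool
    witness: dict | None = None
    fixation_probabilities: dict | None = None
    stationary: dict | None = None
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        out = {
            "model": self.model,
            "n": self.n,
            "group": {"order": self.group_order, "elements": self.group_cycles},
            "site_orbits": self.site_orbits,
            "transitive": self.transitive,
            "reduced_states": self.orbit_count,
            "bounds": {"lower": self.bounds[0], "upper": self.bounds[1]},
            "lumpable": self.lumpable,
            "fixation_axiom": self.fixation_axiom,
        }
        if self.witness is not None:
            out["witness"] = self.witness
        if self.fixation_probabilities is not None:
            out["fixation_probabilities"] = self.fixation_probabilities
        if self.stationary is not None:
            out["stationary_distribution"] = self.stationary
        if self.notes:
            out["notes"] = self.notes
        return out


def analyze_process(
    process: SelectionProcess,
    *,
    generators: Sequence[Permutation] | None = None,
    with_fixation: bool = False,
    with_stationary: bool = False,
) -> AnalysisReport:
    """Run the full pipeline on one process and collect the results."""
    from .markov import build_chain, fixation_probabilities, stationary_distribution
    from .reduction import build_reduced_chain, count_reduced_states, state_count_bounds, state_orbits

    group = symmetry_group(process, generators)
    sorb = site_orbits(group)
    R = count_reduced_states(group, 2)
    bounds = state_count_bounds(process.n, group.order)
    P = build_chain(process)
    lumpable = True
    try:
        build_reduced_chain(P, state_orbits(group))
    except ValueError:
        lumpable = False
    holds, cert = check_fixation_axiom(process)
    witness = cert.to_json() if isinstance(cert, FixationWitness) else None
    report = AnalysisReport(
        model=process.name,
        n=process.n,
        group_order=group.order,
        group_cycles=group.cycle_strings(),
        site_orbits=[[g + 1 for g in orb] for orb in sorb.orbits],
        transitive=sorb.transitive,
        orbit_count=R,
        bounds=(str(bounds.lower), str(bounds.upper)),
        lumpable=lumpable,
        fixation_axiom=holds,
        witness=witness,
    )
    if not bounds.contains(R):
        report.notes.append(f"orbit count {R} violates bounds [{bounds.lower}, {bounds.upper}]")
    if with_fixation:
        try:
            rho = fixation_probabilities(process)
            report.fixation_probabilities = {
                "single_mutant": {str(g + 1): str(rho.single_mutant(g)) for g in range(process.n)}
            }
        except ValueError as e:
            report.notes.append(f"fixation probabilities unavailable: {e}")
    if with_stationary:
        try:
            pi = stationary_distribution(P)
            report.stationary = {
                "".join(map(str, x)): str(pi.pi[state_index(x)]) for x in all_states(process.n)
            }
        except ValueError as e:
            report.notes.append(f"stationary distribution unavailable: {e}")
    return report
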