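"""The fixation axiom: can one site's lineage take over the population?

A selection process is *unitary* when some site g can, with positive
probability, spread its descendants to every site: there must be a
finite sequence of parentage maps alpha_1, ..., alpha_m, each with
positive marginal probability in EVERY state, whose composition
alpha_1 o ... o alpha_m is the constant map onto g.  (After applying
alpha_1 then alpha_2 ... the ancestral site of g' is
alpha_1(alpha_2(...alpha_m(g')...)), so a constant composite means all
sites trace back to g.)  Without this property the two single-allele
states need not be the only recurrent states and fixation probabilities
are ill-defined.

Deciding the axiom is the synchronizing-word problem for the
transformation monoid generated by the always-possible maps D: a
constant composite exists iff every pair of sites can be merged by some
composition over D.  The decision runs pairwise-merge reachability
(sound and complete for constant-composite existence); a positive answer
is returned together with an explicit witness sequence, re-verified by
composition before it is handed back.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .process_core import ZERO_TOL, ParentageMap, SelectionProcess, all_states

__all__ = [
    "FixationWitness",
    "always_possible_maps",
    "check_fixation_axiom",
    "compose_maps",
]


def compose_maps(maps: list[ParentageMap]) -> ParentageMap:
    """Left-to-right composition: maps[0] o maps[1] o ... applied as
    composite(h) = maps[0](maps[1](... maps[-1](h)))."""
    if not maps:
        raise ValueError("need at least one map")
    n = len(maps[0])
    comp = list(maps[-1])
    for alpha in reversed(maps[:-1]):
        comp = [alpha[c] for c in comp]
    if len(comp) != n:
        raise ValueError("inconsistent map lengths")
    return tuple(comp)


@dataclass(frozen=True)
class FixationWitness:
    """A target site and a temporal map sequence whose composite is the
    constant map onto that site."""

    target_site: int
    map_sequence: tuple[ParentageMap, ...]

    def verify(self, process: SelectionProcess | None = None) -> bool:
        """Re-check both axiom conditions by explicit computation."""
        comp = compose_maps(list(self.map_sequence))
        if any(c != self.target_site for c in comp):
            return False
        if process is not None:
            allowed = set(always_possible_maps(process))
            if any(alpha not in allowed for alpha in self.map_sequence):
                return False
        return True

    def to_json(self) -> dict:
        return {
            "target_site": self.target_site + 1,  # 1-based display
            "maps": [list(alpha) for alpha in self.map_sequence],
        }


def always_possible_maps(process: SelectionProcess) -> list[ParentageMap]:
    """Parentage maps whose marginal probability sum_U p_x(alpha, U) is
    positive in every state x."""
    threshold = 0 if process.exact else ZERO_TOL
    common: set[ParentageMap] | None = None
    for x in all_states(process.n):
        marg: dict[ParentageMap, object] = {}
        for (alpha, _U), p in process.event_table(x).items():
            marg[alpha] = marg.get(alpha, 0) + p
        present = {a for a, p in marg.items() if float(p) > threshold}
        common = present if common is None else common & present
        if not common:
            break
    return sorted(common or [])


def _merge_word(n: int, maps: list[ParentageMap], a: int, b: int) -> list[ParentageMap] | None:
    """Shortest sequence of maps (in application order: first applied
    first) sending the pair {a, b} to a single site, or None."""
    if a == b:
        return []
    start = (min(a, b), max(a, b))
    prev: dict[tuple[int, int], tuple[tuple[int, int], ParentageMap]] = {}
    queue = deque([start])
    seen = {start}
    while queue:
        pair = queue.popleft()
        for alpha in maps:
            na, nb = alpha[pair[0]], alpha[pair[1]]
            nxt = (min(na, nb), max(na, nb))
            if nxt in seen:
                continue
            seen.add(nxt)
            prev[nxt] = (pair, alpha)
            if na == nb:
                word = []
                cur = nxt
                while cur != start:
                    cur, used = prev[cur]
                    word.append(used)
                word.reverse()
                return word
            queue.append(nxt)
    return None


def check_fixation_axiom(
    process: SelectionProcess,
) -> tuple[bool, FixationWitness | tuple[int, int] | None]:
    """Decide the fixation axiom.

    Returns (True, witness) where the witness re-verifies by explicit
    composition, or (False, (g, h)) with a pair of sites that no
    composition of always-possible maps can merge — a certificate that
    no constant composite exists.
    """
    n = process.n
    D = always_possible_maps(process)
    if not D:
        return False, (0, 1) if n > 1 else (0, 0)

    # Decision: every site pair must be mergeable by some word over D.
    for a in range(n):
        for b in range(a + 1, n):
            if _merge_word(n, D, a, b) is None:
                return False, (a, b)
    if n == 1:
        return True, FixationWitness(target_site=0, map_sequence=(D[0],))

    # Witness assembly: shrink the image of the composite greedily.  The
    # composite C after temporal steps alpha_1..alpha_t is alpha_1 o ... o
    # alpha_t; prepending an earlier-in-time refinement is done by applying
    # a merge word to the current image, i.e. C <- B o C with B the word's
    # composite read in application order.
    composite = tuple(range(n))  # identity
    temporal: list[ParentageMap] = []
    while True:
        image = sorted(set(composite))
        if len(image) == 1:
            break
        word = _merge_word(n, D, image[0], image[1])
        assert word is not None  # pairwise decision already passed
        # word[0] is applied first to the pair; as temporal steps these
        # come *after* nothing yet chosen — we prepend them so that the
        # overall temporal order stays consistent: new composite =
        # (word[k] o ... o word[0]) o composite, with word[0] innermost.
        for alpha in word:
            composite = tuple(alpha[c] for c in composite)
        temporal = list(reversed(word)) + temporal
    target = composite[0]
    witness = FixationWitness(target_site=target, map_sequence=tuple(temporal))
    if not witness.verify(process):
        raise AssertionError("constructed witness failed re-verification")
    return True, witness
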