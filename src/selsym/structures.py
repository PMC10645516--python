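"""Named symmetry groups of standard population structures.

These constructors build, directly from a structure description and
independently of any selection process, the permutation groups that the
standard model families possess: the full symmetric group (well-mixed
haploids), class-partition groups S_{n_1} x ... x S_{n_k} (classes are
fixed setwise), block-partition groups S_m x (S_k)^m (equal blocks may
be permuted internally and interchanged — diploid individuals or
identical islands), dihedral and cyclic groups (undirected/directed
cycles) and the star group S_{n-1} (any permutation of the leaves).

Having the groups available without a process lets orbit counting and
the group-order cross-checks run at sizes where enumerating a process
support would be impractical.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

from .symmetry import Permutation, SymmetryGroup

__all__ = ["StructureSpec", "make_structure_group", "STRUCTURE_KINDS"]

STRUCTURE_KINDS = ("symmetric", "class_partition", "block_partition", "dihedral", "cyclic", "star")

MAX_GROUP_ORDER = 10**6


@dataclass(frozen=True)
class StructureSpec:
    """Description of a population structure whose group is wanted.

    kind:
        one of ``symmetric``, ``class_partition``, ``block_partition``,
        ``dihedral``, ``cyclic``, ``star``.
    n:
        site count (derived from sizes/blocks when omitted).
    sizes:
        class sizes for ``class_partition``.
    block_count, block_size:
        for ``block_partition`` (n = block_count * block_size).
    """

    kind: str
    n: int | None = None
    sizes: tuple[int, ...] | None = None
    block_count: int | None = None
    block_size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURE_KINDS:
            raise ValueError(f"unknown structure kind {self.kind!r}; expected one of {STRUCTURE_KINDS}")
        if self.kind == "class_partition":
            if not self.sizes or any(s < 1 for s in self.sizes):
                raise ValueError("class_partition needs positive class sizes")
            total = sum(self.sizes)
            if self.n is not None and self.n != total:
                raise ValueError(f"class sizes sum to {total}, not n = {self.n}")
            object.__setattr__(self, "n", total)
            object.__setattr__(self, "sizes", tuple(self.sizes))
        elif self.kind == "block_partition":
            if not self.block_count or not self.block_size or self.block_count < 1 or self.block_size < 1:
                raise ValueError("block_partition needs positive block_count and block_size")
            total = self.block_count * self.block_size
            if self.n is not None and self.n != total:
                raise ValueError(f"block_count x block_size = {total}, not n = {self.n}")
            object.__setattr__(self, "n", total)
        else:
            if self.n is None or self.n < 1:
                raise ValueError(f"{self.kind} needs a positive site count n")
            if self.kind in ("dihedral", "cyclic") and self.n < 1:
                raise ValueError("cycle needs at least 1 site")
            if self.kind == "star" and self.n < 2:
                raise ValueError("star needs a hub and at least one leaf")

    def expected_order(self) -> int:
        n = self.n
        if self.kind == "symmetric":
            return math.factorial(n)
        if self.kind == "class_partition":
            return math.prod(math.factorial(s) for s in self.sizes)
        if self.kind == "block_partition":
            return math.factorial(self.block_count) * math.factorial(self.block_size) ** self.block_count
        if self.kind == "dihedral":
            return 2 * n if n >= 3 else math.factorial(n)
        if self.kind == "cyclic":
            return n
        if self.kind == "star":
            return math.factorial(n - 1)
        raise AssertionError(self.kind)


def _class_blocks(sizes: Sequence[int]) -> list[list[int]]:
    blocks = []
    start = 0
    for s in sizes:
        blocks.append(list(range(start, start + s)))
        start += s
    return blocks


def make_structure_group(spec: StructureSpec) -> SymmetryGroup:
    """Materialise the permutation group of the described structure.

    Groups are enumerated element by element; orders above 10^6 are
    refused (Burnside counting needs per-element cycle counts, so the
    cap keeps memory bounded).
    """
    order = spec.expected_order()
    if order > MAX_GROUP_ORDER:
        raise ValueError(f"group order {order} exceeds the enumeration limit {MAX_GROUP_ORDER}")
    n = spec.n
    if spec.kind == "symmetric":
        elems = [Permutation(img) for img in itertools.permutations(range(n))]
    elif spec.kind == "class_partition":
        blocks = _class_blocks(spec.sizes)
        elems = []
        for parts in itertools.product(*(itertools.permutations(b) for b in blocks)):
            image = [0] * n
            for block, perm in zip(blocks, parts):
                for src, dst in zip(block, perm):
                    image[src] = dst
            elems.append(Permutation(tuple(image)))
    elif spec.kind == "block_partition":
        m, k = spec.block_count, spec.block_size
        blocks = [list(range(j * k, (j + 1) * k)) for j in range(m)]
        elems = []
        for block_perm in itertools.permutations(range(m)):
            for parts in itertools.product(*(itertools.permutations(range(k)) for _ in range(m))):
                image = [0] * n
                for j in range(m):
                    target = blocks[block_perm[j]]
                    for pos, within in enumerate(parts[j]):
                        image[blocks[j][pos]] = target[within]
                elems.append(Permutation(tuple(image)))
    elif spec.kind == "cyclic":
        elems = [
            Permutation(tuple((g + j) % n for g in range(n))) for j in range(n)
        ]
    elif spec.kind == "dihedral":
        rot = [Permutation(tuple((g + j) % n for g in range(n))) for j in range(n)]
        refl = Permutation(tuple((n - 1 - g) % n for g in range(n)))
        elems = set(rot)
        for r in rot:
            elems.add(r.compose(refl))
        elems = list(elems)
    elif spec.kind == "star":
        elems = []
        for leaf_perm in itertools.permutations(range(1, n)):
            elems.append(Permutation((0,) + leaf_perm))
    else:  # pragma: no cover
        raise AssertionError(spec.kind)
    group = SymmetryGroup(elems, check=False)
    if group.order != order:
        raise AssertionError(
            f"constructed {spec.kind} group has order {group.order}, expected {order}"
        )
    return group
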