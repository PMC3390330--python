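"""Decomposition of secondary structures into primitive pseudoknot components.

A structure's base pairs are viewed as a chord diagram: arcs drawn over the
backbone, compared only by the relative order (rank) of their endpoints.  The
decomposition proceeds in two stages:

1. *Irreducible* components: maximal backbone intervals whose pairs cannot be
   split at any point into two independent consecutive parts (found by
   scanning for positions where no pair remains open).
2. *Primitive* components: from each irreducible component, the crossing
   closure of its leftmost arc is taken as one component — it is irreducible
   and non-nested — and the remaining (nested) arcs are re-split and recursed.

Each primitive component is canonicalised as a *pattern token* (``ABAB``,
``ABACBC``, ...) by collapsing stems of stacked parallel arcs into single
arcs ("shadow") and lettering the arcs in order of first endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .structure_io import SecondaryStructure

__all__ = [
    "Diagram",
    "PrimitiveComponent",
    "crossing",
    "diagram_of",
    "split_irreducible",
    "nonnested_closure",
    "extract_primitive",
    "collapse_stems",
    "has_collapsible_pair",
    "pattern_token",
    "parse_token",
    "token_symbols",
]

Arc = tuple[int, int]


@dataclass(frozen=True)
class Diagram:
    """An ordered chord diagram: arcs over ranked backbone positions.

    Arc endpoints keep their original structure coordinates; only their
    relative order is semantic, so relabelling endpoints by rank ``1..2P``
    changes neither the genus nor the pattern token.
    """

    arcs: tuple

    def __post_init__(self) -> None:
        arcs = tuple(sorted(tuple(a) for a in self.arcs))
        object.__setattr__(self, "arcs", arcs)
        seen: set[int] = set()
        for i, j in arcs:
            if i >= j:
                raise ValueError(f"arc ({i},{j}) must have i < j")
            if i in seen or j in seen:
                raise ValueError(f"arc endpoint in ({i},{j}) is not distinct")
            seen.add(i)
            seen.add(j)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def endpoints(self) -> list[int]:
        """All endpoints in backbone order."""
        return sorted(p for arc in self.arcs for p in arc)

    def ranked(self) -> "Diagram":
        """The same diagram with endpoints relabelled 1..2P by rank."""
        rank = {p: r for r, p in enumerate(self.endpoints(), start=1)}
        return Diagram(tuple((rank[i], rank[j]) for i, j in self.arcs))

    @property
    def span(self) -> Arc:
        if not self.arcs:
            raise ValueError("empty diagram has no span")
        pts = self.endpoints()
        return pts[0], pts[-1]


@dataclass(frozen=True)
class PrimitiveComponent:
    """An irreducible, non-nested sub-diagram with original coordinates.

    ``span`` is the (leftmost, rightmost) paired coordinate; ``origin`` names
    the source structure, if any.
    """

    diagram: Diagram
    span: Arc
    origin: str | None = None

    @property
    def length(self) -> int:
        """End-to-end distance in nucleotides, both endpoints included."""
        return self.span[1] - self.span[0] + 1


def crossing(a: Arc, b: Arc) -> bool:
    """Whether two arcs cross: ``a < x < b < y`` or ``x < a < y < b``."""
    (i, j), (k, l) = a, b
    return i < k < j < l or k < i < l < j


def diagram_of(source: SecondaryStructure | Diagram | Iterable[Arc]) -> Diagram:
    if isinstance(source, Diagram):
        return source
    if isinstance(source, SecondaryStructure):
        return Diagram(tuple(source.sorted_pairs()))
    return Diagram(tuple(source))


def split_irreducible(source: SecondaryStructure | Diagram | Iterable[Arc]) -> list[Diagram]:
    """Split into maximal consecutive segments of mutually dependent pairs.

    Scanning the backbone left to right, a cut is made wherever the count of
    open pairs returns to zero; each resulting segment with at least one pair
    becomes one irreducible diagram.  Segments without pairs are dropped, and
    concatenating the segments in order recovers every pair.
    """
    arcs = diagram_of(source).arcs
    components: list[Diagram] = []
    current: list[Arc] = []
    open_until = -1
    for arc in arcs:  # sorted by left endpoint
        if current and arc[0] > open_until:
            components.append(Diagram(tuple(current)))
            current = []
        current.append(arc)
        open_until = max(open_until, arc[1])
    if current:
        components.append(Diagram(tuple(current)))
    return components


def nonnested_closure(d: Diagram) -> frozenset:
    """The crossing closure of the leftmost arc.

    Seed with the leftmost arc, then repeatedly add every arc crossing any
    member until a fixpoint.  For an irreducible diagram this recovers
    exactly the non-nested arcs.
    """
    if not d.arcs:
        return frozenset()
    closure: set[Arc] = set()
    stack: list[Arc] = [d.arcs[0]]
    while stack:
        arc = stack.pop()
        if arc in closure:
            continue
        closure.add(arc)
        for other in d.arcs:
            if other not in closure and crossing(arc, other):
                stack.append(other)
    return frozenset(closure)


def extract_primitive(
    source: SecondaryStructure | Diagram | Iterable[Arc], origin: str | None = None
) -> list[PrimitiveComponent]:
    """Recursively decompose into primitive (irreducible, non-nested) components.

    Each irreducible component contributes its non-nested closure as one
    primitive component; the arcs nested beneath it are re-split and recursed.
    The union of all components' arcs equals the input pair set, and
    components appear in left-to-right order of their leftmost arc at each
    recursion level.  A closure that crosses nothing (a lone helix level) is
    itself a genus-0 primitive component.
    """
    out: list[PrimitiveComponent] = []
    for comp in split_irreducible(source):
        closure = nonnested_closure(comp)
        closure_diagram = Diagram(tuple(sorted(closure)))
        out.append(
            PrimitiveComponent(
                diagram=closure_diagram, span=closure_diagram.span, origin=origin
            )
        )
        nested = [a for a in comp.arcs if a not in closure]
        if nested:
            out.extend(extract_primitive(nested, origin=origin))
    return out


def _collapsible_pair(arcs: Sequence[Arc]) -> tuple[int, int] | None:
    """Find indices (outer, inner) of a collapsible stacked pair, if any.

    Arcs ``(i, j)`` and ``(k, l)`` with ``i < k < l < j`` are collapsible when
    no arc endpoint lies strictly between ``i`` and ``k`` nor between ``l``
    and ``j`` — i.e. they are adjacent pairs of one stem, possibly separated
    by unpaired bulges only.
    """
    points = sorted(p for a in arcs for p in a)
    for oi, (i, j) in enumerate(arcs):
        for ii, (k, l) in enumerate(arcs):
            if oi == ii or not (i < k < l < j):
                continue
            if any(i < p < k for p in points):
                continue
            if any(l < p < j for p in points):
                continue
            return oi, ii
    return None


def collapse_stems(d: Diagram) -> Diagram:
    """Collapse stems of stacked parallel arcs to single arcs (the shadow).

    Repeatedly merges collapsible pairs — keeping the outer arc as the
    representative — until no collapsible pair remains.  The genus of the
    diagram is unchanged by this operation.
    """
    arcs = list(d.arcs)
    while True:
        hit = _collapsible_pair(arcs)
        if hit is None:
            return Diagram(tuple(arcs))
        _, inner = hit
        del arcs[inner]


def has_collapsible_pair(d: Diagram) -> bool:
    return _collapsible_pair(d.arcs) is not None


def token_symbols(n: int) -> list[str]:
    """Arc alphabet: ``A``..``Z`` for the first 26 arcs, then ``a27``, ``a28``, ...."""
    return [chr(ord("A") + k) if k < 26 else f"a{k + 1}" for k in range(n)]


def pattern_token(d: Diagram) -> str:
    """Canonical token of a shadow diagram: letters in order of first endpoint.

    Walk the endpoints in rank order, assign the next unused letter at each
    first (left) endpoint, and emit each arc's letter at both endpoints.  The
    caller is expected to pass a stem-collapse fixpoint; the token of an
    uncollapsed diagram is well-defined but names the diagram, not its shadow.
    """
    symbols = token_symbols(d.n_arcs)
    by_left = {arc[0]: k for k, arc in enumerate(d.arcs)}
    letter: dict[Arc, str] = {}
    out: list[str] = []
    nxt = 0
    for p in d.endpoints():
        if p in by_left:
            arc = d.arcs[by_left[p]]
            letter[arc] = symbols[nxt]
            nxt += 1
            out.append(letter[arc])
        else:
            arc = next(a for a in d.arcs if a[1] == p)
            out.append(letter[arc])
    return "".join(out)


def parse_token(token: str) -> Diagram:
    """Build the diagram of a pattern token at endpoint ranks ``1..2P``.

    Only single-letter symbols (up to 26 arcs) are parseable; each symbol
    must occur exactly twice.
    """
    positions: dict[str, list[int]] = {}
    for pos, ch in enumerate(token, start=1):
        positions.setdefault(ch, []).append(pos)
    arcs = []
    for ch, pos in positions.items():
        if len(pos) != 2:
            raise ValueError(f"malformed token {token!r}: symbol {ch!r} occurs {len(pos)} times")
        arcs.append((pos[0], pos[1]))
    return Diagram(tuple(arcs))
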