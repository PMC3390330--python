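"""Topological genus of chord diagrams by closed-loop counting.

Drawing the backbone as a circle (rank ``2P`` wraps to rank 1) and each base
pair as a chord thickened into a ribbon yields a fatgraph; its boundary
cycles are the *closed loops* ``L``.  With ``P`` pairs the genus of the
embedding surface is::

    g = (P - L + 1) / 2

``g`` is a non-negative integer, zero exactly for pseudoknot-free (crossing
free) diagrams, and additive over primitive components.

Two loop counters are provided.  :func:`count_loops` is the normative one:
place the ``2P`` endpoints at ranks ``1..2P``, let σ be the involution
exchanging the endpoints of each arc and τ the cyclic successor; ``L`` is
the number of cycles of ``r -> τ(σ(r))``.  :func:`count_loops_traversal`
walks the explicit graph of vertices, bidirectional base-pair arcs and
backbone successor edges, marking them visited and counting a loop each time
a traversal returns to a visited arc; it must (and does, by test) agree with
the permutation count on every diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

from .decomposition import Diagram, diagram_of, extract_primitive, parse_token
from .structure_io import SecondaryStructure

__all__ = [
    "GenusResult",
    "count_loops",
    "count_loops_traversal",
    "genus_of",
    "genus_of_token",
    "total_genus",
]


@dataclass(frozen=True)
class GenusResult:
    """Genus of a diagram: ``n_pairs`` (P), ``n_loops`` (L) and ``genus`` (g)."""

    n_pairs: int
    n_loops: int
    genus: int


def _ranked_partner(d: Diagram) -> list[int]:
    """0-based partner array over ranks: partner[r] is the other endpoint."""
    ranked = d.ranked()
    partner = [0] * (2 * ranked.n_arcs)
    for i, j in ranked.arcs:
        partner[i - 1] = j - 1
        partner[j - 1] = i - 1
    return partner


def count_loops(d: Diagram) -> int:
    """Number of closed loops: cycles of ``r -> τ(σ(r))`` over ranks 1..2P."""
    partner = _ranked_partner(d)
    m = len(partner)
    seen = [False] * m
    loops = 0
    for start in range(m):
        if seen[start]:
            continue
        loops += 1
        r = start
        while not seen[r]:
            seen[r] = True
            r = (partner[r] + 1) % m
    return loops


def count_loops_traversal(d: Diagram) -> int:
    """Closed loops by explicit graph traversal.

    The component is the graph (V, A, E): V its paired positions, A the
    base-pair arcs in both directions, E the backbone successor edges with
    the last vertex wrapping to the first.  Starting from any vertex with an
    unvisited outgoing arc, follow its arc, then the backbone edge of the
    vertex reached, and so on; when the outgoing arc of the current vertex is
    found already visited a loop has closed.
    """
    partner = _ranked_partner(d)
    m = len(partner)
    if m == 0:
        return 0
    arc_visited = [False] * m  # directed arc out of vertex r
    edge_visited = [False] * m  # backbone edge r -> (r+1) % m
    loops = 0

    def fresh_start() -> int | None:
        for r in range(m):
            if not arc_visited[r]:
                return r
        return None

    v = fresh_start()
    while v is not None:
        if arc_visited[v]:
            loops += 1
            v = fresh_start()
            continue
        v2 = partner[v]
        arc_visited[v] = True
        if not edge_visited[v2]:
            edge_visited[v2] = True
            v = (v2 + 1) % m
        else:
            v = fresh_start()
    # every traversal that exhausts the arcs has closed its final loop above,
    # because a loop is counted exactly when its starting arc is re-reached
    return loops


def genus_of(d: Diagram | SecondaryStructure) -> GenusResult:
    """Genus of a single diagram via ``g = (P - L + 1) / 2``.

    The empty diagram has genus 0 by convention.  ``P - L + 1`` odd or
    negative indicates a loop-counting bug and raises ``RuntimeError``.
    """
    d = diagram_of(d)
    p = d.n_arcs
    if p == 0:
        return GenusResult(n_pairs=0, n_loops=0, genus=0)
    loops = count_loops(d)
    twice_g = p - loops + 1
    if twice_g < 0 or twice_g % 2:
        raise RuntimeError(
            f"internal inconsistency: P={p}, L={loops} gives non-integral genus"
        )
    return GenusResult(n_pairs=p, n_loops=loops, genus=twice_g // 2)


def genus_of_token(token: str) -> GenusResult:
    """Genus of a pattern token, via its diagram at ranks ``1..2P``."""
    return genus_of(parse_token(token))


def total_genus(s: SecondaryStructure | Diagram) -> int:
    """Total genus of a structure: sum of the genera of its primitive components.

    By additivity this equals the genus of the whole (undecomposed) diagram.
    """
    return sum(genus_of(c.diagram).genus for c in extract_primitive(s))
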