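"""Shared test utilities: exhaustive matchings, random structures, stem inflation."""

from __future__ import annotations

from typing import Iterator

import hypothesis.strategies as st

from pkclass.decomposition import Diagram, parse_token
from pkclass.structure_io import SecondaryStructure


def all_matchings(n: int) -> Iterator[tuple]:
    """All (2n-1)!! perfect matchings of ranks 1..2n, as sorted arc tuples."""

    def rec(points: list[int]) -> Iterator[list[tuple[int, int]]]:
        if not points:
            yield []
            return
        first, rest = points[0], points[1:]
        for k in range(len(rest)):
            for sub in rec(rest[:k] + rest[k + 1 :]):
                yield [(first, rest[k])] + sub

    for arcs in rec(list(range(1, 2 * n + 1))):
        yield tuple(sorted(arcs))


@st.composite
def secondary_structures(draw, max_len: int = 40, with_sequence: bool = False):
    """Random structures: a backbone and an arbitrary partial matching on it."""
    length = draw(st.integers(min_value=0, max_value=max_len))
    k = draw(st.integers(min_value=0, max_value=length // 2))
    positions = draw(st.permutations(list(range(1, length + 1))))
    chosen = positions[: 2 * k]
    pairs = frozenset(
        (min(a, b), max(a, b)) for a, b in zip(chosen[::2], chosen[1::2])
    )
    sequence = None
    if with_sequence:
        sequence = "".join(
            draw(st.lists(st.sampled_from("ACGU"), min_size=length, max_size=length))
        )
    return SecondaryStructure(length=length, pairs=pairs, sequence=sequence)


def inflate(token: str, stem_sizes: dict) -> Diagram:
    """Expand each arc of a token into a stem of parallel arcs (rank space)."""
    d = parse_token(token)
    blocks: dict[int, list[int]] = {}
    pos = 0
    for rank in sorted(p for arc in d.arcs for p in arc):
        arc = next(a for a in d.arcs if rank in a)
        k = stem_sizes[token[rank - 1]]
        blocks[rank] = list(range(pos + 1, pos + 1 + k))
        pos += k
    pairs = []
    for i, j in d.arcs:
        left, right = blocks[i], blocks[j]
        for t, p in enumerate(left):
            pairs.append((p, right[len(right) - 1 - t]))
    return Diagram(tuple(pairs))
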