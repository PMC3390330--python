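"""Enumeration of primitive pseudoknot shadows by tree building.

Counts a(g, n): the number of distinct primitive pseudoknot diagrams
(shadows) built from n arcs whose genus is g.  A shadow qualifies when

* it is irreducible (no backbone cut point splits it),
* the crossing closure of its leftmost arc reaches every arc (non-nested),
* no two arcs are collapsible into one stem (pattern ``..YX..XY..``).

The enumerator grows pattern tokens left to right down a tree whose leaves,
at depth 2n, are exactly the canonical tokens.  Each node carries a FIFO
queue of arc symbols awaiting their left-end emission and a set of symbols
eligible for right-end emission.  Fresh symbols are enqueued while fewer
than n have been created, so left ends appear in alphabetical order and each
leaf token is already canonical.  Three rules prune the tree:

* Rule 1 — a symbol becomes right-eligible only one level after its left end
  was emitted, so a hairpin arc ``..XX..`` can never be written.
* Rule 2 — a right end may not complete a crossing-connected group of arcs
  while other arcs are open or pending: a fully closed group can never cross
  anything emitted later, so it would force a reducible or nested
  sub-diagram.  (Tracked exactly with a union-find over crossing arcs, which
  also subsumes the backbone cut-point check.)
* Rule 3 — a right end may not land immediately after the right end of the
  arc opened immediately after its own left end: that pair would be
  collapsible.

Depth-first traversal with do/undo state keeps memory proportional to the
tree depth; leaves are folded into genus bins immediately and never stored.
A brute-force oracle over all (2n-1)!! perfect matchings provides an
independent check at small n.
"""

from __future__ import annotations

import logging
import time
from typing import Callable, Iterator

from .decomposition import token_symbols

__all__ = [
    "EnumerationBudgetError",
    "enumerate_primitive",
    "iter_tokens",
    "count_by_genus",
    "count_for_genus_total",
    "brute_force_counts",
    "totals_per_arc",
    "genus_support",
    "arc_support",
    "extension_rejection",
]

logger = logging.getLogger(__name__)

_PROGRESS_EVERY = 250_000


class EnumerationBudgetError(RuntimeError):
    """Raised when a time budget runs out; carries the completed partial counts."""

    def __init__(self, message: str, completed: dict):
        super().__init__(message)
        self.completed = dict(completed)


def genus_support(n: int) -> tuple[int, int]:
    """Genus range attainable by a primitive pseudoknot shadow of n arcs."""
    return -(-(n + 2) // 6), n // 2


def arc_support(g: int) -> range:
    """Arc counts over which primitive shadows of genus g exist: 2g..6g-2."""
    return range(2 * g, 6 * g - 1)


def _walk(n: int, on_leaf: Callable[[list[int], list[int], list[int]], None]) -> int:
    """Depth-first tree walk; calls ``on_leaf(token, left_pos, right_pos)``.

    Token symbols are integers 0..n-1 in order of first (left) emission;
    positions are 0-based ranks.  Returns the number of leaves visited.
    """
    if n < 2:
        raise ValueError(
            "no primitive pseudoknot exists with fewer than 2 arcs; "
            "0- and 1-arc diagrams are the pseudoknot-free convention"
        )
    two_n = 2 * n
    left_pos = [-1] * n
    right_pos = [-1] * n
    token: list[int] = []
    queue: list[int] = [0]  # FIFO of symbols awaiting left emission
    state = {"head": 0, "created": 1, "leaves": 0}
    right_elig: list[int] = []  # symbols eligible for right emission, in order
    # union-find over symbols, tracking crossing-connected groups and how
    # many of each group's arcs are still open
    parent = list(range(n))
    size = [1] * n
    open_cnt = [0] * n

    def find(x: int) -> int:
        while parent[x] != x:
            x = parent[x]
        return x

    def union(a: int, b: int, trail: list) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        parent[rb] = ra
        size[ra] += size[rb]
        open_cnt[ra] += open_cnt[rb]
        trail.append((ra, rb))

    def undo(trail: list, opened_root: int) -> None:
        for ra, rb in reversed(trail):
            parent[rb] = rb
            size[ra] -= size[rb]
            open_cnt[ra] -= open_cnt[rb]
        open_cnt[opened_root] += 1

    def recurse() -> None:
        level = len(token)
        prev = token[-1] if token else -1
        # was the parent's last move a left emission? (Rule 1 trigger)
        prev_left = prev if (prev >= 0 and left_pos[prev] == level - 1) else -1

        # -- left-emission child: dequeue the next fresh symbol -------------
        if state["head"] < len(queue):
            s = queue[state["head"]]
            state["head"] += 1
            left_pos[s] = level
            open_cnt[s] = 1
            token.append(s)
            enq = state["created"] < n  # keep exactly n distinct symbols
            if enq:
                queue.append(state["created"])
                state["created"] += 1
            if prev_left >= 0:
                right_elig.append(prev_left)
            recurse()
            if prev_left >= 0:
                right_elig.pop()
            if enq:
                queue.pop()
                state["created"] -= 1
            token.pop()
            open_cnt[s] = 0
            left_pos[s] = -1
            state["head"] -= 1

        # -- right-emission children: one per eligible symbol ---------------
        for idx in range(len(right_elig)):
            e = right_elig[idx]
            le = left_pos[e]
            # Rule 3: previous position closed the arc opened right after e
            if prev >= 0 and right_pos[prev] == level - 1 and left_pos[prev] == le + 1:
                continue
            # close e and merge its crossing partners (all decided now):
            # completed arcs whose right end fell inside (le, level), and
            # open arcs whose left end came after le
            right_pos[e] = level
            root_e = find(e)
            open_cnt[root_e] -= 1
            trail: list = []
            for c in range(n):
                if c == e or left_pos[c] < 0:
                    continue
                rc = right_pos[c]
                if (rc >= 0 and left_pos[c] < le < rc) or (rc < 0 and left_pos[c] > le):
                    union(e, c, trail)
            root = find(e)
            if open_cnt[root] == 0:
                # the group of e can never cross anything emitted later
                if level + 1 == two_n and size[root] == n:
                    token.append(e)
                    state["leaves"] += 1
                    on_leaf(token, left_pos, right_pos)
                    token.pop()
                # otherwise Rule 2: reducible or nested sub-diagram forced
                undo(trail, root_e)
                right_pos[e] = -1
                continue
            del right_elig[idx]
            if prev_left >= 0:
                right_elig.append(prev_left)
            token.append(e)
            recurse()
            token.pop()
            if prev_left >= 0:
                right_elig.pop()
            right_elig.insert(idx, e)
            undo(trail, root_e)
            right_pos[e] = -1

    recurse()
    return state["leaves"]


def enumerate_primitive(n: int, visit: Callable[[str], None] | None = None) -> int:
    """Enumerate all primitive pseudoknot tokens with ``n`` arcs.

    Calls ``visit`` with each completed canonical :class:`PatternToken`
    string exactly once, in the deterministic depth-first order of the tree,
    and returns the number of tokens visited.
    """
    symbols = token_symbols(n)

    def on_leaf(token: list[int], _lp: list[int], _rp: list[int]) -> None:
        if visit is not None:
            visit("".join(symbols[s] for s in token))

    return _walk(n, on_leaf)


def iter_tokens(n: int) -> Iterator[str]:
    """All primitive tokens with ``n`` arcs, materialised eagerly per call."""
    collected: list[str] = []
    enumerate_primitive(n, collected.append)
    return iter(collected)


def count_by_genus(n: int, progress: bool = False) -> dict:
    """Map genus -> count of primitive pseudoknot shadows with ``n`` arcs.

    Each leaf's genus is evaluated immediately by closed-loop counting and
    folded into its bin; leaves are never stored, so memory stays O(n).
    """
    two_n = 2 * n
    counts: dict[int, int] = {}
    partner = [0] * two_n
    mark = [0] * two_n
    state = {"stamp": 0, "seen": 0}

    def on_leaf(_token: list[int], left_pos: list[int], right_pos: list[int]) -> None:
        for s in range(n):
            partner[left_pos[s]] = right_pos[s]
            partner[right_pos[s]] = left_pos[s]
        state["stamp"] += 1
        stamp = state["stamp"]
        loops = 0
        for start in range(two_n):
            if mark[start] == stamp:
                continue
            loops += 1
            r = start
            while mark[r] != stamp:
                mark[r] = stamp
                r = (partner[r] + 1) % two_n
        g = (n - loops + 1) // 2
        counts[g] = counts.get(g, 0) + 1
        if progress:
            state["seen"] += 1
            if state["seen"] % _PROGRESS_EVERY == 0:
                logger.info("n=%d: %d shadows enumerated so far", n, state["seen"])

    _walk(n, on_leaf)
    return dict(sorted(counts.items()))


def count_for_genus_total(
    g: int, budget_seconds: float | None = None, progress: bool = False
) -> int:
    """N(g): primitive pseudoknot shadows of genus g over all admissible arc
    counts, i.e. the sum of a(g, n) for n = 2g .. 6g-2.

    If ``budget_seconds`` elapses before all arc counts are enumerated an
    :class:`EnumerationBudgetError` carrying the completed per-n counts is
    raised.  N(g) grows steeply with g: beyond g = 1 the largest arc counts
    are long computations.
    """
    if g < 1:
        raise ValueError("genus must be >= 1 (genus 0 is the pseudoknot-free convention)")
    t0 = time.monotonic()
    completed: dict[int, int] = {}
    for n in arc_support(g):
        if budget_seconds is not None and time.monotonic() - t0 > budget_seconds:
            raise EnumerationBudgetError(
                f"budget of {budget_seconds} s exhausted after n in "
                f"{sorted(completed)}; remaining n up to {6 * g - 2}",
                completed,
            )
        completed[n] = count_by_genus(n, progress=progress).get(g, 0)
    return sum(completed.values())


def _matchings(points: list[int]) -> Iterator[list[tuple[int, int]]]:
    """All perfect matchings of an even-sized point list, as sorted arc lists."""
    if not points:
        yield []
        return
    first, rest = points[0], points[1:]
    for k in range(len(rest)):
        partner = rest[k]
        for sub in _matchings(rest[:k] + rest[k + 1 :]):
            yield [(first, partner)] + sub


def brute_force_counts(n: int, max_n: int = 7) -> dict:
    """Independent oracle: filter all (2n-1)!! matchings of 2n endpoints.

    A matching survives when it is irreducible, the crossing closure of its
    leftmost arc covers every arc, and it contains no collapsible adjacent
    arc pair; survivors are binned by genus.  Double-factorial growth keeps
    this to small n (10395 matchings at n = 6, 135135 at n = 7).
    """
    if n < 2:
        raise ValueError("no primitive pseudoknot exists with fewer than 2 arcs")
    if n > max_n:
        raise ValueError(f"brute force over (2n-1)!! matchings is limited to n <= {max_n}")
    two_n = 2 * n
    counts: dict[int, int] = {}
    for arcs in _matchings(list(range(1, two_n + 1))):
        arc_set = set(arcs)
        # no collapsible pair: ranks are dense, so stacked means (i,j),(i+1,j-1)
        if any((i + 1, j - 1) in arc_set for i, j in arcs if i + 1 < j - 1):
            continue
        # crossing closure of the leftmost arc must reach every arc; this
        # also implies irreducibility and that every arc crosses another
        closure = {arcs[0]}
        stack = [arcs[0]]
        while stack:
            i, j = stack.pop()
            for other in arcs:
                if other not in closure:
                    k, l = other
                    if i < k < j < l or k < i < l < j:
                        closure.add(other)
                        stack.append(other)
        if len(closure) != n:
            continue
        partner = [0] * two_n
        for i, j in arcs:
            partner[i - 1] = j - 1
            partner[j - 1] = i - 1
        seen = [False] * two_n
        loops = 0
        for start in range(two_n):
            if seen[start]:
                continue
            loops += 1
            r = start
            while not seen[r]:
                seen[r] = True
                r = (partner[r] + 1) % two_n
        g = (n - loops + 1) // 2
        counts[g] = counts.get(g, 0) + 1
    return dict(sorted(counts.items()))


def totals_per_arc(n: int) -> int:
    """Count of distinct primitive components with ``n`` arcs.

    The pseudoknot-free primitive — an empty or single-arc diagram —
    contributes the 0- and 1-arc terms, both 1; for n >= 2 this is the column
    sum of a(g, n) over genus.
    """
    if n < 0:
        raise ValueError("arc count must be non-negative")
    if n <= 1:
        return 1
    return sum(count_by_genus(n).values())


def extension_rejection(prefix: str, symbol: str, n: int) -> str | None:
    """Why appending ``symbol`` as a right end to ``prefix`` is pruned, if it is.

    Reconstructs the tree-node state for a partial canonical token and
    returns ``"rule2"`` (reducible or nested sub-diagram forced), ``"rule3"``
    (collapsible arcs) or ``None`` (the extension is allowed).  ``symbol``
    must be open in ``prefix``: emitted once as a left end.
    """
    occurrences: dict[str, list[int]] = {}
    for pos, ch in enumerate(prefix):
        occurrences.setdefault(ch, []).append(pos)
    if occurrences.get(symbol) is None or len(occurrences[symbol]) != 1:
        raise ValueError(f"symbol {symbol!r} is not open in prefix {prefix!r}")
    le = occurrences[symbol][0]
    level = len(prefix)
    # Rule 3
    if prefix:
        prev = prefix[-1]
        if len(occurrences[prev]) == 2 and occurrences[prev][0] == le + 1:
            return "rule3"
    # Rule 2: union crossing-connected symbols over everything decided so far
    arcs = {ch: pos for ch, pos in occurrences.items()}
    arcs[symbol] = [le, level]
    group = {ch: ch for ch in arcs}

    def find(ch: str) -> str:
        while group[ch] != ch:
            ch = group[ch]
        return ch

    for a, pa in arcs.items():
        if len(pa) != 2:
            continue
        for b, pb in arcs.items():
            if a == b:
                continue
            lb = pb[0]
            crosses = (pa[0] < lb < pa[1] < pb[1]) if len(pb) == 2 else (pa[0] < lb < pa[1])
            if crosses:
                ra, rb = find(a), find(b)
                if ra != rb:
                    group[rb] = ra
    root = find(symbol)
    members = [ch for ch in arcs if find(ch) == root]
    fully_closed = all(len(arcs[ch]) == 2 for ch in members)
    if fully_closed and not (level + 1 == 2 * n and len(members) == n):
        return "rule2"
    return None
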