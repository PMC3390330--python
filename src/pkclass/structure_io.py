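"""Readers, writers and pre-processing for pseudoknotted RNA secondary structures.

Supported formats are the ones RNA structure databases commonly distribute:

* extended dot-bracket, with multiple bracket families ``() [] {} <>`` and
  then ``Aa``..``Zz`` so that crossing (pseudoknotted) stems can be written;
* CT (connectivity table, 6 columns);
* BPSEQ (3 columns: index, base, partner).

All coordinates are 1-based and inclusive, the native convention of CT and
BPSEQ.  The in-memory representation is :class:`SecondaryStructure`: a
backbone length, an optional nucleotide sequence, and a set of base pairs
``(i, j)`` with ``i < j`` in which every index participates at most once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "StructureFormatError",
    "SecondaryStructure",
    "BRACKET_FAMILIES",
    "parse_dotbracket",
    "parse_ct",
    "parse_bpseq",
    "filter_canonical",
    "write_dotbracket",
    "read_records",
    "read_dotbracket_records",
]


class StructureFormatError(ValueError):
    """Raised when an input file or string violates its format contract."""


#: Ordered bracket families used for reading and writing dot-bracket text.
BRACKET_FAMILIES: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
) + tuple((chr(ord("A") + k), chr(ord("a") + k)) for k in range(26))

#: Glyphs accepted as "unpaired" on input; always written back as '.'.
UNPAIRED_GLYPHS = frozenset({".", ":", "-"})

#: Base pairs retained by :func:`filter_canonical` (Watson-Crick + G·U wobble).
CANONICAL_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA secondary structure: backbone, optional sequence, base pairs.

    Parameters
    ----------
    length:
        Number of nucleotides in the backbone.
    pairs:
        Base pairs as 1-based tuples ``(i, j)`` with ``i < j``.  Every index
        may participate in at most one pair.
    sequence:
        Optional nucleotide string of exactly ``length`` characters.
    """

    length: int
    pairs: frozenset
    sequence: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        if self.length < 0:
            raise ValueError("length must be non-negative")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"index in pair ({i},{j}) participates in more than one pair")
            seen.add(i)
            seen.add(j)
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match declared length {self.length}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)


def parse_dotbracket(
    text: str,
    alphabet: Sequence[tuple[str, str]] = BRACKET_FAMILIES,
) -> SecondaryStructure:
    """Parse one extended dot-bracket string into a :class:`SecondaryStructure`.

    Each closing bracket is matched to the most recent unmatched opener of the
    same family (per-family stack discipline), so crossing stems are expressed
    by using distinct families, e.g. ``"([)]"`` for the H-pseudoknot shadow.
    ``':'`` and ``'-'`` are tolerated as unpaired placeholders.
    """
    text = text.strip()
    openers = {o: k for k, (o, _) in enumerate(alphabet)}
    closers = {c: k for k, (_, c) in enumerate(alphabet)}
    stacks: dict[int, list[int]] = {k: [] for k in range(len(alphabet))}
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text, start=1):
        if ch in UNPAIRED_GLYPHS:
            continue
        if ch in openers:
            stacks[openers[ch]].append(pos)
        elif ch in closers:
            fam = closers[ch]
            if not stacks[fam]:
                raise StructureFormatError(
                    f"unbalanced bracket at position {pos}: closing '{ch}' of family "
                    f"'{alphabet[fam][0]}{alphabet[fam][1]}' has no matching opener"
                )
            pairs.add((stacks[fam].pop(), pos))
        else:
            raise StructureFormatError(f"unknown character '{ch}' at position {pos}")
    for fam, stack in stacks.items():
        if stack:
            raise StructureFormatError(
                f"unbalanced bracket at position {stack[-1]}: opener "
                f"'{alphabet[fam][0]}' of family '{alphabet[fam][0]}{alphabet[fam][1]}' never closed"
            )
    return SecondaryStructure(length=len(text), pairs=frozenset(pairs))


def _as_lines(lines: str | Iterable[str] | Path) -> list[str]:
    if isinstance(lines, Path):
        lines = lines.read_text()
    if isinstance(lines, str):
        lines = lines.splitlines()
    return [ln.rstrip("\n") for ln in lines]


def _pairs_from_partner_column(partners: dict[int, int]) -> frozenset:
    """Deduplicate a reciprocal partner map into pairs with i < j."""
    pairs = set()
    for i, j in partners.items():
        if j == 0:
            continue
        back = partners.get(j)
        if back != i:
            raise StructureFormatError(
                f"inconsistent reciprocal pairing: row {i} points to {j} "
                f"but row {j} points to {back}"
            )
        if i == j:
            raise StructureFormatError(f"row {i} pairs with itself")
        pairs.add((min(i, j), max(i, j)))
    return frozenset(pairs)


def parse_ct(lines: str | Iterable[str] | Path) -> SecondaryStructure:
    """Parse a 6-column CT file (index, base, prev, next, pair, natural index).

    The header line declares the length; a pair index of 0 means unpaired.
    Reciprocity is enforced: if row i names j, row j must name i.
    """
    raw = [ln for ln in _as_lines(lines) if ln.strip()]
    if not raw:
        raise StructureFormatError("empty CT input")
    header = raw[0].split()
    try:
        length = int(header[0])
    except (ValueError, IndexError) as exc:
        raise StructureFormatError(f"CT header must start with the length: {raw[0]!r}") from exc
    rows = raw[1 : 1 + length]
    if len(rows) != length:
        raise StructureFormatError(f"CT declares {length} rows but provides {len(rows)}")
    sequence: list[str] = []
    partners: dict[int, int] = {}
    for n, ln in enumerate(rows, start=1):
        cols = ln.split()
        if len(cols) < 6:
            raise StructureFormatError(f"CT row {n} has {len(cols)} columns, expected >= 6")
        idx, base, pair_idx = int(cols[0]), cols[1], int(cols[4])
        if idx != n:
            raise StructureFormatError(f"CT row {n} carries index {idx}")
        if not (0 <= pair_idx <= length):
            raise StructureFormatError(f"CT row {n} pairs with out-of-range index {pair_idx}")
        sequence.append(base)
        partners[idx] = pair_idx
    return SecondaryStructure(
        length=length, pairs=_pairs_from_partner_column(partners), sequence="".join(sequence)
    )


def parse_bpseq(lines: str | Iterable[str] | Path) -> SecondaryStructure:
    """Parse a 3-column BPSEQ file (index, base, partner-or-0), 1-based.

    Leading comment/header lines (anything whose first token is not an
    integer) are skipped, as in the files RNA databases distribute.
    """
    rows: list[tuple[int, str, int]] = []
    for ln in _as_lines(lines):
        cols = ln.split()
        if not cols:
            continue
        try:
            idx = int(cols[0])
        except ValueError:
            continue  # header / comment line
        if len(cols) < 3:
            raise StructureFormatError(f"BPSEQ row {ln!r} has fewer than 3 columns")
        rows.append((idx, cols[1], int(cols[2])))
    length = len(rows)
    sequence: list[str] = []
    partners: dict[int, int] = {}
    for n, (idx, base, partner) in enumerate(rows, start=1):
        if idx != n:
            raise StructureFormatError(f"BPSEQ row {n} carries index {idx}; rows must be 1..N")
        if not (0 <= partner <= length):
            raise StructureFormatError(f"BPSEQ row {n} names out-of-range partner {partner}")
        sequence.append(base)
        partners[idx] = partner
    return SecondaryStructure(
        length=length, pairs=_pairs_from_partner_column(partners), sequence="".join(sequence)
    )


def filter_canonical(s: SecondaryStructure) -> SecondaryStructure:
    """Drop non-canonical base pairs, keeping Watson-Crick and G·U wobble.

    Bases are compared case-insensitively and T is treated as U.  The length
    and sequence are unchanged; only the pair set shrinks.  Idempotent.
    """
    if s.sequence is None:
        raise ValueError("canonical filtering needs bases: structure has no sequence")
    norm = s.sequence.upper().replace("T", "U")
    kept = frozenset(
        (i, j) for i, j in s.pairs if (norm[i - 1], norm[j - 1]) in CANONICAL_PAIRS
    )
    return SecondaryStructure(length=s.length, pairs=kept, sequence=s.sequence)


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return i < k < j < l or k < i < l < j


def write_dotbracket(
    s: SecondaryStructure, alphabet: Sequence[tuple[str, str]] = BRACKET_FAMILIES
) -> str:
    """Render a structure as extended dot-bracket text.

    Bracket families are assigned by greedy first-fit colouring of the pair
    crossing graph, scanning pairs by left endpoint, so mutually crossing
    stems end up in distinct families and ``parse_dotbracket`` round-trips to
    the same pair set.
    """
    chars = ["."] * s.length
    assigned: list[list[tuple[int, int]]] = [[] for _ in alphabet]
    for pair in s.sorted_pairs():
        for fam, members in enumerate(assigned):
            if not any(_crosses(pair, m) for m in members):
                members.append(pair)
                o, c = alphabet[fam]
                chars[pair[0] - 1] = o
                chars[pair[1] - 1] = c
                break
        else:
            raise StructureFormatError(
                f"structure needs more than {len(alphabet)} simultaneous crossing "
                "bracket families"
            )
    return "".join(chars)


_SEQ_CHARS = frozenset("ACGUTNRYSWKMBDHVacgutnryswkmbdhv")


def read_dotbracket_records(
    lines: str | Iterable[str] | Path,
) -> list[tuple[str, SecondaryStructure]]:
    """Read one or more dot-bracket records from FASTA-like text.

    A record is an optional ``>id`` header followed by either a single
    structure line, or a sequence line and then a structure line.  Returns
    ``(id, structure)`` tuples; unnamed records get ``record_<k>`` ids.
    """
    out: list[tuple[str, SecondaryStructure]] = []
    pending_id: str | None = None
    pending_body: list[str] = []

    def flush() -> None:
        nonlocal pending_id, pending_body
        if not pending_body:
            pending_id = None
            return
        rid = pending_id if pending_id is not None else f"record_{len(out) + 1}"
        if len(pending_body) == 1:
            struct = parse_dotbracket(pending_body[0])
        elif len(pending_body) == 2:
            seq, db = pending_body
            struct = parse_dotbracket(db)
            if len(seq) != struct.length:
                raise StructureFormatError(
                    f"record {rid}: sequence length {len(seq)} != structure length {struct.length}"
                )
            struct = SecondaryStructure(length=struct.length, pairs=struct.pairs, sequence=seq)
        else:
            raise StructureFormatError(
                f"record {rid}: expected 1 (structure) or 2 (sequence, structure) lines, "
                f"got {len(pending_body)}"
            )
        out.append((rid, struct))
        pending_id = None
        pending_body = []

    for ln in _as_lines(lines):
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith(">"):
            flush()
            pending_id = ln[1:].strip()
        else:
            pending_body.append(ln)
    flush()
    return out


def read_records(
    source: str | Path | Iterable[str], fmt: str, record_id: str | None = None
) -> list[tuple[str, SecondaryStructure]]:
    """Read structures in ``fmt`` in {'dotbracket', 'ct', 'bpseq'}.

    CT and BPSEQ files carry a single structure each; dot-bracket files may
    carry several records.
    """
    if fmt == "dotbracket":
        return read_dotbracket_records(source)
    if fmt == "ct":
        s = parse_ct(source)
    elif fmt == "bpseq":
        s = parse_bpseq(source)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected dotbracket, ct or bpseq")
    if record_id is None:
        record_id = Path(source).stem if isinstance(source, (str, Path)) else "record_1"
    return [(record_id, s)]
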