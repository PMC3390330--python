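"""Dataset-level topological classification of pseudoknotted structures.

Mirrors the workflow used on curated secondary-structure collections: parse,
optionally drop non-canonical pairs, de-duplicate identical sequences,
decompose every structure into primitive components, and tabulate

* a *subclass table*: one row per distinct pattern token of genus >= 1,
  labelled ``<genus><letter>`` (1A, 1B, ..., 2A, ...) with letters assigned
  within each genus in decreasing number of source structures;
* a *component table*: one row per primitive component per structure;
* a *total-genus histogram* over whole structures.

A seeded fixture generator plants chosen pattern tokens as stems of
configurable length with optional bulges, so the whole pipeline can be
exercised against known ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from statistics import pstdev
from typing import Iterable, Sequence

from .decomposition import (
    collapse_stems,
    extract_primitive,
    has_collapsible_pair as _has_collapsible,
    nonnested_closure as _nonnested_closure,
    parse_token,
    pattern_token,
)
from .genus import genus_of, total_genus
from .structure_io import SecondaryStructure, write_dotbracket

__all__ = [
    "DatasetRecord",
    "SubclassRecord",
    "ComponentRecord",
    "dedupe",
    "classify_dataset",
    "total_genus_histogram",
    "generate_fixture",
    "FixtureError",
]

_CANONICAL_COMPLEMENTS = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class DatasetRecord:
    """One input structure with a stable identifier and optional provenance."""

    id: str
    structure: SecondaryStructure
    source: str | None = None


@dataclass(frozen=True)
class ComponentRecord:
    """One primitive component of one structure."""

    structure_id: str
    token: str
    genus: int
    n_arcs: int
    span_start: int
    span_end: int

    @property
    def length(self) -> int:
        return self.span_end - self.span_start + 1


@dataclass(frozen=True)
class SubclassRecord:
    """Aggregate statistics for one pattern token of genus >= 1.

    ``n_sequences`` counts distinct source structures containing the motif;
    ``n_instances`` counts component occurrences.  Lengths are end-to-end
    spans in nucleotides (leftmost to rightmost paired position, inclusive);
    the standard deviation is the population form (divide by n).
    """

    genus: int
    subclass_id: str
    token: str
    n_sequences: int
    n_instances: int
    length_mean: float
    length_sd: float
    length_min: int


def dedupe(records: Iterable[DatasetRecord]) -> list[DatasetRecord]:
    """Keep the first record for each distinct base sequence.

    Structures sharing an identical sequence are treated as redundant
    annotations of one molecule; keeping the first in input order is the
    deterministic stand-in for an arbitrary choice.  Records without a
    sequence are kept as-is.
    """
    seen: set[str] = set()
    out: list[DatasetRecord] = []
    for rec in records:
        seq = rec.structure.sequence
        if seq is not None:
            if seq in seen:
                continue
            seen.add(seq)
        out.append(rec)
    return out


def classify_dataset(
    records: Iterable[DatasetRecord],
) -> tuple[list[SubclassRecord], list[ComponentRecord], list[str]]:
    """Classify every structure's primitive pseudoknots into subclasses.

    Returns ``(subclasses, components, discarded)`` where ``components``
    lists every primitive component (including genus-0 ones, flagged by
    ``genus == 0``) and ``discarded`` the ids of structures left with no
    pseudoknotted component.  Subclasses are sorted by (genus ascending,
    n_sequences descending); ties break by arc count descending, then token
    lexicographically.
    """
    components: list[ComponentRecord] = []
    discarded: list[str] = []
    per_token: dict[str, list[ComponentRecord]] = {}
    for rec in records:
        any_pk = False
        for comp in extract_primitive(rec.structure, origin=rec.id):
            g = genus_of(comp.diagram).genus
            shadow = collapse_stems(comp.diagram)
            crec = ComponentRecord(
                structure_id=rec.id,
                token=pattern_token(shadow),
                genus=g,
                n_arcs=shadow.n_arcs,
                span_start=comp.span[0],
                span_end=comp.span[1],
            )
            components.append(crec)
            if g >= 1:
                any_pk = True
                per_token.setdefault(crec.token, []).append(crec)
        if not any_pk:
            discarded.append(rec.id)

    rows = []
    for token, crecs in per_token.items():
        lengths = [c.length for c in crecs]
        rows.append(
            dict(
                genus=crecs[0].genus,
                token=token,
                n_arcs=crecs[0].n_arcs,
                n_sequences=len({c.structure_id for c in crecs}),
                n_instances=len(crecs),
                length_mean=sum(lengths) / len(lengths),
                length_sd=pstdev(lengths) if len(lengths) > 1 else 0.0,
                length_min=min(lengths),
            )
        )
    rows.sort(key=lambda r: (r["genus"], -r["n_sequences"], -r["n_arcs"], r["token"]))
    subclasses: list[SubclassRecord] = []
    letter_count: dict[int, int] = {}
    for r in rows:
        k = letter_count.get(r["genus"], 0)
        letter_count[r["genus"]] = k + 1
        subclasses.append(
            SubclassRecord(
                genus=r["genus"],
                subclass_id=f"{r['genus']}{chr(ord('A') + k)}",
                token=r["token"],
                n_sequences=r["n_sequences"],
                n_instances=r["n_instances"],
                length_mean=r["length_mean"],
                length_sd=r["length_sd"],
                length_min=r["length_min"],
            )
        )
    return subclasses, components, discarded


def total_genus_histogram(records: Iterable[DatasetRecord]) -> dict:
    """Bin structures by the total genus of their whole secondary structure."""
    hist: dict[int, int] = {}
    for rec in records:
        tg = total_genus(rec.structure)
        hist[tg] = hist.get(tg, 0) + 1
    return dict(sorted(hist.items()))


class FixtureError(RuntimeError):
    """Raised when a fixture specification cannot be realised."""


MotifSpec = tuple[str, tuple[int, int], float]


def generate_fixture(
    motifs: Sequence[MotifSpec],
    seed: int,
    *,
    record_id: str = "fixture",
    spacer: tuple[int, int] = (1, 6),
    extra_hairpins: int = 0,
) -> tuple[DatasetRecord, list[dict]]:
    """Build one synthetic structure with planted pseudoknot motifs.

    Each motif is ``(token, (stem_min, stem_max), bulge_rate)``: every arc of
    the token is expanded into a stem of ``stem_min..stem_max`` parallel
    pairs, optionally interrupted by short unpaired bulges (which never break
    stem collapse, since collapse only looks at paired endpoints).  Motifs
    are concatenated left to right with unpaired spacers, so each one is a
    separate irreducible component; ``extra_hairpins`` plain (genus-0)
    helices are interleaved.  A random sequence with canonical partners at
    every pair is attached.

    Returns the record and a ground-truth manifest: one dict per planted
    motif with its token, genus, span and length.  Deterministic for a given
    seed and spec.
    """
    rng = random.Random(seed)
    seq: list[str] = []
    pairs: list[tuple[int, int]] = []
    truth: list[dict] = []

    def pad(lo: int, hi: int) -> None:
        for _ in range(rng.randint(lo, hi)):
            seq.append(rng.choice("ACGU"))

    def add_pair(i: int, j: int) -> None:
        pairs.append((i, j))

    def plant_hairpin() -> None:
        k = rng.randint(1, 4)
        pad(*spacer)
        left = []
        for _ in range(k):
            left.append(len(seq) + 1)
            seq.append("N")
        pad(3, 6)  # loop
        for p in reversed(left):
            add_pair(p, len(seq) + 1)
            seq.append("N")
        pad(*spacer)

    for token, (stem_min, stem_max), bulge_rate in motifs:
        if stem_min < 1 or stem_max < stem_min:
            raise FixtureError(f"bad stem range {(stem_min, stem_max)} for motif {token!r}")
        if not 0.0 <= bulge_rate <= 1.0:
            raise FixtureError(f"bulge rate {bulge_rate} outside [0, 1] for motif {token!r}")
        diagram = parse_token(token)
        if pattern_token(diagram) != token:
            raise FixtureError(f"motif token {token!r} is not canonical")
        if _nonnested_closure(diagram) != set(diagram.arcs) or _has_collapsible(diagram):
            raise FixtureError(
                f"motif token {token!r} is not a primitive pseudoknot shadow"
            )
        pad(*spacer)
        stem_len = {arc: rng.randint(stem_min, stem_max) for arc in diagram.arcs}
        # lay out the 2P token positions left to right; each becomes a block
        # of stem_len positions (with optional unpaired bulges inside)
        half_positions: dict[tuple[int, int], list[int]] = {}
        for rank in sorted(p for arc in diagram.arcs for p in arc):
            arc = next(a for a in diagram.arcs if rank in a)
            block: list[int] = []
            for t in range(stem_len[arc]):
                if t > 0 and rng.random() < bulge_rate:
                    pad(1, 3)
                block.append(len(seq) + 1)
                seq.append("N")
            half_positions[(arc[0], arc[1], rank == arc[0])] = block  # type: ignore[index]
            pad(0, 2)
        first_paired = None
        for arc in diagram.arcs:
            lefts = half_positions[(arc[0], arc[1], True)]
            rights = half_positions[(arc[0], arc[1], False)]
            for t, p in enumerate(lefts):
                add_pair(p, rights[len(rights) - 1 - t])
        motif_positions = [p for arc in diagram.arcs for half in (True, False) for p in half_positions[(arc[0], arc[1], half)]]
        first_paired, last_paired = min(motif_positions), max(motif_positions)
        truth.append(
            dict(
                token=token,
                genus=genus_of(diagram).genus,
                span=(first_paired, last_paired),
                length=last_paired - first_paired + 1,
            )
        )
        pad(*spacer)
        if extra_hairpins and rng.random() < 0.75:
            plant_hairpin()
    for _ in range(extra_hairpins):
        plant_hairpin()
    pad(*spacer)

    # fill paired placeholders with canonical partners
    for i, j in pairs:
        base = rng.choice("ACGU")
        seq[i - 1] = base
        seq[j - 1] = _CANONICAL_COMPLEMENTS[base]
    structure = SecondaryStructure(
        length=len(seq), pairs=frozenset(pairs), sequence="".join(seq)
    )
    # sanity: the layout must keep planted motifs separate
    if len(extract_primitive(structure)) < len(motifs):
        raise FixtureError("planted motifs merged; widen spacers")
    return DatasetRecord(id=record_id, structure=structure, source="synthetic"), truth


def fixture_dotbracket(record: DatasetRecord) -> str:
    """FASTA-style dot-bracket text for a generated fixture record."""
    db = write_dotbracket(record.structure)
    return f">{record.id}\n{record.structure.sequence}\n{db}\n"
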