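# Methods

## Model

An RNA secondary structure is a backbone of N nucleotides with a partial
matching of base pairs; drawn as arcs over the backbone it is a chord
diagram. Two arcs (i, j), (k, l) *cross* iff i < k < j < l or
k < i < l < j; a structure is pseudoknotted iff some pair of arcs crosses.
Only the relative order (rank) of paired positions is semantic: unpaired
bases, bulges and the gaps left by extracting nested substructures never
change any topological quantity computed here.

### Decomposition

1. *Irreducible components*: scan the backbone; cut wherever the count of
   open pairs returns to zero. Equivalently, pairs are grouped by chained
   interval overlap. Each segment with at least one pair is one component.
2. *Primitive components*: within an irreducible component, the leftmost
   arc is necessarily non-nested; its crossing closure (repeatedly add all
   arcs crossing a member) collects exactly the non-nested arcs. That
   closure is one primitive component; the remaining nested arcs are
   re-split and recursed. Components keep original coordinates, so spans
   and lengths refer to the source structure.

A closure that crosses nothing (one helix level of a pseudoknot-free
region) is a genus-0 primitive component. We report such components but
flag them with genus 0; only genus ≥ 1 components are *primitive
pseudoknots* and only they receive subclass labels, so pseudoknot tallies
are unaffected by the convention.

### Genus

Close the backbone into a circle (rank 2P wraps to 1) and thicken arcs into
ribbons; the number L of boundary cycles ("closed loops") of the resulting
fatgraph determines the genus of the surface the diagram embeds in:

    g = (P − L + 1) / 2

with P the number of pairs. g is a non-negative integer, 0 iff the diagram
is crossing-free, and additive over primitive components. The closed
backbone is required for the lone-arc case (P = 1, L = 2, g = 0).

Two independent loop counters are shipped and tested to agree exhaustively
on all 1 + 3 + 15 + 105 + 945 matchings of up to 5 arcs plus random larger
diagrams:

* the normative permutation form — L = number of cycles of r ↦ τ(σ(r)),
  where σ exchanges the two endpoints of each arc and τ is the cyclic
  successor on ranks;
* an explicit traversal of the graph (V, A, E) of paired positions,
  bidirectional arcs and backbone successor edges, with visited marks,
  counting a loop whenever the traversal returns to an already-visited
  arc. Its loose ends (edge direction, final-loop counting) are resolved
  precisely by the required agreement with the permutation form.

The affine form of the genus relation is itself executed as a test: a full-
rank least-squares fit of g = aP + bL + c over the fifteen published
(token, genus) anchor pairs returns exactly (½, −½, ½) with zero residual.

### Shadows and pattern tokens

Adjacent stacked pairs — arcs (i, j), (k, l) with i < k < l < j and no
*paired* position strictly inside (i, k) or (l, j) — form one stem and are
merged (keeping the outer arc) until fixpoint. Merging across unpaired
bulges is deliberate: a stem interrupted by a bulge is still one stem. The
fixpoint is the *shadow*; genus is invariant under the collapse (property-
tested by random stem inflation). Note the rule is purely positional: a
stacked pair collapses even when a third arc threads through the stem's
loop, e.g. {(1,4),(2,6),(3,5)} → {(1,4),(2,6)}, which is also why the token
ABCACB is not a valid shadow.

A shadow is canonicalised as a token by walking endpoints in rank order and
assigning letters A, B, C, … at first endpoints (a27, a28, … past 26 arcs;
tokens that large are never reached in practice). Genus is evaluated on the
*uncollapsed* component — the component represents the actual structure —
while tokens name the collapsed shadow; genus invariance under collapse
makes the two views consistent.

## Enumeration of primitive shadows

a(g, n) counts distinct primitive pseudoknot shadows with n arcs and genus
g; its support is 2g ≤ n ≤ 6g − 2. Tokens are generated by a depth-first
tree whose nodes carry a partial token, a FIFO queue of symbols awaiting
left-end emission, and the set of symbols eligible for right-end emission.
Fresh symbols are enqueued while fewer than n exist, so left ends appear in
creation order and every leaf (depth 2n) is born canonical; each token
corresponds to exactly one root-to-leaf path, so no deduplication is ever
needed. Three rules prune the tree:

* **Rule 1** — a symbol becomes right-eligible one level after its left
  emission (the parent's last-appended left character joins each child's
  right set), excluding immediate hairpin closures.
* **Rule 2** — closing an arc must not complete a crossing-connected group
  of arcs while other arcs are open or pending. A fully closed group can
  never cross anything emitted later, so it would end up either reducible
  (separable along the backbone) or nested. This is tracked exactly with a
  rollback union-find over arcs: when an arc closes, its crossing partners
  are all decided (open arcs that started inside it, completed arcs whose
  right end fell inside it), the groups are merged, and the branch is cut
  if the merged group has no open member — unless it is the final arc of a
  connected leaf. The backbone cut-point check is subsumed: a cut point
  would mean every group is closed.
* **Rule 3** — a right end may not land immediately after the right end of
  the arc that opened immediately after its own left end; ranks are dense
  in a shadow, so this is exactly the collapsible-pair pattern …YX…XY….

Leaves are folded into genus bins immediately (loop counting on a reused
partner array) and discarded, so memory is O(n) while the tree itself grows
exponentially. Determinism: pure depth-first order, no randomness.

N(g) = Σ a(g, n) over n = 2g..6g−2 is exposed with an optional wall-clock
budget; exceeding it raises an error carrying the per-n counts already
completed, since the largest columns (n ≥ 10) take days in pure Python and
are reachable only through the CLI's explicit `--allow-long` path.

An independent oracle generates all (2n−1)!! perfect matchings of 2n
endpoints and keeps those that are irreducible, whose leftmost-arc crossing
closure covers every arc, and which contain no collapsible adjacent pair;
survivors are binned by the same genus evaluation. Tree and oracle agree
exactly for all n ≤ 7 (135 135 matchings); the suite runs the tree up to
n = 9 (≈ 6.6 million shadows, ~1.5 min on one core — the chosen ceiling for
a routine test run; n ≥ 10 grows a further order of magnitude per column).

## Dataset pipeline

Input formats: extended dot-bracket (families `()`, `[]`, `{}`, `<>`,
`Aa`–`Zz`; `:`/`-` tolerated as unpaired), 6-column CT and 3-column BPSEQ
(both with reciprocity checking). On writing, stems are assigned bracket
families by greedy first-fit colouring of the crossing graph, and
parse ∘ write is the identity on the pair set (property-tested).

Pre-processing mirrors curated-database practice: optional removal of
non-canonical pairs (canonical = Watson–Crick + G·U wobble,
case-insensitive, T read as U — the wobble choice is recorded in the output
metadata since either convention is defensible), then de-duplication
keeping the first record per identical base sequence as the deterministic
stand-in for an arbitrary choice among redundant annotations.

Classification decomposes each structure, drops genus-0 components,
collapses to shadows and groups by token. Subclass ids `<genus><letter>`
are assigned within each genus by decreasing number of source structures;
ties break by arc count descending, then token lexicographic — a documented
convention for an order the source tables leave unstated. Lengths are
end-to-end spans (leftmost to rightmost paired base, inclusive) pooled over
all component instances; the standard deviation is the population form
(divide by n). Both a distinct-structure count and an instance count are
emitted, since a motif can recur within one molecule. Structures left with
no pseudoknotted component are listed separately. The total-genus histogram
bins whole structures by the sum of their components' genera.

## Synthetic fixtures

The generator emulates pseudoknotted molecules with known ground truth:
each requested motif token (validated to be a canonical primitive shadow)
has every arc expanded into a stem of a configurable number of parallel
pairs (default range up to 20, matching the sizes of real stems), optionally
interrupted by 1–3-nt unpaired bulges at a configurable rate; motifs are
concatenated with 1–6-nt unpaired spacers, optionally interleaved with
plain genus-0 hairpins; paired positions receive canonical partner bases,
the rest random nucleotides. Everything derives from one `random.Random`
seed, so fixtures are byte-identical across runs.

What the generator does *not* emulate: non-canonical pairs, motifs nested
inside other motifs' loops, sequence redundancy across records, or the
length/abundance distributions of real databases. Pipeline tests on these
fixtures therefore demonstrate exact recovery of planted (token, genus)
multisets and spans — i.e. correctness of the topological machinery — not
statistical claims about real RNA collections, whose reproduction would
require the source databases themselves.

## Numerical and degenerate-input choices

* Coordinates 1-based inclusive everywhere; empty structures are legal
  everywhere (empty component list, genus 0, empty tables).
* The empty diagram short-circuits to g = 0; for P ≥ 1 the parity and sign
  of P − L + 1 are asserted and a violation raises, since it can only mean
  a loop-counting bug.
* Stem collapse keeps the outer arc as representative; the choice is
  immaterial (rank-equivalent) and merges cascade until fixpoint.
* Greedy bracket-family assignment can in principle exhaust the 30
  families; this raises a clear error (never observed below hundreds of
  mutually crossing stems).
* All tallies are exact integer arithmetic; no floating point enters any
  count (floats appear only in length statistics and proportions).

## Known limitations

* a(g, n) columns for n ≥ 10 are impractical in pure Python (the n = 12
  column alone exceeds 2 × 10¹⁰ leaves); the algorithm streams them
  correctly but wall-clock time, not memory, is the binding constraint.
* Tokens beyond 26 arcs render with the extended alphabet but cannot be
  re-parsed from strings.
* The CT reader requires the declared row count and exact 1..N indexing;
  permissive variants found in the wild (missing headers, extra columns)
  are accepted only insofar as they reduce to the 6-column core.
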