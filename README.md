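# pkclass — topological classification of RNA pseudoknots

Pseudoknots are RNA secondary-structure motifs in which base pairs cross:
pairs (i, j) and (k, l) with i < k < j < l. Prediction tools handle the
prevalent H-pseudoknot and kissing hairpin, but the number of *possible*
more complex pseudoknots explodes combinatorially while only a handful occur
in real molecules. `pkclass` implements the topological machinery needed to
study that gap:

* **Decomposition.** A structure's base pairs form a chord diagram. It is
  split into *irreducible* components (no backbone cut point) and then into
  *primitive* components — irreducible and non-nested, obtained as the
  crossing closure of each component's leftmost arc, recursing on what is
  nested below.
* **Genus.** Each component's complexity is its topological genus
  g = (P − L + 1)/2, where P is the number of base pairs and L the number of
  closed loops (boundary cycles of the fatgraph drawn on the closed
  backbone). g = 0 exactly for pseudoknot-free diagrams, and the genus of a
  whole structure is the sum over its primitive components. L is counted
  two ways — an explicit arc/backbone traversal and a permutation-cycle
  formulation (cycles of r ↦ τ(σ(r)), σ the arc involution, τ the cyclic
  successor) — which are tested to agree exhaustively.
* **Pattern tokens.** Collapsing each stem of stacked parallel pairs to a
  single arc gives the motif's *shadow*, named by a canonical token over an
  arc alphabet: `ABAB` (H-pseudoknot), `ABACBC` (kissing hairpin),
  `ABCABC` (pseudotrefoil), `ABCACDBD`, …
* **Enumeration.** A depth-first tree algorithm generates every distinct
  primitive pseudoknot shadow with n arcs exactly once and bins the leaves
  by genus, yielding the counts a(g, n) (e.g. a(2, 4) = 17,
  a(3, 7) = 23 482, a(4, 8) = 200 589). A brute-force filter over all
  (2n−1)!! matchings provides an independent oracle at small n.
* **Dataset pipeline.** Readers for extended dot-bracket, CT and BPSEQ;
  canonical-pair filtering (Watson–Crick + G·U); sequence-level
  de-duplication; per-dataset subclass tables (1A, 1B, …) and total-genus
  histograms; and a seeded generator of synthetic structures with planted
  motifs for end-to-end validation.

Intended users: structural bioinformaticians classifying pseudoknot motifs
in curated secondary-structure collections, and developers of prediction
algorithms who need the census of topologically distinct pseudoknots.

## Worked example

```python
from pkclass import (parse_dotbracket, extract_primitive, collapse_stems,
                     pattern_token, genus_of, total_genus, count_by_genus)

s = parse_dotbracket("..((..[[..))..((..]]..))....((.[[[.)).]]]")
for c in extract_primitive(s):
    r = genus_of(c.diagram)
    print(f"span {c.span}  P={r.n_pairs} L={r.n_loops} g={r.genus}  "
          f"token {pattern_token(collapse_stems(c.diagram))}")
print("total genus:", total_genus(s))
print(count_by_genus(4))
```

prints

```
span (3, 24)  P=6 L=5 g=1  token ABACBC
span (29, 41)  P=5 L=4 g=1  token ABAB
total genus: 2
{1: 1, 2: 17}
```

The first component (paired bases 3–24, six pairs forming three stems) is a
kissing hairpin, the second an H-pseudoknot; both have genus 1, so the whole
structure has total genus 2. The last line is the enumeration at 4 arcs:
one shadow of genus 1 and 17 of genus 2 exist.

The same operations are available from the shell:

```sh
pkclass genus --token ABCACDBD        # -> ABCACDBD  P=4  L=1  g=2
pkclass enumerate --arcs 5 --by-genus # -> genus 2: 160
pkclass decompose --input structures.dbn
pkclass classify --input structures.dbn --canonical-only --out-prefix run1
pkclass fixtures --spec fixtures.yaml --seed 7 --out fx/
```

Enumeration beyond 9 arcs is a long computation (hours to days) and is
gated behind `pkclass enumerate --allow-long`.

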