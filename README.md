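# rnaentangle

Automatic identification and classification of **entanglements of structural
elements** in RNA 3D structures.

Complex RNA folds — and, far more often, computationally predicted RNA 3D
models — can contain arrangements in which one structural element threads
through another: a single strand passing through a hairpin loop, two loops
linked like chain rings, a strand piercing the quadrilateral between two
stacked base pairs. Unlike a topological knot, such an entanglement is
defined with respect to base pairing: the "closed" boundary that gets
punctured is a cycle of backbone and canonical base pairs, not the bare
polymer chain. Some entanglements are modelling artifacts and mark a 3D
model as unreliable; others, like the knot-like fold of viral
exoribonuclease-resistant RNAs (xrRNAs) and the SARS-CoV-2 frameshifting
element, are genuine functional motifs. `rnaentangle` finds both, so it can
be used to screen predicted models and to analyze complex pseudoknotted
structures.

## Method

1. **Clean** the input (PDB or PDBx/mmCIF): keep RNA chains only, collapse
   alternate locations, strip surplus atoms of modified residues, drop
   nucleotides too incomplete to analyze.
2. **Secondary structure**: detect canonical pairs (A-U, G-C, G-U) from
   geometry — C1′–C1′ distance, Watson–Crick-edge H-bond distances,
   base-plane angle — or accept a user dot-bracket. Assign every pair a
   *pseudoknot order*: order 0 is a maximum non-crossing subset (the core),
   order *k* ≥ 1 the successive non-crossing layers of the remaining
   crossing pairs.
3. **Elements, per level**: at level *k* only order-*k* pairs count as
   paired. Closed elements are loops **L** (cycles of backbone runs and
   closing pairs) and dinucleotide steps **D** (quadrilaterals between
   stacked pairs *(i,j)*, *(i+1,j−1)*); open elements are single strands
   **S** (maximal unpaired runs not enclosed by any order-*k* pair).
4. **Geometry**: every element becomes a polygonal chain through its P and
   C4′ atoms, with base center-of-mass pseudoatoms bridging each closing
   pair. Closed chains are covered with a triangle mesh (centroid fan +
   recursive longest-edge refinement); punctures are segment–triangle
   intersections (Möller–Trumbore).
5. **Classification**: if one element only punctures and the other is only
   punctured, the pair is a **lasso**, coded `X(Y)`; if two closed elements
   puncture each other, an **interlace**, coded `X&Y`. Extra punctures
   append dots — `L(S..)` is a loop crossed three times by a strand.
   Level 0 gives *primary* entanglements, level *k* ≥ 1 *higher-order*
   ones (e.g. the knot-like fold: a 5′ strand threading a ring closed by
   pseudoknotted pairs).

## Worked example

The generator builds a synthetic emulation of the xrRNA knot-like fold
(60 nt; the 5′ strand threads a ring closed by the order-1 pair G33–C49):

```sh
rnaentangle fixtures make knotlike_pseudoknot --out fx
rnaentangle run fx/knotlike_pseudoknot_m8_p1_s0.pdb --out out
```

prints

```
fx/knotlike_pseudoknot_m8_p1_s0.pdb (model 1): 1 entanglement (level 1: 1)
                            Lassos  Interlaces  All  L(S)
Primary entanglements            0           0    0     0
Higher-order entanglements       1           0    1     1
Total number                     1           0    1     1
```

i.e. no entanglement among core elements, and exactly one higher-order
lasso of class L(S) at pseudoknot order 1. The entanglement table
(`out/..._entanglements.csv`) pins it down:

```
id,level,class,topology,punctured,puncturing,n_punctures,puncture_sites
1,1,L(S),lasso,L-level1-33:49,S-level1-1:31,1,"A.G2:C4'|A.C3:P@(1.30,0.40,0.00)"
```

the loop closed by pair G33–C49 is punctured once by the 5′-end single
strand (residues 1–31), on the chain segment between C4′ of residue 2 and
P of residue 3. The extended dot-bracket (`out/..._dbn`) shows the core
helix as `(...)` and the pseudoknot layer as `[...]`. Re-running with
`--pseudoknots ignore` reports zero entanglements — the knot-like fold is
visible only when pseudoknotted pairs are allowed to close elements.

Other outputs per input model: the cleaned structure, an element table, a
per-run summary, and a puncture "bead" file (`HETATM` pseudoatoms at every
puncture site, loadable next to the structure in any molecular viewer).

All of this is available as a library, e.g.:

```python
from rnaentangle import analyze_file
result = analyze_file("model.cif")[0]
for e in result.entanglements:
    print(e.level, e.class_code, e.punctured.element_id, e.puncturing.element_id)
```

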