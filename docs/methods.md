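# Methods

This note records the model, the tunable parameters, the numerical choices,
and what the synthetic fixtures do and do not demonstrate.

## Definitions

An *entanglement* is a pair of structural elements in which the polygonal
chain of one crosses the surface spanned on the boundary of the other
(closed) one. Closed elements are loops (L) and dinucleotide steps (D);
open elements are single strands (S). *Lasso* `X(Y)`: only one direction
has punctures. *Interlace* `X&Y`: both closed elements puncture each other.
Extra punctures beyond the first are appended as dots after the puncturing
element's symbol (`L(S..)` = three crossings). For interlaces the same dot
rule is applied per side (`L.&L` = first loop punctured twice) — the
reference classification never shows a multi-puncture interlace, so this
dot placement is this package's own, chosen to keep codes regenerable from
(kinds, topology, counts).

A base pair's *pseudoknot order* is its layer in a minimal decomposition of
the pairing into mutually non-crossing sets. The analysis is repeated
independently per level: at level *k*, only order-*k* pairs close elements
and every other residue is treated as unpaired (so core residues can end
up embedded inside higher-order loops and strands, and vice versa).
*Primary* entanglements live at level 0, *higher-order* ones at levels ≥ 1.
Cross-level element pairs are deliberately not tested.

## Input preparation

- A chain counts as RNA when more than half of its residues are standard
  ribonucleotides or modified residues mappable to A/C/G/U (a built-in
  table covers the common modifications; unmapped residues with a ribose
  O2′ and a base ring are kept as generic nucleotides). DNA (no O2′),
  protein, ligands and water are removed.
- Alternate locations collapse to the highest-occupancy conformer (ties:
  alphabetically first label); dropped alt-locs are recorded in the
  cleaning report, since entanglements can be artifacts of alternative
  conformations. Hydrogens are dropped on read (no downstream use).
- Modified residues lose atoms that have no counterpart in the parent
  ribonucleotide ("surplus atoms"). A nucleotide is *incomplete* — and is
  removed — when it lacks C4′ or has no base heavy atom at all; this is
  the minimal set needed for chain construction and pair detection. P is
  optional only at a chain's 5′ terminus.
- Inputs above a configurable size cap (default 50 MB) are rejected before
  parsing.

## Pair detection and order assignment

Geometric gates (config block `PairingConfig`; defaults chosen to accept
ideal Watson–Crick geometry with generous margins): C1′–C1′ distance in
[8.5, 12.0] Å; mean donor/acceptor distance over the pair type's H-bond
atom list ≤ 3.5 Å with a ±1.0 Å tolerance; angle between base-plane
normals ≤ 65°. When one residue passes the gates with two partners, the
pair with the smaller H-bond distance wins (greedy, ties by residue index)
so each residue has at most one canonical partner and the result is
deterministic. No attempt is made to reproduce any particular annotation
tool's non-canonical or edge-case decisions; agreement with such tools on
ideal geometry is what the fixtures verify.

Order assignment extracts a maximum-cardinality non-crossing subset
(exact interval recursion over endpoint positions — each position belongs
to at most one pair, so the recursion is polynomial) as order 0, then
repeats on the remainder for order 1, 2, … Ties prefer the pair with the
smaller 5′ index. Exactness of the core layer is tested against exhaustive
subset enumeration for up to 12 pairs. Several minimal-layering variants
exist in the literature; where layerings are non-unique, element
decompositions at levels ≥ 1 can legitimately differ between tools.

Isolated pairs (no stacked neighbour) are flagged; the
`ignore_isolated_pairs` option removes them before order assignment and
element construction.

## Elements

Per level: every stacked adjacency (i,j)/(i+1,j−1) yields one D step (a
helix of n pairs gives n−1 overlapping steps); a pair whose only immediate
inner pair is its stacked neighbour closes no loop (helix interior); every
other pair closes a loop whose boundary alternates backbone runs and
closing pairs (hairpin, bulge/internal, multibranch — all report simply as
L). D steps across a bulge are not formed: strict (i+1, j−1) adjacency is
required. Single strands are maximal unpaired runs not enclosed by any
level-local pair, split at chain breaks; length-1 strands are kept (their
two-point P/C4′ chain is still testable). Loops with more than
`max_loop_length` boundary residues (default 40, bounding triangulation
cost) are discarded from the closed set; their unpaired runs join the open
set. Because a loop and a D step cut from the same helix end share a
closing pair, a puncture near that shared pair can be reported against
both; reports that share a closing pair and the same partner element are
merged, keeping the one with more punctures.

## Geometry

Chains connect P and C4′ of each residue (configurable), 5′→3′; at every
closing pair the two base center-of-mass pseudoatoms (unweighted centroid
of the base ring heavy atoms; a mass-weighted variant is available) bridge
the pair so closed boundaries form one ring. Triangulation: a centroid fan
refined by recursive longest-edge midpoint subdivision until every edge is
below the target (default 2.0 Å), capped at 8 levels; midpoints are shared
through a cache so the mesh boundary equals the refined chain; non-planar
rings are meshed as-is from the fan, and chains whose points are collinear
(no spannable surface) are skipped with a warning. The refinement target is
a resolution/cost dial only — fixture verdicts are verified identical at
2.0, 1.0 and 0.5 Å.

Punctures use Möller–Trumbore with |det| ≥ 1e-9 (parallel cutoff),
barycentric slack 1e-7, and segment parameter t ∈ [0, 1]. Segments with an
endpoint in a residue of the meshed element are excluded (a shared backbone
cannot entangle with itself); hits within 0.05 Å of each other collapse to
a single crossing (adjacent-triangle duplicates); crossings whose segment
endpoint lies within 0.2 Å of a mesh vertex are discarded as
overlapping-atom artifacts, the known false-positive mode of this kind of
screen. Both directions of every closed-closed pair are tested explicitly.

## Synthetic fixtures

Fixtures use chemically implausible but geometrically exact coordinates —
ideal circles, straight polylines, ideal pair geometry — because the
detector is purely geometric and exactness makes ground truth provable:
an independent winding-number check (plane crossings of the strand inside
the ring polygon, no meshes involved) confirms each construction. Families:
clean and contaminated hairpins, lassoed hairpins with 1–3 crossings,
linked hairpin loops (Hopf-link geometry), and a 60-nt emulation of the
xrRNA knot-like fold whose numbering matches the published description of
PDB entry-style folds: order-1 ring closed by G33–C49, 5′ strand 1–31,
puncture between C4′(2) and P(3). That fixture is synthetic — it
reproduces the fold's topology and reported landmarks, not the
crystallographic coordinates.

What passing fixture tests shows: the pipeline recovers known topology
(class, level, puncture count) exactly, invariant under rigid motion and
mesh resolution. What it does not show: behaviour on thermal-quality
experimental coordinates (distorted pairs near gate boundaries, genuinely
ambiguous pseudoknot layerings, alternative conformations), where pair
detection — not the geometry engine — is the sensitive stage. The noise
tests (0.1 Å jitter keeps every verdict over 20 seeds; 5 Å jitter must
merely not crash) bound but do not close that gap.

## Problem sizes and defaults

The acceptance script analyzes the fixture grid at loop sizes 6–20 with 10
random rigid motions per cell, 10⁴ random segment–triangle pairs, and 200
random pair sets for the layering oracle; the test suite uses 20 motions.
These sizes were chosen to make every statistic either exhaustive or
clearly saturated while the whole suite stays in the minutes range on one
CPU. Server-style defaults: first model only, pseudoknots accepted,
isolated pairs kept, all pseudoknot orders analyzed unless capped.

## Known limitations

- Loop boundaries spanning chain breaks are traced as if connected; for
  multi-chain structures with inter-chain pairs the polygon simply bridges
  the gap geometrically.
- No Leontis–Westhof classification: only canonical A-U, G-C, G-U pairs
  close elements, as in the reference classification.
- Pseudoknot layering is exact but not unique; order labels (hence level
  assignments of higher-order entanglements) can differ from tools using a
  different minimal layering.
- No automatic model verdicts: interlaces and D(S)/L(S) lassos connecting
  helices are *suggestive* of bad geometry, but the package only reports
  and counts them.
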