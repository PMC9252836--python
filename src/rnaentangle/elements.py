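"""Partition of an RNA structure into open and closed structural elements.

The decomposition is performed independently at each pseudoknot order
("level"): at level k only pairs of order k count as paired, every other
residue is treated as unpaired and may end up embedded inside the level's
loops and single strands.  Closed elements are loops (L) and dinucleotide
steps (D); open elements are single strands (S) — maximal unpaired runs not
enclosed by any level-k pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .secondary import BasePair, SecondaryStructure
from .structure_io import StructureModel, global_residue_order


class ElementError(Exception):
    pass


@dataclass
class AnalysisOptions:
    """Construction options; defaults mirror the reference web tool."""

    ignore_isolated_pairs: bool = False
    pseudoknots: str = "accept"  # accept | ignore
    max_loop_length: int = 40
    order_cap: int | None = None
    chain_atoms: tuple[str, ...] = ("P", "C4'")
    mesh_edge_target: float = 2.0
    models: str = "first"  # first | all


@dataclass
class StructuralElement:
    kind: str  # "L" | "D" | "S"
    level: int
    residues: list[int]  # global residue indices tracing the boundary 5'->3'
    closing_pairs: list[BasePair] = field(default_factory=list)
    element_id: str = ""

    @property
    def is_closed(self) -> bool:
        return self.kind in ("L", "D")

    @property
    def residue_set(self) -> frozenset[int]:
        return frozenset(self.residues)


@dataclass
class ElementSet:
    level: int
    closed: list[StructuralElement]
    open: list[StructuralElement]
    options: AnalysisOptions

    @property
    def all_elements(self) -> list[StructuralElement]:
        return self.closed + self.open


def _author_range(model: StructureModel, indices: list[int]) -> str:
    order = global_residue_order(model)
    lo, hi = order[min(indices)], order[max(indices)]
    return f"{lo.res_num}:{hi.res_num}"


def _element_id(kind: str, level: int, model: StructureModel, indices: list[int]) -> str:
    return f"{kind}-level{level}-{_author_range(model, indices)}"


def _chain_break_set(ss: SecondaryStructure) -> set[int]:
    """Global indices where a new chain starts (excluding index 0)."""
    breaks = set()
    offset = 0
    for length in ss.chain_lengths[:-1]:
        offset += length
        breaks.add(offset)
    return breaks


def build_elements(
    model: StructureModel,
    ss: SecondaryStructure,
    level: int,
    options: AnalysisOptions | None = None,
) -> ElementSet:
    """Decompose the structure at one pseudoknot level.

    Loops are the cycles closed by level-k pairs (a pair whose only inner
    neighbour is the directly stacked pair closes no loop — it is helix
    interior).  Every stacked adjacency (i,j)/(i+1,j-1) yields one D step.
    Loops longer than ``max_loop_length`` boundary residues are discarded;
    their unpaired runs join the open set.
    """
    opts = options or AnalysisOptions()
    if level > max(ss.max_order, 0):
        raise ElementError(f"level {level} exceeds max pseudoknot order {ss.max_order}")
    pairs = sorted(ss.pairs_of_order(level), key=lambda p: (p.i, p.j))
    if opts.ignore_isolated_pairs:
        pairs = [p for p in pairs if not p.isolated]
    pair_at = {p.i: p for p in pairs}
    pair_set = {p.as_tuple for p in pairs}
    paired_pos = {p.i for p in pairs} | {p.j for p in pairs}
    breaks = _chain_break_set(ss)
    n = ss.n

    closed: list[StructuralElement] = []
    open_: list[StructuralElement] = []

    # --- dinucleotide steps
    for p in pairs:
        if (p.i + 1, p.j - 1) in pair_set:
            q = pair_at[p.i + 1]
            indices = [p.i, p.i + 1, p.j - 1, p.j]
            closed.append(StructuralElement(
                kind="D", level=level, residues=indices,
                closing_pairs=[p, q],
                element_id=_element_id("D", level, model, indices),
            ))

    # --- loops
    def children_of(p: BasePair) -> list[BasePair]:
        kids = []
        pos = p.i + 1
        while pos < p.j:
            q = pair_at.get(pos)
            if q is not None and q.j < p.j:
                kids.append(q)
                pos = q.j + 1
            else:
                pos += 1
        return kids

    discarded_loops: list[list[int]] = []
    for p in pairs:
        kids = children_of(p)
        if len(kids) == 1 and kids[0].as_tuple == (p.i + 1, p.j - 1):
            continue  # helix interior, covered by a D step
        boundary: list[int] = []
        pos = p.i
        for q in kids:
            boundary.extend(range(pos, q.i + 1))
            pos = q.j
        boundary.extend(range(pos, p.j + 1))
        if len(boundary) > opts.max_loop_length:
            discarded_loops.append(boundary)
            continue
        closed.append(StructuralElement(
            kind="L", level=level, residues=boundary,
            closing_pairs=[p] + kids,
            element_id=_element_id("L", level, model, boundary),
        ))

    # --- single strands: maximal unpaired runs not enclosed by any pair
    enclosed = [False] * n
    for p in pairs:
        for t in range(p.i, p.j + 1):
            enclosed[t] = True
    run: list[int] = []

    def flush(run_indices: list[int]) -> None:
        if run_indices:
            open_.append(StructuralElement(
                kind="S", level=level, residues=list(run_indices),
                element_id=_element_id("S", level, model, run_indices),
            ))

    for t in range(n):
        free = not enclosed[t]
        if free and run and (t in breaks):
            flush(run)
            run = []
        if free:
            run.append(t)
        else:
            flush(run)
            run = []
    flush(run)

    # interior unpaired runs of discarded oversized loops become strands
    for boundary in discarded_loops:
        sub: list[int] = []
        prev = None
        for t in boundary:
            if t in paired_pos or (prev is not None and (t != prev + 1 or t in breaks)):
                flush(sub)
                sub = []
            if t not in paired_pos:
                sub.append(t)
            prev = t
        flush(sub)

    return ElementSet(level=level, closed=closed, open=open_, options=opts)


def enumerate_levels(ss: SecondaryStructure, options: AnalysisOptions | None = None) -> list[int]:
    """Levels to analyze: [0] when pseudoknots are ignored, else every
    assigned order up to the optional cap."""
    opts = options or AnalysisOptions()
    if opts.pseudoknots == "ignore":
        return [0]
    top = max(ss.max_order, 0)
    if opts.order_cap is not None:
        top = min(top, opts.order_cap)
    return list(range(top + 1))
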