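"""Secondary structure from 3D coordinates and extended dot-bracket notation.

Canonical pairs (A-U, G-C, G-U) are detected with geometric gates: C1'-C1'
distance, donor/acceptor distances on the Watson-Crick edge, and the angle
between base-plane normals.  Pseudoknot orders are assigned by iteratively
extracting a maximum-cardinality non-crossing subset of the remaining pairs:
order 0 is the core (largest non-crossing layer), order k >= 1 the successive
layers of crossing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from . import _chemistry as chem
from .structure_io import NucleotideResidue, StructureModel, global_residue_order


class SecondaryStructureError(Exception):
    pass


@dataclass
class PairingConfig:
    """Geometric gates of the canonical-pair detector (Angstrom, degrees)."""

    c1_min: float = 8.5
    c1_max: float = 12.0
    hbond_max: float = 3.5
    hbond_tolerance: float = 1.0
    max_plane_angle_deg: float = 65.0


@dataclass
class BasePair:
    i: int  # global residue index of the 5' partner (smaller)
    j: int  # global residue index of the 3' partner
    pair_class: str = ""
    order: int = -1  # -1 = unset
    isolated: bool = False

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError(f"pair ({self.i},{self.j}): need i < j")

    @property
    def as_tuple(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class SecondaryStructure:
    sequence: str  # concatenated one-letter chain sequences
    chain_lengths: list[int]
    chain_ids: list[str]
    pairs: list[BasePair] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def max_order(self) -> int:
        return max((p.order for p in self.pairs), default=-1)

    def pairs_of_order(self, k: int) -> list[BasePair]:
        return [p for p in self.pairs if p.order == k]


# ---------------------------------------------------------------------------
# geometric pair detection


def _base_frame(res: NucleotideResidue):
    """Return (ring centroid, unit plane normal) or None if degenerate."""
    names = chem.RING_ATOMS.get(res.parent or "", None)
    if names is None:
        names = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
    pts = np.array([res.coord(n) for n in names if res.has(n)])
    if len(pts) < 3:
        return None
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # plane normal = smallest singular vector
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    if np.linalg.norm(normal) < 1e-9:
        return None
    return centroid, normal / np.linalg.norm(normal)


def _hbond_distance(a: NucleotideResidue, b: NucleotideResidue, pair_class: str):
    """Mean available donor/acceptor distance, with `a` the purine partner.

    Falls back to the WC-edge atoms when exocyclic atoms are missing
    (synthetic fixtures may carry ring atoms only).  Returns None if even
    the edge atoms are absent.
    """
    dists = []
    for name_a, name_b in chem.HBOND_ATOMS[pair_class]:
        if a.has(name_a) and b.has(name_b):
            dists.append(float(np.linalg.norm(a.coord(name_a) - b.coord(name_b))))
    if not dists:
        ea = chem.WC_EDGE_ATOM.get(a.parent or "", "N1")
        eb = chem.WC_EDGE_ATOM.get(b.parent or "", "N3")
        if a.has(ea) and b.has(eb):
            dists.append(float(np.linalg.norm(a.coord(ea) - b.coord(eb))))
    if not dists:
        return None
    return float(np.mean(dists))


def detect_canonical_pairs(
    model: StructureModel, config: PairingConfig | None = None
) -> list[BasePair]:
    """Detect canonical base pairs from coordinates (orders unset).

    Candidates passing all gates are ranked by H-bond distance and accepted
    greedily so that each residue has at most one partner; ties are broken
    by residue indices, making the result deterministic.
    """
    cfg = config or PairingConfig()
    residues = global_residue_order(model)
    n = len(residues)
    frames = [_base_frame(r) for r in residues]
    c1 = np.full((n, 3), np.nan)
    for idx, r in enumerate(residues):
        if r.has("C1'"):
            c1[idx] = r.coord("C1'")
    candidates: list[tuple[float, int, int, str]] = []
    hbond_gate = cfg.hbond_max + cfg.hbond_tolerance
    cos_gate = np.cos(np.deg2rad(cfg.max_plane_angle_deg))
    for a_idx in range(n):
        ra = residues[a_idx]
        if ra.parent is None or frames[a_idx] is None or np.isnan(c1[a_idx, 0]):
            continue
        for b_idx in range(a_idx + 1, n):
            rb = residues[b_idx]
            if rb.parent is None or frames[b_idx] is None or np.isnan(c1[b_idx, 0]):
                continue
            pair_class = chem.CANONICAL_PAIRS.get(frozenset((ra.parent, rb.parent)))
            if pair_class is None:
                continue
            d_c1 = float(np.linalg.norm(c1[a_idx] - c1[b_idx]))
            if not (cfg.c1_min <= d_c1 <= cfg.c1_max):
                continue
            # purine partner first for the H-bond atom table
            if ra.parent in chem.PURINES:
                pur, pyr = ra, rb
            else:
                pur, pyr = rb, ra
            # G-U: both can be purine/pyrimidine mix; G is the "purine" slot
            if pair_class == "wobble-GU":
                pur, pyr = (ra, rb) if ra.parent == "G" else (rb, ra)
            d_hb = _hbond_distance(pur, pyr, pair_class)
            if d_hb is None or d_hb > hbond_gate:
                continue
            cos_ang = abs(float(np.dot(frames[a_idx][1], frames[b_idx][1])))
            if cos_ang < cos_gate:
                continue
            candidates.append((d_hb, a_idx, b_idx, pair_class))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    pairs: list[BasePair] = []
    for d_hb, a_idx, b_idx, pair_class in candidates:
        if a_idx in used or b_idx in used:
            continue
        used.add(a_idx)
        used.add(b_idx)
        pairs.append(BasePair(i=a_idx, j=b_idx, pair_class=pair_class))
    pairs.sort(key=lambda p: (p.i, p.j))
    _flag_isolated(pairs)
    return pairs


def _flag_isolated(pairs: list[BasePair]) -> None:
    pair_set = {p.as_tuple for p in pairs}
    for p in pairs:
        p.isolated = (p.i + 1, p.j - 1) not in pair_set and (p.i - 1, p.j + 1) not in pair_set


# ---------------------------------------------------------------------------
# pseudoknot order assignment


def _crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i1, j1), (i2, j2) = p, q
    return (i1 < i2 < j1 < j2) or (i2 < i1 < j2 < j1)


def _max_noncrossing(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximum-cardinality mutually non-crossing subset.

    Each position belongs to at most one pair, so a memoized interval
    recursion over sorted endpoint positions is exact.  Ties prefer keeping
    the pair with the smaller i (then smaller j), scanned left to right.
    """
    if not pairs:
        return []
    partner: dict[int, int] = {}
    for i, j in pairs:
        if i in partner or j in partner:
            raise SecondaryStructureError(f"position reused by pair ({i},{j})")
        partner[i] = j
        partner[j] = i
    positions = sorted(partner)
    pos_rank = {p: r for r, p in enumerate(positions)}
    m = len(positions)

    @lru_cache(maxsize=None)
    def best(lo: int, hi: int) -> int:
        if lo >= hi:
            return 0
        p = positions[lo]
        q = partner[p]
        skip = best(lo + 1, hi)
        take = -1
        if p < q and pos_rank[q] < hi:
            qr = pos_rank[q]
            take = 1 + best(lo + 1, qr) + best(qr + 1, hi)
        return max(skip, take)

    chosen: list[tuple[int, int]] = []

    def rebuild(lo: int, hi: int) -> None:
        while lo < hi:
            p = positions[lo]
            q = partner[p]
            take = -1
            qr = -1
            if p < q and pos_rank[q] < hi:
                qr = pos_rank[q]
                take = 1 + best(lo + 1, qr) + best(qr + 1, hi)
            if take >= best(lo + 1, hi) and take >= 0:
                chosen.append((p, q))
                rebuild(lo + 1, qr)
                lo = qr + 1
            else:
                lo += 1

    rebuild(0, m)
    best.cache_clear()
    return sorted(chosen)


def assign_pseudoknot_orders(pairs: list[BasePair]) -> list[BasePair]:
    """Assign a pseudoknot order to every pair (0 = core).

    Layers are extracted iteratively; within each layer pairs are mutually
    non-crossing, and each layer is a maximum non-crossing subset of what
    remains after removing lower layers.
    """
    preset = [p for p in pairs if p.order >= 0]
    for k in sorted({p.order for p in preset}):
        layer = [p.as_tuple for p in preset if p.order == k]
        for a in range(len(layer)):
            for b in range(a + 1, len(layer)):
                if _crossing(layer[a], layer[b]):
                    raise SecondaryStructureError(
                        f"pairs {layer[a]} and {layer[b]} cross within claimed order {k}"
                    )
    remaining = {p.as_tuple: p for p in pairs}
    out: list[BasePair] = []
    order = 0
    while remaining:
        layer = _max_noncrossing(list(remaining))
        if not layer:
            break
        for t in layer:
            out.append(replace(remaining.pop(t), order=order))
        order += 1
    out.sort(key=lambda p: (p.i, p.j))
    return out


# ---------------------------------------------------------------------------
# extended dot-bracket notation

_BRACKETS = ["()", "[]", "{}", "<>"] + [chr(ord("A") + k) + chr(ord("a") + k) for k in range(26)]


def brackets_for_order(order: int) -> tuple[str, str]:
    if order < 0 or order >= len(_BRACKETS):
        raise SecondaryStructureError(f"no bracket alphabet for order {order}")
    b = _BRACKETS[order]
    return b[0], b[1]


def secondary_structure_from_model(
    model: StructureModel, pairs: list[BasePair]
) -> SecondaryStructure:
    seq = []
    lengths = []
    ids = []
    for chain_id, residues in model.chains:
        ids.append(chain_id)
        lengths.append(len(residues))
        for r in residues:
            seq.append(r.parent if r.parent else "N")
    return SecondaryStructure(
        sequence="".join(seq), chain_lengths=lengths, chain_ids=ids, pairs=pairs
    )


def to_extended_dotbracket(ss: SecondaryStructure, with_headers: bool = True) -> str:
    """Render one character per residue; one block per chain.

    Each block is '>chain', the sequence line, and the structure line.
    """
    chars = ["."] * ss.n
    for p in ss.pairs:
        if p.order < 0:
            raise SecondaryStructureError(f"pair ({p.i},{p.j}) has no order assigned")
        op, cl = brackets_for_order(p.order)
        chars[p.i] = op
        chars[p.j] = cl
    if not with_headers:
        return "".join(chars)
    lines = []
    offset = 0
    for chain_id, length in zip(ss.chain_ids, ss.chain_lengths):
        lines.append(f">{chain_id}")
        lines.append(ss.sequence[offset:offset + length])
        lines.append("".join(chars[offset:offset + length]))
        offset += length
    return "\n".join(lines) + "\n"


def parse_extended_dotbracket(text: str) -> SecondaryStructure:
    """Parse extended dot-bracket (with or without '>chain' headers)."""
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    chain_ids: list[str] = []
    seqs: list[str] = []
    structs: list[str] = []
    if any(ln.startswith(">") for ln in lines):
        idx = 0
        while idx < len(lines):
            if not lines[idx].startswith(">"):
                raise SecondaryStructureError(f"expected '>chain' header, got {lines[idx]!r}")
            chain_ids.append(lines[idx][1:].strip() or "A")
            if idx + 2 >= len(lines):
                raise SecondaryStructureError("truncated dot-bracket block")
            seqs.append(lines[idx + 1])
            structs.append(lines[idx + 2])
            idx += 3
    else:
        if len(lines) == 1:
            structs = [lines[0]]
            seqs = ["N" * len(lines[0])]
        else:
            seqs, structs = [lines[0]], [lines[1]]
        chain_ids = ["A"]
    for s, db in zip(seqs, structs):
        if len(s) != len(db):
            raise SecondaryStructureError("sequence/structure length mismatch")
    structure = "".join(structs)
    stacks: dict[int, list[int]] = {}
    open_of = {b[0]: k for k, b in enumerate(_BRACKETS)}
    close_of = {b[1]: k for k, b in enumerate(_BRACKETS)}
    pairs: list[BasePair] = []
    for pos, ch in enumerate(structure):
        if ch == ".":
            continue
        if ch in open_of:
            stacks.setdefault(open_of[ch], []).append(pos)
        elif ch in close_of:
            k = close_of[ch]
            if not stacks.get(k):
                raise SecondaryStructureError(f"unbalanced bracket {ch!r} at position {pos}")
            i = stacks[k].pop()
            pairs.append(BasePair(i=i, j=pos, order=k))
        else:
            raise SecondaryStructureError(f"unknown character {ch!r} at position {pos}")
    for k, st in stacks.items():
        if st:
            raise SecondaryStructureError(
                f"unbalanced bracket {_BRACKETS[k][0]!r} opened at position {st[-1]}"
            )
    for k in {p.order for p in pairs}:
        layer = [p.as_tuple for p in pairs if p.order == k]
        for a in range(len(layer)):
            for b in range(a + 1, len(layer)):
                if _crossing(layer[a], layer[b]):
                    raise SecondaryStructureError(
                        f"pairs {layer[a]} and {layer[b]} cross within one alphabet"
                    )
    pairs.sort(key=lambda p: (p.i, p.j))
    _flag_isolated(pairs)
    return SecondaryStructure(
        sequence="".join(seqs),
        chain_lengths=[len(s) for s in seqs],
        chain_ids=chain_ids,
        pairs=pairs,
    )
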