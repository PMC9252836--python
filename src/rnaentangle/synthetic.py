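"""Synthetic RNA 3D fixtures with known ground-truth entanglements.

Coordinates are chemically implausible but geometrically exact: loops are
ideal circles, strands are straight polylines, and intended base pairs are
placed at ideal pairing geometry so the detector must recover them exactly.
That exactness makes the ground truth provable — the winding of a strand
about a loop's plane can be checked by independent arithmetic.

Families
--------
clean_hairpin          hairpin, nothing entangled
lassoed_hairpin        a 5' strand threads the hairpin loop n times -> L(S...)
multi_weave            alias geometry with a default of three crossings
interlaced_hairpins    two hairpin loops linked like chain rings -> L&L
knotlike_pseudoknot    synthetic emulation of the xrRNA knot-like fold:
                       an order-1 loop closed by pair G33-C49 threaded by
                       the 5' single strand (residues 1-31), puncture on the
                       segment C4'(2) -> P(3); detected only when
                       pseudoknots are accepted
non_rna_contaminated   clean hairpin plus a peptide chain and waters
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _chemistry as chem
from .structure_io import (
    AtomRecord,
    NucleotideResidue,
    StructureModel,
    write_cleaned_structure,
)

FAMILIES = (
    "clean_hairpin",
    "lassoed_hairpin",
    "multi_weave",
    "interlaced_hairpins",
    "knotlike_pseudoknot",
    "non_rna_contaminated",
)

C1_OFFSET = 1.2          # backbone circle -> C1' circle, A
GLYC_BOND = 1.48         # C1' -> glycosidic N, A
EDGE_BOND = 2.27         # glycosidic N -> WC-edge atom, A
PAIR_C1C1 = 10.4         # ideal C1'-C1' distance across a pair, A
RISE = 3.4               # stacking rise, A

# Planar base templates in a local frame: x toward the WC edge, origin at
# the glycosidic nitrogen.  Shapes are schematic; only planarity, the edge
# atom at (EDGE_BOND, 0) and non-collinearity matter.
_PURINE_LOCAL = {
    "N9": (0.0, 0.0), "C8": (0.15, -1.30), "N7": (1.25, -1.45),
    "C5": (1.65, -0.55), "C4": (0.80, 0.85), "N3": (1.55, 1.55),
    "C2": (2.40, 0.95), "N1": (EDGE_BOND, 0.0), "C6": (2.10, -0.85),
}
_PYRIMIDINE_LOCAL = {
    "N1": (0.0, 0.0), "C2": (0.85, 1.05), "N3": (EDGE_BOND, 0.0),
    "C4": (1.80, -1.05), "C5": (0.85, -1.75), "C6": (-0.15, -1.20),
}


class FixtureError(Exception):
    pass


@dataclass
class FixtureSpec:
    family: str
    loop_size: int = 8
    punctures: int = 1
    seed: int = 0
    transform: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise FixtureError(f"unknown fixture family {self.family!r}")
        entangled = self.family in (
            "lassoed_hairpin", "multi_weave", "interlaced_hairpins",
            "knotlike_pseudoknot",
        )
        if entangled and self.punctures < 1:
            raise FixtureError(f"{self.family}: punctures must be >= 1")
        if self.loop_size < 4:
            raise FixtureError("loop_size below 4 cannot be threaded")


@dataclass
class FixtureTruth:
    family: str
    pairs: list[tuple[int, int, int]]  # (res_num_i, res_num_j, order)
    entanglements: list[dict]
    ring_residues: list[int] = field(default_factory=list)  # boundary, author numbers
    strand_residues: list[int] = field(default_factory=list)
    notes: str = ""


# ---------------------------------------------------------------------------
# low-level residue construction


class _Builder:
    def __init__(self):
        self.residues: list[tuple[str, int, str, dict[str, np.ndarray]]] = []

    def add(self, chain: str, num: int, name: str, atoms: dict[str, np.ndarray]):
        self.residues.append((chain, num, name, atoms))

    def model(self, source: str) -> StructureModel:
        chains: dict[str, list[NucleotideResidue]] = {}
        order: list[str] = []
        for chain, num, name, atoms in self.residues:
            if chain not in chains:
                chains[chain] = []
                order.append(chain)
            recs = {
                a: AtomRecord(name=a, element=_element_of(a), coords=xyz)
                for a, xyz in atoms.items()
            }
            chains[chain].append(NucleotideResidue(
                chain_id=chain, res_num=num, ins_code="", res_name=name,
                seq_index=len(chains[chain]), atoms=recs,
                is_modified=name not in chem.STANDARD_RIBONUCLEOTIDES,
                parent=chem.parent_of(name),
            ))
        return StructureModel(
            model_id=1,
            chains=[(cid, chains[cid]) for cid in order],
            source=source,
        )


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise FixtureError("zero-length direction")
    return v / n


def _base_atoms(c1: np.ndarray, towards: np.ndarray, normal: np.ndarray,
                restype: str) -> dict[str, np.ndarray]:
    """Planar base with the WC edge pointing along ``towards``."""
    t = _unit(np.asarray(towards, float))
    w = _unit(np.asarray(normal, float))
    o = np.cross(w, t)
    glyc = c1 + GLYC_BOND * t
    template = _PURINE_LOCAL if restype in chem.PURINES else _PYRIMIDINE_LOCAL
    atoms = {n: glyc + x * t + y * o for n, (x, y) in template.items()}
    atoms["C1'"] = c1
    atoms["O2'"] = c1 - 0.7 * t + 0.9 * w
    return atoms


def _paired_bases(c1_a, c1_b, normal, type_a, type_b):
    """Two bases facing each other at ideal pairing geometry."""
    d = _unit(np.asarray(c1_b, float) - np.asarray(c1_a, float))
    return (
        _base_atoms(np.asarray(c1_a, float), d, normal, type_a),
        _base_atoms(np.asarray(c1_b, float), -d, normal, type_b),
    )


def _resample(waypoints: list, n_points: int) -> list[np.ndarray]:
    """n_points evenly spaced by arclength along a waypoint polyline."""
    wp = [np.asarray(p, float) for p in waypoints]
    seg = [np.linalg.norm(wp[t + 1] - wp[t]) for t in range(len(wp) - 1)]
    total = sum(seg)
    out = []
    for k in range(n_points):
        s = total * k / max(n_points - 1, 1)
        acc = 0.0
        for t, L in enumerate(seg):
            if acc + L >= s or t == len(seg) - 1:
                f = 0.0 if L == 0 else (s - acc) / L
                out.append(wp[t] + min(max(f, 0.0), 1.0) * (wp[t + 1] - wp[t]))
                break
            acc += L
    return out


def _strand_residues(builder: _Builder, chain: str, start_num: int,
                     points: list[np.ndarray], names: list[str],
                     lateral: np.ndarray | None = None):
    """Consecutive residues from a point list: points 2t/2t+1 become P/C4'."""
    if len(points) != 2 * len(names):
        raise FixtureError("need exactly 2 points (P, C4') per strand residue")
    for t, name in enumerate(names):
        p, c4 = points[2 * t], points[2 * t + 1]
        d = _unit(c4 - p)
        lat = lateral if lateral is not None else _perp(d)
        c1 = c4 + 1.3 * lat
        atoms = {"P": p, "C4'": c4}
        atoms.update(_base_atoms(c1, lat, _unit(np.cross(d, lat)), name))
        builder.add(chain, start_num + t, name, atoms)


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, ref))


# ---------------------------------------------------------------------------
# hairpin scaffold


@dataclass
class _Frame:
    """Local frame: ring in the u-v plane, stem descending along -w."""
    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def to_world(self, local: np.ndarray) -> np.ndarray:
        return self.origin + local[0] * self.u + local[1] * self.v + local[2] * self.w


_WORLD = _Frame(
    origin=np.zeros(3), u=np.array([1.0, 0.0, 0.0]),
    v=np.array([0.0, 1.0, 0.0]), w=np.array([0.0, 0.0, 1.0]),
)


def _ring_radius(n_slots: int) -> tuple[float, float, float]:
    """Backbone radius, gap angle and slot step for a ring of n_slots
    residues closed across a PAIR_C1C1 chord."""
    r = max(6.0, 0.55 * n_slots + 3.0)
    gamma = delta = 0.0
    for _ in range(80):
        r_c1 = r - C1_OFFSET
        if 2 * r_c1 <= PAIR_C1C1 + 0.4:
            r += 0.5
            continue
        gamma = 2 * math.asin(PAIR_C1C1 / (2 * r_c1))
        delta = (2 * math.pi - gamma) / (n_slots - 1)
        chord = 2 * r * math.sin(delta / 2)
        if abs(chord - 5.2) < 0.01:
            break
        r = 0.5 * r + 0.5 * max(r * 5.2 / chord, PAIR_C1C1 / 2 + C1_OFFSET + 0.4)
    return r, gamma, delta


class _Hairpin:
    """Geometry bookkeeping for one hairpin (ring + stem) in a frame."""

    def __init__(self, m: int, stem: int, frame: _Frame):
        self.m = m
        self.stem = stem
        self.frame = frame
        self.n_slots = m + 2
        self.r_bb, self.gamma, self.delta = _ring_radius(self.n_slots)

    def slot_angle(self, t: int) -> float:
        return self.gamma / 2 + t * self.delta

    def ring_point(self, angle: float, radius: float, z: float = 0.0) -> np.ndarray:
        return self.frame.to_world(np.array([
            radius * math.cos(angle), radius * math.sin(angle), z,
        ]))

    def stem_attach_5p(self) -> np.ndarray:
        """World position near the P of the deepest 5'-side stem residue."""
        a = self.slot_angle(0)
        return self.ring_point(a - 0.30 * self.delta, self.r_bb,
                               -RISE * (self.stem - 1))

    def stem_attach_3p(self) -> np.ndarray:
        a = self.slot_angle(self.n_slots - 1)
        return self.ring_point(a + 0.30 * self.delta, self.r_bb,
                               -RISE * (self.stem - 1))

    def build(self, builder: _Builder, chain: str, first_num: int,
              loop_name: str = "A") -> dict:
        """Emit stem5' + ring + stem3' residues; return bookkeeping."""
        f = self.frame
        normal = f.w
        stem_seq = ["G" if d % 2 == 0 else "C" for d in range(self.stem)]
        comp = {"G": "C", "C": "G"}
        num = first_num
        pairs: list[tuple[int, int]] = []
        # 5' stem: deepest pair first
        five_nums, three_nums = [], []
        for d in range(self.stem - 1, 0, -1):
            a_ang = self.slot_angle(0)
            p = self.ring_point(a_ang - 0.30 * self.delta, self.r_bb, -RISE * d)
            c4 = self.ring_point(a_ang + 0.05 * self.delta, self.r_bb, -RISE * d)
            c1 = self.ring_point(a_ang, self.r_bb - C1_OFFSET, -RISE * d)
            b_ang = self.slot_angle(self.n_slots - 1)
            c1b = self.ring_point(b_ang, self.r_bb - C1_OFFSET, -RISE * d)
            base_a, _ = _paired_bases(c1, c1b, normal, stem_seq[d], comp[stem_seq[d]])
            atoms = {"P": p, "C4'": c4}
            atoms.update(base_a)
            builder.add(chain, num, stem_seq[d], atoms)
            five_nums.append((num, d))
            num += 1
        # ring slots 0..n_slots-1 (slot 0 and last are the closing pair)
        ring_first = num
        a_ang = self.slot_angle(0)
        b_ang = self.slot_angle(self.n_slots - 1)
        c1a0 = self.ring_point(a_ang, self.r_bb - C1_OFFSET, 0.0)
        c1b0 = self.ring_point(b_ang, self.r_bb - C1_OFFSET, 0.0)
        base_a0, base_b0 = _paired_bases(c1a0, c1b0, normal, stem_seq[0], comp[stem_seq[0]])
        for t in range(self.n_slots):
            ang = self.slot_angle(t)
            p = self.ring_point(ang - 0.30 * self.delta, self.r_bb, 0.0)
            c4 = self.ring_point(ang + 0.05 * self.delta, self.r_bb, 0.0)
            atoms = {"P": p, "C4'": c4}
            if t == 0:
                name = stem_seq[0]
                atoms.update(base_a0)
            elif t == self.n_slots - 1:
                name = comp[stem_seq[0]]
                atoms.update(base_b0)
            else:
                name = loop_name
                c1 = self.ring_point(ang, self.r_bb - C1_OFFSET, 0.0)
                outward = _unit(self.ring_point(ang, self.r_bb + 1, 0.0)
                                - self.ring_point(ang, self.r_bb, 0.0))
                atoms.update(_base_atoms(c1, outward, normal, name))
            builder.add(chain, num, name, atoms)
            num += 1
        ring_last = num - 1
        pairs.append((ring_first, ring_last))
        # 3' stem, descending
        for d in range(1, self.stem):
            b_ang = self.slot_angle(self.n_slots - 1)
            p = self.ring_point(b_ang - 0.05 * self.delta, self.r_bb, -RISE * d)
            c4 = self.ring_point(b_ang + 0.30 * self.delta, self.r_bb, -RISE * d)
            c1b = self.ring_point(b_ang, self.r_bb - C1_OFFSET, -RISE * d)
            a_ang = self.slot_angle(0)
            c1a = self.ring_point(a_ang, self.r_bb - C1_OFFSET, -RISE * d)
            _, base_b = _paired_bases(c1a, c1b, normal, stem_seq[d], comp[stem_seq[d]])
            atoms = {"P": p, "C4'": c4}
            atoms.update(base_b)
            builder.add(chain, num, comp[stem_seq[d]], atoms)
            three_nums.append((num, d))
            num += 1
        for a_num, d in five_nums:
            b_num = next(bn for bn, bd in three_nums if bd == d)
            pairs.append((a_num, b_num))
        return {
            "pairs": sorted(pairs),
            "ring": list(range(ring_first, ring_last + 1)),
            "next_num": num,
        }


# ---------------------------------------------------------------------------
# families


def _weave_points(hp: _Hairpin, n_cross: int, n_res: int) -> list[np.ndarray]:
    """Strand path threading the hairpin ring n_cross times, ending near the
    5' stem attachment, in the hairpin's frame."""
    r = hp.r_bb
    xs = [(-1.0 * (n_cross - 1) / 2 + i) * min(3.0, (r - 3.0) / max(n_cross, 1))
          for i in range(n_cross)]
    y0 = 0.45
    top, bottom = 8.0, -4.5
    wp: list = [np.array([xs[0], y0, top + 4.0])]
    z_levels = [top, bottom]
    for i, x in enumerate(xs):
        enter = z_levels[i % 2]
        leave = z_levels[(i + 1) % 2]
        wp.append(np.array([x, y0, enter]))
        wp.append(np.array([x, y0, leave]))
    ends_below = n_cross % 2 == 1
    exit_r = r + 5.0
    if ends_below:
        wp.append(np.array([xs[-1], y0, -8.0]))
        wp.append(np.array([0.0, -exit_r, -9.0]))
    else:
        wp.append(np.array([xs[-1], y0, top + 2.0]))
        wp.append(np.array([0.0, -exit_r, top]))
        wp.append(np.array([0.0, -exit_r, -9.0]))
    attach = hp.stem_attach_5p() - hp.frame.origin
    local_attach = np.array([attach @ hp.frame.u, attach @ hp.frame.v, attach @ hp.frame.w])
    away = _unit(np.array([local_attach[0], local_attach[1], 0.0]))
    # circle around below the stem, staying radially outside it, down to the
    # deepest pair; a straight chord here would cut through the helix
    ang_attach = math.atan2(away[1], away[0])
    ang = -math.pi / 2
    diff = (ang_attach - ang) % (2 * math.pi)
    if diff > math.pi:
        diff -= 2 * math.pi
    n_steps = max(2, int(abs(diff) / math.radians(30)) + 1)
    depth0 = -9.0
    depth1 = local_attach[2] - 1.2
    for s in range(1, n_steps + 1):
        a = ang + diff * s / n_steps
        z = depth0 + (depth1 - depth0) * s / n_steps
        wp.append(np.array([exit_r * math.cos(a), exit_r * math.sin(a), z]))
    wp.append(local_attach + np.array([away[0] * 2.5, away[1] * 2.5, -1.2]))
    pts_local = _resample(wp, 2 * n_res)
    return [hp.frame.to_world(p) for p in pts_local]


def _build_lassoed(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    m = spec.loop_size
    stem = 4
    hp = _Hairpin(m, stem, _WORLD)
    n_strand = max(8, 4 + 2 * spec.punctures)
    builder = _Builder()
    pts = _weave_points(hp, spec.punctures, n_strand)
    _strand_residues(builder, "A", 1, pts, ["A"] * n_strand)
    info = hp.build(builder, "A", n_strand + 1)
    truth = FixtureTruth(
        family=spec.family,
        pairs=[(a, b, 0) for a, b in info["pairs"]],
        entanglements=[{
            "level": 0, "topology": "lasso",
            "class_code": f"L(S{'.' * (spec.punctures - 1)})",
            "n_punctures": spec.punctures,
        }],
        ring_residues=info["ring"],
        strand_residues=list(range(1, n_strand + 1)),
    )
    return builder.model(f"{spec.family}(m={m},p={spec.punctures})"), truth


def _build_clean(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    m = spec.loop_size
    stem = 4
    hp = _Hairpin(m, stem, _WORLD)
    builder = _Builder()
    # short 5' dangle routed below the ring plane, outside the ring
    attach = hp.stem_attach_5p()
    away = _unit(np.array([attach[0], attach[1], 0.0]))
    wp = [
        attach + away * 12.0 + np.array([0, 0, -6.0]),
        attach + away * 3.0 + np.array([0, 0, -1.5]),
    ]
    pts = _resample(wp, 8)
    _strand_residues(builder, "A", 1, pts, ["A"] * 4)
    info = hp.build(builder, "A", 5)
    truth = FixtureTruth(
        family=spec.family,
        pairs=[(a, b, 0) for a, b in info["pairs"]],
        entanglements=[],
        ring_residues=info["ring"],
        strand_residues=[1, 2, 3, 4],
    )
    return builder.model(f"{spec.family}(m={m})"), truth


def _build_contaminated(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    model, truth = _build_clean(spec)
    builder = _Builder()
    for chain, reslist in model.chains:
        for r in reslist:
            builder.add(chain, r.res_num, r.res_name,
                        {a.name: a.coords for a in r.atoms.values()})
    # a 3-residue peptide chain far from the RNA
    for t in range(3):
        base = np.array([60.0 + 4.0 * t, 40.0, 10.0])
        builder.add("P", t + 1, "ALA", {
            "N": base, "CA": base + np.array([1.4, 0.3, 0.0]),
            "C": base + np.array([2.4, -0.6, 0.6]),
            "O": base + np.array([2.6, -1.8, 0.4]),
            "CB": base + np.array([1.6, 1.2, 1.2]),
        })
    for t in range(4):
        builder.add("W", t + 1, "HOH", {"O": np.array([70.0, 50.0 + 3.0 * t, 0.0])})
    truth.family = spec.family
    truth.notes = "peptide chain P and water chain W must be removed by cleaning"
    return builder.model(f"{spec.family}(m={spec.loop_size})"), truth


def _build_interlaced(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    m = spec.loop_size
    stem = 4
    # hairpin A: ring in z=0 plane, gap (and stem) on the -x side
    frame_a = _Frame(
        origin=np.zeros(3), u=np.array([-1.0, 0.0, 0.0]),
        v=np.array([0.0, -1.0, 0.0]), w=np.array([0.0, 0.0, 1.0]),
    )
    hp_a = _Hairpin(m, stem, frame_a)
    r = hp_a.r_bb
    # hairpin B: ring in the plane y = 0.9, linked through A's disk
    frame_b = _Frame(
        origin=np.array([r - 2.8 + r, 0.9, 2.5]) - np.array([r, 0.0, 0.0]),
        u=np.array([1.0, 0.0, 0.0]), v=np.array([0.0, 0.0, 1.0]),
        w=np.array([0.0, 1.0, 0.0]),
    )
    hp_b = _Hairpin(m, stem, frame_b)
    builder = _Builder()
    info_a = hp_a.build(builder, "A", 1)
    # linker from A's 3' stem foot to B's 5' stem foot, avoiding both disks
    start = hp_a.stem_attach_3p() + np.array([0.0, 0.0, -2.0])
    end = hp_b.stem_attach_5p() + np.array([0.0, -2.5, 0.0])
    wp = [
        start,
        np.array([start[0], -r - 4.0, -10.0]),
        np.array([end[0] * 0.5, -r - 6.0, -6.0]),
        np.array([end[0], -r - 4.0, end[2]]),
        end,
    ]
    n_link = 8
    pts = _resample(wp, 2 * n_link)
    _strand_residues(builder, "A", info_a["next_num"], pts, ["A"] * n_link)
    info_b = hp_b.build(builder, "A", info_a["next_num"] + n_link)
    truth = FixtureTruth(
        family=spec.family,
        pairs=[(a, b, 0) for a, b in info_a["pairs"] + info_b["pairs"]],
        entanglements=[{
            "level": 0, "topology": "interlace", "class_code": "L&L",
            "n_punctures": 2,
        }],
        ring_residues=info_a["ring"] + info_b["ring"],
        strand_residues=list(range(info_a["next_num"], info_a["next_num"] + n_link)),
    )
    return builder.model(f"{spec.family}(m={m})"), truth


def _cyl(theta_deg: float, radius: float, z: float) -> np.ndarray:
    a = math.radians(theta_deg)
    return np.array([radius * math.cos(a), radius * math.sin(a), z])


def _build_knotlike(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    """Synthetic emulation of the xrRNA knot-like fold (60 nt, one chain).

    Core helix (order 0): pairs (45,59), (46,58), (47,57).
    Pseudoknot helix (order 1): pairs (32,50), (33,49) — they cross every
    core pair, so the layering puts them at order 1 and the ring they close
    (residues 33..49, pair G33-C49) exists only at level 1.  The 5' single
    strand (residues 1..31) threads that ring exactly once, crossing the
    ring plane between C4' of residue 2 and P of residue 3.
    """
    R = 16.0
    builder = _Builder()
    seq = {t: "A" for t in range(1, 61)}
    seq.update({1: "G", 2: "G", 3: "C", 32: "G", 33: "G", 49: "C", 50: "C",
                45: "G", 46: "C", 47: "G", 57: "C", 58: "G", 59: "C"})

    # ring residues 33..49 on a circle of radius R in the z=0 plane
    r_c1 = R - C1_OFFSET
    gamma = 2 * math.asin(PAIR_C1C1 / (2 * r_c1))
    delta = (2 * math.pi - gamma) / 16
    theta = {t: math.degrees(gamma / 2 + (t - 33) * delta) for t in range(33, 50)}

    def rim_atoms(t: int, z: float) -> dict:
        ang = theta[t]
        return {
            "P": _cyl(ang - 0.30 * math.degrees(delta), R, z),
            "C4'": _cyl(ang + 0.05 * math.degrees(delta), R, z),
        }

    normal = np.array([0.0, 0.0, 1.0])

    # --- 5' strand, residues 1..31: threads the ring once
    thread = [
        np.array([1.0, 0.2, 10.8]),   # P1
        np.array([1.1, 0.3, 8.6]),    # C4'1
        np.array([1.2, 0.35, 6.4]),   # P2
        np.array([1.3, 0.40, 4.2]),   # C4'2
        np.array([1.3, 0.40, -2.6]),  # P3   (plane crossed in C4'2 -> P3)
        np.array([1.4, 0.5, -4.4]),   # C4'3
    ]
    descend_wp = [
        thread[-1],
        np.array([1.5, 4.0, -7.0]),
        np.array([0.0, 12.0, -10.0]),
        _cyl(90, 20.0, -12.0),
        _cyl(60, 20.0, -12.0),
        _cyl(35, 20.0, -11.0),
        _cyl(24, 19.0, -8.5),
        _cyl(20, 18.0, -5.3),
    ]
    descend = _resample(descend_wp, 2 * 28)  # residues 4..31
    pts_strand = thread + descend
    # nudge the splice so no strand segment has zero length
    pts_strand[6] = pts_strand[6] + np.array([0.0, 0.2, 0.0])
    _strand_residues(builder, "A", 1, pts_strand,
                     [seq[t] for t in range(1, 32)])

    # --- pseudoknot helix: residues 32/50 one rise below 33/49
    c1_33 = _cyl(theta[33], r_c1, 0.0)
    c1_49 = _cyl(theta[49], r_c1, 0.0)
    base_33, base_49 = _paired_bases(c1_33, c1_49, normal, "G", "C")
    c1_32 = c1_33 + np.array([0, 0, -RISE])
    c1_50 = c1_49 + np.array([0, 0, -RISE])
    base_32, base_50 = _paired_bases(c1_32, c1_50, normal, "G", "C")
    atoms32 = rim_atoms(33, -RISE)
    atoms32.update(base_32)
    builder.add("A", 32, "G", atoms32)

    # --- ring residues 33..49
    core5 = {45: "G", 46: "C", 47: "G"}
    r_c1_out = r_c1 + PAIR_C1C1  # partner C1' radius for the core helix
    for t in range(33, 50):
        atoms = rim_atoms(t, 0.0)
        if t == 33:
            atoms.update(base_33)
        elif t == 49:
            atoms.update(base_49)
        elif t in core5:
            c1 = _cyl(theta[t], r_c1, 0.0)
            c1_out = _cyl(theta[t], r_c1_out, 0.0)
            base_in, _ = _paired_bases(c1, c1_out, normal, core5[t],
                                       {"G": "C", "C": "G"}[core5[t]])
            atoms.update(base_in)
        else:
            c1 = _cyl(theta[t], r_c1, 0.0)
            outward = _unit(_cyl(theta[t], 1.0, 0.0))
            atoms.update(_base_atoms(c1, outward, normal, seq[t]))
        builder.add("A", t, seq[t], atoms)

    atoms50 = rim_atoms(49, -RISE)
    atoms50.update(base_50)
    builder.add("A", 50, "C", atoms50)

    # --- linker 51..56 routed outside the ring, below its plane
    link_wp = [
        _cyl(theta[49], 17.5, -3.2),
        _cyl(345, 20.0, -3.0),
        _cyl(330, 26.0, -2.0),
        _cyl(312, 28.0, -1.2),
        _cyl(theta[47] - 3, 27.0, -0.8),
    ]
    link = _resample(link_wp, 12)
    _strand_residues(builder, "A", 51, link, ["A"] * 6)

    # --- core-helix partners 57..59 (pair 47,46,45), then a 3' dangle
    partner_of = {57: 47, 58: 46, 59: 45}
    for t in (57, 58, 59):
        mate = partner_of[t]
        ang = theta[mate]
        c1_in = _cyl(ang, r_c1, 0.0)
        c1_out = _cyl(ang, r_c1_out, 0.0)
        _, base_out = _paired_bases(c1_in, c1_out, normal, core5[mate], seq[t])
        atoms = {
            "P": _cyl(ang - 2.5, r_c1_out + 1.3, 0.0),
            "C4'": _cyl(ang + 2.5, r_c1_out + 1.3, 0.0),
        }
        atoms.update(base_out)
        builder.add("A", t, seq[t], atoms)
    dangle = _resample([
        _cyl(theta[45] - 8, r_c1_out + 2.0, -1.0),
        _cyl(theta[45] - 14, r_c1_out + 3.0, -1.8),
    ], 2)
    _strand_residues(builder, "A", 60, dangle, ["A"])

    truth = FixtureTruth(
        family=spec.family,
        pairs=[(45, 59, 0), (46, 58, 0), (47, 57, 0), (32, 50, 1), (33, 49, 1)],
        entanglements=[{
            "level": 1, "topology": "lasso", "class_code": "L(S)",
            "n_punctures": 1,
            "closing_pair": [33, 49],
            "strand_range": [1, 31],
            "puncture_between": [[2, "C4'"], [3, "P"]],
        }],
        ring_residues=list(range(33, 50)),
        strand_residues=list(range(1, 32)),
        notes=(
            "synthetic emulation of a flaviviral xrRNA knot-like fold: "
            "order-1 loop closed by G33-C49, threaded by the 5' strand; "
            "no entanglement is reported when pseudoknots are ignored"
        ),
    )
    return builder.model("knotlike_pseudoknot(synthetic-xrRNA-emulation)"), truth


# ---------------------------------------------------------------------------
# public API


def generate_fixture(spec: FixtureSpec) -> tuple[StructureModel, FixtureTruth]:
    """Build the fixture named by ``spec``; optionally apply the rigid
    motion derived from ``spec.seed``."""
    if spec.family in ("lassoed_hairpin", "multi_weave"):
        punctures = spec.punctures if spec.family == "lassoed_hairpin" else max(spec.punctures, 3)
        model, truth = _build_lassoed(
            FixtureSpec(spec.family, spec.loop_size, punctures, spec.seed, spec.transform)
        )
    elif spec.family == "clean_hairpin":
        model, truth = _build_clean(spec)
    elif spec.family == "non_rna_contaminated":
        model, truth = _build_contaminated(spec)
    elif spec.family == "interlaced_hairpins":
        model, truth = _build_interlaced(spec)
    elif spec.family == "knotlike_pseudoknot":
        model, truth = _build_knotlike(spec)
    else:  # pragma: no cover
        raise FixtureError(spec.family)
    if spec.transform:
        model = rigid_transform(model, spec.seed)
    return model, truth


def rigid_transform(model: StructureModel, seed: int) -> StructureModel:
    """Random rotation + translation applied to every atom (seeded)."""
    rng = np.random.default_rng(seed)
    # rotation via QR of a random matrix -> uniform-ish, deterministic
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-25.0, 25.0, size=3)
    return _map_coords(model, lambda x: q @ x + t)


def perturb(model: StructureModel, noise_sd: float, seed: int) -> StructureModel:
    """Gaussian jitter of all atom coordinates (robustness testing)."""
    if noise_sd < 0:
        raise FixtureError("noise_sd must be >= 0")
    if noise_sd == 0:
        return _map_coords(model, lambda x: x.copy())
    rng = np.random.default_rng(seed)
    return _map_coords(model, lambda x: x + rng.normal(0.0, noise_sd, size=3))


def _map_coords(model: StructureModel, fn) -> StructureModel:
    chains = []
    for cid, residues in model.chains:
        new_res = []
        for r in residues:
            atoms = {
                n: AtomRecord(name=a.name, element=a.element, coords=fn(a.coords),
                              occupancy=a.occupancy, alt_loc=a.alt_loc)
                for n, a in r.atoms.items()
            }
            new_res.append(NucleotideResidue(
                chain_id=r.chain_id, res_num=r.res_num, ins_code=r.ins_code,
                res_name=r.res_name, seq_index=r.seq_index, atoms=atoms,
                is_modified=r.is_modified, parent=r.parent,
            ))
        chains.append((cid, new_res))
    return StructureModel(model_id=model.model_id, chains=chains,
                          source=model.source, cleaning_report=list(model.cleaning_report))


def strand_ring_crossings(model: StructureModel, truth: FixtureTruth) -> int:
    """Independent arithmetic check of the construction: number of times the
    strand's P/C4' polyline crosses the ring's best-fit plane inside the
    ring polygon (2D winding test) — no meshes, no Moller-Trumbore."""
    ring_pts = []
    for num in truth.ring_residues:
        res = model.residue_by_number(num)
        for a in ("P", "C4'"):
            if res.has(a):
                ring_pts.append(res.coord(a))
    ring_pts = np.array(ring_pts)
    center = ring_pts.mean(axis=0)
    _, _, vt = np.linalg.svd(ring_pts - center)
    n = vt[-1]
    e1, e2 = vt[0], vt[1]
    poly = np.column_stack([(ring_pts - center) @ e1, (ring_pts - center) @ e2])
    strand_pts = []
    for num in truth.strand_residues:
        res = model.residue_by_number(num)
        for a in ("P", "C4'"):
            if res.has(a):
                strand_pts.append(res.coord(a))
    crossings = 0
    for t in range(len(strand_pts) - 1):
        a, b = strand_pts[t], strand_pts[t + 1]
        ha, hb = (a - center) @ n, (b - center) @ n
        if ha == 0 or hb == 0 or (ha > 0) == (hb > 0):
            continue
        f = ha / (ha - hb)
        hit = a + f * (b - a)
        q = np.array([(hit - center) @ e1, (hit - center) @ e2])
        if _point_in_polygon(q, poly):
            crossings += 1
    return crossings


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _point_in_polygon(q: np.ndarray, poly: np.ndarray) -> bool:
    wn = 0
    n = len(poly)
    for t in range(n):
        a, b = poly[t], poly[(t + 1) % n]
        if a[1] <= q[1]:
            if b[1] > q[1] and _cross2(b - a, q - a) > 0:
                wn += 1
        elif b[1] <= q[1] and _cross2(b - a, q - a) < 0:
            wn -= 1
    return wn != 0


def write_fixture(spec: FixtureSpec, outdir: str) -> dict[str, str]:
    """Write the fixture as PDB + mmCIF with a JSON ground-truth sidecar."""
    model, truth = generate_fixture(spec)
    os.makedirs(outdir, exist_ok=True)
    stem = f"{spec.family}_m{spec.loop_size}_p{spec.punctures}_s{spec.seed}"
    paths = {
        "pdb": os.path.join(outdir, stem + ".pdb"),
        "mmcif": os.path.join(outdir, stem + ".cif"),
        "truth": os.path.join(outdir, stem + ".truth.json"),
    }
    write_cleaned_structure(model, paths["pdb"], "pdb")
    write_cleaned_structure(model, paths["mmcif"], "mmcif")
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
    return paths
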