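"""Entanglement classification.

Two topologies: a lasso, coded ``X(Y)``, where one element is only punctured
and the other only punctures; and an interlace, coded ``X&Y``, where two
closed elements puncture each other.  Element kinds are L (loop), D
(dinucleotide step), S (single strand).  Extra punctures beyond the first
appear as dots: ``L(S..)`` is a loop whose surface a single strand crosses
three times.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .elements import ElementSet, StructuralElement
from .geometry import GeometryConfig, Puncture, PolygonalChain, TriangleMesh, count_punctures


class ClassificationError(Exception):
    pass


@dataclass
class Entanglement:
    id: int
    level: int
    topology: str  # "lasso" | "interlace"
    punctured: StructuralElement  # lasso: the meshed element; interlace: first element
    puncturing: StructuralElement
    class_code: str
    punctures: list[Puncture] = field(default_factory=list)
    punctures_backward: list[Puncture] = field(default_factory=list)
    merged_from: list[int] = field(default_factory=list)

    @property
    def n_forward(self) -> int:
        return len(self.punctures)

    @property
    def n_backward(self) -> int:
        return len(self.punctures_backward)


def class_code(
    kind_punctured: str,
    kind_puncturing: str,
    topology: str,
    n_forward: int,
    n_backward: int = 0,
) -> str:
    """Build the class string from element kinds and puncture counts."""
    if kind_punctured == "S":
        raise ClassificationError("a single strand has no surface and cannot be punctured")
    if topology == "lasso":
        if n_forward < 1:
            raise ClassificationError("lasso requires at least one puncture")
        if n_backward != 0:
            raise ClassificationError("lasso must have punctures in one direction only")
        return f"{kind_punctured}({kind_puncturing}{'.' * (n_forward - 1)})"
    if topology == "interlace":
        if n_forward < 1 or n_backward < 1:
            raise ClassificationError("interlace requires punctures in both directions")
        return (
            f"{kind_punctured}{'.' * (n_forward - 1)}"
            f"&{kind_puncturing}{'.' * (n_backward - 1)}"
        )
    raise ClassificationError(f"unknown topology {topology!r}")


_LASSO_RE = re.compile(r"^([LD])\(([LSD])(\.*)\)$")
_INTERLACE_RE = re.compile(r"^([LD])(\.*)&([LD])(\.*)$")


def parse_class_code(code: str) -> tuple[str, str, str, int, int]:
    """Inverse of :func:`class_code`: (punctured, puncturing, topology, n_fwd, n_bwd)."""
    m = _LASSO_RE.match(code)
    if m:
        return m.group(1), m.group(2), "lasso", 1 + len(m.group(3)), 0
    m = _INTERLACE_RE.match(code)
    if m:
        return m.group(1), m.group(3), "interlace", 1 + len(m.group(2)), 1 + len(m.group(4))
    raise ClassificationError(f"unparseable class code {code!r}")


def _share_closing_pair(a: StructuralElement, b: StructuralElement) -> bool:
    pa = {p.as_tuple for p in a.closing_pairs}
    pb = {p.as_tuple for p in b.closing_pairs}
    return bool(pa & pb)


_KIND_RANK = {"L": 0, "D": 1, "S": 2}


def detect_entanglements(
    element_sets: dict[int, ElementSet],
    chains: dict[str, PolygonalChain],
    meshes: dict[str, TriangleMesh],
    config: GeometryConfig | None = None,
) -> list[Entanglement]:
    """Detect and classify all entanglements, level by level.

    For every closed element A and every other element B at the same level,
    punctures are counted in both available directions (an open B cannot be
    punctured).  Both directions >0 gives one interlace; exactly one gives a
    lasso.  Overlapping reports that share a closing pair and the same
    partner (a loop and a D step cut from the same helix end) are merged,
    keeping the one with more punctures.
    """
    cfg = config or GeometryConfig()
    results: list[Entanglement] = []
    next_id = 1
    for level in sorted(element_sets):
        eset = element_sets[level]
        elems = [e for e in eset.all_elements if e.element_id in chains]
        seen_pairs: set[frozenset] = set()
        level_results: list[Entanglement] = []
        for a in elems:
            if not a.is_closed or a.element_id not in meshes:
                continue
            for b in elems:
                if b.element_id == a.element_id:
                    continue
                key = frozenset((a.element_id, b.element_id))
                if key in seen_pairs:
                    continue
                n_ab = count_punctures(
                    meshes[a.element_id], chains[b.element_id],
                    exclusion=a.residue_set, config=cfg,
                )
                n_ba: list[Puncture] = []
                if b.is_closed and b.element_id in meshes:
                    n_ba = count_punctures(
                        meshes[b.element_id], chains[a.element_id],
                        exclusion=b.residue_set, config=cfg,
                    )
                if not n_ab and not n_ba:
                    continue
                seen_pairs.add(key)
                if n_ab and n_ba:
                    first, second = a, b
                    fwd, bwd = n_ab, n_ba
                    # deterministic ordering: L before D, then smaller first residue
                    ka = (_KIND_RANK[a.kind], min(a.residues))
                    kb = (_KIND_RANK[b.kind], min(b.residues))
                    if kb < ka:
                        first, second = b, a
                        fwd, bwd = n_ba, n_ab
                    code = class_code(first.kind, second.kind, "interlace", len(fwd), len(bwd))
                    level_results.append(Entanglement(
                        id=next_id, level=level, topology="interlace",
                        punctured=first, puncturing=second, class_code=code,
                        punctures=fwd, punctures_backward=bwd,
                    ))
                    next_id += 1
                else:
                    if n_ab:
                        punctured, puncturing, hits = a, b, n_ab
                    else:
                        punctured, puncturing, hits = b, a, n_ba
                    code = class_code(punctured.kind, puncturing.kind, "lasso", len(hits))
                    level_results.append(Entanglement(
                        id=next_id, level=level, topology="lasso",
                        punctured=punctured, puncturing=puncturing, class_code=code,
                        punctures=hits,
                    ))
                    next_id += 1
        results.extend(_merge_overlapping(level_results))
    return results


def _merge_overlapping(ents: list[Entanglement]) -> list[Entanglement]:
    """Merge reports that share >=1 closing pair and the same partner."""
    ents = sorted(
        ents, key=lambda e: (-(e.n_forward + e.n_backward), e.punctured.element_id)
    )
    kept: list[Entanglement] = []
    for ent in ents:
        absorbed = False
        for other in kept:
            if (
                ent.topology == other.topology
                and ent.puncturing.element_id == other.puncturing.element_id
                and ent.punctured.is_closed
                and other.punctured.is_closed
                and _share_closing_pair(ent.punctured, other.punctured)
            ):
                other.merged_from.append(ent.id)
                absorbed = True
                break
        if not absorbed:
            kept.append(ent)
    kept.sort(key=lambda e: (e.level, min(e.punctured.residues), min(e.puncturing.residues)))
    return kept


def summarize(entanglements: list[Entanglement]) -> pd.DataFrame:
    """Count entanglements per class, split into primary (level 0) and
    higher-order (level >= 1) rows; Lassos + Interlaces = All in each row."""
    classes = sorted({e.class_code for e in entanglements})
    rows = {}
    for bucket, pred in [
        ("Primary entanglements", lambda e: e.level == 0),
        ("Higher-order entanglements", lambda e: e.level >= 1),
    ]:
        sub = [e for e in entanglements if pred(e)]
        row = {
            "Lassos": sum(1 for e in sub if e.topology == "lasso"),
            "Interlaces": sum(1 for e in sub if e.topology == "interlace"),
            "All": len(sub),
        }
        for c in classes:
            row[c] = sum(1 for e in sub if e.class_code == c)
        rows[bucket] = row
    total = {
        k: rows["Primary entanglements"][k] + rows["Higher-order entanglements"][k]
        for k in rows["Primary entanglements"]
    }
    rows["Total number"] = total
    return pd.DataFrame.from_dict(rows, orient="index")
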