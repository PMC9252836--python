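"""Reading, validation, cleaning and writing of RNA 3D structures.

PDB and PDBx/mmCIF files are parsed with gemmi into a light in-memory model
(:class:`StructureModel`) that downstream stages consume.  Cleaning removes
everything that is not analyzable RNA: non-RNA chains (protein, DNA, ligands,
water), surplus atoms of modified residues that have no counterpart in the
parent ribonucleotide, and nucleotides too incomplete to contribute to the
polygonal chain or to base-pair detection.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import _chemistry as chem

DEFAULT_MAX_INPUT_BYTES = 50 * 1024 * 1024  # mirrors the public server's cap


class StructureError(Exception):
    """Base class for structure-processing errors."""


class StructureParseError(StructureError):
    pass


class NoRnaContentError(StructureError):
    pass


class InputTooLargeError(StructureError):
    pass


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # (3,) float, Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be 3 finite numbers")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class NucleotideResidue:
    chain_id: str
    res_num: int
    ins_code: str
    res_name: str
    seq_index: int
    atoms: dict[str, AtomRecord]
    is_modified: bool = False
    parent: str | None = None  # A/C/G/U parent type, None for generic

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_num, self.ins_code)

    @property
    def label(self) -> str:
        ins = self.ins_code or ""
        return f"{self.res_name}{self.res_num}{ins}"

    def coord(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].coords

    def has(self, atom_name: str) -> bool:
        return atom_name in self.atoms


@dataclass
class StructureModel:
    model_id: int
    chains: list[tuple[str, list[NucleotideResidue]]]
    source: str = ""
    cleaning_report: list[dict] = field(default_factory=list)

    def iter_residues(self):
        for _, residues in self.chains:
            yield from residues

    @property
    def n_residues(self) -> int:
        return sum(len(r) for _, r in self.chains)

    def residue_by_number(self, res_num: int, chain_id: str | None = None):
        for cid, residues in self.chains:
            if chain_id is not None and cid != chain_id:
                continue
            for r in residues:
                if r.res_num == res_num:
                    return r
        raise KeyError(f"residue {res_num} not found")


# ---------------------------------------------------------------------------
# parsing


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        return "pdb"
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("data_") or s.startswith("#"):
                return "mmcif"
            return "pdb"
    return "pdb"


def _looks_like_rna(res: gemmi.Residue) -> bool:
    name = res.name.strip()
    if name in chem.WATER_NAMES or name in chem.AMINO_ACIDS:
        return False
    if name in chem.DEOXYRIBONUCLEOTIDES:
        return False
    if chem.parent_of(name) is not None:
        return True
    # generic: ribose marker plus some base ring nitrogen
    atom_names = {a.name for a in res}
    return "O2'" in atom_names and ("N9" in atom_names or "N1" in atom_names)


def _select_altlocs(res: gemmi.Residue) -> tuple[list[gemmi.Atom], bool]:
    """Keep one atom per name: highest occupancy, ties by alt-loc label."""
    by_name: dict[str, gemmi.Atom] = {}
    dropped = False
    for atom in res:
        if atom.is_hydrogen():
            continue
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        dropped = True
        better = atom.occ > prev.occ or (
            atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~")
        )
        if better:
            by_name[atom.name] = atom
    return list(by_name.values()), dropped


def parse_structure(
    path: str,
    format: str = "auto",
    max_bytes: int = DEFAULT_MAX_INPUT_BYTES,
) -> list[StructureModel]:
    """Parse a PDB or PDBx/mmCIF file into one StructureModel per MODEL.

    Hydrogens are dropped; alternate locations are collapsed to the
    highest-occupancy conformer (recorded in the cleaning report).  Raises
    :class:`NoRnaContentError` if no chain of any model looks like RNA.
    """
    if not os.path.exists(path):
        raise StructureParseError(f"file not found: {path}")
    size = os.path.getsize(path)
    if size > max_bytes:
        raise InputTooLargeError(
            f"input {path} is {size} bytes, above the {max_bytes}-byte limit"
        )
    fmt = format if format != "auto" else _sniff_format(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
        elif fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc

    models: list[StructureModel] = []
    any_rna = False
    for imodel, gmodel in enumerate(st):
        model_id = getattr(gmodel, "num", None) or (imodel + 1)
        chains: list[tuple[str, list[NucleotideResidue]]] = []
        report: list[dict] = []
        for gchain in gmodel:
            residues: list[NucleotideResidue] = []
            for gres in gchain:
                atoms_sel, dropped = _select_altlocs(gres)
                if dropped:
                    report.append({
                        "action": "altloc_dropped",
                        "chain": gchain.name,
                        "residue": f"{gres.name}{gres.seqid.num}",
                        "reason": "alternate locations collapsed to highest occupancy",
                    })
                atoms = {}
                for a in atoms_sel:
                    atoms[a.name] = AtomRecord(
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        alt_loc=a.altloc or "",
                    )
                if not atoms:
                    continue
                name = gres.name.strip()
                parent = chem.parent_of(name)
                residues.append(
                    NucleotideResidue(
                        chain_id=gchain.name,
                        res_num=gres.seqid.num,
                        ins_code=(gres.seqid.icode or "").strip(),
                        res_name=name,
                        seq_index=len(residues),
                        atoms=atoms,
                        is_modified=name not in chem.STANDARD_RIBONUCLEOTIDES,
                        parent=parent,
                    )
                )
            if residues:
                chains.append((gchain.name, residues))
        model = StructureModel(
            model_id=model_id,
            chains=chains,
            source=f"{os.path.basename(path)}:{fmt}",
            cleaning_report=report,
        )
        models.append(model)
        for gchain in gmodel:
            if any(_looks_like_rna(r) for r in gchain):
                any_rna = True
    if not models:
        raise StructureParseError(f"{path}: no models found")
    if not any_rna:
        raise NoRnaContentError(f"{path}: no RNA content")
    return models


# ---------------------------------------------------------------------------
# cleaning


def _residue_is_rna_like(res: NucleotideResidue) -> bool:
    if res.res_name in chem.WATER_NAMES or res.res_name in chem.AMINO_ACIDS:
        return False
    if res.res_name in chem.DEOXYRIBONUCLEOTIDES:
        return False
    if res.parent is not None:
        return True
    return res.has("O2'") and (res.has("N9") or res.has("N1"))


def _chain_is_rna(residues: list[NucleotideResidue]) -> bool:
    """A chain is RNA if >50% of its residues are (mapped) ribonucleotides."""
    scored = [r for r in residues if r.res_name not in chem.WATER_NAMES]
    if not scored:
        return False
    n_rna = sum(1 for r in scored if _residue_is_rna_like(r))
    return n_rna > 0.5 * len(scored)


def _residue_is_complete(res: NucleotideResidue) -> bool:
    """Minimum atoms: C4' plus at least one base heavy atom.

    P is optional (absent at many 5' termini); the base requirement keeps
    pair detection and base-COM pseudoatoms computable.
    """
    if not res.has("C4'"):
        return False
    if res.parent is not None:
        base = chem.BASE_ATOMS[res.parent]
    else:
        base = {"N9", "N1", "C2", "C4", "C5", "C6", "C8", "N3", "N7"}
    return any(res.has(a) for a in base)


def clean_structure(model: StructureModel) -> StructureModel:
    """Return a cleaned copy: RNA chains only, complete residues only,
    surplus atoms of modified residues removed.  Idempotent."""
    report = list(model.cleaning_report)
    new_chains: list[tuple[str, list[NucleotideResidue]]] = []
    for chain_id, residues in model.chains:
        if not _chain_is_rna(residues):
            report.append({
                "action": "chain_removed",
                "chain": chain_id,
                "residue": None,
                "reason": "non-RNA chain",
            })
            continue
        kept: list[NucleotideResidue] = []
        for res in residues:
            if not _residue_is_rna_like(res):
                report.append({
                    "action": "residue_removed",
                    "chain": chain_id,
                    "residue": res.label,
                    "reason": "non-RNA residue in RNA chain",
                })
                continue
            atoms = dict(res.atoms)
            if res.parent is not None and res.is_modified:
                allowed = chem.allowed_atoms(res.parent)
                surplus = [n for n in atoms if n not in allowed]
                for n in surplus:
                    del atoms[n]
                    report.append({
                        "action": "atom_removed",
                        "chain": chain_id,
                        "residue": res.label,
                        "reason": f"surplus atom {n} not in parent {res.parent} template",
                    })
            candidate = replace(res, atoms=atoms, seq_index=len(kept))
            if not _residue_is_complete(candidate):
                report.append({
                    "action": "residue_removed",
                    "chain": chain_id,
                    "residue": res.label,
                    "reason": "incomplete nucleotide (missing C4' or all base atoms)",
                })
                continue
            kept.append(candidate)
        if kept:
            new_chains.append((chain_id, kept))
        else:
            report.append({
                "action": "chain_removed",
                "chain": chain_id,
                "residue": None,
                "reason": "no residues left after cleaning",
            })
    if not new_chains:
        raise NoRnaContentError("no RNA content after cleaning")
    return StructureModel(
        model_id=model.model_id,
        chains=new_chains,
        source=model.source,
        cleaning_report=report,
    )


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "rnaentangle"
    gmodel = gemmi.Model(int(model.model_id))
    for chain_id, residues in model.chains:
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.res_num, res.ins_code or " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element or atom.name[0])
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.b_iso = 0.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_cleaned_structure(model: StructureModel, path: str, format: str = "auto") -> None:
    """Write the model as PDB or mmCIF; re-parsing reproduces it."""
    fmt = format
    if fmt == "auto":
        ext = os.path.splitext(path)[1].lower()
        fmt = "mmcif" if ext in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(path)
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def global_residue_order(model: StructureModel) -> list[NucleotideResidue]:
    """Residues in global order: chain order, then 5'->3' within chain."""
    out = []
    for _, residues in model.chains:
        out.extend(residues)
    return out
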