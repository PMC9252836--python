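"""End-to-end analysis driver.

One call takes a parsed structure model through cleaning, secondary-structure
extraction (or a user-supplied dot-bracket), pseudoknot-order assignment,
per-level element decomposition, chain/mesh construction and entanglement
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .classify import Entanglement, detect_entanglements, summarize
from .elements import AnalysisOptions, ElementSet, build_elements, enumerate_levels
from .geometry import (
    DegenerateMeshError,
    GeometryConfig,
    GeometryError,
    PolygonalChain,
    TriangleMesh,
    build_polygonal_chain,
    triangulate,
)
from .secondary import (
    PairingConfig,
    SecondaryStructure,
    assign_pseudoknot_orders,
    detect_canonical_pairs,
    secondary_structure_from_model,
    to_extended_dotbracket,
)
from .structure_io import StructureModel, clean_structure, parse_structure

log = logging.getLogger("rnaentangle")


class ConfigError(Exception):
    pass


@dataclass
class ModelResult:
    model: StructureModel  # cleaned
    ss: SecondaryStructure
    dotbracket: str
    element_sets: dict[int, ElementSet]
    chains: dict[str, PolygonalChain]
    meshes: dict[str, TriangleMesh]
    entanglements: list[Entanglement]
    warnings: list[str] = field(default_factory=list)

    @property
    def summary(self):
        return summarize(self.entanglements)


def validate_options(options: AnalysisOptions) -> None:
    if options.pseudoknots not in ("accept", "ignore"):
        raise ConfigError(f"pseudoknots must be accept|ignore, got {options.pseudoknots!r}")
    if options.pseudoknots == "ignore" and options.order_cap is not None:
        raise ConfigError("order_cap cannot be combined with pseudoknots=ignore")
    if options.models not in ("first", "all"):
        raise ConfigError(f"models must be first|all, got {options.models!r}")
    if options.max_loop_length < 4:
        raise ConfigError("max_loop_length below 4 leaves no analyzable loops")


def analyze_model(
    model: StructureModel,
    options: AnalysisOptions | None = None,
    user_ss: SecondaryStructure | None = None,
    pairing: PairingConfig | None = None,
    geometry: GeometryConfig | None = None,
) -> ModelResult:
    """Run the full entanglement analysis on one (parsed) model."""
    opts = options or AnalysisOptions()
    validate_options(opts)
    geom = geometry or GeometryConfig(mesh_edge_target=opts.mesh_edge_target)
    cleaned = clean_structure(model)
    warnings = [
        f"{r['action']}: {r.get('residue') or r.get('chain')} ({r['reason']})"
        for r in cleaned.cleaning_report
    ]
    if user_ss is not None:
        if user_ss.n != cleaned.n_residues:
            raise ConfigError(
                f"user secondary structure has {user_ss.n} positions, "
                f"cleaned model has {cleaned.n_residues} residues"
            )
        pairs = list(user_ss.pairs)
    else:
        pairs = detect_canonical_pairs(cleaned, pairing)
    if opts.ignore_isolated_pairs:
        pairs = [p for p in pairs if not p.isolated]
    pairs = assign_pseudoknot_orders(pairs)
    ss = secondary_structure_from_model(cleaned, pairs)
    levels = enumerate_levels(ss, opts)

    element_sets: dict[int, ElementSet] = {}
    chains: dict[str, PolygonalChain] = {}
    meshes: dict[str, TriangleMesh] = {}
    for level in levels:
        eset = build_elements(cleaned, ss, level, opts)
        element_sets[level] = eset
        for elem in eset.all_elements:
            try:
                chain = build_polygonal_chain(elem, cleaned, opts.chain_atoms, geom)
            except GeometryError as exc:
                warnings.append(f"skipped {elem.element_id}: {exc}")
                continue
            chains[elem.element_id] = chain
            if elem.is_closed:
                try:
                    meshes[elem.element_id] = triangulate(chain, geom)
                except DegenerateMeshError as exc:
                    warnings.append(f"skipped mesh for {elem.element_id}: {exc}")
    entanglements = detect_entanglements(element_sets, chains, meshes, geom)
    return ModelResult(
        model=cleaned,
        ss=ss,
        dotbracket=to_extended_dotbracket(ss),
        element_sets=element_sets,
        chains=chains,
        meshes=meshes,
        entanglements=entanglements,
        warnings=warnings,
    )


def analyze_file(
    path: str,
    options: AnalysisOptions | None = None,
    format: str = "auto",
    **kwargs,
) -> list[ModelResult]:
    """Parse a structure file and analyze the first or all models."""
    opts = options or AnalysisOptions()
    validate_options(opts)
    models = parse_structure(path, format=format)
    if opts.models == "first":
        models = models[:1]
    return [analyze_model(m, opts, **kwargs) for m in models]
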