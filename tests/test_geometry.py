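"""Polygonal chains, triangulation, Moller-Trumbore, puncture counting."""

import numpy as np
import pytest

from conftest import make_linear_model, oracle_segment_triangle, shoelace_area
from rnaentangle.elements import StructuralElement
from rnaentangle.geometry import (
    DegenerateMeshError,
    GeometryConfig,
    PolygonalChain,
    base_center_of_mass,
    build_polygonal_chain,
    count_punctures,
    segment_triangle_intersect,
    triangulate,
)
from rnaentangle.pipeline import analyze_model
from rnaentangle.structure_io import AtomRecord, NucleotideResidue
from rnaentangle.synthetic import FixtureSpec, generate_fixture


def ring_chain(points, element_id="L-test"):
    pts = np.asarray(points, float)
    return PolygonalChain(
        element_id=element_id, points=pts,
        point_sources=[(t, "P") for t in range(len(pts))], closed=True)


class TestChains:
    def test_open_strand_chain_orders_p_then_c4(self):
        model = make_linear_model("AAA")
        elem = StructuralElement(kind="S", level=0, residues=[0, 1, 2],
                                 element_id="S-test")
        chain = build_polygonal_chain(elem, model)
        assert chain.n_points == 6
        assert [s[1] for s in chain.point_sources] == ["P", "C4'"] * 3
        assert [s[0] for s in chain.point_sources] == [0, 0, 1, 1, 2, 2]

    def test_base_com_is_plain_centroid(self):
        res = NucleotideResidue(
            chain_id="A", res_num=1, ins_code="", res_name="X", seq_index=0,
            atoms={
                "N9": AtomRecord("N9", "N", np.zeros(3)),
                "C8": AtomRecord("C8", "C", np.array([2.0, 0.0, 0.0])),
            })
        assert np.allclose(base_center_of_mass(res), [1.0, 0.0, 0.0])

    def test_closed_loop_chain_bridges_pair_with_base_coms(self, clean_hairpin):
        model, _ = clean_hairpin
        result = analyze_model(model)
        loop = next(e for eset in result.element_sets.values()
                    for e in eset.closed if e.kind == "L")
        chain = result.chains[loop.element_id]
        assert chain.closed
        com_sources = [s for s in chain.point_sources if s[1] == "base-COM"]
        assert len(com_sources) == 2  # one per closing-pair nucleotide

    def test_missing_midchain_atom_raises(self):
        model = make_linear_model("AAA")
        del model.chains[0][1][1].atoms["P"]
        elem = StructuralElement(kind="S", level=0, residues=[0, 1, 2],
                                 element_id="S-test")
        with pytest.raises(Exception, match="lacks selected atom"):
            build_polygonal_chain(elem, model)


class TestTriangulation:
    SQUARE = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]

    def test_square_with_coarse_target_is_pure_fan(self):
        mesh = triangulate(ring_chain(self.SQUARE),
                           GeometryConfig(mesh_edge_target=2.0))
        assert mesh.n_triangles == 4

    def test_refinement_caps_edge_length(self):
        mesh = triangulate(ring_chain(self.SQUARE),
                           GeometryConfig(mesh_edge_target=0.6))
        v, t = mesh.vertices, mesh.triangles
        edges = np.concatenate([
            np.linalg.norm(v[t[:, 0]] - v[t[:, 1]], axis=1),
            np.linalg.norm(v[t[:, 1]] - v[t[:, 2]], axis=1),
            np.linalg.norm(v[t[:, 2]] - v[t[:, 0]], axis=1),
        ])
        assert edges.max() <= 0.6 + 1e-9

    def test_mesh_area_equals_shoelace_on_random_convex_polygons(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(2.0, 8.0)
            poly2d = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            # embed in a random plane
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            pts = poly2d @ q[:, :2].T + rng.uniform(-5, 5, 3)
            mesh = triangulate(ring_chain(pts), GeometryConfig(mesh_edge_target=1.0))
            assert mesh.total_area() == pytest.approx(shoelace_area(poly2d), rel=1e-6)

    def test_boundary_equals_refined_chain(self):
        chain = ring_chain(self.SQUARE)
        mesh = triangulate(chain, GeometryConfig(mesh_edge_target=0.6))
        cycle = mesh.boundary_cycle()
        originals = [v for v in cycle if v < chain.n_points]
        # original chain vertices appear once each, in cyclic order
        assert sorted(originals) == list(range(chain.n_points))
        start = originals.index(0)
        rotated = originals[start:] + originals[:start]
        assert rotated in ([0, 1, 2, 3], [0, 3, 2, 1])
        # every boundary vertex lies on the original chain polygon
        for v in cycle:
            p = mesh.vertices[v]
            dists = []
            for t in range(chain.n_points):
                a = chain.points[t]
                b = chain.points[(t + 1) % chain.n_points]
                f = np.clip((p - a) @ (b - a) / ((b - a) @ (b - a)), 0, 1)
                dists.append(np.linalg.norm(p - (a + f * (b - a))))
            assert min(dists) < 1e-9

    def test_collinear_chain_is_degenerate(self):
        pts = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
        with pytest.raises(DegenerateMeshError):
            triangulate(ring_chain(pts))


class TestMollerTrumbore:
    TRI = [(-1, -1, 0), (3, -1, 0), (-1, 3, 0)]

    def test_axis_aligned_crossing(self):
        hit = segment_triangle_intersect((0, 0, -1), (0, 0, 1), self.TRI)
        assert np.allclose(hit, [0, 0, 0])

    def test_segment_short_of_plane_misses(self):
        assert segment_triangle_intersect((0, 0, 1), (0, 0, 3), self.TRI) is None

    def test_parallel_segment_misses(self):
        assert segment_triangle_intersect((0, 0, 1), (1, 1, 1), self.TRI) is None

    def test_agrees_with_bruteforce_oracle_on_random_cases(self):
        rng = np.random.default_rng(2024)
        n_cases = 10_000
        mismatches = 0
        hits = 0
        for _ in range(n_cases):
            p0, p1 = rng.uniform(-2, 2, 3), rng.uniform(-2, 2, 3)
            tri = rng.uniform(-2, 2, (3, 3))
            got = segment_triangle_intersect(p0, p1, tri)
            exp = oracle_segment_triangle(p0, p1, tri)
            if (got is None) != (exp is None):
                mismatches += 1
            elif got is not None:
                hits += 1
                assert np.linalg.norm(got - exp) < 1e-6
        assert mismatches == 0
        assert hits > 100  # the sample must actually exercise intersections


class TestPunctures:
    def test_lassoed_fixture_has_exactly_one(self, lassoed_hairpin):
        model, _ = lassoed_hairpin
        result = analyze_model(model)
        loop_id = next(e.element_id for eset in result.element_sets.values()
                       for e in eset.closed if e.kind == "L")
        strand_id = next(e.element_id for eset in result.element_sets.values()
                         for e in eset.open if 0 in e.residues)
        loop = next(e for eset in result.element_sets.values()
                    for e in eset.closed if e.element_id == loop_id)
        hits = count_punctures(result.meshes[loop_id], result.chains[strand_id],
                               exclusion=loop.residue_set)
        assert len(hits) == 1

    def test_triple_weave_has_three(self):
        model, _ = generate_fixture(FixtureSpec("multi_weave", punctures=3))
        result = analyze_model(model)
        assert [e.n_forward for e in result.entanglements] == [3]

    def test_self_chain_yields_zero(self, lassoed_hairpin):
        model, _ = lassoed_hairpin
        result = analyze_model(model)
        for eset in result.element_sets.values():
            for e in eset.closed:
                if e.element_id not in result.meshes:
                    continue
                hits = count_punctures(result.meshes[e.element_id],
                                       result.chains[e.element_id],
                                       exclusion=e.residue_set)
                assert hits == []

    def test_puncture_point_lies_on_named_triangle(self, lassoed_hairpin):
        model, _ = lassoed_hairpin
        result = analyze_model(model)
        ent = result.entanglements[0]
        mesh = result.meshes[ent.punctured.element_id]
        for p in ent.punctures:
            tri = mesh.vertices[mesh.triangles[p.triangle_index]]
            n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            n = n / np.linalg.norm(n)
            assert abs((p.point - tri[0]) @ n) < 1e-6
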