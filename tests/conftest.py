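"""Shared fixtures: small synthetic models and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from rnaentangle.synthetic import FixtureSpec, _Builder, _strand_residues, generate_fixture


def make_linear_model(seq: str, spacing: float = 6.0):
    """A straight-line 'RNA' with P/C4' and base atoms per residue.

    Geometry is arbitrary (no intended pairs); useful wherever only the
    residue bookkeeping matters.
    """
    builder = _Builder()
    pts = []
    for t in range(len(seq)):
        x = spacing * t
        pts.append(np.array([x, 0.0, 0.0]))
        pts.append(np.array([x + 0.45 * spacing, 0.3, 0.0]))
    _strand_residues(builder, "A", 1, pts, list(seq))
    return builder.model(f"linear({seq})")


@pytest.fixture(scope="session")
def clean_hairpin():
    return generate_fixture(FixtureSpec("clean_hairpin", loop_size=8))


@pytest.fixture(scope="session")
def lassoed_hairpin():
    return generate_fixture(FixtureSpec("lassoed_hairpin", loop_size=8, punctures=1))


@pytest.fixture(scope="session")
def knotlike():
    return generate_fixture(FixtureSpec("knotlike_pseudoknot"))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_max_noncrossing(pairs: list[tuple[int, int]]) -> int:
    """Exhaustive maximum non-crossing subset size (for <= ~12 pairs)."""

    def crossing(p, q):
        (i1, j1), (i2, j2) = p, q
        return (i1 < i2 < j1 < j2) or (i2 < i1 < j2 < j1)

    best = 0
    for r in range(len(pairs), 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(pairs, r):
            if not any(crossing(a, b) for a, b in itertools.combinations(combo, 2)):
                best = r
                break
    return best


def oracle_segment_triangle(p0, p1, tri, eps_par=1e-9, eps_bary=1e-7):
    """Plane-intersection + barycentric-coordinate brute force, independent
    of the Moller-Trumbore implementation."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    v0, v1, v2 = (np.asarray(v, float) for v in tri)
    n = np.cross(v1 - v0, v2 - v0)
    denom = float(n @ (p1 - p0))
    if abs(denom) < eps_par:
        return None
    t = float(n @ (v0 - p0)) / denom
    if t < 0.0 or t > 1.0:
        return None
    x = p0 + t * (p1 - p0)
    a = np.column_stack([v1 - v0, v2 - v0])
    uv, *_ = np.linalg.lstsq(a, x - v0, rcond=None)
    u, v = float(uv[0]), float(uv[1])
    if u >= -eps_bary and v >= -eps_bary and u + v <= 1.0 + eps_bary:
        return x
    return None


def shoelace_area(points_2d: np.ndarray) -> float:
    x, y = points_2d[:, 0], points_2d[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def random_matching(rng: np.random.Generator, n_positions: int, n_pairs: int):
    """Random pair set with each position used at most once."""
    pos = rng.permutation(n_positions)[: 2 * n_pairs]
    pairs = []
    for k in range(n_pairs):
        i, j = int(pos[2 * k]), int(pos[2 * k + 1])
        pairs.append((min(i, j), max(i, j)))
    return sorted(pairs)
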