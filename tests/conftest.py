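import numpy as np
import pytest
import trimesh

from renalnav.geometry import SurfaceModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def icosphere():
    """Unit-radius icosphere, ~320 faces."""
    m = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    return SurfaceModel(m.vertices, m.faces, "lesion")


@pytest.fixture(scope="session")
def bumpy_mesh():
    """An irregular closed mesh with < 500 faces (perturbed icosphere)."""
    m = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    r = np.random.default_rng(7)
    verts = m.vertices * (1.0 + 0.15 * r.standard_normal((len(m.vertices), 1)))
    return SurfaceModel(verts, m.faces, "kidney")


def brute_force_closest(p, model, tie_tol=1e-12):
    """Independent oracle: exhaustive point-to-triangle minimization.

    Scalar barycentric-region point-triangle projection, looped over every
    face; ties within ``tie_tol`` broken by lowest face index.
    """
    p = np.asarray(p, float)
    best_d, best_pt, best_f = np.inf, None, -1
    for fi, face in enumerate(model.faces):
        a, b, c = model.vertices[face]
        q = _closest_on_triangle(p, a, b, c)
        d = np.linalg.norm(p - q)
        if d < best_d - tie_tol:
            best_d, best_pt, best_f = d, q, fi
    return best_pt, best_d, best_f


def _closest_on_triangle(p, a, b, c):
    # region-based projection (Ericson), written independently of the package
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + ((d4 - d3) / ((d4 - d3) + (d5 - d6))) * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)
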