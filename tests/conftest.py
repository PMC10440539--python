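import numpy as np
import pytest

from plaquemech.contours import Contour, VesselSliceContours
from plaquemech.materials import default_registry


def circle_contour(r: float, label: str, n: int = 100, center=(0.0, 0.0)) -> Contour:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    cx, cy = center
    return Contour(np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]), label)


def concentric_slice(radii=(1.5, 1.8, 2.0, 2.3), n: int = 100) -> VesselSliceContours:
    rl, ri, re, ra = radii
    return VesselSliceContours(
        lumen=circle_contour(rl, "lumen", n), iem=circle_contour(ri, "IEM", n),
        eem=circle_contour(re, "EEM", n), adv=circle_contour(ra, "ADV", n),
    ).validate()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def three_layer_slice():
    return concentric_slice()


@pytest.fixture(scope="session")
def solved_concentric(registry, three_layer_slice):
    """Three-layer concentric cylinder solved at 100 mmHg, lam_z = 1.05
    (shared by solver and oracle-comparison tests)."""
    from plaquemech.fem import MMHG_TO_KPA, solve_inflation
    from plaquemech.mesh import build_mesh
    mesh = build_mesh(three_layer_slice, n_rays=48, n_radial_per_layer=3, n_slabs=1)
    sol = solve_inflation(mesh, registry, 100 * MMHG_TO_KPA, 1.05)
    return mesh, sol
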