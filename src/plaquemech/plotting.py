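"""Matplotlib helpers for material curves and solved slice fields."""

from __future__ import annotations

import numpy as np

from .fem import SolutionField
from .materials import MaterialRegistry, default_registry, stress_stretch_curve


def plot_stress_stretch(layers=("intima", "media", "adventitia", "lipid", "calcification"),
                        direction: str = "circumferential", lmax: float = 1.3,
                        registry: MaterialRegistry | None = None, ax=None):
    """Stress-stretch curves of the registry materials (log stress axis)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(1.0, lmax, 31)
    for name in layers:
        table = stress_stretch_curve(name, direction, grid, registry=registry)
        ax.plot(table[:, 0], table[:, 1], label=name)
    ax.set_xlabel("stretch ratio")
    ax.set_ylabel("Cauchy stress (kPa)")
    ax.set_yscale("symlog", linthresh=1.0)
    ax.set_title(f"uniaxial {direction} response")
    ax.legend()
    return ax


def plot_slice_field(sol: SolutionField, field: str = "stress", ax=None):
    """Scatter of nodal max-principal stress (kPa) or strain on the deformed
    z=0 face."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    mesh = sol.mesh
    face = mesh.zminus_nodes
    xy = sol.deformed_nodes[face][:, :2]
    vals = (sol.sigma_max if field == "stress" else sol.eps_max)[face]
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=vals, s=12, cmap="turbo")
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    label = "max principal stress (kPa)" if field == "stress" else "max principal strain"
    plt.colorbar(sc, ax=ax, label=label)
    return ax
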