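"""Plots: learned response signatures and searchlight accuracy slices."""

from __future__ import annotations

import numpy as np

from .encoding import VoxelEncodingResults
from .searchlight import SearchlightResult

__all__ = ["plot_signature", "plot_accuracy_slices"]


def plot_signature(results: VoxelEncodingResults, voxel: int, feature: str,
                   ax=None, scale: str = "original"):
    """Line plot of one voxel's L-point response curve to one feature."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = results.extract_signature(voxel, feature, scale=scale)
    ax.plot(results.design.lag_seconds, curve, marker="o")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("time after feature onset (s)")
    ax.set_ylabel("response weight")
    ax.set_title(f"voxel {voxel}, feature {feature!r} "
                 f"(lambda={results.penalties[voxel]:g})")
    return ax


def plot_accuracy_slices(result: SearchlightResult, n_slices: int = 4,
                         vmin: float = 0.4, vmax: float = 1.0):
    """Axial (z) slices of a searchlight accuracy map, NaN shown blank."""
    import matplotlib.pyplot as plt

    tbl = result.table
    zs = np.unique(tbl["z"])
    pick = zs[np.linspace(0, len(zs) - 1, min(n_slices, len(zs))).astype(int)]
    fig, axes = plt.subplots(1, len(pick), figsize=(3 * len(pick), 3),
                             squeeze=False)
    for ax, z in zip(axes[0], pick):
        sl = tbl[np.isclose(tbl["z"], z)]
        sc = ax.scatter(sl["x"], sl["y"], c=sl["accuracy"], vmin=vmin,
                        vmax=vmax, marker="s", s=60, cmap="viridis")
        ax.set_title(f"z = {z:g} mm")
        ax.set_aspect("equal")
    fig.colorbar(sc, ax=axes[0].tolist(), label="accuracy")
    fig.suptitle(f"feature set: {result.feature_set}")
    return fig
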