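"""Minimal visualization: 3-D scatter colormaps of per-source maps.

A folded synthetic shell has no inflated-surface rendering; a colored 3-D
scatter of the source positions is the honest equivalent and is enough to
eyeball depth gradients and method differences.  matplotlib is imported
lazily so the core pipeline has no hard plotting dependency.
"""

from __future__ import annotations

import numpy as np

from .cohort import SourceSpace


def scatter_map(source_space: SourceSpace, values: np.ndarray, path,
                title: str = "", cmap: str = "viridis") -> None:
    """Save a 3-D scatter of per-source values as an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = np.asarray(values, dtype=float)
    if v.shape != (source_space.n_sources,):
        raise ValueError("values must be one scalar per source")
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    pos = source_space.positions
    sc = ax.scatter(pos[:, 0], pos[:, 1], pos[:, 2], c=v, cmap=cmap, s=12)
    fig.colorbar(sc, ax=ax, shrink=0.7)
    if title:
        ax.set_title(title)
    ax.set_box_aspect((1, 1, 1))
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = ["scatter_map"]
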