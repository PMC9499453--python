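"""Optional static figures: spectra overlays and similarity heatmaps."""

from __future__ import annotations

import numpy as np

from .similarity import SimilarityMatrix
from .types import Spectrum


def plot_spectra(spectra, ax=None, offset: float = 0.0):
    """Overlay absorbance spectra; ``offset`` stacks them vertically."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for k, s in enumerate(spectra):
        ax.plot(s.freq, s.absorbance + k * offset, label=s.name)
    ax.set_xlabel("frequency (THz)")
    ax.set_ylabel("absorbance (a.u.)")
    ax.legend(fontsize="small")
    return ax


def plot_similarity_matrix(m: SimilarityMatrix, ax=None):
    """Heatmap of a pairwise similarity/distance matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(m.values, cmap="viridis" if m.kind == "similarity" else "magma")
    ax.set_xticks(np.arange(len(m.names)), m.names, rotation=45, ha="right")
    ax.set_yticks(np.arange(len(m.names)), m.names)
    ax.set_title(m.metric.upper())
    ax.figure.colorbar(im, ax=ax)
    return ax
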