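"""Cosmetic plotting helpers: pseudo-color parameter maps and ROC curves."""

from __future__ import annotations

import numpy as np

from .diffusion_models import ParameterMap

__all__ = ["plot_parameter_map", "plot_roc"]


def plot_parameter_map(pmap: ParameterMap, slice_index: int | None = None, ax=None,
                       cmap: str = "jet"):
    """Show one axial slice of a parameter map as a pseudo-color image."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    k = pmap.values.shape[2] // 2 if slice_index is None else slice_index
    sl = np.where(pmap.mask[:, :, k], pmap.values[:, :, k], np.nan)
    im = ax.imshow(sl.T, origin="lower", cmap=cmap)
    ax.set_title(f"{pmap.name} (slice {k})")
    ax.figure.colorbar(im, ax=ax, label=pmap.name)
    return ax


def plot_roc(scores, labels, ax=None, label: str | None = None):
    """Plot an empirical ROC curve (higher score = positive convention)."""
    import matplotlib.pyplot as plt

    from .diagnostic_stats import roc_analysis

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    res = roc_analysis(s, y)
    work = s if res.direction == "higher" else -s
    order = np.argsort(-work, kind="stable")
    tps = np.cumsum(y[order] == 1) / max((y == 1).sum(), 1)
    fps = np.cumsum(y[order] == 0) / max((y == 0).sum(), 1)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.r_[0, fps], np.r_[0, tps],
            label=f"{label or 'marker'} (AUC={res.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax
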