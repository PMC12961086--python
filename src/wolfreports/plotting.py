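"""Quick-look plots of fitted occurrence and valence effects.

Matplotlib is imported lazily so the core analysis has no hard plotting
dependency.
"""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_occurrence_curve(results, over: str = "season", ax=None):
    """Relative occurrence (with 95% band) along one covariate.

    ``results`` is an OccurrenceResults; ``over`` one of "season",
    "zone", "footprint".
    """
    ax = _axes(ax)
    curve = results.predict_curve(over)
    g = curve["grid"].to_numpy()
    if over == "zone":
        ax.errorbar(
            g, curve["score"], yerr=[curve["score"] - curve["lower"],
                                     curve["upper"] - curve["score"]],
            fmt="o", capsize=3,
        )
    else:
        ax.plot(g, curve["score"], color="C0")
        ax.fill_between(g, curve["lower"], curve["upper"], alpha=0.25, color="C0")
    labels = {"season": "Julian day", "zone": "recolonization step",
              "footprint": "human footprint"}
    ax.set_xlabel(labels[over])
    ax.set_ylabel("relative occurrence score")
    return ax


def plot_valence_curve(results, h_scale: tuple[float, float], grid=None, ax=None):
    """Negative-valence probability along the footprint gradient.

    ``h_scale`` is the (mean, sd) used for the footprint z-transform so
    the x-axis is on the raw 0-50 index.
    """
    from scipy.special import expit

    ax = _axes(ax)
    m, s = h_scale
    hz_tr = results.model.data["H_z"].to_numpy()
    if grid is None:
        grid = np.linspace(m + s * hz_tr.min(), m + s * hz_tr.max(), 200)
    f = results.smooth_curve((np.asarray(grid) - m) / s)
    base = np.log(results.model.y.mean() / (1 - results.model.y.mean()))
    ax.plot(grid, expit(f + base), color="C3")
    ax.set_xlabel("human footprint")
    ax.set_ylabel("P(negative valence)")
    return ax
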