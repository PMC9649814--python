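"""Optional psychometric-function plot (aggregate data per group)."""

from __future__ import annotations

import numpy as np

from .psychometric import fit_group_aggregate


def plot_group_psychometric(participants, groups=("control", "ADHD"), ax=None, colors=None):
    """Aggregate proportion of "many" responses per level with the fitted
    cumulative Gaussian, one curve per group.  Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = colors or {"control": "k", "ADHD": "r"}
    for g in groups:
        res = fit_group_aggregate(participants, g)
        model = res.model
        lv = 10**model._lv
        ax.scatter(lv, model._k / model._m, color=colors.get(g, None), label=f"{g} (data)")
        grid = np.geomspace(lv.min(), lv.max(), 200)
        ax.plot(grid, res.predict(grid), color=colors.get(g, None),
                label=f"{g}: PSE={res.pse:.1f}, Wf={res.wf:.2f}")
    ax.set_xscale("log")
    ax.set_xlabel("numerosity (dots, log scale)")
    ax.set_ylabel('p("many")')
    ax.axhline(0.5, ls=":", lw=0.8, color="grey")
    ax.legend(fontsize=8)
    return ax
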