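"""Optional matplotlib helpers (not imported by the core package)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_stay_pattern(ppc_summary: pd.DataFrame,
                      observed: pd.Series | None = None, ax=None):
    """Bar plot of the four stay-probability cells with simulation HDIs.

    ``ppc_summary`` is the output of :func:`twostep.ppc.ppc_stay_summary`;
    ``observed`` (optional) overlays the empirical subject-averaged cells.
    Returns the matplotlib axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    cells = list(ppc_summary.index)
    x = np.arange(len(cells))
    mean = ppc_summary["mean"].to_numpy()
    yerr = np.vstack([mean - ppc_summary.hdi_low, ppc_summary.hdi_high - mean])
    ax.bar(x, mean, yerr=yerr, capsize=4, color="#7fb3d5",
           label="simulation (95% HDI)")
    if observed is not None:
        ax.plot(x, observed.reindex(cells).to_numpy(), "ko", label="observed")
    ax.set_xticks(x)
    ax.set_xticklabels([c.replace("_", "\n") for c in cells], fontsize=8)
    ax.set_ylabel("P(stay)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8, frameon=False)
    return ax
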