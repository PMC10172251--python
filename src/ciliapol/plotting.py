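"""Rose diagrams (circular histograms) for polarity angle samples."""

from __future__ import annotations

import math
import os
from pathlib import Path
from typing import Optional

import numpy as np

os.environ.setdefault("MPLBACKEND", "Agg")

from .circstats import circular_summary, wrap_angle

__all__ = ["rose_plot"]

_N_BINS = 18  # 20-degree sectors


def rose_plot(angles_deg, path: str | Path, title: Optional[str] = None) -> np.ndarray:
    """Circular histogram with mean-direction arrow and resultant annotation.

    18 sectors of 20 degrees; the arrow length is proportional to the mean
    resultant length R.  Returns the per-sector counts (useful for tests).
    Rendering is deterministic given the data.
    """
    import matplotlib.pyplot as plt  # deferred so a backend is only set up on use

    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("cannot plot an empty angle sample")
    a = wrap_angle(a)
    edges = np.linspace(-180.0, 180.0, _N_BINS + 1)
    counts, _ = np.histogram(a, bins=edges)
    summ = circular_summary(a)

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    centers = np.radians((edges[:-1] + edges[1:]) / 2.0)
    ax.bar(
        centers,
        counts,
        width=np.radians(360.0 / _N_BINS),
        bottom=0.0,
        color="#4878a8",
        edgecolor="white",
        linewidth=0.5,
    )
    if summ.mean_defined:
        rmax = max(counts.max(), 1)
        ax.annotate(
            "",
            xy=(math.radians(summ.mean_deg), summ.resultant_length * rmax),
            xytext=(0.0, 0.0),
            arrowprops={"arrowstyle": "-|>", "color": "crimson", "linewidth": 2.0},
        )
        label = f"n={summ.n}  R={summ.resultant_length:.2f}  mean={summ.mean_deg:.1f}°"
    else:
        label = f"n={summ.n}  R=0 (mean undefined)"
    ax.set_title(title or "", fontsize=10)
    ax.text(0.5, -0.1, label, transform=ax.transAxes, ha="center", fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return counts
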