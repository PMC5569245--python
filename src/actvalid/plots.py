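"""Bland–Altman plotting."""
from __future__ import annotations

import numpy as np

from .agreement import BlandAltmanResult


def bland_altman_plot(a, b, result: BlandAltmanResult, ax=None, title: str = ""):
    """Difference-vs-mean plot with bias and limits of agreement.

    Homoscedastic results draw horizontal LoA lines; heteroscedastic results
    draw the back-transformed function-of-the-mean LoA curves.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    m = (a + b) / 2.0
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(m, d, s=12, alpha=0.6, edgecolor="none")
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:.1f}")
    if result.log_transformed:
        grid = np.linspace(max(m.min(), 1e-9), m.max(), 200)
        half = result.loa_halfwidth(grid)
        ax.plot(grid, result.bias + half, "r--", lw=1, label="LoA (fn of mean)")
        ax.plot(grid, result.bias - half, "r--", lw=1)
    else:
        ax.axhline(result.loa_low, color="r", ls="--", lw=1, label="LoA (bias ± 2 SD)")
        ax.axhline(result.loa_high, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of methods (min/day)")
    ax.set_ylabel("difference, diary − device (min/day)")
    note = "heteroscedastic" if result.heteroscedastic else "homoscedastic"
    ax.set_title(f"{title} (tau={result.tau:.2f}, {note})".strip())
    ax.legend(loc="best", fontsize=8)
    return ax
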