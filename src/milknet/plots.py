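"""Basic plotting helpers (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def manhattan(assoc: pd.DataFrame, out_png: str, threshold: float = 5e-5) -> None:
    """Simple Manhattan plot of GC-corrected P-values for one trait."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = assoc.dropna(subset=["p_gc"]).copy()
    df["logp"] = -np.log10(df["p_gc"].clip(lower=1e-300))
    fig, ax = plt.subplots(figsize=(10, 3.5))
    offset = 0
    ticks, labels = [], []
    for c, sub in df.groupby("chrom", sort=True):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["logp"], s=4, color="C0" if int(c) % 2 else "C1")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(c))
        offset += sub["pos"].max() + 1
    ax.axhline(-np.log10(threshold), color="red", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
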