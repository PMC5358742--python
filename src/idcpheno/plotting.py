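"""Manhattan and marker-effect plots for the genetics stages."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _genome_x(chrom: np.ndarray, pos: np.ndarray):
    """Cumulative x-coordinates and per-chromosome tick centers."""
    x = np.empty(len(pos), dtype=float)
    offset = 0.0
    ticks = {}
    for c in pd.unique(chrom):
        sel = chrom == c
        p = pos[sel].astype(float)
        x[sel] = p + offset
        ticks[c] = offset + (p.min() + p.max()) / 2.0
        offset += p.max() + p.max() * 0.02
    return x, ticks


def manhattan_plot(assoc: pd.DataFrame, ax=None, fdr_line: float | None = None):
    """-log10(p) against genome position, colored by chromosome.

    ``fdr_line``, if given, is the largest p-value called significant
    (drawn as a dashed threshold line).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    chrom = assoc["chrom"].to_numpy()
    x, ticks = _genome_x(chrom, assoc["pos"].to_numpy())
    logp = -np.log10(np.clip(assoc["p"].to_numpy(), 1e-300, None))
    for i, c in enumerate(pd.unique(chrom)):
        sel = chrom == c
        ax.scatter(x[sel], logp[sel], s=6,
                   color="tab:blue" if i % 2 == 0 else "tab:gray")
    if fdr_line is not None and fdr_line > 0:
        ax.axhline(-np.log10(fdr_line), ls="--", color="tab:red", lw=1)
    ax.set_xticks(list(ticks.values()), list(ticks.keys()), rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_xlabel("chromosome")
    return ax


def marker_effect_plot(profile: pd.DataFrame, ax=None):
    """Shrunken marker effects across the genome (RR-BLUP profile)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    chrom = profile["chrom"].to_numpy()
    x, ticks = _genome_x(chrom, profile["pos"].to_numpy())
    for i, c in enumerate(pd.unique(chrom)):
        sel = chrom == c
        ax.scatter(x[sel], profile["effect"].to_numpy()[sel], s=6,
                   color="tab:green" if i % 2 == 0 else "tab:gray")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xticks(list(ticks.values()), list(ticks.keys()), rotation=90, fontsize=7)
    ax.set_ylabel("marker effect")
    ax.set_xlabel("chromosome")
    return ax
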