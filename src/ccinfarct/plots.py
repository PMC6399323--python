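"""Genome-scan figures: LOD curves with thresholds, founder coefficient tracks."""

from __future__ import annotations

import numpy as np

from .qtl import QTLScan, Thresholds
from .simulate import FOUNDER_NAMES

_THRESHOLD_STYLE = {0.05: ("red", "-"), 0.10: ("orange", "--"), 0.63: ("gray", ":")}


def plot_lod(qscan: QTLScan, thresholds: Thresholds | None = None, ax=None):
    """LOD along the genome, chromosomes laid end to end, threshold lines overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for chrom in dict.fromkeys(qscan.chrom):
        sel = qscan.chrom == chrom
        x = qscan.pos[sel] + offset
        ax.plot(x / 1e6, qscan.lod[sel], lw=1, label=str(chrom))
        offset += qscan.pos[sel].max()
    if thresholds is not None:
        for alpha, cut in thresholds.cutoffs.items():
            color, ls = _THRESHOLD_STYLE.get(alpha, ("black", "-"))
            ax.axhline(cut, color=color, ls=ls, lw=0.8, label=f"P={alpha}")
    ax.set_xlabel("position (Mb, chromosomes concatenated)")
    ax.set_ylabel("LOD")
    ax.set_title(qscan.trait)
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_founder_coefficients(qscan: QTLScan, chrom: str, ax=None):
    """Centered founder-effect tracks along one chromosome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    sel = qscan.chrom == chrom
    x = qscan.pos[sel] / 1e6
    for k in range(8):
        ax.plot(x, qscan.coef[sel, k], lw=1, label=FOUNDER_NAMES[k])
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel(f"{chrom} position (Mb)")
    ax.set_ylabel("founder effect")
    ax.legend(fontsize=7, ncol=4)
    return ax
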