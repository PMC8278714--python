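"""Manhattan and QQ plot rendering (PNG/SVG by file extension)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .association import manhattan_table  # noqa: E402


def render_manhattan(results: pd.DataFrame, threshold: float | None, out_path) -> None:
    """Manhattan plot: -log10 p against cumulative SNP order, chromosomes
    alternately shaded, horizontal FDR line when a threshold exists."""
    table, offsets = manhattan_table(results)
    fig, ax = plt.subplots(figsize=(10, 3.5))
    if len(table):
        chroms = list(dict.fromkeys(table["chromosome"]))
        for ci, chrom in enumerate(chroms):
            sub = table[table["chromosome"] == chrom]
            ax.scatter(
                sub["x"], sub["minus_log10_p"], s=8,
                color="#3b6ea5" if ci % 2 == 0 else "#9bb7d4",
            )
        ticks = [offsets[c] + (table["chromosome"] == c).sum() / 2 for c in chroms]
        ax.set_xticks(ticks)
        ax.set_xticklabels(chroms, fontsize=8)
    if threshold is not None:
        ax.axhline(threshold, color="blue", lw=1)
    else:
        ax.set_title("FDR threshold was not met", fontsize=9)
    ax.set_xlabel("chromosome (SNP order)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def render_qq(p, out_path) -> None:
    """Observed vs expected -log10 p with the identity line."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values to plot")
    obs = -np.log10(np.clip(np.sort(p), 1e-300, 1.0))[::-1]
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(exp, obs, s=8, color="#3b6ea5")
    lim = max(float(exp.max()), float(obs.max()), 1.0)
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
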