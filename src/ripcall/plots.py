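"""Optional matplotlib figures mirroring the standard RIP-seq panels."""

from __future__ import annotations

from pathlib import Path
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def region_bar(region_df: pd.DataFrame, path: Path) -> None:
    """Grouped bar chart of per-sample region fractions."""
    fig, ax = plt.subplots(figsize=(6, 4))
    if "sample" in region_df.columns:
        pivot = region_df.pivot_table(index="region", columns="sample",
                                      values="fraction", fill_value=0.0)
        pivot.plot.bar(ax=ax)
    else:
        ax.bar(region_df["region"], region_df["fraction"])
    ax.set_ylabel("fraction of reads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def correlation_heatmap(corr: pd.DataFrame, order: list[str],
                        path: Path) -> None:
    """Clustered Pearson-correlation heatmap between samples."""
    mat = corr.loc[order, order]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    fig.colorbar(im, ax=ax, label="Pearson r (log2 RPKM)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def rpkm_scatter(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                 labels: tuple[str, str], path: Path) -> None:
    """log-log RPKM scatter between two samples."""
    merged = expr_a.merge(expr_b, on="gene_id", suffixes=("_a", "_b"))
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(np.log2(merged["rpkm_a"] + 1), np.log2(merged["rpkm_b"] + 1),
               s=8, alpha=0.6)
    ax.set_xlabel(f"log2 RPKM+1 ({labels[0]})")
    ax.set_ylabel(f"log2 RPKM+1 ({labels[1]})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
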