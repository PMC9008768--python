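"""Basic diagnostic plots: rate heatmap and Manhattan-style VEP panel."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rate_heatmap", "vep_manhattan"]


def rate_heatmap(rates: pd.DataFrame, groups: pd.Series, ax=None):
    """Heatmap of predicted rates, rows (subjects) ordered by group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    order = groups.reindex(rates.index).sort_values(kind="stable").index
    M = rates.loc[order]
    lim = np.nanmax(np.abs(M.to_numpy())) or 1.0
    im = ax.imshow(M.to_numpy(), aspect="auto", cmap="coolwarm", vmin=-lim, vmax=lim)
    ax.set_xlabel("ROI")
    ax.set_ylabel("subject (grouped CN/MCI/AD)")
    ax.figure.colorbar(im, ax=ax, label="rate of change / month")
    return ax


def vep_manhattan(
    vip_table: pd.DataFrame,
    snps: pd.DataFrame,
    n_bootstrap: int,
    ax=None,
    priority_cut: float = 0.5,
    top_cut: float = 0.9,
):
    """-log10(VEP) per SNP, grouped by linkage region, with the priority
    and top-hit cut-offs as reference lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    merged = vip_table.merge(snps[["snp_id", "chrom", "bp", "region"]], on="snp_id")
    merged = merged.sort_values(["chrom", "bp"]).reset_index(drop=True)
    eps = 1.0 / (2.0 * n_bootstrap)
    y = -np.log10(np.clip(merged["vep"], eps, None))
    regions = merged["region"].fillna("unassigned")
    for i, reg in enumerate(pd.unique(regions)):
        mask = (regions == reg).to_numpy()
        ax.scatter(np.flatnonzero(mask), y[mask], s=8, label=str(reg))
    ax.axhline(-np.log10(1 - priority_cut), ls="--", c="gray", lw=0.8)
    ax.axhline(-np.log10(1 - top_cut), ls=":", c="gray", lw=0.8)
    ax.set_xlabel("SNP (by position within region)")
    ax.set_ylabel(r"$-\log_{10}$(VEP)")
    ax.legend(fontsize=7, ncol=2)
    return ax
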