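"""Simple ERD figures: group-mean bars and age scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def erd_bar_plot(erd: pd.DataFrame, meta: pd.DataFrame, path) -> Path:
    """Group-mean ERD% (± SE) per band × region, one bar group per genotype."""
    data = erd.merge(meta[["subject_id", "clu_group"]], on="subject_id")
    agg = data.groupby(["band", "region", "clu_group"])["erd_percent"].agg(["mean", "sem"])
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    for ax, band in zip(axes, sorted(data["band"].unique())):
        sub = agg.loc[band].reset_index()
        groups = sorted(sub["clu_group"].unique())
        width = 0.35
        for gi, grp in enumerate(groups):
            g = sub[sub["clu_group"] == grp]
            x = [i + (gi - 0.5) * width for i in range(len(g))]
            ax.bar(x, g["mean"], width, yerr=g["sem"], capsize=3, label=grp)
        ax.set_xticks(range(len(sub["region"].unique())))
        ax.set_xticklabels(sorted(sub["region"].unique()))
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(band)
    axes[0].set_ylabel("ERD/S (%)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def age_scatter_plot(erd: pd.DataFrame, meta: pd.DataFrame, path,
                     band: str = "alpha2", region: str = "Fs") -> Path:
    """Age vs ERD% scatter by genotype group with least-squares lines."""
    data = erd.merge(meta[["subject_id", "clu_group", "age"]], on="subject_id")
    data = data[(data["band"] == band) & (data["region"] == region)]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for grp, sub in data.groupby("clu_group"):
        ax.scatter(sub["age"], sub["erd_percent"], s=14, label=grp, alpha=0.7)
        if len(sub) >= 3:
            import numpy as np

            coef = np.polyfit(sub["age"], sub["erd_percent"], 1)
            xs = np.linspace(sub["age"].min(), sub["age"].max(), 10)
            ax.plot(xs, np.polyval(coef, xs), lw=1)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"{band} ERD/S (%), {region}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
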