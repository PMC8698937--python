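"""Mean-methylation summaries by CpG annotation context."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .manifest_io import Manifest

AXES = ("island_relation", "gene_region")


def summarize_context(
    beta: pd.DataFrame,
    manifest: Manifest,
    groups: Optional[Sequence[str]] = None,
    axis: str = "island_relation",
) -> pd.DataFrame:
    """Mean β per annotation category, overall and per sample group.

    The per-group mean is the plain mean over all (CpG-in-category,
    sample-in-group) cells; for complete matrices this equals the mean of
    per-sample category means. Category n values sum to the manifest size.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    mdf = manifest.to_frame()
    if not mdf.index.equals(beta.index):
        beta = beta.reindex(mdf.index)
        if beta.isna().any().any():
            raise ValueError("beta matrix does not cover the manifest")
    categories = mdf[axis].to_numpy()
    group_labels = (
        np.asarray(groups) if groups is not None else np.array(["all"] * beta.shape[1])
    )
    if len(group_labels) != beta.shape[1]:
        raise ValueError("groups must align with beta columns")
    vals = beta.to_numpy(float)
    rows = []
    for cat in pd.unique(categories):
        mask = categories == cat
        rows.append(
            {"category": cat, "group": "all", "mean_beta": float(vals[mask].mean()),
             "n_cpgs": int(mask.sum())}
        )
        if groups is not None:
            for g in pd.unique(group_labels):
                sub = vals[np.ix_(mask, group_labels == g)]
                rows.append(
                    {"category": cat, "group": str(g), "mean_beta": float(sub.mean()),
                     "n_cpgs": int(mask.sum())}
                )
    return pd.DataFrame(rows, columns=["category", "group", "mean_beta", "n_cpgs"])


def category_means(summary: pd.DataFrame, group: str = "all") -> dict:
    sub = summary[summary["group"] == group]
    return dict(zip(sub["category"], sub["mean_beta"]))


def plot_context(summary: pd.DataFrame, path) -> None:
    """Optional bar-chart export (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary["group"] == "all"]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(sub["category"], sub["mean_beta"], color="steelblue")
    ax.set_ylabel("mean β")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
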