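"""Basic figure export for delta tables (strip plots by percentile)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import PERCENTILES

_TREATMENT_COLORS = {
    "oxygen": "tab:blue",
    "combination_analgesic": "tab:orange",
    "unspecified": "tab:green",
    "none": "tab:gray",
    "sumatriptan_sc": "tab:red",
    "zolmitriptan_nasal": "tab:purple",
}


def save_delta_stripplot(delta_df: pd.DataFrame, path, title: str = None) -> None:
    """One strip of per-attack deltas per percentile, colored by treatment."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for j, q in enumerate(PERCENTILES):
        sub = delta_df[delta_df["percentile"] == q]
        for _, row in sub.iterrows():
            ax.plot(
                j + (hash((row["attack_id"], q)) % 100 - 50) / 400.0,
                row["delta"],
                "o",
                color=_TREATMENT_COLORS.get(row["treatment"], "black"),
                alpha=0.8,
                markersize=5,
            )
    ax.axhline(0.0, color="black", lw=0.8, ls="--")
    ax.set_xticks(range(len(PERCENTILES)), [f"p{q}" for q in PERCENTILES])
    ax.set_ylabel("ΔAI (attack − matched non-attack), g")
    if title:
        ax.set_title(title)
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=c, label=t)
        for t, c in _TREATMENT_COLORS.items()
        if t in set(delta_df["treatment"])
    ]
    if handles:
        ax.legend(handles=handles, fontsize=8, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_bin_boxplot(bin_delta_df: pd.DataFrame, path, percentile: int = 90) -> None:
    """Onset-relative delta distributions at one percentile."""
    from .intervals import ONSET_BINS

    order = [b for b, _, _ in ONSET_BINS]
    sub = bin_delta_df[bin_delta_df["percentile"] == percentile]
    data, labels = [], []
    for b in order:
        vals = sub[sub["scope"] == b]["delta"].to_numpy()
        if vals.size:
            data.append(vals)
            labels.append(f"{b}\n(N={vals.size})")
    fig, ax = plt.subplots(figsize=(8, 4))
    if data:
        ax.boxplot(data, tick_labels=labels)
    ax.axhline(0.0, color="black", lw=0.8, ls="--")
    ax.set_ylabel(f"ΔAI at p{percentile}, g")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
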