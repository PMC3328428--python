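"""Optional matplotlib figures: ratio histograms and the dosage profile."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dosage_analysis import PROFILE_CLASSES, YX_BIN_LABELS


def plot_yx_histogram(records_df: pd.DataFrame, path: str | Path) -> None:
    """Histogram of per-contig male Y/X expression ratios with the median."""
    yx = records_df["yx_ratio"].to_numpy()
    yx = yx[np.isfinite(yx)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(yx, bins=np.arange(0, max(3.0, yx.max() if yx.size else 3.0) + 0.1, 0.1))
    if yx.size:
        ax.axvline(np.median(yx), color="red", label=f"median = {np.median(yx):.2f}")
        ax.legend()
    ax.set_xlabel("Y/X expression ratio (males)")
    ax.set_ylabel("contigs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_xm2xf_histogram(records_df: pd.DataFrame, path: str | Path) -> None:
    """Xmale/2Xfemale distributions split by Y/X ratio category."""
    groups = [
        ("Y/X < 0.5", records_df["yx_ratio"] < 0.5),
        ("0.5 <= Y/X < 1", (records_df["yx_ratio"] >= 0.5) & (records_df["yx_ratio"] < 1.0)),
        ("1 <= Y/X < 1.5", (records_df["yx_ratio"] >= 1.0) & (records_df["yx_ratio"] < 1.5)),
        ("Y/X >= 1.5", records_df["yx_ratio"] >= 1.5),
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.arange(0, 3.05, 0.1)
    for label, mask in groups:
        vals = records_df.loc[mask, "xm2xf_ratio"].to_numpy()
        vals = vals[np.isfinite(vals)]
        if not vals.size:
            continue
        ax.hist(vals, bins=bins, histtype="step", label=f"{label} (median {np.median(vals):.2f})")
    ax.axvline(0.5, color="grey", linestyle=":")
    ax.axvline(1.0, color="grey", linestyle=":")
    ax.set_xlabel("Xmale / 2Xfemale expression ratio")
    ax.set_ylabel("contigs")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dosage_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Grouped bars of rescaled per-bin medians with bootstrap CIs."""
    bins = [b for b in YX_BIN_LABELS if b in set(profile["yx_bin"])]
    x = np.arange(len(bins))
    width = 0.2
    fig, ax = plt.subplots(figsize=(8, 4))
    for k, cls in enumerate(PROFILE_CLASSES):
        sub = profile[profile["allele_class"] == cls].set_index("yx_bin").reindex(bins)
        med = sub["median_rescaled"].to_numpy()
        err = np.vstack(
            [med - sub["ci_low"].to_numpy(), sub["ci_high"].to_numpy() - med]
        )
        err = np.where(np.isfinite(err), np.clip(err, 0, None), 0)
        ax.bar(x + (k - 1.5) * width, med, width, yerr=err, capsize=2, label=cls)
    ax.axhline(1.0, color="grey", linestyle=":")
    ax.set_xticks(x)
    ax.set_xticklabels(bins, fontsize=8)
    ax.set_xlabel("Y/X expression ratio bin")
    ax.set_ylabel("median expression / female median")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
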