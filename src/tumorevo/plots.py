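"""Static report figures (presence heatmap, logR tracks with segments)."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_presence_heatmap(presence: pd.DataFrame, path: str | Path) -> None:
    """Mutation x region presence/absence heatmap."""
    try:
        fig, ax = plt.subplots(
            figsize=(max(4, 0.4 * presence.shape[1]), max(3, 0.12 * presence.shape[0]))
        )
        ax.imshow(presence.values, aspect="auto", cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(presence.shape[1]), presence.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(presence.shape[0]), presence.index, fontsize=4)
        ax.set_xlabel("region")
        ax.set_title("validated mutation presence")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    except Exception as exc:  # plotting never aborts the pipeline
        warnings.warn(f"presence heatmap failed: {exc}")


def plot_logr_tracks(
    tracks: dict[str, pd.DataFrame],
    segments: pd.DataFrame | None,
    path: str | Path,
) -> None:
    """Per-region logR scatter with fitted segment means overlaid."""
    try:
        samples = list(tracks)
        fig, axes = plt.subplots(len(samples), 1, sharex=True,
                                 figsize=(8, 1.2 * len(samples) + 1), squeeze=False)
        # lay chromosomes end to end on one axis
        first = tracks[samples[0]]
        offsets, off = {}, 0
        for chrom in pd.unique(first.chrom):
            offsets[chrom] = off
            off += int(first.loc[first.chrom == chrom, "end"].max())
        for ax, s in zip(axes.ravel(), samples):
            t = tracks[s]
            x = t["start"].to_numpy() + np.array([offsets[c] for c in t["chrom"]])
            ax.plot(x, t["logr"], ".", ms=1, color="grey")
            if segments is not None:
                sub = segments[segments["sample"] == s] if "sample" in segments else segments
                for _, seg in sub.iterrows():
                    o = offsets[str(seg.chrom)]
                    col = "mean_logr" if "mean_logr" in seg else None
                    if col:
                        ax.hlines(seg[col], seg.start + o, seg.end + o, color="red", lw=1.5)
            ax.set_ylabel(s, fontsize=6)
        axes.ravel()[-1].set_xlabel("genome position")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    except Exception as exc:
        warnings.warn(f"logR plot failed: {exc}")
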