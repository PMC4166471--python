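"""logR preprocessing, exact multi-sample joint segmentation, breakpoints.

Preprocessing removes a GC trend (local regression), quantile-normalizes
each sample against the patient-average distribution, and Winsorizes
outliers at median +/- k*MAD. Segmentation is an exact piecewise-constant
fit shared across all samples of a patient: a dynamic program minimises

    sum_samples sum_bins (logR - segment mean)^2 + gamma * n_breakpoints

per chromosome, with breakpoints common to every sample. The O(n^2 * S)
exact optimum is affordable at the bin counts this package works with and
doubles as a clean oracle contract for tests. Ties break toward fewer
breakpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentationConfig",
    "RawSegment",
    "preprocess_logr",
    "joint_segment",
    "merge_segments",
    "map_breakpoint",
    "drop_excluded",
]

MAD_SCALE = 1.4826  # consistency factor for a Gaussian


@dataclass(frozen=True)
class SegmentationConfig:
    """Joint segmentation settings.

    gamma is the per-breakpoint penalty on the summed-SSE scale; the
    default matches the published genome-wide setting and should be scaled
    down for small bin counts (see docs/methods.md).
    """

    gamma: float = 1000.0
    winsor_k: float = 2.5
    excluded_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class RawSegment:
    chrom: str
    start: int
    end: int
    mean_logr: dict[str, float]   # per sample
    n_bins: int


def drop_excluded(
    track: pd.DataFrame,
    excluded: Sequence[tuple[str, int, int]] = (),
    drop_sex: bool = True,
) -> pd.DataFrame:
    """Remove bins on sex chromosomes or overlapping blacklist intervals."""
    keep = np.ones(len(track), dtype=bool)
    if drop_sex:
        sex = {"X", "Y", "chrX", "chrY"}
        keep &= ~track["chrom"].astype(str).isin(sex)
    for chrom, start, end in excluded:
        hit = (track["chrom"].astype(str) == str(chrom)) & \
              (track["end"] >= start) & (track["start"] <= end)
        keep &= ~hit
    return track.loc[keep].reset_index(drop=True)


def _gc_correct(logr: np.ndarray, gc: np.ndarray, span: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if np.ptp(gc) == 0:
        warnings.warn("constant GC vector: skipping GC correction")
        return logr
    trend = lowess(logr, gc, frac=span, return_sorted=False)
    corrected = logr - trend
    return corrected + np.median(logr) - np.median(corrected)  # keep the level


def _quantile_normalize(columns: pd.DataFrame) -> pd.DataFrame:
    """Map each column onto the mean of the per-column order statistics."""
    ranks = columns.rank(method="first").astype(int) - 1
    target = np.sort(columns.values, axis=0).mean(axis=1)
    return columns.apply(lambda col: target[ranks[col.name].values])


def _winsorize(values: np.ndarray, k: float, window: int = 5) -> np.ndarray:
    """Clamp each bin to running-median +/- k*MAD of the residuals.

    The sliding window keeps multi-bin copy-number segments intact (the
    local median tracks the segment level) while single-bin outliers are
    pulled back to the local level.
    """
    n = len(values)
    if n == 0:
        return values
    w = min(window, n if n % 2 == 1 else n - 1)
    runmed = (pd.Series(values).rolling(w, center=True, min_periods=1)
              .median().to_numpy())
    resid = values - runmed
    mad = MAD_SCALE * np.median(np.abs(resid - np.median(resid)))
    if mad == 0:
        return values
    return runmed + np.clip(resid, -k * mad, k * mad)


def preprocess_logr(
    tracks: Mapping[str, pd.DataFrame],
    winsor_k: float = 2.5,
    gc_span: float = 0.3,
    quantile_normalize: bool = True,
) -> dict[str, pd.DataFrame]:
    """Normalize per-region logR tracks (GC-correct, quantile-normalize
    across the patient's samples, Winsorize within a sliding window per
    chromosome).

    Each track needs columns chrom/start/end/gc/logr on an identical bin
    grid. Steps run in the fixed order listed.
    """
    samples = list(tracks)
    if not samples:
        raise ValueError("no tracks supplied")
    first = tracks[samples[0]]
    if len(first) < 10:
        raise ValueError("need at least 10 bins")
    out = {}
    for s in samples:
        t = tracks[s].reset_index(drop=True).copy()
        t["logr"] = _gc_correct(t["logr"].to_numpy(float), t["gc"].to_numpy(float), gc_span)
        out[s] = t

    mat = pd.DataFrame({s: out[s]["logr"].values for s in samples})
    if quantile_normalize:
        mat = _quantile_normalize(mat)
    for s in samples:
        t = out[s]
        t["logr"] = mat[s].values
        t["logr"] = np.concatenate([
            _winsorize(t.loc[t.chrom == c, "logr"].to_numpy(float), winsor_k)
            for c in pd.unique(t.chrom)
        ])
    return out


def _segment_chrom(Y: np.ndarray, gamma: float) -> list[tuple[int, int]]:
    """Exact DP over one chromosome. Y is bins x samples. Returns segment
    (start_bin, end_bin) index pairs, inclusive."""
    n, S = Y.shape
    c1 = np.vstack([np.zeros(S), np.cumsum(Y, axis=0)])          # prefix sums
    c2 = np.vstack([np.zeros(S), np.cumsum(Y ** 2, axis=0)])

    def cost(i: int, j: int) -> float:
        # summed SSE of bins i..j (inclusive) across samples
        m = j - i + 1
        s1 = c1[j + 1] - c1[i]
        s2 = c2[j + 1] - c2[i]
        return float(np.sum(s2 - s1 ** 2 / m))

    # best[j] = (objective, n_segments) for bins 0..j; ties -> fewer segments
    best = [(0.0, 0)] * (n + 1)
    back = [0] * (n + 1)
    for j in range(1, n + 1):
        cand = (np.inf, np.inf)
        arg = 0
        for i in range(j):
            prev_obj, prev_k = best[i]
            penalty = gamma if i > 0 else 0.0
            obj = prev_obj + cost(i, j - 1) + penalty
            better = obj < cand[0] - 1e-12 or (
                abs(obj - cand[0]) <= 1e-12 and prev_k + 1 < cand[1]
            )
            if better:
                cand = (obj, prev_k + 1)
                arg = i
        best[j] = cand
        back[j] = arg
    # traceback
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j - 1))
        j = i
    return bounds[::-1]


def joint_segment(
    tracks: Mapping[str, pd.DataFrame],
    config: SegmentationConfig | float = SegmentationConfig(),
) -> list[RawSegment]:
    """Jointly segment all regions of a patient into shared-breakpoint
    segments of constant logR (exact penalized least squares optimum)."""
    if isinstance(config, (int, float)):
        config = SegmentationConfig(gamma=float(config))
    samples = list(tracks)
    if not samples:
        raise ValueError("no tracks supplied")
    grid = tracks[samples[0]][["chrom", "start", "end"]].reset_index(drop=True)
    for s in samples[1:]:
        other = tracks[s][["chrom", "start", "end"]].reset_index(drop=True)
        if not grid.equals(other):
            raise ValueError(f"bin grid of sample {s!r} does not match")

    segments: list[RawSegment] = []
    for chrom in pd.unique(grid.chrom):
        mask = (grid.chrom == chrom).to_numpy()
        sub = grid.loc[mask].reset_index(drop=True)
        Y = np.column_stack([
            tracks[s].reset_index(drop=True).loc[mask, "logr"].to_numpy(float)
            for s in samples
        ])
        for i, j in _segment_chrom(Y, config.gamma):
            means = {s: float(Y[i:j + 1, k].mean()) for k, s in enumerate(samples)}
            segments.append(RawSegment(
                chrom=str(chrom),
                start=int(sub.loc[i, "start"]),
                end=int(sub.loc[j, "end"]),
                mean_logr=means,
                n_bins=j - i + 1,
            ))
    return segments


def merge_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-chromosome segments with equal total copy,
    minor copy and clonality; means are recomputed weighted by n_bins.

    Expects sorted columns chrom/start/end/n_bins/q/nB/clonal plus any
    mean-logR columns (merged by weighted average). Idempotent.
    """
    if segments.empty:
        return segments.copy()
    mean_cols = [c for c in segments.columns if c.startswith("mean_logr")]
    rows = []
    for _, seg in segments.iterrows():
        seg = seg.copy()
        if rows:
            prev = rows[-1]
            same = (prev["chrom"] == seg["chrom"]
                    and prev["q"] == seg["q"] and prev["nB"] == seg["nB"]
                    and bool(prev["clonal"]) == bool(seg["clonal"])
                    and prev["end"] + 1 == seg["start"])
            if same:
                w1, w2 = prev["n_bins"], seg["n_bins"]
                for c in mean_cols:
                    prev[c] = (prev[c] * w1 + seg[c] * w2) / (w1 + w2)
                prev["end"] = seg["end"]
                prev["n_bins"] = w1 + w2
                continue
        rows.append(seg)
    return pd.DataFrame(rows).reset_index(drop=True)


def map_breakpoint(
    position: int,
    annotation: pd.DataFrame,
    chrom: str = "3",
) -> tuple[str, int]:
    """Label a breakpoint with the containing annotation feature, or the
    nearest feature and its distance in bases.

    ``annotation`` holds 1-based inclusive chrom/start/end/name rows.
    """
    feats = annotation[annotation["chrom"].astype(str) == str(chrom)]
    if feats.empty:
        raise ValueError(f"annotation does not cover chromosome {chrom}")
    best_name, best_dist = None, None
    for _, f in feats.iterrows():
        if f.start <= position <= f.end:
            return str(f["name"]), 0
        dist = int(min(abs(position - f.start), abs(position - f.end)))
        if best_dist is None or dist < best_dist:
            best_name, best_dist = str(f["name"]), dist
    return best_name, best_dist
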