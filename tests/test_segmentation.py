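"""logR preprocessing, exact joint segmentation and breakpoint annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tumorevo.segmentation import (SegmentationConfig, drop_excluded, joint_segment,
                                   map_breakpoint, merge_segments, preprocess_logr)
from tumorevo.simulate import chr3_annotation


def make_track(logr, gc=None, chrom="1"):
    n = len(logr)
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * 100_000 + 1,
        "end": (np.arange(n) + 1) * 100_000,
        "gc": gc if gc is not None else rng.uniform(0.4, 0.6, n),
        "logr": np.asarray(logr, dtype=float),
    })


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_gc_trend_removed():
    rng = np.random.default_rng(1)
    gc = rng.uniform(0.3, 0.7, 2000)
    logr = 0.8 * (gc - 0.5) + rng.normal(0, 0.05, 2000)
    out = preprocess_logr({"s": make_track(logr, gc=gc)})["s"]
    assert abs(np.corrcoef(out.logr, gc)[0, 1]) < 0.05
    # the level is preserved, not re-centred arbitrarily
    assert abs(np.median(out.logr) - np.median(logr)) < 0.02


def test_single_bin_outlier_clamped():
    rng = np.random.default_rng(2)
    logr = rng.normal(0, 0.05, 100)
    logr[50] = 3.0
    out = preprocess_logr({"s": make_track(logr)})["s"]
    assert out.logr.iloc[50] < 1.0


def test_real_segment_survives_winsorization():
    rng = np.random.default_rng(3)
    logr = rng.normal(0, 0.05, 100)
    logr[40:60] -= 0.6  # a genuine 20-bin loss
    out = preprocess_logr({"s": make_track(logr)})["s"]
    assert out.logr.iloc[45:55].mean() < -0.5


def test_quantile_normalization_identity_for_identical_samples():
    rng = np.random.default_rng(4)
    logr = rng.normal(0, 0.1, 200)
    tracks = {"a": make_track(logr), "b": make_track(logr)}
    out = preprocess_logr(tracks)
    np.testing.assert_allclose(out["a"].logr, out["b"].logr)


def test_quantile_normalize_flag():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 0.1, 100), rng.normal(0.3, 0.2, 100)
    gc = rng.uniform(0.4, 0.6, 100)
    out = preprocess_logr({"a": make_track(a, gc=gc), "b": make_track(b, gc=gc)},
                          quantile_normalize=False)
    # without QN the level difference between samples persists
    assert out["b"].logr.mean() - out["a"].logr.mean() > 0.15


def test_constant_gc_warns_and_skips():
    logr = np.zeros(20)
    with pytest.warns(UserWarning, match="constant GC"):
        preprocess_logr({"s": make_track(logr, gc=np.full(20, 0.5))})


def test_too_few_bins_errors():
    with pytest.raises(ValueError):
        preprocess_logr({"s": make_track(np.zeros(5))})
    with pytest.raises(ValueError):
        preprocess_logr({})


# ---------------------------------------------------------------------------
# joint segmentation
# ---------------------------------------------------------------------------

def brute_force_objective(Y, gamma):
    """Optimum of the penalized SSE over all breakpoint subsets."""
    n = Y.shape[0]
    best = np.inf
    for k in range(n):
        for cuts in itertools.combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            sse = sum(
                ((Y[i:j] - Y[i:j].mean(axis=0)) ** 2).sum()
                for i, j in zip(bounds, bounds[1:])
            )
            best = min(best, sse + gamma * k)
    return best


def segmentation_objective(segments, tracks, gamma):
    sse = 0.0
    for seg in segments:
        for s, t in tracks.items():
            mask = (t.chrom == seg.chrom) & (t.start >= seg.start) & (t.end <= seg.end)
            vals = t.loc[mask, "logr"].to_numpy()
            sse += ((vals - vals.mean()) ** 2).sum()
    return sse + gamma * (len(segments) - 1)


def test_step_signal_recovered():
    logr = np.r_[np.zeros(50), np.full(50, -0.8)]
    segs = joint_segment({"s": make_track(logr)}, SegmentationConfig(gamma=1.0))
    assert len(segs) == 2
    assert segs[0].end == 50 * 100_000
    assert segs[1].mean_logr["s"] == pytest.approx(-0.8)
    assert segs[0].n_bins == segs[1].n_bins == 50


def test_large_gamma_gives_single_segment():
    logr = np.r_[np.zeros(20), np.full(20, -0.8)]
    segs = joint_segment({"s": make_track(logr)}, SegmentationConfig(gamma=1e6))
    assert len(segs) == 1


def test_shared_breakpoints_across_samples():
    a = np.r_[np.zeros(30), np.full(30, -0.6)]
    b = np.r_[np.zeros(30), np.full(30, 0.5)]
    segs = joint_segment({"a": make_track(a), "b": make_track(b)}, 1.0)
    assert len(segs) == 2
    assert segs[1].mean_logr == pytest.approx({"a": -0.6, "b": 0.5})


def test_tie_breaks_toward_fewer_segments():
    # splitting [0,0,1,1] saves SSE exactly 1.0; at gamma=1.0 it is a tie
    segs = joint_segment({"s": make_track([0.0, 0.0, 1.0, 1.0])},
                         SegmentationConfig(gamma=1.0))
    assert len(segs) == 1


def test_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(4, 11))
        n_samples = int(rng.integers(1, 4))
        Y = rng.normal(0, 0.3, (n, n_samples))
        if rng.random() < 0.7:
            cut = int(rng.integers(1, n))
            Y[cut:] += rng.normal(0, 1.0, n_samples)
        gamma = float(rng.uniform(0.05, 2.0))
        tracks = {f"s{k}": make_track(Y[:, k]) for k in range(n_samples)}
        segs = joint_segment(tracks, SegmentationConfig(gamma=gamma))
        assert segmentation_objective(segs, tracks, gamma) == pytest.approx(
            brute_force_objective(Y, gamma), abs=1e-9)


def test_grid_mismatch_errors():
    a = make_track(np.zeros(20))
    b = make_track(np.zeros(20))
    b.loc[0, "start"] = 42
    with pytest.raises(ValueError, match="grid"):
        joint_segment({"a": a, "b": b}, 1.0)


def test_chromosomes_segmented_independently():
    t = pd.concat([make_track(np.zeros(20), chrom="1"),
                   make_track(np.full(20, -1.0), chrom="2")], ignore_index=True)
    segs = joint_segment({"s": t}, SegmentationConfig(gamma=0.5))
    assert [(s.chrom, s.n_bins) for s in segs] == [("1", 20), ("2", 20)]


# ---------------------------------------------------------------------------
# merging, breakpoints, exclusions
# ---------------------------------------------------------------------------

def test_merge_segments_weighted_and_idempotent():
    table = pd.DataFrame([
        dict(chrom="1", start=1, end=100, n_bins=1, q=2, nB=1, clonal=True,
             mean_logr=0.0),
        dict(chrom="1", start=101, end=300, n_bins=2, q=2, nB=1, clonal=True,
             mean_logr=0.3),
        dict(chrom="1", start=301, end=400, n_bins=1, q=1, nB=0, clonal=True,
             mean_logr=-0.5),
    ])
    merged = merge_segments(table)
    assert len(merged) == 2
    assert merged.loc[0, "end"] == 300 and merged.loc[0, "n_bins"] == 3
    assert merged.loc[0, "mean_logr"] == pytest.approx(0.2)
    pd.testing.assert_frame_equal(merge_segments(merged), merged)


def test_merge_requires_adjacency():
    table = pd.DataFrame([
        dict(chrom="1", start=1, end=100, n_bins=1, q=2, nB=1, clonal=True),
        dict(chrom="1", start=201, end=300, n_bins=1, q=2, nB=1, clonal=True),
    ])
    assert len(merge_segments(table)) == 2


def test_map_breakpoint_labels():
    ann = chr3_annotation()
    assert map_breakpoint(1_200_001, ann) == ("CLRN1", 0)
    assert map_breakpoint(2_400_001, ann) == ("ALCAM", 0)
    assert map_breakpoint(5_100_001, ann) == ("centromere", 0)
    assert map_breakpoint(4_200_001, ann) == ("BFSP2", 0)
    name, dist = map_breakpoint(1_300_000, ann)
    assert name == "CLRN1" and dist == 50_000
    with pytest.raises(ValueError):
        map_breakpoint(100, ann, chrom="17")


def test_drop_excluded():
    t = pd.concat([make_track(np.zeros(10), chrom="1"),
                   make_track(np.zeros(10), chrom="X")], ignore_index=True)
    out = drop_excluded(t)
    assert set(out.chrom) == {"1"}
    out = drop_excluded(t, excluded=[("1", 1, 250_000)], drop_sex=False)
    assert len(out[out.chrom == "1"]) == 7  # bins overlapping 1-250k removed
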