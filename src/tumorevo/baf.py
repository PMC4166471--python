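"""Mirrored B-allele frequencies, purity adjustment and imbalance tests.

At a heterozygous SNP the B-allele frequency of an admixed tumor sample is

    BAF = ((1-rho) + rho*b) / (2(1-rho) + rho*q)

for b tumor copies of the B allele out of q total. Mirrored BAF folds the
value into [0.5, 1]; inverting the mixture equation with the sample purity
recovers the tumor-intrinsic minor-allele fraction, and a Wilcoxon
signed-rank test on paired (tumor - normal) mirrored BAFs flags segments
with allelic imbalance (Bonferroni-corrected across segments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImbalanceCall",
    "select_het_snps",
    "mirrored_baf",
    "adjust_mbaf",
    "test_allelic_imbalance",
]


@dataclass(frozen=True)
class ImbalanceCall:
    segment_id: str
    p_value: float
    p_bonferroni: float
    significant: bool
    n_snps: int
    reason: str = ""


def select_het_snps(
    snp_counts: pd.DataFrame,
    min_coverage: int = 40,
    posterior_threshold: float = 0.9,
    random_state: int = 0,
) -> pd.DataFrame:
    """Select heterozygous SNPs by mixture-model clustering of normal BAFs.

    A 3-component Gaussian mixture (homozygous-ref / het / homozygous-alt)
    is fitted to the normal-sample BAFs; SNPs assigned to the component
    centred nearest 0.5 with posterior above the threshold, and with tumor
    coverage strictly above ``min_coverage``, are kept. Falls back to a
    hard BAF window [0.3, 0.7] with a warning if the fit fails.

    Expects columns normal_ref/normal_alt/tumor_ref/tumor_alt; returns the
    kept rows with added columns baf_normal, baf_tumor, mbaf_normal,
    mbaf_tumor.
    """
    if snp_counts.empty:
        raise ValueError("empty SNP count table")
    df = snp_counts.copy()
    n_depth = df["normal_ref"] + df["normal_alt"]
    t_depth = df["tumor_ref"] + df["tumor_alt"]
    df["baf_normal"] = df["normal_alt"] / n_depth.clip(lower=1)
    df["baf_tumor"] = df["tumor_alt"] / t_depth.clip(lower=1)

    covered = t_depth > min_coverage
    baf = df["baf_normal"].to_numpy(float).reshape(-1, 1)
    try:
        from sklearn.mixture import GaussianMixture

        gmm = GaussianMixture(
            n_components=3,
            means_init=[[0.02], [0.5], [0.98]],
            random_state=random_state,
            max_iter=200,
        ).fit(baf)
        if not gmm.converged_:
            raise RuntimeError("mixture fit did not converge")
        het_comp = int(np.argmin(np.abs(gmm.means_.ravel() - 0.5)))
        post = gmm.predict_proba(baf)[:, het_comp]
        het = post > posterior_threshold
    except Exception as exc:  # degenerate input or non-convergence
        warnings.warn(f"GMM het filter failed ({exc}); falling back to BAF window [0.3, 0.7]")
        het = (df["baf_normal"] >= 0.3) & (df["baf_normal"] <= 0.7)

    out = df.loc[covered & het].copy()
    out["mbaf_normal"] = mirrored_baf(out["baf_normal"].to_numpy(float))
    out["mbaf_tumor"] = mirrored_baf(out["baf_tumor"].to_numpy(float))
    return out


def mirrored_baf(baf):
    """Fold a B-allele frequency into [0.5, 1]: max(baf, 1 - baf)."""
    arr = np.asarray(baf, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("BAF must lie in [0, 1]")
    out = np.maximum(arr, 1.0 - arr)
    return float(out) if np.isscalar(baf) else out


def adjust_mbaf(mbaf_obs, rho: float, q: int):
    """Purity-adjust an observed mirrored BAF to the tumor-intrinsic value.

    Inverts BAF = ((1-rho) + rho*nB) / (2(1-rho) + rho*q) for the minor
    allele count nB (clamped to [0, q] against sampling noise) and returns
    (q - nB)/q, the tumor's own mirrored allele fraction.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if q < 1:
        raise ValueError("total copy number must be >= 1")
    arr = np.asarray(mbaf_obs, dtype=float)
    baf_minor = 1.0 - arr
    denom = 2.0 * (1.0 - rho) + rho * q
    nb = (baf_minor * denom - (1.0 - rho)) / rho
    nb = np.clip(nb, 0.0, q)
    out = (q - nb) / q
    return float(out) if np.isscalar(mbaf_obs) else out


def test_allelic_imbalance(
    normal_mbaf: Sequence[float],
    tumor_mbaf: Sequence[float],
    n_segments: int,
    alpha: float = 0.05,
    segment_id: str = "",
    paired: bool = True,
    min_snps: int = 5,
) -> ImbalanceCall:
    """Test one segment for allelic imbalance.

    Two-sided Wilcoxon signed-rank on paired per-SNP (tumor - normal)
    mirrored BAFs (zero differences dropped), Bonferroni-corrected over
    ``n_segments``. ``paired=False`` switches to the two-sample
    Mann-Whitney variant. Segments with fewer than ``min_snps`` SNPs are
    reported non-significant with a reason.
    """
    normal = np.asarray(normal_mbaf, dtype=float)
    tumor = np.asarray(tumor_mbaf, dtype=float)
    n = len(tumor)
    if paired and len(normal) != n:
        raise ValueError("paired test needs matched normal/tumor SNP vectors")
    if n < min_snps:
        return ImbalanceCall(segment_id, 1.0, 1.0, False, n, "insufficient SNPs")
    if paired:
        diffs = tumor - normal
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs, zero_method="wilcox",
                                     alternative="two-sided").pvalue)
    else:
        p = float(stats.mannwhitneyu(tumor, normal, alternative="two-sided").pvalue)
    p_bonf = min(1.0, p * n_segments)
    return ImbalanceCall(segment_id, p, p_bonf, p_bonf < alpha, n)
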