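"""Grid-search purity/ploidy inference with FACS priors, cross-sample
model selection and cancer-cell-fraction clonality calls.

For a candidate purity rho and tumor ploidy tau the average copy number of
the admixed sample is D = 2(1-rho) + rho*tau, and the model predicts

    logR(segment with q copies)          = log2((2(1-rho) + rho*q) / D)
    VAF(mutation on m of q copies, CCF f) = rho*m*f / (2(1-rho) + rho*q)

The likelihood of a (rho, tau) grid point mixes segment mean logR over
integer q and SNV allele fractions over integer multiplicity m; the top
five models per sample enter a cross-sample rank aggregation that trades
pairwise profile concordance (L1 on expected modal copy number and SNV
multiplicity) against per-sample likelihood ranks. Flow-cytometric DNA
indices bound the ploidy grid at 2*DI +/- 0.5.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI

__all__ = [
    "FacsPrior",
    "PurityPloidyModel",
    "SnvState",
    "ploidy_prior_from_dna_index",
    "fit_purity_ploidy",
    "joint_model_selection",
    "ccf_and_clonality",
]


@dataclass(frozen=True)
class FacsPrior:
    """Ploidy prior derived from a flow-cytometric DNA index."""

    dna_index: float

    @property
    def prior_ploidy(self) -> float:
        return 2.0 * self.dna_index

    @property
    def ploidy_bounds(self) -> tuple[float, float]:
        return (self.prior_ploidy - 0.5, self.prior_ploidy + 0.5)


def ploidy_prior_from_dna_index(di: float) -> FacsPrior:
    """Prior ploidy = 2 * DNA index, grid bounded to +/- 0.5 around it."""
    if not di > 0:
        raise ValueError("DNA index must be positive")
    return FacsPrior(float(di))


@dataclass
class PurityPloidyModel:
    """One candidate (purity, ploidy) solution for a sample."""

    purity: float
    tumor_ploidy: float
    log_likelihood: float
    expected_modal_cn: np.ndarray          # integer q per segment
    expected_multiplicity: pd.Series       # integer m per admitted SNV
    sample: str = ""
    rank: int = 0                          # 0 = best likelihood in its sample

    @property
    def D(self) -> float:
        """Average copy number of the admixed sample (logR normalizer)."""
        return 2.0 * (1.0 - self.purity) + self.purity * self.tumor_ploidy


def _expected_logr(rho: float, q: np.ndarray, D: float) -> np.ndarray:
    mix = 2.0 * (1.0 - rho) + rho * q
    return np.log2(np.maximum(mix, 1e-9) / D)


def _expected_vaf(rho: float, m: np.ndarray, q: float) -> np.ndarray:
    return rho * m / (2.0 * (1.0 - rho) + rho * q)


def fit_purity_ploidy(
    segments: pd.DataFrame,
    snvs: pd.DataFrame | None,
    prior: FacsPrior,
    rho_grid: np.ndarray | None = None,
    tau_step: float = 0.05,
    q_max: int = 8,
    top_k: int = 5,
    logr_sd: float = 0.1,
    min_vaf: float = 0.05,
    min_depth: int = 50,
    sample: str = "",
) -> list[PurityPloidyModel]:
    """Rank (purity, ploidy) grid models for one sample.

    ``segments`` needs columns mean_logr and n_bins; ``snvs`` needs vaf
    and depth (rows failing the VAF>5% / depth>50 admission rule are
    dropped). Returns the top ``top_k`` models by log-likelihood.
    """
    if segments.empty:
        raise ValueError("need at least one segment")
    if rho_grid is None:
        rho_grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    lo, hi = prior.ploidy_bounds
    tau_grid = np.round(np.arange(max(lo, tau_step), hi + 1e-9, tau_step), 3)
    if len(tau_grid) == 0:
        raise ValueError("empty ploidy grid after applying FACS bounds")

    if snvs is not None and len(snvs):
        snvs = snvs[(snvs["vaf"] > min_vaf) & (snvs["depth"] > min_depth)]
    seg_logr = segments["mean_logr"].to_numpy(float)
    n_bins = segments["n_bins"].to_numpy(float)
    seg_sd = logr_sd / np.sqrt(n_bins)
    q_levels = np.arange(0, q_max + 1)

    # map SNVs onto their segment's modal copy number at evaluation time
    snv_vaf = snvs["vaf"].to_numpy(float) if snvs is not None and len(snvs) else np.empty(0)
    snv_depth = snvs["depth"].to_numpy(float) if snvs is not None and len(snvs) else np.empty(0)
    snv_seg = (snvs["segment"].to_numpy() if snvs is not None and len(snvs)
               and "segment" in snvs.columns else np.zeros(len(snv_vaf), dtype=int))
    snv_sd = np.sqrt(np.maximum(snv_vaf * (1 - snv_vaf), 1e-4) / np.maximum(snv_depth, 1.0))
    snv_index = snvs.index if snvs is not None and len(snvs) else pd.Index([])

    models: list[PurityPloidyModel] = []
    for rho in rho_grid:
        for tau in tau_grid:
            D = 2.0 * (1.0 - rho) + rho * tau
            mu = _expected_logr(rho, q_levels[None, :], D)          # 1 x Q
            ll_q = _norm_logpdf(seg_logr[:, None], mu, seg_sd[:, None])
            # the per-segment SD already shrinks with n_bins, so each
            # segment enters once (weighting again by n_bins would count
            # the bin evidence twice and overwhelm the SNV term)
            seg_ll = logsumexp(ll_q - np.log(len(q_levels)), axis=1)
            ll = float(np.sum(seg_ll))
            q_hat = q_levels[np.argmax(ll_q, axis=1)]

            m_hat = np.empty(len(snv_vaf), dtype=int)
            for i in range(len(snv_vaf)):
                q_i = max(int(q_hat[snv_seg[i]]), 1)
                m_levels = np.arange(1, q_i + 1)
                mu_v = _expected_vaf(rho, m_levels, q_i)
                ll_m = _norm_logpdf(snv_vaf[i], mu_v, snv_sd[i])
                ll += float(logsumexp(ll_m - np.log(q_i)))
                m_hat[i] = int(m_levels[np.argmax(ll_m)])
            models.append(PurityPloidyModel(
                purity=float(rho), tumor_ploidy=float(tau), log_likelihood=ll,
                expected_modal_cn=q_hat.astype(int),
                expected_multiplicity=pd.Series(m_hat, index=snv_index, dtype=int),
                sample=sample,
            ))
    models.sort(key=lambda m: -m.log_likelihood)
    for i, m in enumerate(models[:top_k]):
        m.rank = i
    return models[:top_k]


def _pairwise_distance(a: PurityPloidyModel, b: PurityPloidyModel) -> float:
    d = float(np.abs(a.expected_modal_cn - b.expected_modal_cn).sum())
    shared = a.expected_multiplicity.index.intersection(b.expected_multiplicity.index)
    if len(shared):
        d += float(np.abs(a.expected_multiplicity[shared] - b.expected_multiplicity[shared]).sum())
    return d


def joint_model_selection(
    per_sample_models: Mapping[str, Sequence[PurityPloidyModel]],
    lam: float = 1.0,
    max_exhaustive: int = 1_000_000,
    seed: int = 0,
) -> dict[str, PurityPloidyModel]:
    """Pick one model per sample minimising cross-sample discordance.

    Objective = sum over sample pairs of the L1 distance between expected
    modal copy-number profiles plus L1 distance between multiplicities of
    shared SNVs, plus lam * sum of per-sample likelihood ranks. Solved
    exhaustively when the search space allows, else by cross-entropy
    sampling; ties break toward better likelihood ranks, then
    lexicographically.
    """
    samples = list(per_sample_models)
    cand = {s: list(per_sample_models[s]) for s in samples}
    for s in samples:
        if not cand[s]:
            raise ValueError(f"sample {s!r} has no candidate models")
    if len(samples) == 1:
        s = samples[0]
        return {s: min(cand[s], key=lambda m: m.rank)}

    sizes = [len(cand[s]) for s in samples]
    pair_d: dict[tuple[int, int], np.ndarray] = {}
    for i, j in itertools.combinations(range(len(samples)), 2):
        mat = np.zeros((sizes[i], sizes[j]))
        for a in range(sizes[i]):
            for b in range(sizes[j]):
                mat[a, b] = _pairwise_distance(cand[samples[i]][a], cand[samples[j]][b])
        pair_d[(i, j)] = mat
    ranks = [np.array([m.rank for m in cand[s]], dtype=float) for s in samples]

    def objective(sel: tuple[int, ...]) -> tuple[float, float, tuple[int, ...]]:
        dist = sum(pair_d[(i, j)][sel[i], sel[j]] for i, j in pair_d)
        rank_sum = sum(ranks[i][sel[i]] for i in range(len(samples)))
        return (dist + lam * rank_sum, rank_sum, sel)

    n_comb = int(np.prod(sizes))
    if n_comb <= max_exhaustive:
        best = min(objective(sel) for sel in itertools.product(*[range(k) for k in sizes]))
    else:
        best = _cross_entropy_search(objective, sizes, seed)
    sel = best[2]
    return {s: cand[s][sel[i]] for i, s in enumerate(samples)}


def _cross_entropy_search(objective, sizes, seed, n_iter=60, n_sample=200,
                          elite_frac=0.1, smooth=0.7):
    rng = np.random.default_rng(seed)
    probs = [np.full(k, 1.0 / k) for k in sizes]
    best = None
    n_elite = max(1, int(n_sample * elite_frac))
    for _ in range(n_iter):
        draws = [rng.choice(len(p), size=n_sample, p=p) for p in probs]
        scored = sorted(
            objective(tuple(int(draws[i][t]) for i in range(len(sizes))))
            for t in range(n_sample)
        )
        if best is None or scored[0] < best:
            best = scored[0]
        elite = [s[2] for s in scored[:n_elite]]
        for i, k in enumerate(sizes):
            freq = np.bincount([e[i] for e in elite], minlength=k) / len(elite)
            probs[i] = smooth * freq + (1 - smooth) * probs[i]
    return best


@dataclass
class SnvState:
    """Multiplicity, cancer-cell fraction posterior and clonality call."""

    multiplicity: int
    ccf_mode: float
    pr_subclonal: float          # Pr(CCF < 0.95)
    clonal: bool
    posterior: np.ndarray | None = None
    ccf_grid: np.ndarray | None = None


def ccf_and_clonality(
    alt_count: int,
    depth: int,
    model: PurityPloidyModel,
    q: int,
    grid_points: int = 301,
    ccf_max: float = 1.5,
    keep_posterior: bool = False,
) -> SnvState:
    """Cancer-cell-fraction posterior and clonality of one SNV.

    Multiplicity is the nearest positive integer to VAF*(2(1-rho)+rho*q)/rho
    clamped to [1, q]; the CCF posterior is proportional to the binomial
    likelihood of the alt count with success probability
    rho*m*CCF/(2(1-rho)+rho*q). The grid extends above 1 (to ``ccf_max``)
    so that a clonal variant whose sampling noise pushes the estimate past
    1 is not truncated into apparent subclonality. Clonal iff
    Pr(CCF < 0.95) < 0.5.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if q < 1:
        raise ValueError("q must be >= 1")
    rho = model.purity
    denom = 2.0 * (1.0 - rho) + rho * q
    vaf = alt_count / depth
    m_hat = int(np.clip(round(vaf * denom / rho), 1, q))
    if rho * m_hat == 0:
        raise ValueError("rho * multiplicity is zero; CCF undefined")
    grid = np.linspace(0.0, ccf_max, grid_points)
    p = np.clip(rho * m_hat * grid / denom, 0.0, 1.0)
    loglik = binom.logpmf(alt_count, depth, p)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    pr_sub = float(post[grid < 0.95].sum())
    return SnvState(
        multiplicity=m_hat,
        ccf_mode=float(grid[np.argmax(post)]),
        pr_subclonal=pr_sub,
        clonal=pr_sub < 0.5,
        posterior=post if keep_posterior else None,
        ccf_grid=grid if keep_posterior else None,
    )
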