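"""Purity/ploidy grid inference, joint model selection and CCF clonality."""

import numpy as np
import pandas as pd
import pytest

from tumorevo.purity import (FacsPrior, PurityPloidyModel, ccf_and_clonality,
                             fit_purity_ploidy, joint_model_selection,
                             ploidy_prior_from_dna_index)


def expected_logr(rho, q, tau):
    return np.log2((2 * (1 - rho) + rho * q) / (2 * (1 - rho) + rho * tau))


def expected_vaf(rho, m, q):
    return rho * m / (2 * (1 - rho) + rho * q)


def seg_frame(rho, tau, qs, n_bins=100):
    return pd.DataFrame({
        "mean_logr": [expected_logr(rho, q, tau) for q in qs],
        "n_bins": n_bins,
    })


def snv_frame(rho, tau, specs):
    """specs: list of (segment_index, m, q)."""
    return pd.DataFrame({
        "vaf": [expected_vaf(rho, m, q) for _, m, q in specs],
        "depth": 1000,
        "segment": [s for s, _, _ in specs],
    }, index=[f"snv{i}" for i in range(len(specs))])


# ---------------------------------------------------------------------------
# FACS prior
# ---------------------------------------------------------------------------

def test_facs_prior():
    prior = ploidy_prior_from_dna_index(1.82)
    assert prior.prior_ploidy == pytest.approx(3.64)
    assert prior.ploidy_bounds == pytest.approx((3.14, 4.14))
    assert ploidy_prior_from_dna_index(1.0).prior_ploidy == 2.0
    with pytest.raises(ValueError):
        ploidy_prior_from_dna_index(0.0)
    with pytest.raises(ValueError):
        ploidy_prior_from_dna_index(-1.5)


# ---------------------------------------------------------------------------
# grid fit on noise-free data
# ---------------------------------------------------------------------------

def test_pure_diploid_recovered():
    segs = seg_frame(1.0, 2.0, [2, 1])
    # the SNV on the single-copy (LOH) segment pins the purity: an SNV on
    # an even-copy segment alone leaves (rho, q) and (rho/2, 2q-2) tied
    snvs = snv_frame(1.0, 2.0, [(0, 1, 2), (1, 1, 1)])
    models = fit_purity_ploidy(segs, snvs, ploidy_prior_from_dna_index(1.0))
    assert models[0].purity == 1.0
    assert models[0].tumor_ploidy == 2.0
    assert list(models[0].expected_modal_cn[:2]) == [2, 1]
    assert models[0].expected_multiplicity["snv0"] == 1


def test_half_purity_recovered_via_loh_snv():
    rho = 0.5
    segs = seg_frame(rho, 2.0, [2, 1])
    # one SNV on the diploid segment, one second hit on the LOH segment:
    # the odd-copy SNV breaks the (rho, q) <-> (rho/2, 2q-2) degeneracy
    snvs = snv_frame(rho, 2.0, [(0, 1, 2), (1, 1, 1)])
    models = fit_purity_ploidy(segs, snvs, ploidy_prior_from_dna_index(1.0))
    assert models[0].purity == pytest.approx(0.5, abs=0.011)
    assert models[0].tumor_ploidy == pytest.approx(2.0, abs=0.051)


def test_genome_doubled_with_facs_prior():
    segs = seg_frame(1.0, 4.0, [4, 2])
    snvs = snv_frame(1.0, 4.0, [(0, 2, 4), (1, 1, 2)])
    models = fit_purity_ploidy(segs, snvs, ploidy_prior_from_dna_index(2.0))
    assert models[0].purity == 1.0
    assert models[0].tumor_ploidy == 4.0
    assert models[0].expected_multiplicity["snv0"] == 2


def test_top_k_sorted_and_ranked():
    segs = seg_frame(0.7, 2.0, [2, 1])
    models = fit_purity_ploidy(segs, None, ploidy_prior_from_dna_index(1.0))
    assert len(models) == 5
    lls = [m.log_likelihood for m in models]
    assert lls == sorted(lls, reverse=True)
    assert [m.rank for m in models] == [0, 1, 2, 3, 4]


def test_snv_admission_rule():
    segs = seg_frame(0.8, 2.0, [2])
    snvs = pd.DataFrame({"vaf": [0.04, 0.4], "depth": [1000, 40], "segment": [0, 0]},
                        index=["low_vaf", "low_depth"])
    # both SNVs are inadmissible (VAF <= 5% or depth <= 50): the fit runs on
    # segments alone and reports no multiplicities
    models = fit_purity_ploidy(segs, snvs, ploidy_prior_from_dna_index(1.0))
    assert len(models[0].expected_multiplicity) == 0


def test_empty_segments_error():
    with pytest.raises(ValueError):
        fit_purity_ploidy(pd.DataFrame(columns=["mean_logr", "n_bins"]), None,
                          ploidy_prior_from_dna_index(1.0))


# ---------------------------------------------------------------------------
# joint model selection
# ---------------------------------------------------------------------------

def model(cn, rank, sample=""):
    return PurityPloidyModel(
        purity=0.5, tumor_ploidy=2.0, log_likelihood=-float(rank),
        expected_modal_cn=np.asarray(cn),
        expected_multiplicity=pd.Series(dtype=int),
        sample=sample, rank=rank)


def test_single_sample_takes_best_rank():
    models = [model([2, 2], 0), model([2, 1], 1)]
    sel = joint_model_selection({"A": models})
    assert sel["A"].rank == 0


def test_concordance_beats_rank():
    # rank-0 models disagree; picking one rank-1 model restores concordance
    cand = {
        "A": [model([2, 2], 0, "A"), model([2, 1], 1, "A")],
        "B": [model([2, 1], 0, "B"), model([2, 2], 1, "B")],
    }
    sel = joint_model_selection(cand, lam=0.5)
    assert list(sel["A"].expected_modal_cn) == list(sel["B"].expected_modal_cn)


def test_large_lambda_keeps_best_ranks():
    cand = {
        "A": [model([2, 2], 0, "A"), model([2, 1], 1, "A")],
        "B": [model([2, 1], 0, "B"), model([2, 2], 1, "B")],
    }
    sel = joint_model_selection(cand, lam=100.0)
    assert sel["A"].rank == 0 and sel["B"].rank == 0


def test_cross_entropy_matches_exhaustive():
    rng = np.random.default_rng(0)
    cand = {
        s: [model(rng.integers(1, 4, size=6), r, s) for r in range(5)]
        for s in ("A", "B", "C")
    }
    exact = joint_model_selection(cand, lam=0.3)
    approx = joint_model_selection(cand, lam=0.3, max_exhaustive=1, seed=0)
    for s in cand:
        assert approx[s].rank == exact[s].rank


def test_empty_candidates_error():
    with pytest.raises(ValueError):
        joint_model_selection({"A": []})


# ---------------------------------------------------------------------------
# CCF and clonality
# ---------------------------------------------------------------------------

def diploid_model(rho):
    return PurityPloidyModel(
        purity=rho, tumor_ploidy=2.0, log_likelihood=0.0,
        expected_modal_cn=np.array([2]),
        expected_multiplicity=pd.Series(dtype=int))


def test_clonal_call():
    # VAF 0.25 at rho=0.5, q=2: CCF = 1, clonal
    state = ccf_and_clonality(50, 200, diploid_model(0.5), q=2)
    assert state.multiplicity == 1
    assert state.ccf_mode == pytest.approx(1.0, abs=0.02)
    assert state.pr_subclonal < 0.5
    assert state.clonal


def test_subclonal_call():
    # VAF 0.10 at rho=0.5, q=2: CCF = 0.4, subclonal
    state = ccf_and_clonality(20, 200, diploid_model(0.5), q=2)
    assert state.ccf_mode == pytest.approx(0.4, abs=0.02)
    assert state.pr_subclonal > 0.5
    assert not state.clonal


def test_multiplicity_two():
    # VAF 0.5 at rho=0.5, q=2 implies both copies mutated
    state = ccf_and_clonality(100, 200, diploid_model(0.5), q=2)
    assert state.multiplicity == 2
    assert state.clonal


def test_posterior_normalized():
    state = ccf_and_clonality(50, 200, diploid_model(0.5), q=2, keep_posterior=True)
    assert state.posterior.sum() == pytest.approx(1.0, abs=1e-9)
    assert state.ccf_grid[0] == 0.0 and state.ccf_grid[-1] == pytest.approx(1.5)


def test_ccf_errors():
    with pytest.raises(ValueError):
        ccf_and_clonality(10, 0, diploid_model(0.5), q=2)
    with pytest.raises(ValueError):
        ccf_and_clonality(10, 100, diploid_model(0.5), q=0)
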