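"""Inverse normal transform, matched-pair mixed model and correlations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

from pylorimet.assoc import (
    AssocError, ModelSpec, build_design, fit_pair_lmm, inverse_normal_transform,
    metabolome_scan, pairwise_correlation, stratified_scan,
)
from conftest import make_paired_samples

CASE_ONLY = ModelSpec(covariates=())


# ---------------------------------------------------------------------------
# transformation

def test_transform_maps_ranks_to_normal_quantiles():
    out = inverse_normal_transform([5.0, 1.0, 9.0])
    expect = stats.norm.ppf([3 / 6, 1 / 6, 5 / 6])
    assert np.allclose(out, expect)
    assert out[0] == 0.0  # middle value of odd tie-free input


def test_transform_tie_handling_average_ranks():
    assert np.allclose(inverse_normal_transform([2.0, 2.0]), [0.0, 0.0])
    out = inverse_normal_transform([1.0, 3.0, 3.0, 7.0])
    # tied middle pair takes average rank 2.5 -> (2.5 - .5)/4 = .5 -> 0
    assert np.allclose(out[1:3], 0.0)


def test_transform_blom_offset():
    out = inverse_normal_transform([1.0, 2.0, 3.0], offset="blom")
    expect = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
    assert np.allclose(out, expect)


def test_transform_requires_two_finite_values():
    with pytest.raises(AssocError):
        inverse_normal_transform([1.0])
    with pytest.raises(AssocError):
        inverse_normal_transform([np.nan, np.nan, 1.0])


def test_transform_propagates_nan():
    out = inverse_normal_transform([1.0, np.nan, 3.0])
    assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()


@settings(max_examples=25, deadline=None)
@given(st.lists(st.integers(-10**4, 10**4), min_size=3, max_size=40,
                unique=True),
       st.sampled_from(["atan", "cube", "affine"]))
def test_transform_invariant_to_monotone_maps(values, fn):
    """Rank-based: any strictly increasing input transform leaves the
    output unchanged; tie-free output has sample mean zero."""
    x = np.asarray(values, dtype=float)
    base = inverse_normal_transform(x)
    g = {"atan": np.arctan, "cube": lambda v: v ** 3,
         "affine": lambda v: 2.5 * v + 7}[fn]
    assert np.allclose(base, inverse_normal_transform(g(x)))
    assert abs(base.mean()) < 1e-12


# ---------------------------------------------------------------------------
# matched-pair model

def test_case_only_model_equals_paired_difference():
    rng = np.random.default_rng(1)
    samples = make_paired_samples(40, rng)
    y = rng.normal(size=80) + 0.3 * samples["case"].to_numpy() \
        + np.repeat(rng.normal(0, 0.7, 40), 2)
    _, res = fit_pair_lmm(y, samples, CASE_ONLY)
    d = y[0::2] - y[1::2]
    assert res.beta == pytest.approx(d.mean(), rel=1e-10)
    assert res.se == pytest.approx(d.std(ddof=1) / np.sqrt(40), rel=1e-6)


def test_null_within_pairs_gives_zero_beta():
    rng = np.random.default_rng(2)
    samples = make_paired_samples(15, rng)
    y = np.repeat(rng.normal(size=15), 2)  # identical within every pair
    _, res = fit_pair_lmm(y, samples, CASE_ONLY)
    assert res.beta == pytest.approx(0.0, abs=1e-12)


def test_agrees_with_generic_reml_mixed_model():
    """Independent route: statsmodels MixedLM (generic numerical REML)."""
    rng = np.random.default_rng(3)
    samples = make_paired_samples(120, rng)
    y = (0.35 * samples["case"].to_numpy()
         + 0.1 * samples["gestational_age_wk"].to_numpy()
         + np.repeat(rng.normal(0, 0.8, 120), 2) + rng.normal(size=240))
    model = ModelSpec()
    fit, res = fit_pair_lmm(y, samples, model)
    design = build_design(samples, model)
    ref = sm.MixedLM(y, design.X, groups=np.repeat(np.arange(120), 2)
                     ).fit(reml=True)
    j = design.names.index("case")
    assert res.beta == pytest.approx(ref.fe_params[j], rel=1e-5)
    assert res.se == pytest.approx(ref.bse_fe[j], rel=1e-3)


def test_invariance_to_pair_relabeling_and_shift():
    rng = np.random.default_rng(4)
    samples = make_paired_samples(30, rng)
    y = rng.normal(size=60) + np.repeat(rng.normal(0, 1, 30), 2)
    _, base = fit_pair_lmm(y, samples, ModelSpec())

    relabeled = samples.copy()
    relabeled["pair_id"] = relabeled["pair_id"].map(
        lambda p: f"zz-{p}")
    _, rel = fit_pair_lmm(y, relabeled, ModelSpec())
    assert rel.beta == pytest.approx(base.beta, rel=1e-9)

    _, shifted = fit_pair_lmm(y + 11.5, samples, ModelSpec())
    assert shifted.beta == pytest.approx(base.beta, rel=1e-9)
    assert shifted.se == pytest.approx(base.se, rel=1e-6)


def test_collinear_covariate_pruned_and_reported():
    """A covariate duplicating case status is dropped (and listed), while
    the case coefficient stays estimable."""
    rng = np.random.default_rng(5)
    samples = make_paired_samples(10, rng)
    samples["parity"] = samples["case"]
    fit, res = fit_pair_lmm(rng.normal(size=20), samples, ModelSpec())
    assert "parity" in fit.dropped
    assert np.isfinite(res.beta)


def test_incomplete_pairs_rejected():
    rng = np.random.default_rng(6)
    samples = make_paired_samples(8, rng).iloc[:-1]  # drop one control
    with pytest.raises(AssocError, match="pair"):
        fit_pair_lmm(rng.normal(size=15), samples, ModelSpec())


def test_pairs_with_missing_covariates_dropped_whole():
    rng = np.random.default_rng(7)
    samples = make_paired_samples(12, rng)
    samples.loc[samples.index[2], "parity"] = np.nan  # hits pair p1
    y = rng.normal(size=24)
    fit, res = fit_pair_lmm(y, samples, ModelSpec())
    assert res.n_pairs == 11


def test_wald_t_option_gives_larger_p():
    rng = np.random.default_rng(8)
    samples = make_paired_samples(12, rng)
    y = rng.normal(size=24) + 0.5 * samples["case"].to_numpy()
    _, z_res = fit_pair_lmm(y, samples, ModelSpec(pvalue_method="wald_z"))
    _, t_res = fit_pair_lmm(y, samples, ModelSpec(pvalue_method="t"))
    assert t_res.p > z_res.p
    assert t_res.beta == pytest.approx(z_res.beta)


# ---------------------------------------------------------------------------
# scans

def _matrix(samples, rng, k=5, effects=None):
    n = len(samples)
    cols = {}
    for i in range(k):
        mu = (effects or {}).get(i, 0.0) * samples["case"].to_numpy()
        cols[f"M{i}"] = np.exp(rng.normal(mu, 1.0, n))
    mat = pd.DataFrame(cols, index=samples["sample_id"])
    return mat


def test_scan_bonferroni_uses_tested_count():
    rng = np.random.default_rng(9)
    samples = make_paired_samples(60, rng)
    mat = _matrix(samples, rng, k=1, effects={0: 2.0})
    res = metabolome_scan(mat, samples, alpha=0.05)
    assert len(res) == 1
    # single metabolite -> threshold is alpha itself
    assert res[0].significant_bonferroni == (res[0].p < 0.05)
    assert res[0].p < 0.05


def test_scan_lowering_alpha_shrinks_significant_set():
    rng = np.random.default_rng(10)
    samples = make_paired_samples(80, rng)
    mat = _matrix(samples, rng, k=6, effects={0: 1.5, 1: 0.8})
    sig = {}
    for alpha in (0.2, 0.05, 0.01):
        res = metabolome_scan(mat, samples, alpha=alpha)
        sig[alpha] = {r.metabolite for r in res if r.significant_bonferroni}
    assert sig[0.01] <= sig[0.05] <= sig[0.2]


def test_scan_results_sorted_and_top_hit_strongest():
    rng = np.random.default_rng(11)
    samples = make_paired_samples(100, rng)
    mat = _matrix(samples, rng, k=4, effects={2: 1.8, 3: 0.4})
    res = metabolome_scan(mat, samples)
    ps = [r.p for r in res]
    assert ps == sorted(ps)
    assert res[0].metabolite == "M2"


def test_stratified_split_below_all_years_equals_full():
    rng = np.random.default_rng(12)
    samples = make_paired_samples(40, rng)
    mat = _matrix(samples, rng, k=3)
    full = metabolome_scan(mat, samples)
    strata = stratified_scan(mat, samples, split_year=1900)
    assert strata["pre_policy"] == []
    post = {r.metabolite: r for r in strata["post_policy"]}
    for r in full:
        assert post[r.metabolite].beta == pytest.approx(r.beta, rel=1e-9)
        assert post[r.metabolite].n_pairs == r.n_pairs


def test_stratified_pair_counts_sum_to_total():
    rng = np.random.default_rng(13)
    samples = make_paired_samples(50, rng)
    mat = _matrix(samples, rng, k=2)
    strata = stratified_scan(mat, samples, split_year=2009)
    n_pre = strata["pre_policy"][0].n_pairs if strata["pre_policy"] else 0
    n_post = strata["post_policy"][0].n_pairs if strata["post_policy"] else 0
    assert n_pre + n_post == 50
    assert all(r.stratum == "pre_policy" for r in strata["pre_policy"])


def test_stratified_global_transform_option_runs():
    rng = np.random.default_rng(14)
    samples = make_paired_samples(40, rng)
    mat = _matrix(samples, rng, k=2)
    model = ModelSpec(retransform_within_stratum=False)
    strata = stratified_scan(mat, samples, model=model)
    assert set(strata) == {"pre_policy", "post_policy"}


# ---------------------------------------------------------------------------
# correlations

def test_correlation_diagonal_and_sign():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    mat = pd.DataFrame({"a": x, "b": -x, "c": x * 2})
    r, p = pairwise_correlation(mat)
    assert r.loc["a", "a"] == 1.0
    assert r.loc["a", "b"] == pytest.approx(-1.0)
    assert r.loc["a", "c"] == pytest.approx(1.0)
    assert np.allclose(r.to_numpy(), r.to_numpy().T)


def test_correlation_closed_form_example():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
    mat = pd.DataFrame({"x": x, "y": y})
    r, p = pairwise_correlation(mat)
    # closed form: r = cov / (sd_x sd_y) = 10 / sqrt(10 * 14.8)
    r_expect = 10.0 / np.sqrt(10.0 * 14.8)
    assert r.loc["x", "y"] == pytest.approx(r_expect, rel=1e-12)
    # t-test with n - 2 = 3 degrees of freedom
    t = r_expect * np.sqrt(3) / np.sqrt(1 - r_expect ** 2)
    assert p.loc["x", "y"] == pytest.approx(2 * stats.t.sf(t, 3), rel=1e-9)


def test_correlation_pairwise_complete_and_degenerate():
    mat = pd.DataFrame({
        "a": [1.0, 2.0, 3.0, np.nan, 5.0],
        "b": [2.0, 4.0, 6.0, 8.0, np.nan],
        "c": [1.0, 1.0, 1.0, 1.0, 1.0],   # zero variance
    })
    r, p = pairwise_correlation(mat)
    assert r.loc["a", "b"] == pytest.approx(1.0)   # 3 complete rows
    assert np.isnan(r.loc["a", "c"])
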