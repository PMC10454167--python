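"""MCMC kernels, HPD intervals, summaries, determinism."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import kstest, ks_2samp, norm, truncnorm

from pedliab import _kernels
from pedliab.model import ModelSpec
from pedliab.pedigree import FamilyGraph
from pedliab.sampler import (
    ChainConfig,
    LiabilityThresholdModel,
    _Chain,
    hpd_interval,
)

from conftest import make_ind


# ---------------------------------------------------------------------------
# truncated-normal kernel
# ---------------------------------------------------------------------------

def test_truncnorm_kernel_upper_truncation_mean():
    """Standard normal truncated above at 1.64485: closed-form mean -phi(c)/Phi(c)."""
    c = 1.64485
    _kernels.set_seed(7)
    draws = np.array([-_kernels.truncnorm_lower_std(-c) for _ in range(100_000)])
    oracle = float(truncnorm.mean(-np.inf, c))
    assert oracle == pytest.approx(-norm.pdf(c) / norm.cdf(c), abs=1e-12)
    se = float(truncnorm.std(-np.inf, c)) / math.sqrt(draws.size)
    assert draws.mean() == pytest.approx(oracle, abs=4 * se)
    assert np.all(draws < c)


@pytest.mark.parametrize("a", [-1.5, 0.3, 2.0, 5.0])
def test_truncnorm_kernel_distribution(a):
    _kernels.set_seed(13)
    draws = np.array([_kernels.truncnorm_lower_std(a) for _ in range(20_000)])
    assert np.all(draws > a)
    stat = kstest(draws, lambda x: truncnorm.cdf(x, a, np.inf))
    assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# Gibbs sweep
# ---------------------------------------------------------------------------

def _sweep_setup(sigma, mu, lower, upper):
    n = sigma.shape[0]
    omega = np.linalg.inv(sigma)[None]
    sizes = np.array([n], dtype=np.int64)
    offsets = np.array([0], dtype=np.int64)
    return omega, sizes, offsets, np.asarray(mu, float), \
        np.asarray(lower, float), np.asarray(upper, float)


def test_sweep_independent_members_match_truncnorm():
    """With Sigma = I the sweep is exact independent truncated sampling."""
    c = 0.8
    omega, sizes, offsets, mu, lo, hi = _sweep_setup(
        np.eye(2), [0.0, 0.0], [c, -math.inf], [math.inf, c])
    _kernels.set_seed(3)
    L = np.array([1.5, 0.0])
    draws = np.empty((4000, 2))
    for i in range(4000):
        _kernels.gibbs_sweep(L, mu, omega, sizes, offsets, lo, hi)
        draws[i] = L
    assert np.all(draws[:, 0] > c) and np.all(draws[:, 1] < c)
    m_case = float(truncnorm.mean(c, np.inf))
    m_ctrl = float(truncnorm.mean(-np.inf, c))
    assert draws[:, 0].mean() == pytest.approx(m_case, abs=0.05)
    assert draws[:, 1].mean() == pytest.approx(m_ctrl, abs=0.05)


def test_sweep_correlated_pair_matches_rejection_sampling():
    """rho = 0.9, both affected: Gibbs marginal equals rejection sampling."""
    c = 0.5
    sigma = np.array([[1.0, 0.9], [0.9, 1.0]])
    omega, sizes, offsets, mu, lo, hi = _sweep_setup(
        sigma, [0.0, 0.0], [c, c], [math.inf, math.inf])
    _kernels.set_seed(21)
    L = np.array([1.0, 1.0])
    kept = []
    for i in range(30_000):
        _kernels.gibbs_sweep(L, mu, omega, sizes, offsets, lo, hi)
        if i % 3 == 0:
            kept.append(L[0])
    kept = np.asarray(kept)
    rng = np.random.default_rng(17)
    z = rng.multivariate_normal([0.0, 0.0], sigma, size=300_000)
    ref = z[(z[:, 0] > c) & (z[:, 1] > c), 0]
    assert ref.size > 5_000
    assert np.all(kept > c)
    assert ks_2samp(kept, ref).pvalue > 0.01


# ---------------------------------------------------------------------------
# HPD
# ---------------------------------------------------------------------------

def test_hpd_uniform_grid_earliest_window():
    lo, hi = hpd_interval(np.arange(1, 101, dtype=float), 0.95)
    assert (lo, hi) == (1.0, 95.0)


def test_hpd_degenerate_draws():
    lo, hi = hpd_interval(np.full(200, 3.14), 0.95)
    assert lo == hi == 3.14


def test_hpd_matches_equal_tailed_for_gaussian():
    rng = np.random.default_rng(8)
    lo, hi = hpd_interval(rng.standard_normal(100_000), 0.95)
    assert lo == pytest.approx(-1.96, abs=0.04)
    assert hi == pytest.approx(1.96, abs=0.04)


def test_hpd_requires_enough_draws():
    with pytest.raises(ValueError):
        hpd_interval(np.arange(50, dtype=float))


# ---------------------------------------------------------------------------
# full sampler contracts
# ---------------------------------------------------------------------------

def _toy_families():
    fams = []
    for j, aff in enumerate([(True, False, True), (True, True, False)]):
        kids = [
            make_ind(f"k{i}", f"F{j}", "f", "m", "male" if i % 2 else "female",
                     affected=aff[i], proband=(i == 0), yob=1950 + i)
            for i in range(3)
        ]
        fams.append(FamilyGraph(f"F{j}", [
            make_ind("f", f"F{j}", None, None, "male", yob=1920),
            make_ind("m", f"F{j}", None, None, "female", yob=1921),
            *kids,
        ]))
    return fams


def _toy_spec(**kw):
    defaults = dict(variance_components=("h2",), covariates=(),
                    prevalence=0.25, standardize_covariates=False,
                    ascertainment_correction=False)
    defaults.update(kw)
    return ModelSpec(**defaults)


def test_run_is_deterministic_under_seed():
    fams = _toy_families()
    cfg = ChainConfig(n_chains=2, n_warmup=50, n_sampling=80, seed=99)
    r1 = LiabilityThresholdModel(fams, _toy_spec()).fit(cfg)
    r2 = LiabilityThresholdModel(fams, _toy_spec()).fit(cfg)
    for name in r1.draws.params:
        assert np.array_equal(r1.draws[name], r2.draws[name])


def test_run_empty_sampling_warns():
    fams = _toy_families()
    with pytest.warns(UserWarning, match="empty"):
        res = LiabilityThresholdModel(fams, _toy_spec()).fit(
            ChainConfig(n_chains=1, n_warmup=10, n_sampling=0, seed=1))
    assert res.draws["h2"].size == 0


def test_toy_posterior_converges_across_chains():
    """Easy two-family posterior: four chains agree (split R-hat < 1.01)."""
    import arviz as az

    fams = _toy_families()
    res = LiabilityThresholdModel(fams, _toy_spec()).fit(
        ChainConfig(n_chains=4, n_warmup=800, n_sampling=2_000, seed=5))
    for name in ("h2", "e2"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert float(az.rhat(res.draws[name])) < 1.01


def test_beta_update_matches_conjugate_posterior():
    """Known-variance Gaussian sub-case: with L fixed and an (effectively)
    untruncated singleton family, the beta kernel targets the closed-form
    normal-normal posterior."""
    fam = FamilyGraph("C", [
        make_ind("x", "C", None, None, "female", yob=1950),
    ])
    spec = ModelSpec(variance_components=("h2",), covariates=("sex",),
                     prevalence=1e-9, standardize_covariates=False,
                     ascertainment_correction=False)
    model = LiabilityThresholdModel([fam], spec)
    chain = _Chain(model.packed, spec, seed=31)
    y0 = 1.5
    chain.L[:] = y0
    chain.lp = chain._loglik(chain.vcfull, chain.beta)
    for _ in range(2_000):  # adapt
        chain.step_beta(adapt=True)
    draws = np.empty(30_000)
    for i in range(30_000):
        chain.step_beta(adapt=False)
        draws[i] = chain.beta[0]
    # posterior: precision 1 + 1/100, mean y0 * (1 / (1 + 1/100))
    post_var = 1.0 / (1.0 + 1.0 / 100.0)
    post_mean = y0 * post_var
    assert draws.mean() == pytest.approx(post_mean, abs=0.03)
    assert draws.var() == pytest.approx(post_var, rel=0.1)


def test_prior_sampling_moments_without_data():
    """No families: variance proportions are flat on the simplex and betas
    keep their Normal(0, 10) prior (moment check; the distributional test
    lives in the acceptance suite)."""
    spec = ModelSpec(variance_components=("h2", "c2_sibs"), covariates=("sex",),
                     prevalence=0.1, standardize_covariates=False,
                     ascertainment_correction=False)
    res = LiabilityThresholdModel([], spec).fit(
        ChainConfig(n_chains=1, n_warmup=2_000, n_sampling=30_000, seed=2))
    h2 = res.draws.stacked("h2")
    assert h2.mean() == pytest.approx(1.0 / 3.0, abs=0.03)  # Dirichlet(1,1,1)
    beta = res.draws.stacked("beta_sex")
    assert beta.mean() == pytest.approx(0.0, abs=0.8)
    assert beta.std() == pytest.approx(10.0, rel=0.1)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summary_layout_and_derived_quantities():
    fams = _toy_families()
    spec = _toy_spec(variance_components=("h2", "c2_sibs", "c2_mother_off"))
    res = LiabilityThresholdModel(fams, spec).fit(
        ChainConfig(n_chains=2, n_warmup=150, n_sampling=200, seed=4))
    # per-draw c2 total dominates each component
    c2t = res.derived_series()["c2_total_resid"]
    for name in ("c2_sibs", "c2_mother_off"):
        assert np.all(c2t >= res.draws[name] - 1e-12)
    summ = res.summary()
    params = set(summ.table["parameter"])
    assert {"h2", "c2_total", "e2", "h2_resid"} <= params
    row = summ.row("h2")
    assert row["hpd_low"] <= row["median"] <= row["hpd_high"]


def test_summary_median_sd_against_order_statistics():
    """Summary statistics agree with direct empirical quantiles."""
    rng = np.random.default_rng(12)
    arr = rng.gamma(2.0, 1.0, size=(2, 2_000))
    from pedliab.sampler import FitResult, PosteriorDraws

    cfg = ChainConfig(n_chains=2, n_warmup=0, n_sampling=2_000, seed=0)
    draws = PosteriorDraws({"h2": arr * 0.2, "e2": 1.0 - arr * 0.2}, cfg,
                           ("h2",), ())

    class _Design:
        columns = ()
        X = np.zeros((0, 0))
        standardized = False
        sds = np.ones(0)

    class _Model:
        design = _Design()
        spec = ModelSpec(variance_components=("h2",), covariates=(),
                         prevalence=0.1, standardize_covariates=False)

    res = FitResult(draws, _Model())
    summ = res.summary()
    flat = (arr * 0.2).reshape(-1)
    assert summ.value("h2") == pytest.approx(float(np.median(flat)), rel=1e-12)
    assert summ.value("h2", "sd") == pytest.approx(float(np.std(flat, ddof=1)),
                                                   rel=1e-9)
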