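"""Liability model: threshold, covariance, design, variance decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erfcinv
from scipy.stats import norm

from pedliab.model import (
    ModelSpec,
    Theta,
    build_design,
    build_sigma,
    decompose_fixed_effects,
    gxe_similarity,
    threshold_from_prevalence,
)
from pedliab.pedigree import FamilyGraph, RelationshipMatrices, relationship_matrices

from conftest import make_ind


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------

def test_threshold_midpoint_and_known_value():
    assert threshold_from_prevalence(0.5) == pytest.approx(0.0, abs=1e-12)
    # independent route: Phi^-1(1-p) = sqrt(2) * erfcinv(2p)
    p = 157 / 100_000
    oracle = float(np.sqrt(2.0) * erfcinv(2.0 * p))
    assert threshold_from_prevalence(p) == pytest.approx(oracle, abs=1e-10)
    assert threshold_from_prevalence(p) == pytest.approx(2.9537, abs=5e-4)


def test_threshold_monotone_in_prevalence():
    assert threshold_from_prevalence(176e-5) < threshold_from_prevalence(103e-5)


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
def test_threshold_domain_errors(bad):
    with pytest.raises(ValueError):
        threshold_from_prevalence(bad)


def test_threshold_cdf_mutual_inverse():
    prevs = np.geomspace(1e-6, 0.5, 40)
    prevs = np.concatenate([prevs, 1.0 - prevs[::-1][1:]])
    for p in prevs:
        c = threshold_from_prevalence(p)
        assert norm.sf(c) == pytest.approx(p, rel=1e-10, abs=1e-16)


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def _pair_mats(k2_off, sibs=0.0, mother=0.0):
    return RelationshipMatrices(
        ids=["a", "b"],
        k2=np.array([[1.0, k2_off], [k2_off, 1.0]]),
        h_sibs=np.array([[1.0, sibs], [sibs, 1.0]]),
        h_mother_off=np.array([[1.0, mother], [mother, 1.0]]),
        h_father_off=np.eye(2),
        h_spouses=np.eye(2),
    )


def test_sigma_identity_when_pure_noise():
    spec = ModelSpec(variance_components=("h2",), covariates=(),
                     prevalence=0.1, standardize_covariates=False)
    theta = Theta(vc={"h2": 0.0}, beta=np.zeros(0))
    sigma = build_sigma(theta, _pair_mats(0.5), spec)
    assert np.allclose(sigma, np.eye(2))


def test_sigma_sibling_pair_hand_value():
    spec = ModelSpec(variance_components=("h2", "c2_sibs"), covariates=(),
                     prevalence=0.1, standardize_covariates=False)
    theta = Theta(vc={"h2": 0.5, "c2_sibs": 0.3}, beta=np.zeros(0))
    sigma = build_sigma(theta, _pair_mats(0.5, sibs=1.0), spec)
    assert sigma[0, 1] == pytest.approx(0.5 * 0.5 + 0.3 * 1.0)
    assert np.allclose(np.diag(sigma), 1.0)


def test_sigma_mother_offspring_hand_value():
    spec = ModelSpec(variance_components=("h2", "c2_mother_off"), covariates=(),
                     prevalence=0.1, standardize_covariates=False)
    theta = Theta(vc={"h2": 0.5, "c2_mother_off": 0.2}, beta=np.zeros(0))
    sigma = build_sigma(theta, _pair_mats(0.5, mother=1.0), spec)
    assert sigma[0, 1] == pytest.approx(0.5 * 0.5 + 0.2)


def test_sigma_perfect_correlation_gives_identical_liabilities():
    # an MZ-like pair (relationship 1) under pure additive variance
    spec = ModelSpec(variance_components=("h2",), covariates=(),
                     prevalence=0.1, standardize_covariates=False)
    theta = Theta(vc={"h2": 1.0}, beta=np.zeros(0))
    sigma = build_sigma(theta, _pair_mats(1.0), spec)
    chol = np.linalg.cholesky(sigma)
    z = np.random.default_rng(0).standard_normal((2, 500))
    L = chol @ z
    assert np.max(np.abs(L[0] - L[1])) < 1e-3  # equal up to the PSD ridge


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3))
def test_sigma_unit_diagonal_and_psd(raw):
    w = np.asarray(raw)
    vc = w / w.sum() * 0.9  # leave e2 = 0.1
    spec = ModelSpec(variance_components=("h2", "c2_sibs", "c2_mother_off"),
                     covariates=(), prevalence=0.1, standardize_covariates=False)
    theta = Theta(vc={"h2": vc[0], "c2_sibs": vc[1], "c2_mother_off": vc[2]},
                  beta=np.zeros(0))
    sigma = build_sigma(theta, _pair_mats(0.5, sibs=1.0, mother=0.0), spec)
    assert np.allclose(np.diag(sigma), 1.0, atol=2e-8)
    assert np.linalg.eigvalsh(sigma)[0] >= -1e-12


# ---------------------------------------------------------------------------
# GxE similarity
# ---------------------------------------------------------------------------

def test_gxe_single_stratum_warns(nuclear5):
    for m in nuclear5.members:
        m.year_of_birth = 1950
    with pytest.warns(UserWarning, match="confounded"):
        s = gxe_similarity(nuclear5, "yob1946")
    assert np.allclose(s, 1.0)
    assert np.allclose(relationship_matrices(nuclear5).k2 * s,
                       relationship_matrices(nuclear5).k2)


def test_gxe_cross_stratum_zero(nuclear5):
    yobs = [1920, 1921, 1940, 1950, 1960]
    for m, y in zip(nuclear5.members, yobs):
        m.year_of_birth = y
    s = gxe_similarity(nuclear5, "yob1946")
    ids = [m.individual_id for m in nuclear5.analysis_members]
    k0, k2 = ids.index("k0"), ids.index("k2")  # 1940 vs 1960: different strata
    assert s[k0, k2] == 0.0
    # brute-force elementwise oracle
    strata = [1.0 if y >= 1946 else 0.0 for y in yobs]
    expect = np.array([[1.0 if a == b else 0.0 for b in strata] for a in strata])
    assert np.array_equal(s, expect)
    assert np.allclose(np.diag(s), 1.0)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _one_family(sexes, yobs):
    members = [
        make_ind(f"i{k}", "F", None, None, s, yob=y)
        for k, (s, y) in enumerate(zip(sexes, yobs))
    ]
    return FamilyGraph("F", members)


def test_design_zero_variance_errors():
    fam = _one_family(["male"] * 4, [1950] * 4)
    spec = ModelSpec(covariates=("sex",), prevalence=0.1)
    with pytest.raises(ValueError, match="zero variance"):
        build_design([fam], spec)


def test_design_balanced_binary_standardizes_to_unit():
    fam = _one_family(["male", "female"] * 4, [1940, 1950] * 4)
    spec = ModelSpec(covariates=("sex",), prevalence=0.1)
    d = build_design([fam], spec)
    # balanced 0/1 column: mean .5, sd .5 -> values +-1 (sample sd uses ddof=1)
    vals = np.unique(np.round(d.X[:, 0], 10))
    assert len(vals) == 2 and vals[0] == -vals[1]
    assert d.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
    assert d.X[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_design_continuous_year_standardized():
    yobs = list(range(1946, 2001))
    fam = _one_family(["male", "female"] * 28, yobs + [yobs[0]])
    spec = ModelSpec(covariates=("year10",), prevalence=0.1)
    d = build_design([fam], spec)
    assert d.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
    assert d.X[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_design_raw_effect_reverses_standardization():
    fam = _one_family(["male", "female"] * 6, [1940, 1950] * 6)
    spec = ModelSpec(covariates=("sex", "yob1946"), prevalence=0.1)
    d = build_design([fam], spec)
    beta_std = np.array([1.0, 2.0])
    raw = d.raw_effect(beta_std)
    assert np.allclose(raw, beta_std / d.sds)


# ---------------------------------------------------------------------------
# fixed-effect variance decomposition
# ---------------------------------------------------------------------------

def test_decompose_zero_beta():
    X = np.random.default_rng(0).standard_normal((50, 2))
    d = decompose_fixed_effects(X, np.zeros(2), columns=["a", "b"])
    assert d.tau2_total == 0.0
    assert all(v == 0.0 for v in d.tau2_per_covariate.values())


def test_decompose_orthonormal_analytic():
    rng = np.random.default_rng(1)
    Z = rng.standard_normal((400, 2))
    # exactly whiten: sample covariance becomes the identity
    Z = Z - Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False, ddof=1)
    Z = Z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    d = decompose_fixed_effects(Z, np.array([1.0, 2.0]), columns=["a", "b"])
    assert d.tau2_total == pytest.approx(5.0, abs=1e-9)
    assert d.tau2_per_covariate["a"] == pytest.approx(1.0, abs=1e-9)
    assert d.tau2_per_covariate["b"] == pytest.approx(4.0, abs=1e-9)
    assert d.cov_terms[("a", "b")] == pytest.approx(0.0, abs=1e-9)


def test_decompose_correlated_analytic():
    rng = np.random.default_rng(2)
    Z = rng.standard_normal((400, 2))
    Z = Z - Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False, ddof=1)
    Z = Z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    target = np.array([[1.0, 0.5], [0.5, 1.0]])
    Z = Z @ np.linalg.cholesky(target).T  # sample correlation exactly 0.5
    d = decompose_fixed_effects(Z, np.array([1.0, 2.0]), columns=["a", "b"])
    assert d.tau2_total == pytest.approx(7.0, abs=1e-9)
    assert d.cov_terms[("a", "b")] == pytest.approx(2.0, abs=1e-9)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 10_000))
def test_decompose_identity_property(seed):
    """The decomposition identity holds to near machine precision."""
    rng = np.random.default_rng(seed)
    n, p = rng.integers(5, 60), rng.integers(1, 4)
    X = rng.standard_normal((n, p)) * rng.uniform(0.1, 5.0)
    beta = rng.standard_normal(p) * 3.0
    d = decompose_fixed_effects(X, beta)
    parts = sum(d.tau2_per_covariate.values()) + sum(d.cov_terms.values())
    assert d.tau2_total == pytest.approx(parts, abs=1e-12 * max(1.0, abs(d.tau2_total)))
    assert all(v >= 0.0 for v in d.tau2_per_covariate.values())


def test_phenotypic_scale_fractions_sum_to_one_with_components():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((200, 2))
    beta = np.array([0.7, -1.2])
    d = decompose_fixed_effects(X, beta, columns=["sex", "yr"])
    frac = d.phenotypic_scale_fractions
    # residual components sum to 1 on their own scale; rescaled they fill 1 - tau2 share
    resid_share = 1.0 / (1.0 + d.tau2_total)
    assert frac["tau2_total"] + resid_share == pytest.approx(1.0, abs=1e-12)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(variance_components=())
    with pytest.raises(ValueError):
        ModelSpec(variance_components=("h2", "e2"))
    with pytest.raises(ValueError):
        ModelSpec(prevalence=0.0)
    with pytest.raises(ValueError):
        Theta(vc={"h2": 0.7, "c2_sibs": 0.5}, beta=np.zeros(1))


def test_model_spec_yaml_round_trip(tmp_path):
    import yaml

    spec = ModelSpec(variance_components=("h2", "c2_sibs"), covariates=("sex",),
                     prevalence=0.01, standardize_covariates=False)
    p = tmp_path / "spec.yaml"
    p.write_text(yaml.safe_dump(spec.to_dict()))
    back = ModelSpec.from_yaml(p)
    assert back.to_dict() == spec.to_dict()
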