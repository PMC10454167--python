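"""MCMC posterior inference for the liability threshold model.

The sampler alternates (i) single-site Gibbs updates of the latent
liabilities from their truncated-normal full conditionals and (ii)
adaptive random-walk Metropolis updates of the parameters: the variance
proportions on a log-ratio-transformed simplex (flat Dirichlet prior over
the listed components plus the derived e2) and the fixed effects under
independent Normal(0, beta_sd) priors.  The stationary distribution is

    p(theta, L | Y)  ∝  exp(conditional loglik) * p(theta)

with the ascertainment-corrected conditional likelihood.  Proposal scales
are tuned during warmup by Robbins-Monro adaptation and frozen afterwards,
so the post-warmup chain is a valid Markov chain.

Per-chain seeds derive deterministically from the master seed; runs are
bitwise reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .ascertainment import AscertainmentError, fictitious_proband
from .model import (
    _COMPONENT_MATRIX,
    DesignMatrix,
    ModelSpec,
    Theta,
    build_design,
    gxe_similarity,
    threshold_from_prevalence,
)
from .pedigree import FamilyGraph, relationship_matrices

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "FitSummary",
    "LiabilityThresholdModel",
    "fit_families",
    "hpd_interval",
    "summarize",
]

_ADAPT_TARGET = 0.3


@dataclass
class ChainConfig:
    """Chain settings.  Defaults follow the study configuration: four
    chains, 5000 warmup and 5000 sampling iterations each."""

    n_chains: int = 4
    n_warmup: int = 5000
    n_sampling: int = 5000
    seed: int = 0
    init_strategy: str = "default"

    def __post_init__(self) -> None:
        if self.n_chains <= 0 or self.n_warmup < 0 or self.n_sampling < 0:
            raise ValueError("chain counts must be positive")

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.n_sampling

    def chain_seed(self, chain: int) -> int:
        return int((self.seed * 1000003 + 7919 * chain + 12345) % (2**31 - 1))


class PosteriorDraws:
    """Posterior draws, one array of shape (n_chains, n_sampling) per parameter."""

    def __init__(self, params: dict[str, np.ndarray], config: ChainConfig,
                 vc_names: tuple[str, ...], beta_names: tuple[str, ...]):
        self.params = params
        self.config = config
        self.vc_names = vc_names
        self.beta_names = beta_names

    def stacked(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    @property
    def n_draws(self) -> int:
        first = next(iter(self.params.values()))
        return int(first.size)

    def to_dataframe(self):
        import pandas as pd

        cols = {name: self.stacked(name) for name in self.params}
        n_chains, n_samp = next(iter(self.params.values())).shape
        cols["chain"] = np.repeat(np.arange(n_chains), n_samp)
        cols["draw"] = np.tile(np.arange(n_samp), n_chains)
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# simplex transform
# ---------------------------------------------------------------------------

def _softmax0(z: np.ndarray) -> np.ndarray:
    """Map z in R^m to an (m+1)-simplex point (last entry is the reference)."""
    full = np.concatenate([z, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _log_jacobian(vcfull: np.ndarray) -> float:
    # |d vc / d z| for the softmax-with-reference map
    return float(np.sum(np.log(np.maximum(vcfull, 1e-300))))


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------

@dataclass
class _Packed:
    sizes: np.ndarray
    offsets: np.ndarray
    comp: np.ndarray  # (F, K+1, maxn, maxn), identity last
    X: np.ndarray
    proband_X: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    c: float
    correct: bool
    design: DesignMatrix
    proband_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))

    @property
    def n_individuals(self) -> int:
        return int(self.sizes.sum())


def _pack(families: Sequence[FamilyGraph], spec: ModelSpec,
          design: DesignMatrix | None = None) -> _Packed:
    design = design if design is not None else build_design(families, spec)
    c = threshold_from_prevalence(spec.prevalence)
    F = len(families)
    sizes = design.family_sizes
    offsets = design.family_offsets
    maxn = int(sizes.max()) if F else 1
    K = len(spec.variance_components)
    comp = np.zeros((F, K + 1, maxn, maxn))
    lower = np.empty(int(sizes.sum()))
    upper = np.empty(int(sizes.sum()))
    proband_X = np.zeros((F, design.X.shape[1]))
    proband_counts = np.zeros(F, np.int64)
    for f, fam in enumerate(families):
        mats = relationship_matrices(fam)
        by = mats.by_name()
        n = int(sizes[f])
        s_gxe = None
        if "h2_gxe" in spec.variance_components:
            s_gxe = gxe_similarity(fam, spec.gxe_stratum)
        for k, name in enumerate(spec.variance_components):
            if name == "h2_gxe":
                comp[f, k, :n, :n] = by["k2"] * s_gxe
            else:
                comp[f, k, :n, :n] = by[_COMPONENT_MATRIX[name]]
        comp[f, K, :n, :n] = np.eye(n)
        o = int(offsets[f])
        for i, m in enumerate(fam.analysis_members):
            if m.affected:
                lower[o + i], upper[o + i] = c, math.inf
            else:
                lower[o + i], upper[o + i] = -math.inf, c
        if spec.ascertainment_correction:
            rec = fictitious_proband(fam, design, f)
            proband_X[f] = rec.covariate_row
            proband_counts[f] = rec.n_actual_probands
    return _Packed(sizes=sizes, offsets=offsets, comp=comp, X=design.X,
                   proband_X=proband_X, lower=lower, upper=upper, c=c,
                   correct=spec.ascertainment_correction, design=design,
                   proband_counts=proband_counts)


# ---------------------------------------------------------------------------
# one chain
# ---------------------------------------------------------------------------

class _Chain:
    """State and transition kernels of a single chain (exposed for testing)."""

    def __init__(self, packed: _Packed, spec: ModelSpec, seed: int):
        self.packed = packed
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        _kernels.set_seed(seed)
        self.m = len(spec.variance_components)
        self.p = packed.X.shape[1]
        self.z = np.zeros(self.m)
        self.vcfull = _softmax0(self.z)
        self.beta = np.zeros(self.p)
        self.log_s_z = math.log(0.4 / math.sqrt(self.m + 1))
        self.log_s_b = math.log(0.2 / math.sqrt(self.p + 1))
        self.t = 0
        self._init_liabilities()
        self._refresh_precisions()
        self.lp = self._loglik(self.vcfull, self.beta)

    # -- initialization --------------------------------------------------

    def _init_liabilities(self) -> None:
        from scipy.stats import norm

        N = self.packed.n_individuals
        self.L = np.zeros(N)
        if N == 0:
            return
        mu = self.packed.X @ self.beta
        lo, hi = self.packed.lower, self.packed.upper
        for i in range(N):
            if lo[i] > -1e290:  # case: mean of N(mu,1) above the threshold
                a = lo[i] - mu[i]
                self.L[i] = mu[i] + norm.pdf(a) / max(norm.sf(a), 1e-300)
            else:  # control: mean below the threshold
                a = hi[i] - mu[i]
                self.L[i] = mu[i] - norm.pdf(a) / max(norm.cdf(a), 1e-300)

    def _refresh_precisions(self) -> None:
        pk = self.packed
        F = pk.sizes.shape[0]
        if F == 0:
            self.omega = np.zeros((0, 1, 1))
            self.mu = np.zeros(0)
            return
        maxn = pk.comp.shape[2]
        if not hasattr(self, "omega"):
            self.omega = np.zeros((F, maxn, maxn))
            self.mu = np.zeros(pk.n_individuals)
        _kernels.packed_precisions(self.vcfull, self.beta, pk.comp, pk.sizes,
                                   pk.offsets, pk.X, self.omega, self.mu)

    # -- kernels ---------------------------------------------------------

    def _loglik(self, vcfull: np.ndarray, beta: np.ndarray) -> float:
        pk = self.packed
        if pk.sizes.shape[0] == 0:
            return 0.0
        return float(_kernels.packed_loglik(
            vcfull, beta, pk.comp, pk.sizes, pk.offsets, pk.X, self.L,
            pk.proband_X, pk.c, pk.correct))

    def _log_prior_beta(self, beta: np.ndarray) -> float:
        sd = self.spec.prior.beta_sd
        return -0.5 * float(np.sum((beta / sd) ** 2))

    def step_liabilities(self) -> None:
        pk = self.packed
        if pk.sizes.shape[0] == 0:
            return
        _kernels.gibbs_sweep(self.L, self.mu, self.omega, pk.sizes, pk.offsets,
                             pk.lower, pk.upper)
        self.lp = self._loglik(self.vcfull, self.beta)

    def step_vc(self, adapt: bool) -> bool:
        zp = self.z + math.exp(self.log_s_z) * self.rng.standard_normal(self.m)
        vcp = _softmax0(zp)
        lpp = self._loglik(vcp, self.beta)
        log_a = (lpp + _log_jacobian(vcp)) - (self.lp + _log_jacobian(self.vcfull))
        acc_prob = min(1.0, math.exp(min(log_a, 0.0)))
        accepted = self.rng.random() < acc_prob
        if accepted:
            self.z, self.vcfull, self.lp = zp, vcp, lpp
        if adapt:
            self.log_s_z += (acc_prob - _ADAPT_TARGET) / (self.t + 10) ** 0.6
            self.log_s_z = min(max(self.log_s_z, -10.0), 3.0)
        return accepted

    def step_beta(self, adapt: bool) -> bool:
        if self.p == 0:
            return False
        bp = self.beta + math.exp(self.log_s_b) * self.rng.standard_normal(self.p)
        lpp = self._loglik(self.vcfull, bp)
        log_a = (lpp + self._log_prior_beta(bp)) - (self.lp + self._log_prior_beta(self.beta))
        acc_prob = min(1.0, math.exp(min(log_a, 0.0)))
        accepted = self.rng.random() < acc_prob
        if accepted:
            self.beta, self.lp = bp, lpp
        if adapt:
            self.log_s_b += (acc_prob - _ADAPT_TARGET) / (self.t + 10) ** 0.6
            self.log_s_b = min(max(self.log_s_b, -10.0), 3.0)
        return accepted

    def step(self, adapt: bool) -> None:
        self.step_liabilities()
        a1 = self.step_vc(adapt)
        a2 = self.step_beta(adapt)
        if a1 or a2:
            self._refresh_precisions()
        self.t += 1


# ---------------------------------------------------------------------------
# the model front end
# ---------------------------------------------------------------------------

class LiabilityThresholdModel:
    """Bayesian liability threshold model on ascertained families.

    Parameters
    ----------
    families : list of FamilyGraph
        Validated, filtered families.  May be empty, in which case the
        sampler draws from the prior.
    spec : ModelSpec
        Variance components, covariates, prevalence, priors and the
        ascertainment-correction toggle.
    """

    def __init__(self, families: Sequence[FamilyGraph], spec: ModelSpec,
                 design: DesignMatrix | None = None):
        self.families = list(families)
        self.spec = spec
        self.packed = _pack(self.families, spec, design)
        self.design = self.packed.design
        self.threshold = self.packed.c

    def fit(self, config: ChainConfig | None = None) -> "FitResult":
        config = config or ChainConfig()
        if config.n_sampling == 0:
            warnings.warn("n_sampling=0: returning empty draws", stacklevel=2)
        vc_names = self.spec.variance_components
        beta_names = tuple(f"beta_{c}" for c in self.design.columns)
        names = list(vc_names) + ["e2"] + list(beta_names)
        out = {n: np.zeros((config.n_chains, config.n_sampling)) for n in names}
        for ch in range(config.n_chains):
            chain = _Chain(self.packed, self.spec, config.chain_seed(ch))
            for it in range(config.n_warmup):
                chain.step(adapt=True)
            for it in range(config.n_sampling):
                chain.step(adapt=False)
                for k, n in enumerate(vc_names):
                    out[n][ch, it] = chain.vcfull[k]
                out["e2"][ch, it] = chain.vcfull[-1]
                for k, n in enumerate(beta_names):
                    out[n][ch, it] = chain.beta[k]
        draws = PosteriorDraws(out, config, vc_names, beta_names)
        return FitResult(draws, self)


def fit_families(families: Sequence[FamilyGraph], spec: ModelSpec,
                 config: ChainConfig | None = None) -> "FitResult":
    """One-call convenience wrapper: build the model and run the chains."""
    return LiabilityThresholdModel(families, spec).fit(config)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * n) sorted draws
    (earliest window on ties)."""
    x = np.sort(np.asarray(draws, dtype=float).reshape(-1))
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws for an HPD interval, got {n}")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass
class FitSummary:
    """Per-parameter posterior median, SD, 95% HPD and diagnostics."""

    table: "object"  # pandas.DataFrame
    reporting_scale: str = "phenotypic"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def row(self, parameter: str) -> dict:
        t = self.table
        return t[t["parameter"] == parameter].iloc[0].to_dict()

    def value(self, parameter: str, col: str = "median") -> float:
        return float(self.row(parameter)[col])


def _diagnostics(arr: np.ndarray) -> tuple[float, float]:
    try:
        import arviz as az

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        return rhat, ess
    except Exception:
        return float("nan"), float("nan")


def _derived_series(result: "FitResult") -> dict[str, np.ndarray]:
    """Per-draw series on the reporting scale of the output tables.

    Residual-scale components keep a ``_resid`` suffix; the headline rows
    divide everything by the per-draw total phenotypic variance 1 + tau2
    so the printed fractions (components + tau2 shares) sum to one.
    Fixed effects are reported per raw covariate contrast.
    """
    draws = result.draws
    design = result.model.design
    spec = result.model.spec
    cols = design.columns
    vc_names = draws.vc_names

    series: dict[str, np.ndarray] = {}
    beta_mat = (np.stack([draws[f"beta_{c}"] for c in cols], axis=-1)
                if cols else np.zeros(next(iter(draws.params.values())).shape + (0,)))
    shape = next(iter(draws.params.values())).shape

    if len(cols) and design.X.shape[0] > 1:
        cov = np.cov(design.X, rowvar=False, ddof=1).reshape(len(cols), len(cols))
        tau2_total = np.einsum("cdk,kl,cdl->cd", beta_mat, cov, beta_mat)
        tau2_per = {c: beta_mat[..., k] ** 2 * cov[k, k] for k, c in enumerate(cols)}
        cov_terms = {
            (cols[k], cols[l]): 2.0 * beta_mat[..., k] * beta_mat[..., l] * cov[k, l]
            for k in range(len(cols)) for l in range(k + 1, len(cols))
        }
    else:
        tau2_total = np.zeros(shape)
        tau2_per = {c: np.zeros(shape) for c in cols}
        cov_terms = {(cols[k], cols[l]): np.zeros(shape)
                     for k in range(len(cols)) for l in range(k + 1, len(cols))}

    denom = 1.0 + tau2_total
    c2_parts = [n for n in vc_names if n.startswith("c2_")]
    c2_total = sum((draws[n] for n in c2_parts), np.zeros(shape))

    for n in vc_names:
        series[n] = draws[n] / denom
        series[f"{n}_resid"] = draws[n]
    if c2_parts:
        series["c2_total"] = c2_total / denom
        series["c2_total_resid"] = c2_total
    series["e2"] = draws["e2"] / denom
    series["e2_resid"] = draws["e2"]
    if len(cols):
        series["tau2_" + "_".join(cols)] = tau2_total / denom
        for c in cols:
            series[f"tau2_{c}"] = tau2_per[c] / denom
        for (a, b), v in cov_terms.items():
            series[f"2cov_{a}_{b}"] = v / denom
        raw_scale = design.sds if design.standardized else np.ones(len(cols))
        for k, c in enumerate(cols):
            series[f"beta_{c}"] = beta_mat[..., k] / raw_scale[k]
    return series


def summarize(result: "FitResult", mass: float = 0.95) -> FitSummary:
    """Posterior median / SD / HPD table plus split R-hat and ESS."""
    import pandas as pd

    rows = []
    for name, arr in _derived_series(result).items():
        flat = arr.reshape(-1)
        try:
            lo, hi = hpd_interval(flat, mass)
        except ValueError:
            lo = hi = float("nan")
        rhat, ess = _diagnostics(arr)
        rows.append({
            "parameter": name,
            "median": float(np.median(flat)),
            "sd": float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0,
            "hpd_low": lo,
            "hpd_high": hi,
            "rhat": rhat,
            "ess": ess,
        })
    return FitSummary(pd.DataFrame(rows))


class FitResult:
    """Posterior draws plus the fitted model context."""

    def __init__(self, draws: PosteriorDraws, model: LiabilityThresholdModel):
        self.draws = draws
        self.model = model

    def summary(self, mass: float = 0.95) -> FitSummary:
        return summarize(self, mass)

    def derived_series(self) -> dict[str, np.ndarray]:
        return _derived_series(self)

    def median_theta(self) -> Theta:
        vc = {n: float(np.median(self.draws.stacked(n))) for n in self.draws.vc_names}
        beta = np.array([
            float(np.median(self.draws.stacked(f"beta_{c}")))
            for c in self.model.design.columns
        ])
        total = sum(vc.values())
        if total > 1.0:  # medians need not respect the simplex exactly
            vc = {k: v / (total + 1e-9) for k, v in vc.items()}
        return Theta(vc=vc, beta=beta)
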