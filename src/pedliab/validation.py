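"""Independent checking tools: gene-dropping kinship, tetrachoric
correlation, implied prevalence, and simulator/fitter round-trip harnesses.

These are deliberately separate computational routes from the main code
paths (Monte Carlo allele dropping vs. the kinship recursion, 2x2-table
inversion vs. the generative covariance) so they can serve as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from . import _kernels
from .model import ModelSpec, Theta, threshold_from_prevalence
from .pedigree import FamilyGraph
from .sampler import ChainConfig, LiabilityThresholdModel, hpd_interval
from .simulate import SimDesign, simulate_study

__all__ = [
    "gene_drop_k2",
    "tetrachoric_correlation",
    "implied_prevalence",
    "RecoveryReplicate",
    "parameter_recovery",
    "sbc_ranks",
]


def gene_drop_k2(fam: FamilyGraph, n_rep: int = 100_000, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo additive-relationship estimate over the analysis members.

    Drops two uniquely labelled founder alleles down the pedigree ``n_rep``
    times and scores identity-by-descent sharing.  Returns (K2_hat, SE).
    """
    fa, mo = fam.parent_indices()
    order = fam.topological_order()
    _kernels.set_seed(seed)
    k2_full, se_full = _kernels.gene_drop_k2(fa, mo, order, n_rep)
    idx = [i for i, m in enumerate(fam.members) if m.in_analysis]
    sel = np.ix_(idx, idx)
    return k2_full[sel], se_full[sel]


def tetrachoric_correlation(counts: np.ndarray, threshold1: float,
                            threshold2: float) -> float:
    """Latent-normal correlation from a 2x2 table of dichotomized pairs.

    ``counts[i, j]`` counts pairs with (first > t1) == i and
    (second > t2) == j.  Solves P(Z1 > t1, Z2 > t2; r) = observed p11.
    """
    counts = np.asarray(counts, dtype=float)
    p11 = counts[1, 1] / counts.sum()

    def upper_quadrant(r: float) -> float:
        mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
        # P(Z1 > t1, Z2 > t2) by inclusion-exclusion on CDFs
        return (1.0 - norm.cdf(threshold1) - norm.cdf(threshold2)
                + mvn.cdf([threshold1, threshold2]))

    return brentq(lambda r: upper_quadrant(r) - p11, -0.999, 0.999, xtol=1e-6)


def implied_prevalence(beta: np.ndarray, c: float,
                       covariate_cells: dict[tuple, int]) -> float:
    """Population prevalence implied by fixed effects and the threshold:
    the covariate-cell-weighted average of P(L > c | x) = 1 - Phi(c - x'b)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    total = sum(covariate_cells.values())
    acc = 0.0
    for cell, cnt in covariate_cells.items():
        acc += cnt * float(norm.sf(c - np.dot(cell, beta)))
    return acc / total


# ---------------------------------------------------------------------------
# round-trip harnesses
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReplicate:
    """One simulate-and-refit replicate."""

    medians: dict[str, float]
    hpd: dict[str, tuple[float, float]]
    covered: dict[str, bool]
    implied_prevalence_hpd: tuple[float, float]
    true_implied_prevalence: float
    bias_detected: bool  # implied-prevalence HPD entirely above the truth


def _true_values(design: SimDesign) -> dict[str, float]:
    vals = dict(design.theta_true.vc)
    vals["e2"] = design.theta_true.e2
    for k, cov in enumerate(design.covariates):
        vals[f"beta_{cov}"] = float(design.theta_true.beta[k])
    return vals


def parameter_recovery(
    design: SimDesign,
    config: ChainConfig,
    n_replicates: int,
    seed: int = 0,
    ascertainment_correction: bool = True,
) -> list[RecoveryReplicate]:
    """Simulate ``n_replicates`` studies from ``design`` and refit each.

    Per replicate records posterior medians, 95% HPDs, coverage of the true
    values, and whether the fit's implied population prevalence sits
    detectably above the simulation truth (ascertainment-bias signal).
    """
    spec = design.model_spec(ascertainment_correction)
    c = threshold_from_prevalence(design.prevalence)
    out = []
    for rep in range(n_replicates):
        sim = simulate_study(design, seed=seed * 100_003 + rep)
        model = LiabilityThresholdModel(sim.families, spec)
        rep_cfg = ChainConfig(n_chains=config.n_chains, n_warmup=config.n_warmup,
                              n_sampling=config.n_sampling,
                              seed=config.seed * 1009 + rep)
        res = model.fit(rep_cfg)
        truth = _true_values(design)
        medians, hpds, covered = {}, {}, {}
        for name in truth:
            flat = res.draws.stacked(name)
            medians[name] = float(np.median(flat))
            lo, hi = hpd_interval(flat)
            hpds[name] = (lo, hi)
            covered[name] = bool(lo <= truth[name] <= hi)
        # implied prevalence per draw over the candidate covariate cells
        cells = sim.candidate_covariate_cells
        total = sum(cells.values())
        xs = np.array([list(k) for k in cells])
        w = np.array([cells[tuple(x)] for x in xs], dtype=float) / total
        beta_mat = np.stack(
            [res.draws.stacked(f"beta_{cov}") for cov in design.covariates], axis=-1)
        ip_draws = norm.sf(c - beta_mat @ xs.T) @ w
        ip_lo, ip_hi = hpd_interval(ip_draws)
        out.append(RecoveryReplicate(
            medians=medians, hpd=hpds, covered=covered,
            implied_prevalence_hpd=(ip_lo, ip_hi),
            true_implied_prevalence=sim.candidate_implied_prevalence,
            bias_detected=bool(ip_lo > sim.candidate_implied_prevalence),
        ))
    return out


def sbc_ranks(
    design_template: SimDesign,
    spec: ModelSpec,
    config: ChainConfig,
    n_datasets: int,
    n_rank_draws: int = 20,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulation-based calibration rank statistics.

    For each dataset: draw theta from the model prior, simulate a study at
    that truth, fit, and record the rank of the true value within
    ``n_rank_draws`` thinned posterior draws.  Exact posterior computation
    makes the ranks uniform on {0..n_rank_draws}.
    """
    rng = np.random.default_rng(seed)
    comp_names = spec.variance_components
    m = len(comp_names)
    params = list(comp_names) + ["e2"] + [f"beta_{c}" for c in spec.covariates]
    ranks: dict[str, list[int]] = {p: [] for p in params}
    for d in range(n_datasets):
        vc_full = rng.dirichlet(np.ones(m + 1))
        beta = rng.normal(0.0, spec.prior.beta_sd, size=len(spec.covariates))
        theta = Theta(vc=dict(zip(comp_names, vc_full[:m])), beta=beta)
        design = SimDesign(
            n_families=design_template.n_families,
            shape=design_template.shape,
            theta_true=theta,
            prevalence=design_template.prevalence,
            covariates=design_template.covariates,
            ascertainment=design_template.ascertainment,
            p_proband=design_template.p_proband,
            max_candidates=design_template.max_candidates,
        )
        sim = simulate_study(design, seed=int(rng.integers(2**31 - 1)))
        res = LiabilityThresholdModel(sim.families, spec).fit(
            ChainConfig(n_chains=config.n_chains, n_warmup=config.n_warmup,
                        n_sampling=config.n_sampling,
                        seed=int(rng.integers(2**31 - 1))))
        truth = {**dict(zip(comp_names, vc_full[:m])), "e2": float(vc_full[m])}
        for k, cov in enumerate(spec.covariates):
            truth[f"beta_{cov}"] = float(beta[k])
        for p in params:
            flat = res.draws.stacked(p)
            idx = np.linspace(0, flat.size - 1, n_rank_draws).astype(int)
            thin = flat[idx]
            ranks[p].append(int(np.sum(thin < truth[p])))
    return {p: np.asarray(v) for p, v in ranks.items()}
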