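"""Ascertainment-corrected conditional likelihood.

Families enter the study through affected probands, so the complete-data
likelihood (a truncated multivariate normal over the latent liabilities)
must be divided by the probability of the ascertainment event.  Under the
assumption-free proband correction that probability depends only on the
proband's *phenotype*: per family,

    p(proband) = mu^y (1 - mu)^(1-y),   mu = P(L_p > c) = 1 - Phi(c - x_p' b)

with y = 1 for every ascertained family.  When several (possibly
distantly related) probands exist in a family, a single fictitious proband
is used whose covariate row is the mean of the actual probands' rows.

The correction is a function of beta and the proband covariates only — it
has no dependence on the latent liabilities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .model import DesignMatrix
from .pedigree import FamilyGraph

logger = logging.getLogger(__name__)

MU_CLAMP = 1e-12
_LOG2PI = math.log(2.0 * math.pi)

__all__ = [
    "AscertainmentError",
    "ProbandRecord",
    "LiabilityState",
    "truncation_bounds",
    "complete_data_loglik",
    "fictitious_proband",
    "proband_loglik",
    "conditional_loglik",
]


class AscertainmentError(ValueError):
    """A family cannot be ascertainment-corrected (e.g. no probands)."""


@dataclass
class ProbandRecord:
    """Fictitious proband of one ascertained family."""

    family_id: str
    covariate_row: np.ndarray  # on the same (possibly standardized) scale as X
    y_p: int = 1
    n_actual_probands: int = 1  # diagnostics: quality of the single-proband surrogate

    def mu(self, beta: np.ndarray, c: float) -> float:
        """P(proband liability exceeds the threshold), clamped away from {0, 1}."""
        raw = float(norm.sf(c - float(self.covariate_row @ np.atleast_1d(beta))))
        if raw < MU_CLAMP or raw > 1.0 - MU_CLAMP:
            logger.warning("family %s: mu=%.3e clamped", self.family_id, raw)
            return min(max(raw, MU_CLAMP), 1.0 - MU_CLAMP)
        return raw


@dataclass
class LiabilityState:
    """Current latent liabilities with their per-individual truncation bounds."""

    L: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)

    def in_bounds(self) -> bool:
        return bool(np.all(self.L > self.lower) and np.all(self.L < self.upper))


def truncation_bounds(affected: bool, c: float) -> tuple[float, float]:
    """(-inf, c) for controls, (c, +inf) for cases."""
    return (c, math.inf) if affected else (-math.inf, c)


def complete_data_loglik(
    state: LiabilityState,
    mu: np.ndarray,
    sigmas: Sequence[np.ndarray],
    family_offsets: np.ndarray,
) -> float:
    """Log truncated-MVN density of the liabilities: the sum over families of
    log MVN(L_f; mu_f, Sigma_f), or -inf if any truncation bound is violated."""
    if not state.in_bounds():
        return -math.inf
    total = 0.0
    for f, sigma in enumerate(sigmas):
        n = sigma.shape[0]
        o = int(family_offsets[f])
        r = state.L[o:o + n] - mu[o:o + n]
        c_and_lower = cho_factor(sigma, lower=True)
        y = cho_solve(c_and_lower, r)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c_and_lower[0]))))
        total += -0.5 * (float(r @ y) + logdet + n * _LOG2PI)
    return total


def fictitious_proband(fam: FamilyGraph, design: DesignMatrix, family_index: int) -> ProbandRecord:
    """Average the actual probands' covariate rows into one pseudo-proband."""
    members = fam.analysis_members
    rows = design.family_rows(family_index)
    proband_rows = [rows[i] for i, m in enumerate(members) if m.is_proband]
    if not proband_rows:
        raise AscertainmentError(
            f"family {fam.family_id}: no probands; cannot build the ascertainment correction"
        )
    return ProbandRecord(
        family_id=fam.family_id,
        covariate_row=np.mean(proband_rows, axis=0),
        y_p=1,
        n_actual_probands=len(proband_rows),
    )


def proband_loglik(probands: Sequence[ProbandRecord], beta: np.ndarray, c: float) -> float:
    """Sum over families of y*log(mu/(1-mu)) + log(1-mu) — the Bernoulli
    log-pmf of the proband's phenotype at probability mu."""
    total = 0.0
    for rec in probands:
        mu = rec.mu(beta, c)
        total += rec.y_p * math.log(mu / (1.0 - mu)) + math.log(1.0 - mu)
    return total


def conditional_loglik(
    state: LiabilityState,
    mu: np.ndarray,
    sigmas: Sequence[np.ndarray],
    family_offsets: np.ndarray,
    probands: Sequence[ProbandRecord],
    beta: np.ndarray,
    c: float,
) -> float:
    """Ascertainment-corrected log-likelihood: complete-data term minus the
    proband (phenotype-only) correction term."""
    full = complete_data_loglik(state, mu, sigmas, family_offsets)
    if not math.isfinite(full):
        return -math.inf
    return full - proband_loglik(probands, beta, c)
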