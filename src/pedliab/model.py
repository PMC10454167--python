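"""Liability-scale model building blocks.

The binary phenotype is the thresholding of a latent liability,
L ~ MVN(Xb, Sigma), affected iff L > c with c the standard-normal upper
quantile at the population prevalence.  Per family,

    Sigma = h2*K2 + c2_sibs*H1 + c2_mo*H2 + c2_fo*H3 + c2_sp*H4 + e2*I
            [+ h2_gxe * (K2 o S)]

where the variance parameters are proportions of the residual (liability
given covariates) variance and e2 is derived as one minus the sum of the
listed components, so Sigma has unit diagonal on non-inbred pedigrees.
The optional gene-by-environment term uses the same-stratum indicator S
(elementwise product with K2).

Fixed effects contribute tau2 = var(Xb), decomposable into per-covariate
shares and pairwise covariance terms; on the reported scale every variance
parameter is re-expressed as a fraction of the total phenotypic variance
1 + tau2, so the printed components (including the tau2 shares) sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .pedigree import FamilyGraph, Individual, RelationshipMatrices

__all__ = [
    "VC_COMPONENTS",
    "PriorSpec",
    "ModelSpec",
    "Theta",
    "DesignMatrix",
    "VarianceDecomposition",
    "threshold_from_prevalence",
    "build_sigma",
    "gxe_similarity",
    "build_design",
    "decompose_fixed_effects",
]

#: recognized variance components, in canonical order
VC_COMPONENTS = ("h2", "c2_sibs", "c2_mother_off", "c2_father_off", "c2_spouses", "h2_gxe")

_COMPONENT_MATRIX = {
    "h2": "k2",
    "c2_sibs": "h_sibs",
    "c2_mother_off": "h_mother_off",
    "c2_father_off": "h_father_off",
    "c2_spouses": "h_spouses",
}


@dataclass
class PriorSpec:
    """Priors: flat Dirichlet over (variance components, e2) jointly —
    the joint version of independent Beta(1,1) margins under the
    sum-to-one constraint — and Normal(0, beta_sd) on each fixed effect."""

    beta_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.beta_sd <= 0:
            raise ValueError("beta_sd must be positive")


@dataclass
class ModelSpec:
    """Configuration of one liability-threshold analysis."""

    variance_components: tuple[str, ...] = (
        "h2", "c2_sibs", "c2_mother_off", "c2_father_off", "c2_spouses")
    covariates: tuple[str, ...] = ("sex", "yob1946")
    prevalence: float = 157e-5
    standardize_covariates: bool = True
    prior: PriorSpec = field(default_factory=PriorSpec)
    gxe_stratum: str = "yob1946"
    ascertainment_correction: bool = True

    def __post_init__(self) -> None:
        self.variance_components = tuple(self.variance_components)
        self.covariates = tuple(self.covariates)
        if not self.variance_components:
            raise ValueError("at least one variance component is required")
        if "e2" in self.variance_components:
            raise ValueError("e2 is derived (1 minus the sum) and must not be listed")
        for vc in self.variance_components:
            if vc not in VC_COMPONENTS:
                raise ValueError(f"unknown variance component {vc!r}")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "prior" in raw:
            raw["prior"] = PriorSpec(**raw["prior"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "variance_components": list(self.variance_components),
            "covariates": list(self.covariates),
            "prevalence": self.prevalence,
            "standardize_covariates": self.standardize_covariates,
            "prior": {"beta_sd": self.prior.beta_sd},
            "gxe_stratum": self.gxe_stratum,
            "ascertainment_correction": self.ascertainment_correction,
        }


@dataclass
class Theta:
    """One parameter state: listed variance proportions plus fixed effects.

    The proportions live on the residual liability scale and must leave a
    non-negative remainder e2 = 1 - sum(vc).
    """

    vc: dict[str, float]
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        for name, v in self.vc.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"variance component {name}={v} outside [0, 1]")
        if self.e2 < -1e-12:
            raise ValueError(f"variance components sum to {sum(self.vc.values())} > 1")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    @property
    def e2(self) -> float:
        return 1.0 - float(sum(self.vc.values()))


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------

def threshold_from_prevalence(prevalence: float) -> float:
    """Liability threshold c with upper-tail mass equal to the prevalence:
    c = Phi^-1(1 - prevalence)."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    return float(norm.isf(prevalence))


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------

def gxe_similarity(fam: FamilyGraph, stratum_covariate: str = "yob1946") -> np.ndarray:
    """Same-stratum indicator S over the analysis members (diagonal 1).

    The gene-by-environment covariance contribution is h2_gxe * (K2 o S).
    A single-stratum family makes that term proportional to K2, i.e.
    confounded with the additive component; a warning is emitted.
    """
    values = [_covariate_value(m, stratum_covariate) for m in fam.analysis_members]
    uniq = set(values)
    if len(uniq) > 2:
        raise ValueError(f"stratum covariate {stratum_covariate!r} is not binary")
    if len(uniq) == 1 and len(values) > 1:
        warnings.warn(
            f"family {fam.family_id}: all analysis members share one "
            f"{stratum_covariate} stratum; the GxE term is confounded with h2 "
            f"in this family",
            stacklevel=2,
        )
    v = np.asarray(values)
    return (v[:, None] == v[None, :]).astype(float)


def build_sigma(
    theta: Theta,
    mats: RelationshipMatrices,
    spec: ModelSpec,
    gxe_s: np.ndarray | None = None,
) -> np.ndarray:
    """Per-family liability covariance under the configured component set.

    Applies the positive-semidefiniteness jitter policy: an eigenvalue
    floor slightly below zero is tolerated with a 1e-8 diagonal ridge;
    anything below -1e-8 is an error (genuine mis-specification).
    """
    by_name = mats.by_name()
    n = len(mats.ids)
    sigma = theta.e2 * np.eye(n)
    for name in spec.variance_components:
        coef = theta.vc.get(name, 0.0)
        if name == "h2_gxe":
            if gxe_s is None:
                raise ValueError("h2_gxe requested but no stratum similarity matrix given")
            mat = by_name["k2"] * gxe_s
        else:
            mat = by_name[_COMPONENT_MATRIX[name]]
        if mat.shape != (n, n):
            raise ValueError(
                f"component {name}: matrix shape {mat.shape} does not match family size {n}"
            )
        sigma = sigma + coef * mat
    eigmin = float(np.linalg.eigvalsh(sigma)[0])
    if eigmin < -1e-8:
        raise np.linalg.LinAlgError(
            f"family {mats.ids[0] if mats.ids else '?'}: covariance not PSD "
            f"(min eigenvalue {eigmin:.3e})"
        )
    if eigmin < 1e-10:
        sigma = sigma + 1e-8 * np.eye(n)
    return sigma


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _covariate_value(ind: Individual, name: str) -> float:
    if name == "sex":
        return 1.0 if ind.sex == "female" else 0.0
    if name == "yob1946":
        if ind.year_of_birth is None:
            raise ValueError(f"individual {ind.individual_id}: missing year_of_birth")
        return 1.0 if ind.year_of_birth >= 1946 else 0.0
    if name == "year10":
        # exact year of birth as a continuous covariate, in decades from 1946
        if ind.year_of_birth is None:
            raise ValueError(f"individual {ind.individual_id}: missing year_of_birth")
        return (ind.year_of_birth - 1946) / 10.0
    raise ValueError(f"unknown covariate {name!r}")


#: human-readable raw contrast per covariate column
CONTRAST_LABELS = {
    "sex": "females vs. males",
    "yob1946": ">=1946 vs. <1946",
    "year10": "10 years increase",
}


@dataclass
class DesignMatrix:
    """Covariate matrix over the concatenated analysis members.

    Row order is the concatenation of ``fam.analysis_members`` over the
    family list.  When standardization is enabled each column is centred
    and scaled to sample SD 1 over the analysis set; the raw-scale
    transform (mean, sd) is retained so fitted effects can be reported per
    raw contrast unit.
    """

    X: np.ndarray
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    standardized: bool
    family_sizes: np.ndarray
    row_ids: list[tuple[str, str]]  # (family_id, individual_id)

    @property
    def family_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.family_sizes)[:-1]]).astype(np.int64)

    def raw_effect(self, beta: np.ndarray) -> np.ndarray:
        """Fixed effects per raw covariate unit (undoes standardization)."""
        beta = np.asarray(beta, dtype=float)
        return beta / self.sds if self.standardized else beta.copy()

    def family_rows(self, f: int) -> np.ndarray:
        o = self.family_offsets[f]
        return self.X[o:o + self.family_sizes[f]]


def build_design(families: Sequence[FamilyGraph], spec: ModelSpec) -> DesignMatrix:
    """Assemble the covariate design matrix over all analysis members."""
    cols = spec.covariates
    rows, row_ids, sizes = [], [], []
    for fam in families:
        members = fam.analysis_members
        sizes.append(len(members))
        for m in members:
            rows.append([_covariate_value(m, c) for c in cols])
            row_ids.append((fam.family_id, m.individual_id))
    X = np.asarray(rows, dtype=float).reshape(len(rows), len(cols))
    means = np.zeros(len(cols))
    sds = np.ones(len(cols))
    if spec.standardize_covariates and len(cols) and X.shape[0] > 1:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        for k, c in enumerate(cols):
            if sds[k] == 0 or not np.isfinite(sds[k]):
                raise ValueError(f"covariate {c!r} has zero variance; cannot standardize")
        X = (X - means) / sds
    return DesignMatrix(
        X=X, columns=cols, means=means, sds=sds,
        standardized=bool(spec.standardize_covariates and len(cols)),
        family_sizes=np.asarray(sizes, dtype=np.int64),
        row_ids=row_ids,
    )


# ---------------------------------------------------------------------------
# fixed-effect variance decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarianceDecomposition:
    """tau2 = var(Xb) split into per-covariate shares and covariance terms.

    ``phenotypic_scale_fractions`` re-expresses every piece as a fraction
    of the total phenotypic variance 1 + tau2 (the scale on which the
    residual variance components are also reported).
    """

    tau2_total: float
    tau2_per_covariate: dict[str, float]
    cov_terms: dict[tuple[str, str], float]

    @property
    def phenotypic_scale_fractions(self) -> dict[str, float]:
        denom = 1.0 + self.tau2_total
        out = {f"tau2_{k}": v / denom for k, v in self.tau2_per_covariate.items()}
        for (a, b), v in self.cov_terms.items():
            out[f"2cov_{a}_{b}"] = v / denom
        out["tau2_total"] = self.tau2_total / denom
        return out


def decompose_fixed_effects(design: DesignMatrix | np.ndarray, beta: np.ndarray,
                            columns: Sequence[str] | None = None) -> VarianceDecomposition:
    """Decompose var(Xb) into beta_k^2 var(X_k) terms plus 2 beta_k beta_l cov(X_k, X_l)."""
    if isinstance(design, DesignMatrix):
        X, cols = design.X, design.columns
    else:
        X = np.asarray(design, dtype=float)
        cols = tuple(columns) if columns is not None else tuple(
            f"x{k}" for k in range(X.shape[1]))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X.shape[1] != beta.shape[0]:
        raise ValueError("X and beta are not conformable")
    if X.shape[1] == 0:
        return VarianceDecomposition(0.0, {}, {})
    cov = np.cov(X, rowvar=False, ddof=1).reshape(len(cols), len(cols))
    per = {c: float(beta[k] ** 2 * cov[k, k]) for k, c in enumerate(cols)}
    pairs = {
        (cols[k], cols[l]): float(2.0 * beta[k] * beta[l] * cov[k, l])
        for k in range(len(cols)) for l in range(k + 1, len(cols))
    }
    total = float(beta @ cov @ beta)
    return VarianceDecomposition(total, per, pairs)
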