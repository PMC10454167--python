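"""Synthetic ascertained-family generator.

Emulates the study design end to end: random 2-4 generation extended
pedigrees (parents, siblings, spouses, uncles/aunts, cousins,
nieces/nephews, grandparents all arise), sex and year-of-birth covariates
with the 1946 dichotomization, liabilities drawn from the family
covariance at a true parameter value, thresholding at the
prevalence-implied cutoff, and retention of families that contain at
least one affected member with probands labelled among the affected.

Simulated fixed effects apply to the RAW covariate codes (female=1,
born on/after 1946=1), so a true beta is well defined before any
sample-dependent standardization; fit with
``standardize_covariates=False`` to recover it on the same scale.

Default shape parameters were calibrated once against the study's family
table: sizes spanning roughly 7-93 with a median in the mid-20s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .model import ModelSpec, Theta, _covariate_value, build_sigma, threshold_from_prevalence
from .pedigree import FamilyGraph, Individual, relationship_matrices

__all__ = [
    "PedigreeShape",
    "SimDesign",
    "SimResult",
    "generate_pedigree",
    "simulate_phenotypes",
    "ascertain",
    "simulate_study",
]


@dataclass
class PedigreeShape:
    """Generator knobs for one extended pedigree."""

    generations: tuple[int, ...] = (3, 4)  # depth sampled uniformly from these
    mean_offspring: float = 3.4            # Poisson mean per reproducing couple
    fixed_offspring: int | None = None     # override: exact offspring count
    p_marry: float = 0.75                  # chance a non-terminal member gets a spouse
    founder_year: float = 1911.0
    founder_year_sd: float = 6.0
    generation_gap: float = 27.0
    generation_gap_sd: float = 5.0
    enrollment_year: int = 1995


@dataclass
class SimDesign:
    """Full study-level simulation design (the test-bed conditions)."""

    n_families: int = 24
    shape: PedigreeShape = field(default_factory=PedigreeShape)
    theta_true: Theta = field(
        default_factory=lambda: Theta(vc={"h2": 0.5, "c2_sibs": 0.2},
                                      beta=np.array([0.4, 3.0])))
    prevalence: float = 157e-5
    covariates: tuple[str, ...] = ("sex", "yob1946")
    ascertainment: str = "proband_based"  # or "none"
    p_proband: float = 0.75               # chance an affected member is a proband
    max_candidates: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ascertainment not in ("proband_based", "none"):
            raise ValueError(f"unknown ascertainment mode {self.ascertainment!r}")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")

    def model_spec(self, ascertainment_correction: bool = True) -> ModelSpec:
        """The fitting configuration matched to this design."""
        return ModelSpec(
            variance_components=tuple(self.theta_true.vc.keys()),
            covariates=self.covariates,
            prevalence=self.prevalence,
            standardize_covariates=False,
            ascertainment_correction=ascertainment_correction,
        )


@dataclass
class SimResult:
    """Retained families plus the generative ground truth."""

    families: list[FamilyGraph]
    liabilities: dict[str, np.ndarray]
    theta_true: Theta
    prevalence: float
    covariates: tuple[str, ...]
    n_candidates: int
    candidate_case_rate: float
    candidate_implied_prevalence: float
    candidate_covariate_means: np.ndarray
    #: pre-ascertainment covariate-cell counts {raw covariate row -> count},
    #: the population covariate distribution for implied-prevalence checks
    candidate_covariate_cells: dict[tuple, int] = field(default_factory=dict)

    @property
    def retention_rate(self) -> float:
        return len(self.families) / self.n_candidates

    @property
    def case_fraction(self) -> float:
        n = sum(len(f.members) for f in self.families)
        aff = sum(m.affected for f in self.families for m in f.members)
        return aff / n


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------

def generate_pedigree(shape: PedigreeShape, rng: np.random.Generator,
                      family_id: str = "F1") -> FamilyGraph:
    """One random extended pedigree with year-of-birth covariates by generation."""
    n_gen = int(rng.choice(np.asarray(shape.generations)))
    members: list[Individual] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{family_id}_{counter[0]}"

    def yob_child(f_yob: float, m_yob: float) -> int:
        base = max(f_yob, m_yob)
        return int(round(base + rng.normal(shape.generation_gap, shape.generation_gap_sd)))

    def add(ind: Individual) -> Individual:
        members.append(ind)
        return ind

    def n_offspring() -> int:
        if shape.fixed_offspring is not None:
            return shape.fixed_offspring
        return int(rng.poisson(shape.mean_offspring))

    def founder(sex: str, yob: int) -> Individual:
        return add(Individual(new_id(), family_id, None, None, sex, False,
                              year_of_birth=yob,
                              age_at_enrollment=max(shape.enrollment_year - yob, 0)))

    def grow(father: Individual, mother: Individual, gen: int) -> None:
        # children are generation `gen`; reproduce while gen < n_gen - 1
        k = n_offspring()
        if gen == 1 and k == 0:
            k = 1  # the founding couple has at least one child
        for _ in range(k):
            sex = "female" if rng.random() < 0.5 else "male"
            yob = yob_child(father.year_of_birth, mother.year_of_birth)
            child = add(Individual(new_id(), family_id,
                                   father.individual_id, mother.individual_id,
                                   sex, False, year_of_birth=yob,
                                   age_at_enrollment=max(shape.enrollment_year - yob, 0)))
            if gen < n_gen - 1 and rng.random() < shape.p_marry:
                s_yob = int(round(child.year_of_birth + rng.normal(0.0, 4.0)))
                spouse = founder("male" if sex == "female" else "female", s_yob)
                fa, mo = (child, spouse) if sex == "male" else (spouse, child)
                grow(fa, mo, gen + 1)

    f_yob = int(round(rng.normal(shape.founder_year, shape.founder_year_sd)))
    m_yob = int(round(f_yob + rng.normal(0.0, 4.0)))
    fa = founder("male", f_yob)
    mo = founder("female", m_yob)
    grow(fa, mo, 1)
    return FamilyGraph(family_id, members)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    fam: FamilyGraph,
    theta: Theta,
    prevalence: float,
    covariates: Sequence[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw liabilities L ~ MVN(Xb, Sigma(theta)) and set affection L > c.

    X uses raw covariate codes; returns the liability vector (members order).
    Mutates the family's ``affected`` flags in place.
    """
    c = threshold_from_prevalence(prevalence)
    spec = ModelSpec(variance_components=tuple(theta.vc.keys()),
                     covariates=tuple(covariates), prevalence=prevalence,
                     standardize_covariates=False)
    mats = relationship_matrices(fam)
    gxe_s = None
    if "h2_gxe" in theta.vc:
        from .model import gxe_similarity

        gxe_s = gxe_similarity(fam, spec.gxe_stratum)
    sigma = build_sigma(theta, mats, spec, gxe_s)
    X = np.array([[_covariate_value(m, cov) for cov in covariates]
                  for m in fam.analysis_members])
    mean = X @ theta.beta if len(covariates) else np.zeros(len(fam.analysis_members))
    chol = np.linalg.cholesky(sigma)
    L = mean + chol @ rng.standard_normal(len(mean))
    for i, m in enumerate(fam.analysis_members):
        m.affected = bool(L[i] > c)
        m.is_proband = False
    return L


# ---------------------------------------------------------------------------
# ascertainment
# ---------------------------------------------------------------------------

def ascertain(
    families_with_liabilities: Sequence[tuple[FamilyGraph, np.ndarray]],
    mode: str,
    rng: np.random.Generator,
    p_proband: float = 0.75,
) -> list[tuple[FamilyGraph, np.ndarray]]:
    """Retain families per the ascertainment mode and label probands.

    ``proband_based``: keep families with at least one affected member and
    mark each affected member a proband independently with probability
    ``p_proband`` (at least one forced).  ``none``: keep everything,
    no probands.
    """
    retained = []
    for fam, L in families_with_liabilities:
        affected = [m for m in fam.members if m.affected]
        if mode == "none":
            retained.append((fam, L))
            continue
        if not affected:
            continue
        chosen = [m for m in affected if rng.random() < p_proband]
        if not chosen:
            chosen = [affected[int(rng.integers(len(affected)))]]
        for m in chosen:
            m.is_proband = True
        retained.append((fam, L))
    if not retained:
        raise RuntimeError(
            "ascertainment retained zero families; increase the number of "
            "candidate families or the prevalence")
    return retained


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(design: SimDesign, seed: int | None = None) -> SimResult:
    """Generate candidate families until the target number is retained."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    c = threshold_from_prevalence(design.prevalence)
    families: list[FamilyGraph] = []
    liabilities: dict[str, np.ndarray] = {}
    n_candidates = 0
    cand_n = 0
    cand_aff = 0
    cand_cov_sum = np.zeros(len(design.covariates))
    cand_implied_sum = 0.0
    cand_cells: dict[tuple, int] = {}
    while len(families) < design.n_families:
        if n_candidates >= design.max_candidates:
            raise RuntimeError(
                f"exhausted {design.max_candidates} candidate families with only "
                f"{len(families)} retained; the design is not ascertainable at this "
                f"prevalence")
        n_candidates += 1
        fam = generate_pedigree(design.shape, rng,
                                family_id=f"SIM{n_candidates}")
        L = simulate_phenotypes(fam, design.theta_true, design.prevalence,
                                design.covariates, rng)
        X = np.array([[_covariate_value(m, cov) for cov in design.covariates]
                      for m in fam.members])
        cand_n += len(fam.members)
        cand_aff += sum(m.affected for m in fam.members)
        if len(design.covariates):
            cand_cov_sum += X.sum(axis=0)
            cand_implied_sum += float(np.sum(norm.sf(c - X @ design.theta_true.beta)))
            for row in X:
                key = tuple(row)
                cand_cells[key] = cand_cells.get(key, 0) + 1
        else:
            cand_implied_sum += len(fam.members) * float(norm.sf(c))
        kept = ascertain([(fam, L)], design.ascertainment, rng,
                         design.p_proband) if (design.ascertainment == "none"
                                               or any(m.affected for m in fam.members)) else []
        for fam_k, L_k in kept:
            families.append(fam_k)
            liabilities[fam_k.family_id] = L_k
    return SimResult(
        families=families,
        liabilities=liabilities,
        theta_true=design.theta_true,
        prevalence=design.prevalence,
        covariates=design.covariates,
        n_candidates=n_candidates,
        candidate_case_rate=cand_aff / cand_n,
        candidate_implied_prevalence=cand_implied_sum / cand_n,
        candidate_covariate_means=(cand_cov_sum / cand_n
                                   if len(design.covariates) else cand_cov_sum),
        candidate_covariate_cells=cand_cells,
    )
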