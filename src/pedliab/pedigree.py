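"""Pedigree data structures, file I/O, inclusion filters and relationship matrices.

A :class:`FamilyGraph` holds the full pedigree structure of one extended
family.  Individuals carry an ``in_analysis`` flag: inclusion filters never
delete anyone, they only remove individuals from the analysis set, so that
kinship coefficients between retained members — computed over the *full*
structure — are unchanged by filtering ("structural ancestors" stay in
place as links).

The additive-relationship matrix is twice the kinship matrix, computed with
the standard recursion over a topological ordering of the pedigree:

    phi(i, i) = (1 + phi(father_i, mother_i)) / 2
    phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2     (j not a descendant of i)

Founders are assumed non-inbred and mutually unrelated; families are
treated as independent (zero relatedness across families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"

__all__ = [
    "Individual",
    "FamilyGraph",
    "RelationshipMatrices",
    "PedDialect",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "apply_inclusion_filters",
    "kinship2",
    "environment_matrices",
    "relationship_matrices",
    "write_matrix_bundle",
]


class PedigreeError(ValueError):
    """Structural or validation error in a pedigree."""


@dataclass
class Individual:
    """One pedigree member with phenotype and covariate fields.

    ``father_id`` / ``mother_id`` are ``None`` for founders.  ``in_analysis``
    marks membership in the analysis set (phenotyped, passes inclusion
    filters); structural-only ancestors have it ``False``.
    """

    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female"
    affected: bool
    is_proband: bool = False
    year_of_birth: int | None = None
    age_at_enrollment: int | None = None
    in_analysis: bool = True

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise PedigreeError(
                f"individual {self.individual_id}: sex must be 'male' or 'female', got {self.sex!r}"
            )
        if self.is_proband and not self.affected:
            raise PedigreeError(
                f"individual {self.individual_id}: probands must be affected"
            )


class FamilyGraph:
    """One family: an ordered member list plus parent adjacency.

    The member ordering is fixed at construction and reused by every matrix
    built from this family (rows of K2, the H matrices and the design matrix
    all follow ``analysis_members`` order).
    """

    def __init__(self, family_id: str, members: Sequence[Individual], validate: bool = True):
        self.family_id = family_id
        self.members: list[Individual] = list(members)
        self._index = {m.individual_id: i for i, m in enumerate(self.members)}
        if validate:
            self._validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_individuals(
        cls, family_id: str, members: Iterable[Individual], add_missing_parents: bool = True
    ) -> "FamilyGraph":
        """Build a family, instantiating referenced-but-absent parents.

        Missing parents referenced by ID are auto-added as unphenotyped
        founders (sex inferred from the parental role) with a logged warning.
        """
        members = list(members)
        if add_missing_parents:
            present = {m.individual_id for m in members}
            stubs: dict[str, Individual] = {}
            for m in members:
                for pid, sex in ((m.father_id, "male"), (m.mother_id, "female")):
                    if pid is not None and pid not in present and pid not in stubs:
                        logger.warning(
                            "family %s: parent %s referenced but absent; added as founder",
                            family_id, pid,
                        )
                        stubs[pid] = Individual(
                            individual_id=pid, family_id=family_id,
                            father_id=None, mother_id=None, sex=sex,
                            affected=False, in_analysis=False,
                        )
            members = members + list(stubs.values())
        return cls(family_id, members)

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.individual_id in seen:
                raise PedigreeError(
                    f"family {self.family_id}: duplicate individual_id {m.individual_id!r}"
                )
            seen.add(m.individual_id)
        for m in self.members:
            for pid, want in ((m.father_id, "male"), (m.mother_id, "female")):
                if pid is None:
                    continue
                if pid not in self._index:
                    raise PedigreeError(
                        f"family {self.family_id}: {m.individual_id} references "
                        f"unknown parent {pid!r}"
                    )
                parent = self.members[self._index[pid]]
                if parent.sex != want:
                    role = "father" if want == "male" else "mother"
                    raise PedigreeError(
                        f"family {self.family_id}: {role} {pid} of {m.individual_id} "
                        f"has sex={parent.sex}"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self._index)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    g.add_edge(pid, m.individual_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(e[0] for e in cycle) + " -> " + cycle[-1][1]
            raise PedigreeError(f"family {self.family_id}: cyclic parentage: {path}")

    # -- accessors -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    def index_of(self, individual_id: str) -> int:
        return self._index[individual_id]

    @property
    def analysis_members(self) -> list[Individual]:
        return [m for m in self.members if m.in_analysis]

    @property
    def probands(self) -> list[Individual]:
        return [m for m in self.members if m.is_proband and m.in_analysis]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(father, mother) positional indices over the full member list; -1 = founder."""
        fa = np.full(len(self.members), -1, dtype=np.int64)
        mo = np.full(len(self.members), -1, dtype=np.int64)
        for i, m in enumerate(self.members):
            if m.father_id is not None:
                fa[i] = self._index[m.father_id]
            if m.mother_id is not None:
                mo[i] = self._index[m.mother_id]
        return fa, mo

    def topological_order(self) -> np.ndarray:
        """Member positions ordered parents-before-offspring."""
        fa, mo = self.parent_indices()
        n = len(self.members)
        order, state = [], np.zeros(n, dtype=np.int8)

        def visit(i: int) -> None:
            stack = [i]
            while stack:
                j = stack[-1]
                if state[j] == 2:
                    stack.pop()
                    continue
                pending = [p for p in (fa[j], mo[j]) if p >= 0 and state[p] == 0]
                if pending:
                    stack.extend(pending)
                else:
                    state[j] = 2
                    order.append(j)
                    stack.pop()

        for i in range(n):
            if state[i] == 0:
                visit(i)
        return np.asarray(order, dtype=np.int64)

    def copy(self) -> "FamilyGraph":
        return FamilyGraph(self.family_id, [replace(m) for m in self.members], validate=False)


@dataclass
class RelationshipMatrices:
    """Per-family covariance building blocks over the analysis members.

    ``k2`` is twice the kinship matrix; the H matrices are 0/1 shared-
    household indicators with unit diagonal (full siblings, mother-offspring,
    father-offspring, spouses = pairs with a common offspring).
    """

    ids: list[str]
    k2: np.ndarray
    h_sibs: np.ndarray
    h_mother_off: np.ndarray
    h_father_off: np.ndarray
    h_spouses: np.ndarray

    @property
    def identity(self) -> np.ndarray:
        return np.eye(len(self.ids))

    def by_name(self) -> dict[str, np.ndarray]:
        return {
            "k2": self.k2,
            "h_sibs": self.h_sibs,
            "h_mother_off": self.h_mother_off,
            "h_father_off": self.h_father_off,
            "h_spouses": self.h_spouses,
            "identity": self.identity,
        }


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

@dataclass
class PedDialect:
    """Options for the extended whitespace-delimited ped format.

    Defaults follow PLINK conventions: sex 1=male/2=female, affection
    1=unaffected/2=affected ("plink") or 0/1 ("binary"), missing parent "0".
    A header row naming the columns is required; '#' starts a comment.
    """

    affection_coding: str = "plink"  # "plink" (1/2) or "binary" (0/1)
    missing_parent: str = MISSING_PARENT
    missing_values: tuple[str, ...] = ("NA", ".", "-9", "")


_SEX_CODES = {"1": "male", "m": "male", "male": "male",
              "2": "female", "f": "female", "female": "female"}
_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}

REQUIRED_COLUMNS = ("family_id", "individual_id", "father_id", "mother_id", "sex", "affection")
OPTIONAL_COLUMNS = ("year_of_birth", "is_proband", "age_at_enrollment")


def _parse_affection(tok: str, dialect: PedDialect) -> bool:
    if dialect.affection_coding == "plink":
        if tok == "2":
            return True
        if tok == "1":
            return False
    else:
        if tok == "1":
            return True
        if tok == "0":
            return False
    raise PedigreeError(f"unrecognized affection code {tok!r} "
                        f"for coding {dialect.affection_coding!r}")


def read_pedigree(path, dialect: PedDialect | None = None) -> list[FamilyGraph]:
    """Read an extended ped file into a list of validated families.

    The file is whitespace- or tab-delimited with a header row naming at
    least the required columns (family_id, individual_id, father_id,
    mother_id, sex, affection) plus optional covariate columns.
    """
    dialect = dialect or PedDialect()
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype=str).fillna("NA")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"{path}: missing required columns {missing}")

    def opt_int(tok: str) -> int | None:
        return None if tok in dialect.missing_values else int(float(tok))

    families: list[FamilyGraph] = []
    for fam_id, block in df.groupby("family_id", sort=False):
        members = []
        for row in block.itertuples(index=False):
            rec = dict(zip(block.columns, row))
            sex_tok = rec["sex"].strip().lower()
            if sex_tok not in _SEX_CODES:
                raise PedigreeError(f"family {fam_id}: unrecognized sex code {rec['sex']!r}")
            father = rec["father_id"] if rec["father_id"] != dialect.missing_parent else None
            mother = rec["mother_id"] if rec["mother_id"] != dialect.missing_parent else None
            proband = False
            if "is_proband" in rec:
                tok = rec["is_proband"].strip().lower()
                if tok in _TRUE:
                    proband = True
                elif tok not in _FALSE and tok not in dialect.missing_values:
                    raise PedigreeError(f"family {fam_id}: bad is_proband value {tok!r}")
            members.append(Individual(
                individual_id=rec["individual_id"],
                family_id=str(fam_id),
                father_id=father,
                mother_id=mother,
                sex=_SEX_CODES[sex_tok],
                affected=_parse_affection(rec["affection"].strip(), dialect),
                is_proband=proband,
                year_of_birth=opt_int(rec["year_of_birth"]) if "year_of_birth" in rec else None,
                age_at_enrollment=(opt_int(rec["age_at_enrollment"])
                                   if "age_at_enrollment" in rec else None),
            ))
        families.append(FamilyGraph.from_individuals(str(fam_id), members))
    return families


def write_pedigree(families: Sequence[FamilyGraph], path, dialect: PedDialect | None = None) -> None:
    """Write families in the extended ped format read by :func:`read_pedigree`."""
    dialect = dialect or PedDialect()
    rows = []
    for fam in families:
        for m in fam.members:
            rows.append({
                "family_id": fam.family_id,
                "individual_id": m.individual_id,
                "father_id": m.father_id or dialect.missing_parent,
                "mother_id": m.mother_id or dialect.missing_parent,
                "sex": "1" if m.sex == "male" else "2",
                "affection": ("2" if m.affected else "1") if dialect.affection_coding == "plink"
                             else ("1" if m.affected else "0"),
                "year_of_birth": m.year_of_birth if m.year_of_birth is not None else "NA",
                "is_proband": int(m.is_proband),
                "age_at_enrollment": (m.age_at_enrollment
                                      if m.age_at_enrollment is not None else "NA"),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_matrix_bundle(mats: RelationshipMatrices, path) -> None:
    """Dump a family's relationship matrices as plain text for inspection."""
    with open(path, "w") as fh:
        fh.write("# relationship matrix bundle\n")
        fh.write("ids\t" + "\t".join(mats.ids) + "\n")
        for name, mat in mats.by_name().items():
            fh.write(f"#matrix {name} {len(mats.ids)}\n")
            for row in mat:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# kinship and household matrices
# ---------------------------------------------------------------------------

def _kinship_full(fam: FamilyGraph) -> np.ndarray:
    """Kinship coefficients phi over the *full* member list, member order."""
    n = len(fam.members)
    fa, mo = fam.parent_indices()
    order = fam.topological_order()
    phi = np.zeros((n, n))
    done: list[int] = []
    for a in order:
        f, m = fa[a], mo[a]
        phi_fm = phi[f, m] if (f >= 0 and m >= 0) else 0.0
        for b in done:
            v = 0.0
            if f >= 0:
                v += phi[f, b]
            if m >= 0:
                v += phi[m, b]
            v *= 0.5
            phi[a, b] = phi[b, a] = v
        phi[a, a] = 0.5 * (1.0 + phi_fm)
        done.append(a)
    return phi


def kinship2(fam: FamilyGraph) -> np.ndarray:
    """Additive-relationship matrix (2 x kinship) over the analysis members.

    Computed over the full pedigree structure, then restricted, so filtered
    link ancestors still transmit relatedness.
    """
    phi = _kinship_full(fam)
    idx = [i for i, m in enumerate(fam.members) if m.in_analysis]
    return 2.0 * phi[np.ix_(idx, idx)]


def environment_matrices(fam: FamilyGraph) -> dict[str, np.ndarray]:
    """Shared-household 0/1 indicator matrices over the analysis members.

    Full siblings share both parents; half-siblings get 0 here (their
    genetic covariance is already carried by K2).  Spouses are pairs with
    at least one common offspring anywhere in the pedigree.
    """
    members = fam.analysis_members
    n = len(members)
    sibs = np.eye(n)
    mother = np.eye(n)
    father = np.eye(n)
    spouses = np.eye(n)
    couples = {
        (m.father_id, m.mother_id)
        for m in fam.members
        if m.father_id is not None and m.mother_id is not None
    }
    for i in range(n):
        a = members[i]
        for j in range(i + 1, n):
            b = members[j]
            if (a.father_id is not None and a.mother_id is not None
                    and a.father_id == b.father_id and a.mother_id == b.mother_id):
                sibs[i, j] = sibs[j, i] = 1.0
            if b.mother_id == a.individual_id or a.mother_id == b.individual_id:
                mother[i, j] = mother[j, i] = 1.0
            if b.father_id == a.individual_id or a.father_id == b.individual_id:
                father[i, j] = father[j, i] = 1.0
            pair = ((a.individual_id, b.individual_id)
                    if a.sex == "male" else (b.individual_id, a.individual_id))
            if a.sex != b.sex and pair in couples:
                spouses[i, j] = spouses[j, i] = 1.0
    return {"h_sibs": sibs, "h_mother_off": mother,
            "h_father_off": father, "h_spouses": spouses}


def relationship_matrices(fam: FamilyGraph) -> RelationshipMatrices:
    """Bundle K2 and the four H matrices for one family."""
    h = environment_matrices(fam)
    return RelationshipMatrices(
        ids=[m.individual_id for m in fam.analysis_members],
        k2=kinship2(fam),
        **h,
    )


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

def apply_inclusion_filters(
    fam: FamilyGraph,
    min_unaffected_age: int = 20,
    max_degree: int | None = None,
) -> FamilyGraph:
    """Drop too-young unaffected members and too-distant relatives.

    Dropped members stay in the structure as link ancestors (``in_analysis``
    flips to False), so kinship between retained members is unchanged.
    ``max_degree`` bounds the relationship degree d (2*phi = 2^-d) to the
    *closest* proband; members beyond it are excluded from the analysis set.
    """
    out = fam.copy()
    had_probands = any(m.is_proband and m.in_analysis for m in fam.members)

    if min_unaffected_age > 0:
        for m in out.members:
            if m.in_analysis and not m.affected:
                if m.age_at_enrollment is None:
                    raise PedigreeError(
                        f"family {fam.family_id}: {m.individual_id} is unaffected with "
                        f"missing age_at_enrollment; cannot apply the age filter"
                    )
                if m.age_at_enrollment < min_unaffected_age:
                    m.in_analysis = False

    if max_degree is not None:
        k2_full = 2.0 * _kinship_full(out)
        proband_idx = [i for i, m in enumerate(out.members) if m.is_proband]
        for i, m in enumerate(out.members):
            if not m.in_analysis or m.is_proband:
                continue
            best = np.inf
            for p in proband_idx:
                r = k2_full[i, p]
                if r > 0:
                    best = min(best, -np.log2(r))
            if best > max_degree:
                m.in_analysis = False

    if had_probands and not any(m.is_proband and m.in_analysis for m in out.members):
        raise PedigreeError(
            f"family {fam.family_id}: inclusion filters removed all probands; "
            f"family is no longer ascertainable"
        )
    return out
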