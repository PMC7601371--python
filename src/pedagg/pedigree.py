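"""Pedigree data model, PED-dialect I/O and phenotype masking.

A cohort is a forest of pedigrees carrying, for every member, a clinical
phenotype subtype of endemic congenital hypothyroidism (endemic CH), vital
status, approximate age and WHO goitre grade.  Members are grouped into
recorded *family units* (``family_id``); multigeneration and polygamous
units decompose into nuclear families, each with a dedicated father and
mother.

Only living members with a known phenotype count as *phenotyped*: they form
the case/control pools of every downstream test.  Deceased members remain
in the pedigree (they contribute kinship structure) but are never cases or
controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import PedigreeError

#: Founder marker in PED files and parent fields.
FOUNDER = "0"

SEXES = ("male", "female", "unknown")

#: Clinical phenotype subtypes.  ``ech_unspecified`` records subjects
#: (typically deceased) reported to have had signs of endemic CH without a
#: recorded subtype; ``unknown`` marks subjects excluded from all statistics.
PHENOTYPES = (
    "unaffected",
    "myxedematous_severe",
    "myxedematous_moderate",
    "myxedematous_unknown_grade",
    "mixed",
    "neurological",
    "deaf_mute",
    "ech_unspecified",
    "unknown",
)

GOITRE_GRADES = ("absent", "palpable_not_visible", "visible", "missing")

#: Aggregation is assessed for three phenotype categories.  Under
#: ``myxedematous`` the affected set is the myxedematous subtypes plus the
#: mixed form; under ``neurological`` it is the neurological and deaf-mute
#: subtypes; ``combined`` is their union.  A subject affected under one
#: category is a *control* under the other (the prevalence denominator is
#: the full phenotyped cohort in every category).
CATEGORY_SUBTYPES: dict[str, frozenset[str]] = {
    "myxedematous": frozenset(
        {"myxedematous_severe", "myxedematous_moderate",
         "myxedematous_unknown_grade", "mixed"}
    ),
    "neurological": frozenset({"neurological", "deaf_mute"}),
}
CATEGORY_SUBTYPES["combined"] = (
    CATEGORY_SUBTYPES["myxedematous"] | CATEGORY_SUBTYPES["neurological"]
)

CATEGORIES = tuple(CATEGORY_SUBTYPES)

_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_PED_TO_SEX = {v: k for k, v in _SEX_TO_PED.items()}

_NA = "NA"


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    Parameters
    ----------
    id
        Unique identifier (opaque string).
    family_id
        Recorded family unit the member belongs to.
    father_id, mother_id
        Identifiers of the parents, or :data:`FOUNDER` for founders.  Either
        both resolve within the cohort or both are founder markers.
    sex
        ``male`` / ``female`` / ``unknown``.
    alive
        Vital status at survey time.  Deceased members never enter the
        phenotyped pools.
    age_years
        Approximate age, or ``None`` when not recorded.
    phenotype
        Clinical subtype, one of :data:`PHENOTYPES`.
    goitre
        WHO goitre grade, one of :data:`GOITRE_GRADES`.
    generation
        Optional generation label (metadata only; never used by any test).
    """

    id: str
    family_id: str
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: str = "unknown"
    alive: bool = True
    age_years: float | None = None
    phenotype: str = "unknown"
    goitre: str = "missing"
    generation: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.id or self.id == FOUNDER:
            raise ValueError(f"invalid individual id {self.id!r}")
        if self.sex not in SEXES:
            raise ValueError(f"{self.id}: invalid sex {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"{self.id}: invalid phenotype {self.phenotype!r}")
        if self.goitre not in GOITRE_GRADES:
            raise ValueError(f"{self.id}: invalid goitre grade {self.goitre!r}")
        if self.age_years is not None:
            if math.isnan(self.age_years) or self.age_years < 0:
                raise ValueError(f"{self.id}: invalid age {self.age_years!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER


@dataclass(frozen=True)
class NuclearFamily:
    """A father-mother pair and their common offspring.

    ``sibship_size`` counts *living* offspring only; deceased siblings stay
    in ``offspring_ids`` for pedigree structure.
    """

    family_id: str
    father_id: str
    mother_id: str
    offspring_ids: tuple[str, ...]
    sibship_size: int


class Cohort:
    """Validated pedigree forest with family grouping and phenotype masks.

    Construction validates the structural invariants: unique identifiers,
    resolvable (or founder) parent references of compatible sex, and
    acyclicity of the parent graph.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in members:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            members[ind.id] = ind
        self._members = members
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self._members)
        for ind in self._members.values():
            n_founder = (ind.father_id == FOUNDER) + (ind.mother_id == FOUNDER)
            if n_founder == 1:
                raise PedigreeError(
                    f"{ind.id}: exactly one parent recorded; parents must be "
                    "both known or both founders"
                )
            if n_founder == 2:
                continue
            for parent_id, role, bad_sex in (
                (ind.father_id, "father", "female"),
                (ind.mother_id, "mother", "male"),
            ):
                parent = self._members.get(parent_id)
                if parent is None:
                    raise PedigreeError(
                        f"{ind.id}: unresolved {role} reference {parent_id!r}"
                    )
                if parent.sex == bad_sex:
                    raise PedigreeError(
                        f"{ind.id}: {role} {parent_id!r} has sex {parent.sex}"
                    )
                g.add_edge(parent_id, ind.id)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(edge[0] for edge in cycle)
            raise PedigreeError(f"pedigree contains a cycle: {path}")
        self._parent_graph = g

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self):
        return iter(self._members.values())

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._members

    def __getitem__(self, individual_id: str) -> Individual:
        return self._members[individual_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return list(self) == list(other)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._members)

    @property
    def family_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ind in self:
            seen.setdefault(ind.family_id, None)
        return tuple(seen)

    def family_members(self, family_id: str) -> tuple[Individual, ...]:
        return tuple(ind for ind in self if ind.family_id == family_id)

    @property
    def phenotyped_count(self) -> int:
        """Living members with a known phenotype (the statistics denominator)."""
        return sum(1 for i in self if i.alive and i.phenotype != "unknown")

    @property
    def parent_graph(self) -> nx.DiGraph:
        return self._parent_graph

    # -- derived structure --------------------------------------------------

    @property
    def nuclear_families(self) -> list[NuclearFamily]:
        return split_nuclear(self)

    def phenotype_mask(self, category: str) -> pd.Series:
        return phenotype_mask(self, category)


def split_nuclear(cohort: Cohort) -> list[NuclearFamily]:
    """Decompose a cohort into nuclear families.

    Every member with resolvable parents appears as offspring of exactly one
    nuclear family; a father with *w* wives yields *w* nuclear families.
    Sibship size counts living offspring only.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for ind in cohort:
        if ind.is_founder:
            continue
        groups.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)
    out = []
    for (father_id, mother_id), offspring in groups.items():
        out.append(
            NuclearFamily(
                family_id=cohort[offspring[0]].family_id,
                father_id=father_id,
                mother_id=mother_id,
                offspring_ids=tuple(offspring),
                sibship_size=sum(1 for o in offspring if cohort[o].alive),
            )
        )
    return out


def phenotype_mask(cohort: Cohort, category: str) -> pd.Series:
    """Affection status of every member under one phenotype category.

    Returns a Series over cohort members with values ``affected``,
    ``control`` or ``unphenotyped``.  Deceased members and members with an
    unknown phenotype are unphenotyped; every other living member not
    affected under *category* is a control — including subjects affected
    under the sibling category, since the prevalence denominator is the
    whole phenotyped cohort.
    """
    if category not in CATEGORY_SUBTYPES:
        raise ValueError(
            f"unknown category {category!r}; expected one of {CATEGORIES}"
        )
    affected = CATEGORY_SUBTYPES[category]
    values = []
    for ind in cohort:
        if not ind.alive or ind.phenotype == "unknown":
            values.append("unphenotyped")
        elif ind.phenotype in affected:
            values.append("affected")
        else:
            values.append("control")
    return pd.Series(values, index=list(cohort.ids), name=category)


# -- I/O ---------------------------------------------------------------------

_PED_COLUMNS = ["family_id", "id", "father_id", "mother_id", "sex", "affection"]
_SIDECAR_COLUMNS = ["id", "phenotype", "alive", "age", "goitre"]


def read_pedigree(ped_path, phenotype_path) -> Cohort:
    """Read a cohort from a 6-column PED file and its phenotype sidecar.

    The PED affection column is ignored in favour of the sidecar subtype.
    Sidecar rows whose id is absent from the PED file are rejected.
    """
    ped_path, phenotype_path = Path(ped_path), Path(phenotype_path)
    try:
        ped = pd.read_csv(
            ped_path, sep=r"\s+", names=_PED_COLUMNS, dtype=str, comment="#"
        )
    except pd.errors.EmptyDataError:
        ped = pd.DataFrame(columns=_PED_COLUMNS)
    side = pd.read_csv(phenotype_path, sep="\t", dtype=str, na_values=[_NA])
    if list(side.columns) != _SIDECAR_COLUMNS:
        raise ValueError(
            f"{phenotype_path}: expected columns {_SIDECAR_COLUMNS}, "
            f"got {list(side.columns)}"
        )
    ped_ids = set(ped["id"])
    unknown = set(side["id"]) - ped_ids
    if unknown:
        raise ValueError(
            f"{phenotype_path}: ids absent from PED file: {sorted(unknown)}"
        )
    if side["id"].duplicated().any():
        dupes = side.loc[side["id"].duplicated(), "id"].tolist()
        raise PedigreeError(f"{phenotype_path}: duplicate ids {dupes}")
    side = side.set_index("id")

    individuals = []
    for row in ped.itertuples(index=False):
        sex = _PED_TO_SEX.get(row.sex)
        if sex is None:
            raise ValueError(f"{row.id}: invalid PED sex code {row.sex!r}")
        phenotype, alive, age, goitre = "unknown", True, None, "missing"
        if row.id in side.index:
            rec = side.loc[row.id]
            phenotype = rec["phenotype"]
            alive = rec["alive"] == "1"
            age = None if pd.isna(rec["age"]) else float(rec["age"])
            goitre = "missing" if pd.isna(rec["goitre"]) else rec["goitre"]
        individuals.append(
            Individual(
                id=row.id,
                family_id=row.family_id,
                father_id=row.father_id,
                mother_id=row.mother_id,
                sex=sex,
                alive=alive,
                age_years=age,
                phenotype=phenotype,
                goitre=goitre,
            )
        )
    return Cohort(individuals)


def write_pedigree(cohort: Cohort, ped_path, phenotype_path) -> None:
    """Write PED + sidecar files that :func:`read_pedigree` round-trips.

    The PED affection column is filled 2/1/0 (affected/control/unphenotyped)
    under the combined category, for interoperability with pedigree tools;
    the sidecar remains authoritative.
    """
    mask = phenotype_mask(cohort, "combined")
    affection = {"affected": "2", "control": "1", "unphenotyped": "0"}
    ped_rows = []
    side_rows = []
    for ind in cohort:
        ped_rows.append(
            [ind.family_id, ind.id, ind.father_id, ind.mother_id,
             _SEX_TO_PED[ind.sex], affection[mask[ind.id]]]
        )
        age = _NA if ind.age_years is None else _format_age(ind.age_years)
        goitre = _NA if ind.goitre == "missing" else ind.goitre
        side_rows.append(
            [ind.id, ind.phenotype, "1" if ind.alive else "0", age, goitre]
        )
    with open(ped_path, "w", encoding="utf-8") as fh:
        for row in ped_rows:
            fh.write("\t".join(row) + "\n")
    with open(phenotype_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SIDECAR_COLUMNS) + "\n")
        for row in side_rows:
            fh.write("\t".join(row) + "\n")


def _format_age(age: float) -> str:
    return str(int(age)) if float(age).is_integer() else repr(float(age))
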