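"""Synthetic cohort generation.

Two producers:

* :func:`generate_cohort` draws cohorts of nuclear families with a given
  sibship-size distribution, unaffected parents, and offspring affection
  following one of three mechanisms — independent Bernoulli (``null_iid``),
  a family random effect (``beta_binomial``) or Mendelian recessive
  transmission (``recessive``);
* :func:`reference_cohort` deterministically rebuilds the historical
  62-family / 468-subject endemic-CH survey cohort from its published
  summary counts (per-sibship-size family and case totals, the two fully
  affected five-sibling families A and B, family-structure counts, subtype
  and sex margins).

The exact allocation of cases to families outside A and B was never
published; :func:`reference_cohort` uses a documented, configurable
allocation rule consistent with all published totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .pedigree import Cohort, Individual

#: Published per-sibship-size nuclear-family counts (sizes 1..9).
REFERENCE_FAMILY_COUNTS: dict[int, int] = {
    1: 19, 2: 15, 3: 19, 4: 11, 5: 10, 6: 4, 7: 6, 8: 3, 9: 2,
}

#: Documented case allocation: per sibship size, the affected-family case
#: counts.  Consistent with the published affected-family and case totals;
#: the two size-5 entries of 5 are families A and B.
DEFAULT_ALLOCATION: dict[int, tuple[int, ...]] = {
    1: (1,),
    2: (1, 1, 1, 1, 1),
    3: (2, 2, 2, 1, 1, 1),
    4: (1, 1, 1, 1),
    5: (5, 5, 2, 1),
    6: (3,),
    7: (4, 3, 1),
    8: (2,),
    9: (1,),
}

REFERENCE_PREVALENCE = 46 / 468

#: Family-unit structure of the surveyed cohort: monogamous, bigamous,
#: polygamous (4 wives) unit counts.
REFERENCE_STRUCTURE = (45, 12, 5)
POLY_WIVES = 4


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic cohorts.

    Defaults emulate the reference survey: 62 family units (45 monogamous,
    12 bigamous, 5 polygamous with 4 wives), sibship sizes drawn from the
    published empirical distribution, case prevalence 46/468 (~10%).

    ``sibship_size_distribution`` is either a mapping size -> exact
    nuclear-family count (the reference profile) or a sequence of
    (size, probability) pairs.  ``mechanism`` is one of ``null_iid``,
    ``beta_binomial`` (intra-family correlation ``rho``) or ``recessive``
    (allele frequency ``q``; offspring affected iff homozygous, parents
    never expressed).
    """

    n_families: int = 62
    sibship_size_distribution: (
        Mapping[int, int] | Sequence[tuple[int, float]]
    ) = field(default_factory=lambda: dict(REFERENCE_FAMILY_COUNTS))
    prevalence: float = REFERENCE_PREVALENCE
    mechanism: str = "null_iid"
    rho: float = 0.2
    q: float = 0.076  # carrier-couple frequency (2q(1-q))^2 ~ 0.02
    family_structure: tuple[float, float, float] = (45 / 62, 12 / 62, 5 / 62)
    poly_wives: int = POLY_WIVES
    seed: int | None = None

    def __post_init__(self):
        if self.mechanism not in ("null_iid", "beta_binomial", "recessive"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.mechanism == "beta_binomial" and not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if self.mechanism == "recessive" and not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if not isinstance(self.sibship_size_distribution, Mapping):
            probs = [p for _, p in self.sibship_size_distribution]
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError("sibship size probabilities must sum to 1")
        if abs(sum(self.family_structure) - 1.0) > 1e-9:
            raise ValueError("family structure fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "sibship_size_distribution" in raw:
            dist = raw["sibship_size_distribution"]
            if isinstance(dist, dict):
                raw["sibship_size_distribution"] = {
                    int(k): int(v) for k, v in dist.items()
                }
            else:
                raw["sibship_size_distribution"] = [
                    (int(s), float(p)) for s, p in dist
                ]
        if "family_structure" in raw:
            raw["family_structure"] = tuple(raw["family_structure"])
        return cls(**raw)


def _unit_layout(config: GeneratorConfig, rng: np.random.Generator):
    """Per family unit, the list of sibship sizes of its nuclear families."""
    if isinstance(config.sibship_size_distribution, Mapping):
        sizes = [
            s
            for s, count in sorted(config.sibship_size_distribution.items())
            for _ in range(count)
        ]
        fracs = config.family_structure
        n_mono = round(fracs[0] * config.n_families)
        n_big = round(fracs[1] * config.n_families)
        n_poly = config.n_families - n_mono - n_big
        wanted = n_mono + 2 * n_big + config.poly_wives * n_poly
        if wanted != len(sizes):
            raise ValueError(
                f"fixed sibship counts ({len(sizes)} nuclear families) do not "
                f"fit the unit structure ({wanted} slots)"
            )
        sizes = list(rng.permutation(sizes))
        layout = []
        for _ in range(n_mono):
            layout.append([sizes.pop()])
        for _ in range(n_big):
            layout.append([sizes.pop(), sizes.pop()])
        for _ in range(n_poly):
            layout.append([sizes.pop() for _ in range(config.poly_wives)])
        return layout

    support = np.array([s for s, _ in config.sibship_size_distribution])
    probs = np.array([p for _, p in config.sibship_size_distribution])
    probs = probs / probs.sum()
    n_wives = {0: 1, 1: 2, 2: config.poly_wives}
    layout = []
    for _ in range(config.n_families):
        kind = rng.choice(3, p=np.asarray(config.family_structure))
        w = n_wives[int(kind)]
        layout.append([int(rng.choice(support, p=probs)) for _ in range(w)])
    return layout


def generate_cohort(
    config: GeneratorConfig, *, with_details: bool = False
):
    """Draw a synthetic cohort under the configured mechanism.

    Parents are alive, unaffected, phenotyped controls with no recorded
    age.  With ``with_details=True`` also returns a dict of per-individual
    recessive-allele counts (recessive mechanism only), for validation.
    """
    rng = np.random.default_rng(config.seed)
    layout = _unit_layout(config, rng)
    individuals: list[Individual] = []
    genotypes: dict[str, int] = {}

    def parent(pid: str, family_id: str, sex: str) -> Individual:
        if config.mechanism == "recessive":
            genotypes[pid] = int(rng.binomial(2, config.q))
        return Individual(
            id=pid, family_id=family_id, sex=sex, phenotype="unaffected"
        )

    for u, wives in enumerate(layout):
        fid = f"S{u + 1:03d}"
        father = parent(f"{fid}.f", fid, "male")
        individuals.append(father)
        for w, size in enumerate(wives):
            mother = parent(f"{fid}.m{w + 1}", fid, "female")
            individuals.append(mother)
            if config.mechanism == "null_iid":
                affected = rng.random(size) < config.prevalence
            elif config.mechanism == "beta_binomial":
                pi, rho = config.prevalence, config.rho
                a = pi * (1 - rho) / rho
                b = (1 - pi) * (1 - rho) / rho
                affected = rng.random(size) < rng.beta(a, b)
            else:  # recessive: one allele from each parent per offspring
                gf, gm = genotypes[father.id], genotypes[mother.id]
                from_f = rng.random(size) < gf / 2.0
                from_m = rng.random(size) < gm / 2.0
                affected = from_f & from_m
            for o in range(size):
                oid = f"{fid}.m{w + 1}.o{o + 1}"
                if config.mechanism == "recessive":
                    genotypes[oid] = int(from_f[o]) + int(from_m[o])
                individuals.append(
                    Individual(
                        id=oid,
                        family_id=fid,
                        father_id=father.id,
                        mother_id=mother.id,
                        sex="male" if rng.random() < 0.5 else "female",
                        phenotype=(
                            "myxedematous_unknown_grade"
                            if affected[o] else "unaffected"
                        ),
                    )
                )

    cohort = Cohort(individuals)
    if with_details:
        return cohort, genotypes
    return cohort


# -- deterministic reconstruction of the survey cohort -----------------------

def reference_cohort(
    allocation: Mapping[int, Sequence[int]] | None = None,
) -> Cohort:
    """Deterministically rebuild the 62-family survey cohort.

    The cohort reproduces the published structure exactly: 89 nuclear
    families with the published per-size counts; 45 monogamous, 12 bigamous
    and 5 four-wife polygamous family units; families A and B as five
    living affected offspring of eight (A: five myxedematous, three
    deceased reported affected; B: four myxedematous plus one neurological,
    three deceased); 468 phenotyped living subjects with 46 cases (44
    myxedematous, 2 neurological) and the published subtype and sex
    margins; 4 phenotype-unknown subjects excluded from all statistics.

    *allocation* overrides the per-size case allocation (for sensitivity
    checks); it must keep the two fully affected size-5 families.
    """
    alloc = {s: tuple(v) for s, v in (allocation or DEFAULT_ALLOCATION).items()}
    _check_allocation(alloc)

    # affected units, deterministically ordered: A, B, then by size
    affected_units: list[tuple[int, int]] = []  # (sibship_size, k)
    for size in sorted(alloc):
        for k in sorted(alloc[size], reverse=True):
            if size == 5 and k == 5:
                continue  # families A and B, built specially
            affected_units.append((size, k))

    # Unaffected sibship pool, ascending size.  Which sibships shared a
    # father was never published; every half-sib pair is therefore an
    # invented relationship, so the multi-wife units take the smallest
    # sibships (the minimal-relatedness reconstruction).
    pool = [
        s
        for s in sorted(REFERENCE_FAMILY_COUNTS)
        for _ in range(REFERENCE_FAMILY_COUNTS[s] - len(alloc.get(s, ())))
    ]
    n_mono, n_big, n_poly = REFERENCE_STRUCTURE
    n_aff_units = len(affected_units) + 2
    n_poly_sibs = POLY_WIVES * n_poly
    poly_units = [
        pool[POLY_WIVES * i: POLY_WIVES * (i + 1)] for i in range(n_poly)
    ]
    big_units = [
        pool[n_poly_sibs + 2 * i: n_poly_sibs + 2 * i + 2]
        for i in range(n_big)
    ]
    mono_unaff = pool[n_poly_sibs + 2 * n_big:]
    assert len(mono_unaff) == n_mono - n_aff_units

    # myxedematous subtype pool outside families A and B
    subtype_pool = (
        ["myxedematous_severe"] * 14
        + ["myxedematous_moderate"] * 16
        + ["myxedematous_unknown_grade"] * 3
        + ["mixed"] * 2
    )
    subtype_iter = iter(subtype_pool)
    affected_sexes = iter(
        ["male", "female"] * 18  # 36 cases outside A and B alternate
    )

    individuals: list[Individual] = []
    unit_no = 0

    def next_fid() -> str:
        nonlocal unit_no
        unit_no += 1
        return {1: "A", 2: "B"}.get(unit_no, f"F{unit_no:02d}")

    def add_parents(fid: str, wives: int) -> list[tuple[str, str]]:
        father = Individual(
            id=f"{fid}.f", family_id=fid, sex="male", phenotype="unaffected"
        )
        individuals.append(father)
        couples = []
        for w in range(wives):
            tag = "m" if wives == 1 else f"m{w + 1}"
            mother = Individual(
                id=f"{fid}.{tag}", family_id=fid, sex="female",
                phenotype="unaffected",
            )
            individuals.append(mother)
            couples.append((father.id, mother.id))
        return couples

    # family A: eight offspring, five living myxedematous, three deceased
    # reported affected (undefined subtype), ages bounded 5-25
    fid = next_fid()
    (fa, mo), = add_parents(fid, 1)
    a_alive = [("male", 25.0), ("male", 15.0), ("female", 12.0),
               ("female", 8.0), ("female", 5.0)]
    for i, (sex, age) in enumerate(a_alive, 1):
        individuals.append(
            Individual(
                id=f"{fid}.o{i}", family_id=fid, father_id=fa, mother_id=mo,
                sex=sex, age_years=age, phenotype="myxedematous_severe",
            )
        )
    for i in range(6, 9):
        individuals.append(
            Individual(
                id=f"{fid}.o{i}", family_id=fid, father_id=fa, mother_id=mo,
                alive=False, phenotype="ech_unspecified",
            )
        )

    # family B: eight offspring, five living (one neurological woman, four
    # myxedematous: two mixed, one unspecified-grade-severe, one moderate),
    # three deceased without reported signs, ages bounded 6-30
    fid = next_fid()
    (fa, mo), = add_parents(fid, 1)
    b_alive = [
        ("female", 30.0, "neurological"),
        ("male", 24.0, "mixed"),
        ("male", 20.0, "mixed"),
        ("male", 14.0, "myxedematous_severe"),
        ("male", 6.0, "myxedematous_moderate"),
    ]
    for i, (sex, age, phen) in enumerate(b_alive, 1):
        individuals.append(
            Individual(
                id=f"{fid}.o{i}", family_id=fid, father_id=fa, mother_id=mo,
                sex=sex, age_years=age, phenotype=phen,
            )
        )
    for i in range(6, 9):
        individuals.append(
            Individual(
                id=f"{fid}.o{i}", family_id=fid, father_id=fa, mother_id=mo,
                alive=False, phenotype="unknown",
            )
        )

    # remaining affected units (monogamous); the single size-9 case is the
    # second neurological subject
    max_size = max(REFERENCE_FAMILY_COUNTS)
    for size, k in affected_units:
        fid = next_fid()
        (fa, mo), = add_parents(fid, 1)
        for i in range(1, size + 1):
            if i <= k:
                phen = (
                    "neurological" if size == max_size and i == 1
                    else next(subtype_iter)
                )
                sex = next(affected_sexes)
            else:
                phen, sex = "unaffected", "unknown"  # sex filled below
            individuals.append(
                Individual(
                    id=f"{fid}.o{i}", family_id=fid, father_id=fa,
                    mother_id=mo, sex=sex, phenotype=phen,
                )
            )

    # unaffected monogamous, bigamous and polygamous units
    for sizes, wives in (
        [([s], 1) for s in mono_unaff]
        + [(pair, 2) for pair in big_units]
        + [(quad, POLY_WIVES) for quad in poly_units]
    ):
        fid = next_fid()
        couples = add_parents(fid, wives)
        for w, ((fa, mo), size) in enumerate(zip(couples, sizes)):
            tag = "" if wives == 1 else f"w{w + 1}."
            for i in range(1, size + 1):
                individuals.append(
                    Individual(
                        id=f"{fid}.{tag}o{i}", family_id=fid, father_id=fa,
                        mother_id=mo, phenotype="unaffected",
                    )
                )

    # 9 padding founder relatives (multigeneration members recorded without
    # parent links; they enlarge only the phenotyped null pool) and the 4
    # phenotype-unknown subjects excluded from all statistics
    fids = [i.family_id for i in individuals]
    host_units = [f for f in dict.fromkeys(fids) if f.startswith("F")]
    base = len(affected_units)  # first unaffected monogamous unit
    for j in range(9):
        fid = host_units[base + j]
        individuals.append(
            Individual(
                id=f"{fid}.r1", family_id=fid, phenotype="unaffected",
                generation=0,
            )
        )
    for j in range(4):
        fid = host_units[base + 9 + j]
        individuals.append(
            Individual(id=f"{fid}.u1", family_id=fid, phenotype="unknown")
        )

    # deterministic control sexes to the published margins: fathers male,
    # mothers female, then 123 of the remaining 271 controls male
    controls = [
        i for i, ind in enumerate(individuals)
        if ind.phenotype == "unaffected" and ind.alive and ind.sex == "unknown"
    ]
    out = list(individuals)
    for rank, i in enumerate(controls):
        ind = out[i]
        out[i] = Individual(
            id=ind.id, family_id=ind.family_id, father_id=ind.father_id,
            mother_id=ind.mother_id,
            sex="male" if rank < 123 else "female",
            alive=ind.alive, age_years=ind.age_years,
            phenotype=ind.phenotype, goitre=ind.goitre,
            generation=ind.generation,
        )
    return Cohort(out)


def _check_allocation(alloc: Mapping[int, tuple[int, ...]]) -> None:
    for size, ks in alloc.items():
        if size not in REFERENCE_FAMILY_COUNTS:
            raise ValueError(f"sibship size {size} outside the survey range")
        if len(ks) > REFERENCE_FAMILY_COUNTS[size]:
            raise ValueError(f"more affected families than exist at size {size}")
        if any(not 1 <= k <= size for k in ks):
            raise ValueError(f"case counts at size {size} outside [1, {size}]")
    if tuple(sorted(alloc.get(5, ()), reverse=True))[:2] != (5, 5):
        raise ValueError(
            "allocation must keep the two fully affected size-5 families"
        )
    n_cases = sum(sum(ks) for ks in alloc.values())
    if n_cases != 46:
        raise ValueError(f"allocation yields {n_cases} cases, expected 46")
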