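"""Sibship-level case distribution, recessive-model probabilities and
descriptive cohort comparisons.

The sibship table stratifies nuclear families by sibship size s and
compares the observed number of affected offspring O_s with the expectation
E_s = F_s * s * pi under random, independent affection at prevalence pi;
the departure is assessed with a chi-square statistic over the size cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pedigree import Cohort, NuclearFamily


@dataclass(frozen=True)
class SibshipTable:
    """Per-sibship-size family and case counts.

    ``table`` is indexed by sibship size with columns ``n_families`` (F_s),
    ``n_affected_families`` (A_s), ``observed`` (O_s) and ``expected``
    (E_s = F_s * s * prevalence).
    """

    table: pd.DataFrame
    prevalence: float


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


def sibship_table(
    nuclear: Sequence[NuclearFamily],
    mask: pd.Series,
    prevalence: float,
) -> SibshipTable:
    """Tabulate affected offspring by sibship size.

    Only living offspring count towards sibship size; affection follows the
    supplied phenotype mask.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")
    rows: dict[int, dict[str, float]] = {}
    for fam in nuclear:
        s = fam.sibship_size
        if s < 1:
            continue
        affected = sum(
            1 for o in fam.offspring_ids if mask.get(o) == "affected"
        )
        row = rows.setdefault(
            s,
            {"n_families": 0, "n_affected_families": 0, "observed": 0},
        )
        row["n_families"] += 1
        row["n_affected_families"] += int(affected > 0)
        row["observed"] += affected
    table = (
        pd.DataFrame.from_dict(rows, orient="index")
        .sort_index()
        .rename_axis("sibship_size")
        .astype(int)
    )
    table["expected"] = table["n_families"] * table.index * prevalence
    return SibshipTable(table=table, prevalence=prevalence)


def chi2_random_distribution(table: SibshipTable) -> Chi2Result:
    """Chi-square of observed vs expected cases over sibship-size cells.

    df is the number of cells minus one; cells are the sizes actually
    present (no pooling of small expected counts).
    """
    obs = table.table["observed"].to_numpy(dtype=float)
    exp = table.table["expected"].to_numpy(dtype=float)
    if np.any(exp <= 0.0):
        raise ValueError("every expected count must be positive")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return Chi2Result(chi2=chi2, df=df, p=float(sps.chi2.sf(chi2, df)))


def recessive_model_prob(n_offspring: int, k_min_affected: int) -> float:
    """P(X >= k), X ~ Binomial(n, 1/4), in exact rational arithmetic.

    The 1/4 per-offspring risk is the autosomal recessive expectation for
    offspring of two heterozygous carrier parents.
    """
    n, k = n_offspring, k_min_affected
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    q = Fraction(1, 4)
    tail = sum(
        comb(n, j) * q**j * (1 - q) ** (n - j) for j in range(k, n + 1)
    )
    return float(tail)


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the table [[a, b], [c, d]].

    Uses the mass-summation convention: the sum of hypergeometric masses no
    larger than the observed table's.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table is empty")
    return float(sps.fisher_exact([[a, b], [c, d]])[1])


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Descriptive comparison of affected vs control members (combined).

    Mirrors the usual case/control characteristics table: sex split,
    missing-value counts, age median/IQR and strata (<5, 5-18, >=18 years;
    the boundary 18 falls in the upper stratum), goitre any-form and
    visible-form proportions, with Fisher exact p for each 2x2 and a
    two-sided Mann-Whitney p for age.
    """
    mask = cohort.phenotype_mask("combined")
    groups = {
        "affected": [cohort[i] for i in mask.index[mask == "affected"]],
        "control": [cohort[i] for i in mask.index[mask == "control"]],
    }

    def col(members):
        ages = [m.age_years for m in members if m.age_years is not None]
        goitre = [m.goitre for m in members if m.goitre != "missing"]
        n_obs = len(ages)
        return {
            "n": len(members),
            "male": sum(m.sex == "male" for m in members),
            "female": sum(m.sex == "female" for m in members),
            "age_missing": len(members) - n_obs,
            "age_median": float(np.median(ages)) if ages else np.nan,
            "age_q1": float(np.quantile(ages, 0.25)) if ages else np.nan,
            "age_q3": float(np.quantile(ages, 0.75)) if ages else np.nan,
            "age_lt5": sum(a < 5 for a in ages),
            "age_5_18": sum(5 <= a < 18 for a in ages),
            "age_ge18": sum(a >= 18 for a in ages),
            "goitre_missing": len(members) - len(goitre),
            "goitre_any": sum(g != "absent" for g in goitre),
            "goitre_visible": sum(g == "visible" for g in goitre),
            "goitre_obs": len(goitre),
            "_ages": ages,
        }

    cols = {name: col(members) for name, members in groups.items()}
    aff, ctl = cols["affected"], cols["control"]

    def fisher_p(a, b, c, d):
        # all-missing strata are tolerated and reported without a p-value
        return fisher_2x2(a, b, c, d) if a + b + c + d > 0 else float("nan")

    tests = {
        "sex": fisher_p(aff["male"], aff["female"], ctl["male"], ctl["female"]),
        "age_missing": fisher_p(
            aff["age_missing"], aff["n"] - aff["age_missing"],
            ctl["age_missing"], ctl["n"] - ctl["age_missing"],
        ),
        "age_ge18": fisher_p(
            aff["age_ge18"], (aff["n"] - aff["age_missing"]) - aff["age_ge18"],
            ctl["age_ge18"], (ctl["n"] - ctl["age_missing"]) - ctl["age_ge18"],
        ),
        "goitre_missing": fisher_p(
            aff["goitre_missing"], aff["n"] - aff["goitre_missing"],
            ctl["goitre_missing"], ctl["n"] - ctl["goitre_missing"],
        ),
        "goitre_any": fisher_p(
            aff["goitre_any"], aff["goitre_obs"] - aff["goitre_any"],
            ctl["goitre_any"], ctl["goitre_obs"] - ctl["goitre_any"],
        ),
        "goitre_visible": fisher_p(
            aff["goitre_visible"], aff["goitre_obs"] - aff["goitre_visible"],
            ctl["goitre_visible"], ctl["goitre_obs"] - ctl["goitre_visible"],
        ),
        "age_mannwhitney": mannwhitney_age(aff["_ages"], ctl["_ages"]),
    }

    frame = pd.DataFrame(
        {k: {s: v for s, v in c.items() if not s.startswith("_")}
         for k, c in cols.items()}
    )
    frame["p"] = np.nan
    frame.loc["male", "p"] = tests["sex"]
    frame.loc["age_missing", "p"] = tests["age_missing"]
    frame.loc["age_median", "p"] = tests["age_mannwhitney"]
    frame.loc["age_ge18", "p"] = tests["age_ge18"]
    frame.loc["goitre_missing", "p"] = tests["goitre_missing"]
    frame.loc["goitre_any", "p"] = tests["goitre_any"]
    frame.loc["goitre_visible", "p"] = tests["goitre_visible"]
    return frame


def mannwhitney_age(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p, exact when sample sizes and ties allow."""
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
    )
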