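"""Model/Results interface to the familial-aggregation analysis.

:class:`FamilialAggregation` binds a cohort to a phenotype category and a
disease prevalence; :meth:`~FamilialAggregation.fit` calibrates the
Monte-Carlo null of random case allocation and returns an
:class:`AggregationResults` carrying every test's statistic, p-value,
BH-adjusted p-value and Monte-Carlo metadata, with a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import pandas as pd

from . import aggregation as agg
from .kinship import KinshipMatrix, kinship_matrix
from .pedigree import CATEGORIES, Cohort

ALL_TESTS = (
    "binomial",
    "kinship_sum",
    "genealogical_index",
    "family_genealogical_index",
    "familial_clustering",
)


class FamilialAggregation:
    """Familial-aggregation analysis of one phenotype category.

    Parameters
    ----------
    cohort
        Validated pedigree cohort.
    category
        ``combined`` (default), ``myxedematous`` or ``neurological``.
    prevalence
        Disease prevalence for the binomial family test.  Default: the
        cohort's own affected/phenotyped ratio under *category*'s
        denominator convention (the full phenotyped cohort).
    exclude_families
        Family units dropped from the cohort before any computation
        (sensitivity analysis); prevalence defaults then refer to the
        reduced cohort.
    """

    def __init__(
        self,
        cohort: Cohort,
        category: str = "combined",
        prevalence: float | None = None,
        exclude_families: Sequence[str] = (),
    ):
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if exclude_families:
            dropped = set(exclude_families)
            missing = dropped - set(cohort.family_ids)
            if missing:
                raise ValueError(f"unknown family ids {sorted(missing)}")
            cohort = Cohort(
                ind for ind in cohort if ind.family_id not in dropped
            )
        self.cohort = cohort
        self.category = category
        self.excluded = tuple(exclude_families)
        self.mask = cohort.phenotype_mask(category)
        n_pheno = int((self.mask != "unphenotyped").sum())
        n_aff = int((self.mask == "affected").sum())
        if prevalence is None:
            if n_aff == 0 or n_pheno == 0:
                raise ValueError(
                    "cannot derive prevalence from a cohort without cases"
                )
            prevalence = n_aff / n_pheno
        self.prevalence = float(prevalence)
        self.n_phenotyped = n_pheno
        self.n_affected = n_aff

    @classmethod
    def from_files(
        cls, ped_path, phenotype_path, category: str = "combined", **kwargs
    ) -> "FamilialAggregation":
        from .pedigree import read_pedigree

        return cls(read_pedigree(ped_path, phenotype_path), category, **kwargs)

    @cached_property
    def kinship(self) -> KinshipMatrix:
        return kinship_matrix(self.cohort)

    @cached_property
    def family_counts(self) -> list[agg.FamilyCounts]:
        return agg.family_counts(self.cohort, self.mask)

    def fit(
        self,
        B: int = 100_000,
        seed: int | None = 0,
        alpha: float = 0.05,
        tests: Sequence[str] = ALL_TESTS,
        kinship_null: str = "pooled",
    ) -> "AggregationResults":
        """Run the requested aggregation tests.

        Each Monte-Carlo test gets its own child seed derived from *seed*,
        so results are reproducible for identical inputs and any subset of
        tests can be re-run consistently.
        """
        unknown = set(tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}")
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha {alpha} outside (0, 1)")
        seeds = {
            name: None if seed is None else (seed * 1000003 + i) % (2**31)
            for i, name in enumerate(ALL_TESTS)
        }
        results: dict[str, list[agg.TestResult]] = {}

        if "binomial" in tests:
            results["binomial"] = agg.adjust_results(
                [
                    agg.binomial_family_test(c, self.prevalence)
                    for c in self.family_counts
                ]
            )
        if "kinship_sum" in tests:
            results["kinship_sum"] = agg.adjust_results(
                agg.kinship_sum_test(
                    self.kinship, self.mask, B=B,
                    seed=seeds["kinship_sum"], null=kinship_null,
                )
            )
        if "genealogical_index" in tests:
            results["genealogical_index"] = [
                agg.genealogical_index(
                    self.kinship, self.mask, B=B,
                    seed=seeds["genealogical_index"],
                )
            ]
        if "family_genealogical_index" in tests:
            eligible = [
                c.family_id for c in self.family_counts if c.k_affected >= 2
            ]
            results["family_genealogical_index"] = agg.adjust_results(
                [
                    agg.family_genealogical_index(
                        self.kinship, self.mask, fam, self.cohort, B=B,
                        seed=seeds["family_genealogical_index"],
                    )
                    for fam in eligible
                ]
            )
        if "familial_clustering" in tests:
            results["familial_clustering"] = [
                agg.familial_clustering_test(
                    self.family_counts, B=B,
                    seed=seeds["familial_clustering"],
                )
            ]
        return AggregationResults(
            model=self, results=results, B=B, seed=seed, alpha=alpha
        )


@dataclass
class AggregationResults:
    """Fitted aggregation tests for one cohort and category."""

    model: FamilialAggregation
    results: dict[str, list[agg.TestResult]]
    B: int
    seed: int | None
    alpha: float

    @property
    def frame(self) -> pd.DataFrame:
        """All results in long format (TSV-ready)."""
        frames = [
            agg.results_frame(res, self.model.category)
            for res in self.results.values()
        ]
        return pd.concat(frames, ignore_index=True)

    def significant_families(self, test: str = "binomial") -> list[str]:
        """Family units with BH-adjusted p below alpha for one family test."""
        if test not in self.results:
            raise ValueError(f"test {test!r} was not fitted")
        hits = [
            r for r in self.results[test]
            if r.p_adj is not None and r.p_adj < self.alpha
        ]
        if test == "kinship_sum":  # map affected individuals to their units
            fams = {
                self.model.cohort[r.unit_id].family_id for r in hits
            }
            return sorted(fams)
        return sorted(
            {r.unit_id for r in hits}, key=lambda f: f
        )

    def scenario_table(
        self, prevalences: Sequence[float], alpha: float | None = None
    ) -> pd.DataFrame:
        """Binomial-test significant-family counts over prevalence values."""
        return agg.prevalence_scenarios(
            self.model.cohort,
            self.model.category,
            prevalences,
            alpha=self.alpha if alpha is None else alpha,
        )

    def summary(self) -> str:
        """Plain-text summary in the style of a model results table."""
        m = self.model
        lines = [
            "Familial aggregation analysis",
            "=" * 64,
            f"category:            {m.category}",
            f"phenotyped members:  {m.n_phenotyped}",
            f"affected members:    {m.n_affected}",
            f"prevalence:          {m.prevalence:.6g}",
            f"family units:        {len(m.family_counts)}",
            f"B (null draws):      {self.B}",
            f"seed:                {self.seed}",
            f"alpha (BH FDR):      {self.alpha}",
        ]
        if m.excluded:
            lines.append(f"excluded families:   {', '.join(m.excluded)}")
        lines.append("-" * 64)
        for test, res in self.results.items():
            if test in ("genealogical_index", "familial_clustering"):
                r = res[0]
                p_txt = (
                    f"p < {1.0 / r.n_sims:.3g}" if r.p_is_bound
                    else f"p = {r.p:.3g}"
                )
                lines.append(
                    f"{test:28s} statistic = {r.statistic:.4g}, {p_txt}"
                )
            else:
                hits = [
                    r for r in res
                    if r.p_adj is not None and r.p_adj < self.alpha
                ]
                n_deg = sum(r.degenerate for r in res)
                msg = (
                    f"{test:28s} {len(hits)}/{len(res)} units significant "
                    f"at BH {self.alpha:g}"
                )
                if n_deg:
                    msg += f" ({n_deg} degenerate)"
                lines.append(msg)
                for r in sorted(hits, key=lambda r: (r.p_adj, r.unit_id)):
                    lines.append(
                        f"    {r.unit_id:12s} stat = {r.statistic:.4g}  "
                        f"p = {r.p:.3g}  p_adj = {r.p_adj:.3g}"
                    )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)
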