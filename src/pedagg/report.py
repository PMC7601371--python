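"""Full analysis pipeline: tables, scenario sweeps, sensitivity re-runs.

:func:`run_analysis` ties the stages together and emits, per requested
category, the sibship table with its chi-square, the aggregation test
results with BH adjustment, the prevalence-scenario counts, plus the
descriptive cohort summary and the per-nuclear-family scatter data
(sibship size vs affected offspring).  With ``exclude_families`` set, the
aggregation stage is re-run without those families into a subdirectory.
All outputs are TSV; identical configuration (including seed) yields
byte-identical tables.
"""

from __future__ import annotations

import platform
import shutil
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .model import ALL_TESTS, FamilialAggregation
from .pedigree import CATEGORIES, Cohort, read_pedigree
from .simulate import reference_cohort
from .stats import chi2_random_distribution, cohort_summary, sibship_table

DEFAULT_SCENARIOS = (0.02, 0.05, 0.07)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    ped_path: str | None = None
    phenotype_path: str | None = None
    fixture: bool = False
    categories: Sequence[str] = CATEGORIES
    B: int = 100_000
    seed: int = 0
    alpha: float = 0.05
    prevalence: float | None = None
    scenarios: Sequence[float] = DEFAULT_SCENARIOS
    exclude_families: Sequence[str] = ()
    out_dir: str = "pedagg_report"
    plot: bool = False
    tests: Sequence[str] = ALL_TESTS

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.fixture and (self.ped_path is None
                                 or self.phenotype_path is None):
            raise ValueError("either fixture=True or input paths are required")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _log(lines: list[str], fh, message: str) -> None:
    lines.append(message)
    print(message, file=fh)


def run_analysis(config: RunConfig) -> dict:
    """Run the pipeline; returns a dict of result frames and output paths.

    Partial outputs are removed when a stage fails.
    """
    t0 = time.monotonic()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    log_lines: list[str] = []

    def emit(frame: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=index)
        created.append(path)
        return path

    try:
        cohort = (
            reference_cohort() if config.fixture
            else read_pedigree(config.ped_path, config.phenotype_path)
        )
        bundle: dict = {"out_dir": out_dir, "tables": {}}
        if not list(config.categories):
            message = "no categories requested; nothing to do"
            log_lines.append(message)
            bundle["message"] = message
            _write_log(out_dir, log_lines, config, t0, created)
            return bundle

        _log(log_lines, sys.stderr,
             f"cohort: {len(cohort)} members, "
             f"{cohort.phenotyped_count} phenotyped, "
             f"{len(cohort.family_ids)} family units")

        summary = cohort_summary(cohort)
        bundle["tables"]["cohort_summary"] = summary
        emit(summary, "cohort_summary.tsv", index=True)

        nuclear = cohort.nuclear_families
        fig1 = pd.DataFrame(
            [
                {
                    "family_id": f.family_id,
                    "father_id": f.father_id,
                    "mother_id": f.mother_id,
                    "sibship_size": f.sibship_size,
                    **{
                        f"affected_{cat}": sum(
                            cohort.phenotype_mask(cat)[o] == "affected"
                            for o in f.offspring_ids
                        )
                        for cat in config.categories
                    },
                }
                for f in nuclear
            ]
        )
        bundle["tables"]["figure1_data"] = fig1
        emit(fig1, "figure1_data.tsv")
        if config.plot:
            created.append(_plot_figure1(fig1, out_dir, config))

        for category in config.categories:
            prefix = f"{category}"
            mask = cohort.phenotype_mask(category)
            model = FamilialAggregation(
                cohort, category, prevalence=config.prevalence
            )
            pi = model.prevalence

            st = sibship_table(nuclear, mask, pi)
            chi2 = chi2_random_distribution(st)
            emit(st.table, f"sibship_{prefix}.tsv", index=True)
            bundle["tables"][f"sibship_{category}"] = st
            _log(log_lines, sys.stderr,
                 f"[{category}] chi2 = {chi2.chi2:.4g}, df = {chi2.df}, "
                 f"p = {chi2.p:.4g}")
            bundle["tables"][f"chi2_{category}"] = chi2

            fit = model.fit(
                B=config.B, seed=config.seed, alpha=config.alpha,
                tests=config.tests,
            )
            bundle["tables"][f"aggregation_{category}"] = fit
            emit(fit.frame, f"aggregation_{prefix}.tsv")
            _log(log_lines, sys.stderr, fit.summary())

            scen = fit.scenario_table([*config.scenarios, pi])
            bundle["tables"][f"scenarios_{category}"] = scen
            emit(scen, f"scenarios_{prefix}.tsv")

            if config.exclude_families:
                sub_dir = out_dir / (
                    "excluding_" + "_".join(config.exclude_families)
                )
                sub_dir.mkdir(exist_ok=True)
                created.append(sub_dir)
                sub_model = FamilialAggregation(
                    cohort, category, prevalence=config.prevalence,
                    exclude_families=config.exclude_families,
                )
                sub_fit = sub_model.fit(
                    B=config.B, seed=config.seed, alpha=config.alpha,
                    tests=config.tests,
                )
                bundle["tables"][f"aggregation_{category}_excluded"] = sub_fit
                sub_fit.frame.to_csv(
                    sub_dir / f"aggregation_{prefix}.tsv", sep="\t",
                    index=False,
                )
                _log(log_lines, sys.stderr,
                     f"[{category}] without {list(config.exclude_families)}: "
                     f"{len(sub_fit.significant_families('binomial')) if 'binomial' in config.tests else 'n/a'}"
                     " families significant (binomial)")

        bundle["log"] = _write_log(out_dir, log_lines, config, t0, created)
        return bundle
    except Exception:
        for path in created:
            if path.is_dir():
                shutil.rmtree(path, ignore_errors=True)
            else:
                path.unlink(missing_ok=True)
        raise


def _write_log(out_dir, log_lines, config, t0, created) -> Path:
    import numpy
    import scipy

    path = out_dir / "run_log.txt"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"seed: {config.seed}\nB: {config.B}\n")
        fh.write(f"alpha: {config.alpha}\n")
        fh.write(
            f"python: {platform.python_version()} "
            f"numpy: {numpy.__version__} scipy: {scipy.__version__} "
            f"pandas: {pd.__version__}\n"
        )
        fh.write(f"wall_time_s: {time.monotonic() - t0:.2f}\n")
        for line in log_lines:
            fh.write(line + "\n")
    created.append(path)
    return path


def _plot_figure1(fig1: pd.DataFrame, out_dir: Path, config: RunConfig) -> Path:
    """Cosmetic scatter of affected vs living offspring per nuclear family."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cat = list(config.categories)[0]
    rng_jitter = 0.08
    x = fig1["sibship_size"].to_numpy(dtype=float)
    y = fig1[f"affected_{cat}"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    jx = (pd.Series(range(len(x))) % 5 - 2) * (rng_jitter / 2)
    ax.scatter(x + jx, y, s=18, alpha=0.7)
    xs = [0, max(x.max(), 1)]
    ax.plot(xs, [0.1 * v for v in xs], "--", color="grey",
            label="random, prevalence 10%")
    ax.plot(xs, [0.25 * v for v in xs], "-", color="grey",
            label="recessive, 25% per offspring")
    ax.set_xlabel("living offspring")
    ax.set_ylabel(f"affected offspring ({cat})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = out_dir / "figure1.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
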