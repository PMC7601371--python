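"""Familial-aggregation tests with Monte-Carlo nulls.

Five tests assess whether endemic CH cases concentrate within families more
than random allocation of case labels over the phenotyped cohort predicts:

* **binomial family test** — per family unit, exact upper-tail binomial
  probability of the observed case count given family size and prevalence;
* **kinship sum** — per affected member, the summed kinship with all other
  affected members, against a case-relabelling null;
* **genealogical index of familiality (GIF)** — cohort-level scaled mean
  kinship over affected pairs, against the same null;
* **family GIF** — the GIF restricted to one family, resampling affected
  labels within that family only;
* **probability of familial clustering** — cohort-level probability mass of
  the per-family case-count configuration under the multivariate
  hypergeometric law of random allocation.

Monte-Carlo p-values use the add-one estimator (k + 1)/(B + 1); a result
with zero exceedances carries ``p_is_bound=True`` and is best read as
"p < 1/B".  Ties in null statistics count as exceedances (the conservative
convention).  Identical seed and inputs give identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .kinship import KinshipMatrix
from .pedigree import Cohort

DEFAULT_B = 1_000_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one aggregation test on one unit.

    ``unit_id`` names the tested unit: an individual (kinship sum), a family
    (binomial, family GIF) or ``"cohort"``.  ``p`` is ``None`` for a
    degenerate null.  ``p_adj`` is filled in by BH adjustment across the
    units of one test/category.
    """

    unit_id: str
    test: str
    statistic: float
    p: float | None
    p_is_bound: bool = False
    p_adj: float | None = None
    n_sims: int = 0
    exceedances: int = 0
    degenerate: bool = False
    seed: int | None = None
    #: size of the null distribution when it differs from n_sims (the
    #: pooled kinship-sum null holds n_sims * n_affected values)
    null_size: int | None = None

    def __post_init__(self):
        if self.p is not None and not 0.0 < self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        size = self.n_sims if self.null_size is None else self.null_size
        if size > 0 and self.exceedances > size:
            raise ValueError("exceedances exceed the null distribution size")


@dataclass(frozen=True)
class FamilyCounts:
    """Phenotyped size and case count of one family unit (parents included)."""

    family_id: str
    n_phenotyped: int
    k_affected: int

    def __post_init__(self):
        if not 0 <= self.k_affected <= self.n_phenotyped:
            raise ValueError(
                f"{self.family_id}: k_affected={self.k_affected} outside "
                f"[0, {self.n_phenotyped}]"
            )


def family_counts(cohort: Cohort, mask: pd.Series) -> list[FamilyCounts]:
    """Tabulate phenotyped members and cases per recorded family unit."""
    out = []
    for family_id in cohort.family_ids:
        members = [m.id for m in cohort.family_members(family_id)]
        sub = mask[members]
        out.append(
            FamilyCounts(
                family_id=family_id,
                n_phenotyped=int((sub != "unphenotyped").sum()),
                k_affected=int((sub == "affected").sum()),
            )
        )
    return out


# -- binomial family test ----------------------------------------------------

def binomial_family_test(counts: FamilyCounts, prevalence: float) -> TestResult:
    """Exact upper-tail binomial probability of the family's case count.

    p = P(X >= k), X ~ Binomial(n_phenotyped, prevalence).  Deterministic
    (``n_sims = 0``).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")
    n, k = counts.n_phenotyped, counts.k_affected
    p = 1.0 if k == 0 else float(binom.sf(k - 1, n, prevalence))
    return TestResult(
        unit_id=counts.family_id,
        test="binomial",
        statistic=float(k),
        p=min(p, 1.0),
    )


# -- shared Monte-Carlo machinery -------------------------------------------

def _draw_chunks(
    rng: np.random.Generator, n_pool: int, n_draw: int, n_sims: int,
    max_elements: int = 4_000_000,
) -> Iterator[np.ndarray]:
    """Yield arrays of shape (chunk, n_draw): uniform draws without replacement."""
    chunk = max(1, max_elements // max(n_pool, 1))
    done = 0
    while done < n_sims:
        c = min(chunk, n_sims - done)
        u = rng.random((c, n_pool))
        yield np.argpartition(u, n_draw - 1, axis=1)[:, :n_draw]
        done += c


def _pool_and_affected(kin: KinshipMatrix, mask: pd.Series):
    mask = mask.reindex(list(kin.member_ids))
    pheno_ids = [m for m in kin.member_ids if mask[m] != "unphenotyped"]
    affected_ids = [m for m in pheno_ids if mask[m] == "affected"]
    phi = kin.submatrix(pheno_ids)
    aff_pos = np.array(
        [pheno_ids.index(a) for a in affected_ids], dtype=np.intp
    )
    return pheno_ids, affected_ids, phi, aff_pos


# -- kinship sum -------------------------------------------------------------

def kinship_sum_test(
    kin: KinshipMatrix,
    mask: pd.Series,
    B: int = DEFAULT_B,
    seed: int | None = None,
    null: str = "pooled",
) -> list[TestResult]:
    """Per-affected-member kinship sum against a case-relabelling null.

    The statistic for affected member *i* is s_i = sum over the other
    affected members of phi(i, j).  Each of B null draws samples the same
    number of case labels uniformly without replacement from the phenotyped
    pool.  With ``null="pooled"`` (default) every sampled member's kinship
    sum enters one pooled null distribution and
    p_i = (1 + #{pooled sums >= s_i}) / (1 + B * n_affected); with
    ``null="max"`` only each draw's maximum sum enters the null and
    p_i = (1 + #{max sums >= s_i}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if null not in ("pooled", "max"):
        raise ValueError(f"unknown null convention {null!r}")
    pheno_ids, affected_ids, phi, aff_pos = _pool_and_affected(kin, mask)
    m = len(affected_ids)
    if m < 2:
        raise ValueError("kinship sum test needs at least 2 affected members")

    sub = phi[np.ix_(aff_pos, aff_pos)]
    observed = sub.sum(axis=1) - np.diag(sub)

    rng = np.random.default_rng(seed)
    diag = np.diag(phi)
    exceed = np.zeros(m, dtype=np.int64)
    for idx in _draw_chunks(rng, len(pheno_ids), m, B):
        sums = phi[idx[:, :, None], idx[:, None, :]].sum(axis=2) - diag[idx]
        if null == "max":
            pool = np.sort(sums.max(axis=1))
        else:
            pool = np.sort(sums, axis=None)
        exceed += pool.size - np.searchsorted(pool, observed, side="left")

    size = B * m if null == "pooled" else B
    return [
        TestResult(
            unit_id=affected_ids[i],
            test="kinship_sum",
            statistic=float(observed[i]),
            p=float((exceed[i] + 1) / (size + 1)),
            p_is_bound=bool(exceed[i] == 0),
            n_sims=B,
            exceedances=int(exceed[i]),
            seed=seed,
            null_size=size,
        )
        for i in range(m)
    ]


# -- genealogical index ------------------------------------------------------

GIF_SCALE = 1e5


def _gif(phi: np.ndarray, pos: np.ndarray) -> float:
    """Scaled mean kinship over all unordered pairs of ``pos``."""
    m = len(pos)
    sub = phi[np.ix_(pos, pos)]
    total = (sub.sum() - np.trace(sub)) / 2.0
    return GIF_SCALE * total / (m * (m - 1) / 2.0)


def genealogical_index(
    kin: KinshipMatrix,
    mask: pd.Series,
    B: int = DEFAULT_B,
    seed: int | None = None,
) -> TestResult:
    """Cohort-level GIF test: scaled mean kinship among affected pairs."""
    if B < 1:
        raise ValueError("B must be >= 1")
    pheno_ids, affected_ids, phi, aff_pos = _pool_and_affected(kin, mask)
    m = len(affected_ids)
    if m < 2:
        raise ValueError("GIF test needs at least 2 affected members")
    observed = _gif(phi, aff_pos)

    rng = np.random.default_rng(seed)
    pairs = m * (m - 1) / 2.0
    diag = np.diag(phi)
    exceed = 0
    for idx in _draw_chunks(rng, len(pheno_ids), m, B):
        tot = (
            phi[idx[:, :, None], idx[:, None, :]].sum(axis=(1, 2))
            - diag[idx].sum(axis=1)
        ) / 2.0
        exceed += int((GIF_SCALE * tot / pairs >= observed).sum())

    return TestResult(
        unit_id="cohort",
        test="genealogical_index",
        statistic=observed,
        p=float((exceed + 1) / (B + 1)),
        p_is_bound=exceed == 0,
        n_sims=B,
        exceedances=exceed,
        seed=seed,
    )


def family_genealogical_index(
    kin: KinshipMatrix,
    mask: pd.Series,
    family_id: str,
    cohort: Cohort,
    B: int = DEFAULT_B,
    seed: int | None = None,
) -> TestResult:
    """GIF restricted to one family, resampling within that family only.

    The null redraws the family's number of affected labels from the
    family's own phenotyped members.  When that null collapses to a point
    mass (e.g. every phenotyped member is affected) no p-value is
    interpretable: the result is flagged ``degenerate`` with ``p=None``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    mask = mask.reindex(list(kin.member_ids))
    members = [
        m.id for m in cohort.family_members(family_id)
        if mask[m.id] != "unphenotyped"
    ]
    affected = [m for m in members if mask[m] == "affected"]
    m_aff = len(affected)
    if m_aff < 2:
        raise ValueError(
            f"family {family_id!r} has fewer than 2 affected phenotyped members"
        )
    phi = kin.submatrix(members)
    pos = np.array([members.index(a) for a in affected], dtype=np.intp)
    observed = _gif(phi, pos)

    rng = np.random.default_rng(seed)
    pairs = m_aff * (m_aff - 1) / 2.0
    diag = np.diag(phi)
    exceed = 0
    lo, hi = math.inf, -math.inf
    for idx in _draw_chunks(rng, len(members), m_aff, B):
        gifs = GIF_SCALE * (
            (phi[idx[:, :, None], idx[:, None, :]].sum(axis=(1, 2))
             - diag[idx].sum(axis=1)) / 2.0
        ) / pairs
        exceed += int((gifs >= observed).sum())
        lo, hi = min(lo, float(gifs.min())), max(hi, float(gifs.max()))

    degenerate = hi - lo == 0.0
    return TestResult(
        unit_id=family_id,
        test="family_genealogical_index",
        statistic=observed,
        p=None if degenerate else float((exceed + 1) / (B + 1)),
        p_is_bound=not degenerate and exceed == 0,
        n_sims=B,
        exceedances=exceed,
        degenerate=degenerate,
        seed=seed,
    )


# -- probability of familial clustering --------------------------------------

def _log_choose(n, k):
    n, k = np.asarray(n, float), np.asarray(k, float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def familial_clustering_test(
    counts: Sequence[FamilyCounts],
    B: int = DEFAULT_B,
    seed: int | None = None,
) -> TestResult:
    """Cohort-level clustering test on per-family case counts.

    Under random allocation of the A case labels among the N phenotyped
    members, the vector of per-family case counts follows the multivariate
    hypergeometric law.  The statistic is the probability mass of the
    observed configuration; the Monte-Carlo p-value is the probability of
    drawing a configuration with mass less than or equal to it.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = np.array([c.n_phenotyped for c in counts], dtype=np.int64)
    k = np.array([c.k_affected for c in counts], dtype=np.int64)
    N, A = int(n.sum()), int(k.sum())
    if A < 1:
        raise ValueError("clustering test needs at least 1 case")
    if A > N:
        raise ValueError("more cases than phenotyped members")

    n_fam = len(counts)
    # per-family log C(n_f, j) lookup, j = 0..A
    js = np.arange(A + 1)
    table = np.full((n_fam, A + 1), -np.inf)
    for f in range(n_fam):
        jmax = min(int(n[f]), A)
        table[f, : jmax + 1] = _log_choose(n[f], js[: jmax + 1])
    log_norm = float(_log_choose(N, A))
    log_obs = float(table[np.arange(n_fam), k].sum())
    tol = 1e-9  # float ties across summation orders count as exceedances

    labels = np.repeat(np.arange(n_fam), n)
    rng = np.random.default_rng(seed)
    exceed = 0
    fam_idx = np.arange(n_fam)
    for idx in _draw_chunks(rng, N, A, B):
        c = idx.shape[0]
        cnt = np.zeros((c, n_fam), dtype=np.int64)
        np.add.at(cnt, (np.repeat(np.arange(c), A), labels[idx].ravel()), 1)
        log_mass = table[fam_idx[None, :], cnt].sum(axis=1)
        exceed += int((log_mass <= log_obs + tol).sum())

    return TestResult(
        unit_id="cohort",
        test="familial_clustering",
        statistic=float(np.exp(log_obs - log_norm)),
        p=float((exceed + 1) / (B + 1)),
        p_is_bound=exceed == 0,
        n_sims=B,
        exceedances=exceed,
        seed=seed,
    )


# -- multiple testing --------------------------------------------------------

def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    p_adj(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted
    sequence, mapped back to the input order.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0.0) | (p > 1.0)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def adjust_results(results: Sequence[TestResult]) -> list[TestResult]:
    """BH-adjust a batch of results from one test/category; skips degenerates."""
    testable = [i for i, r in enumerate(results) if r.p is not None]
    if not testable:
        return list(results)
    adj = bh_adjust([results[i].p for i in testable])
    out = list(results)
    for j, i in enumerate(testable):
        out[i] = replace(out[i], p_adj=float(adj[j]))
    return out


# -- prevalence scenarios ----------------------------------------------------

def prevalence_scenarios(
    cohort: Cohort,
    category: str,
    prevalences: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial family test swept over prevalence values.

    For each prevalence the test runs on every family unit, p-values are
    BH-adjusted across families and families with adjusted p < *alpha* are
    counted.  Returns a table with columns ``prevalence``, ``category``,
    ``n_significant`` and ``families`` (ids, ordered by adjusted p).
    """
    if len(prevalences) == 0:
        raise ValueError("prevalence list must not be empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    counts = family_counts(cohort, cohort.phenotype_mask(category))
    rows = []
    for pi in prevalences:
        results = adjust_results(
            [binomial_family_test(c, pi) for c in counts]
        )
        hits = sorted(
            (r for r in results if r.p_adj is not None and r.p_adj < alpha),
            key=lambda r: (r.p_adj, r.unit_id),
        )
        rows.append(
            {
                "prevalence": pi,
                "category": category,
                "n_significant": len(hits),
                "families": ",".join(r.unit_id for r in hits),
            }
        )
    return pd.DataFrame(rows)


def results_frame(results: Sequence[TestResult], category: str) -> pd.DataFrame:
    """Long-format results table (one row per tested unit)."""
    frame = pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "category": category,
                "test": r.test,
                "statistic": r.statistic,
                "p": r.p,
                "p_is_bound": r.p_is_bound,
                "p_adj": r.p_adj,
                "B": r.n_sims,
                "exceedances": r.exceedances,
                "degenerate": r.degenerate,
                "seed": r.seed,
            }
            for r in results
        ]
    )
    for col in ("statistic", "p", "p_adj"):
        frame[col] = pd.to_numeric(frame[col])
    return frame
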