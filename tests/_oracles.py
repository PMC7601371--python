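"""Independent oracles for the test suite.

Everything here is deliberately implemented by brute force — gene-dropping
simulation, exhaustive enumeration of case-label assignments, literal
double-loop step-up — and never calls the code paths it is used to check.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np


def gene_drop_phi(
    parents: dict[str, tuple[str | None, str | None]],
    a: str,
    b: str,
    n_drops: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Estimate the kinship coefficient of a and b by gene dropping.

    Founders get unique allele labels; every offspring inherits one random
    allele from each parent.  phi is the probability that one allele drawn
    from each of a and b is identical by descent.  Returns (estimate,
    Monte-Carlo standard error).
    """
    order: list[str] = []
    seen: set[str] = set()

    def visit(x: str):
        if x in seen:
            return
        fa, mo = parents[x]
        if fa is not None:
            visit(fa)
            visit(mo)
        seen.add(x)
        order.append(x)

    for x in parents:
        visit(x)

    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    label = itertools.count()
    for x in order:
        fa, mo = parents[x]
        if fa is None:
            alleles[x] = (
                np.full(n_drops, next(label)),
                np.full(n_drops, next(label)),
            )
        else:
            pick_f = rng.integers(0, 2, n_drops)
            pick_m = rng.integers(0, 2, n_drops)
            alleles[x] = (
                np.where(pick_f == 0, alleles[fa][0], alleles[fa][1]),
                np.where(pick_m == 0, alleles[mo][0], alleles[mo][1]),
            )
    a1, a2 = alleles[a]
    b1, b2 = alleles[b]
    ibd = (
        (a1 == b1).astype(float) + (a1 == b2) + (a2 == b1) + (a2 == b2)
    ) / 4.0
    return float(ibd.mean()), float(ibd.std(ddof=1) / math.sqrt(n_drops))


def kinship_sums(phi: np.ndarray, subset: tuple[int, ...]) -> list[float]:
    """Per-member sums of kinship with the other subset members."""
    return [
        sum(phi[i, j] for j in subset if j != i) for i in subset
    ]


def enum_kinship_sum_pooled(
    phi: np.ndarray, n_affected: int, observed: float
) -> float:
    """B -> infinity pooled-null tail for one observed kinship sum."""
    n = phi.shape[0]
    total = 0
    hits = 0
    for subset in itertools.combinations(range(n), n_affected):
        for s in kinship_sums(phi, subset):
            total += 1
            hits += s >= observed
    return hits / total


def gif(phi: np.ndarray, subset: tuple[int, ...]) -> float:
    m = len(subset)
    tot = sum(
        phi[i, j] for i, j in itertools.combinations(subset, 2)
    )
    return 1e5 * tot / (m * (m - 1) / 2)


def enum_gif_tail(phi: np.ndarray, n_affected: int, observed: float) -> float:
    """Exact fraction of case-label assignments with GIF >= observed."""
    n = phi.shape[0]
    subsets = list(itertools.combinations(range(n), n_affected))
    hits = sum(gif(phi, s) >= observed for s in subsets)
    return hits / len(subsets)


def enum_clustering_tail(ns: list[int], ks: list[int]) -> float:
    """Exact clustering p: mass of configurations no more likely than observed.

    Enumerates every assignment of the A case labels to the N individuals
    and accumulates assignments whose per-family configuration mass is <=
    the observed configuration's mass.
    """
    N, A = sum(ns), sum(ks)
    labels = [f for f, nf in enumerate(ns) for _ in range(nf)]

    def mass(counts):
        return math.prod(
            comb(nf, cf) for nf, cf in zip(ns, counts)
        ) / comb(N, A)

    obs = mass(ks)
    hits = 0
    for subset in itertools.combinations(range(N), A):
        counts = [0] * len(ns)
        for i in subset:
            counts[labels[i]] += 1
        hits += mass(counts) <= obs + 1e-12
    return hits / comb(N, A)


def stepup_bh(pvals) -> list[float]:
    """Literal double-loop BH step-up reference."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for rank_index, i in enumerate(order):
        candidates = [
            min(1.0, p[order[j]] * m / (j + 1))
            for j in range(rank_index, m)
        ]
        adjusted[i] = min(candidates)
    return adjusted


def mc_ci99(p_hat: float, n: int) -> float:
    """Half-width of a 99% normal-approximation binomial CI."""
    return 2.576 * math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n)
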