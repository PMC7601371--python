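"""Malécot kinship coefficients over a pedigree forest.

The kinship coefficient phi(i, j) is the probability that one allele drawn
at random from *i* and one from *j* are identical by descent.  It obeys the
classic recursion on an acyclic pedigree:

* phi(i, i) = (1 + phi(father_i, mother_i)) / 2
* phi(i, j) = (phi(father_i, j) + phi(mother_i, j)) / 2, expanding an
  individual that is not an ancestor of the other
* distinct founders are unrelated (phi = 0)

Members of different connected components of the parent graph are unrelated,
so the matrix is computed block-wise per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .pedigree import FOUNDER, Cohort


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric matrix of kinship coefficients over cohort members."""

    member_ids: tuple[str, ...]
    phi: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {m: i for i, m in enumerate(self.member_ids)}
        )

    def phi_between(self, a: str, b: str) -> float:
        return float(self.phi[self._index[a], self._index[b]])

    def indices(self, ids) -> np.ndarray:
        return np.fromiter((self._index[i] for i in ids), dtype=np.intp)

    def submatrix(self, ids) -> np.ndarray:
        idx = self.indices(ids)
        return self.phi[np.ix_(idx, idx)]


def kinship_matrix(cohort: Cohort) -> KinshipMatrix:
    """Compute the full kinship matrix of a cohort.

    Acyclicity is guaranteed by :class:`~pedagg.pedigree.Cohort` validation.
    """
    ids = list(cohort.ids)
    index = {m: i for i, m in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))

    # generation rank: founders 0, child strictly deeper than its parents;
    # the deeper of two members can never be an ancestor of the other
    depth: dict[str, int] = {}
    order = nx.topological_sort(cohort.parent_graph)
    parents: dict[str, tuple[str, str]] = {}
    for member_id in order:
        ind = cohort[member_id]
        if ind.is_founder:
            depth[member_id] = 0
            parents[member_id] = (FOUNDER, FOUNDER)
        else:
            depth[member_id] = 1 + max(depth[ind.father_id], depth[ind.mother_id])
            parents[member_id] = (ind.father_id, ind.mother_id)

    memo: dict[tuple[str, str], float] = {}

    def phi_pair(a: str, b: str) -> float:
        if a == FOUNDER or b == FOUNDER:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            fa, mo = parents[a]
            val = 0.5 * (1.0 + phi_pair(fa, mo))
        else:
            # expand the deeper member; ties broken arbitrarily (equal depth
            # implies neither is an ancestor of the other)
            x, y = (a, b) if depth[a] >= depth[b] else (b, a)
            fa, mo = parents[x]
            if fa == FOUNDER:
                val = 0.0
            else:
                val = 0.5 * (phi_pair(fa, y) + phi_pair(mo, y))
        memo[key] = val
        return val

    undirected = cohort.parent_graph.to_undirected(as_view=True)
    for component in nx.connected_components(undirected):
        block = sorted(component, key=index.__getitem__)
        for ai, a in enumerate(block):
            ia = index[a]
            for b in block[ai:]:
                ib = index[b]
                phi[ia, ib] = phi[ib, ia] = phi_pair(a, b)

    return KinshipMatrix(member_ids=tuple(ids), phi=phi)
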