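"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own EM / ICM / analytic-null code
paths: the grid search enumerates Bernoulli parameters exhaustively, the
Potts oracle enumerates every labeling, and the enrichment oracle
enumerates every same-size node subset.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from numba import njit

EPS = 1e-4  # same clamp as the fitter, so the grids cover the same space


@njit(cache=True)
def _grid_max(B: np.ndarray, n: np.ndarray) -> float:
    """Max mixture LL over all K=2 theta-config pairs for 3 row patterns.

    ``B[c, p]`` is the likelihood of pattern p under theta config c; ``n``
    the pattern counts.  For fixed configs the profile stationarity in the
    mixing weight pi is quadratic, so pi is solved in closed form; the
    endpoints pi in {0, 1} reduce to the best single-config term.
    """
    C = B.shape[0]
    best = -1e18
    for i in range(C):
        ll = n[0] * np.log(B[i, 0]) + n[1] * np.log(B[i, 1]) + n[2] * np.log(B[i, 2])
        if ll > best:
            best = ll
    for i in range(C):
        for j in range(i + 1, C):
            A0 = B[i, 0] - B[j, 0]
            A1 = B[i, 1] - B[j, 1]
            A2 = B[i, 2] - B[j, 2]
            C0, C1, C2 = B[j, 0], B[j, 1], B[j, 2]
            a2 = (n[0] + n[1] + n[2]) * A0 * A1 * A2
            a1 = (n[0] * A0 * (A1 * C2 + A2 * C1)
                  + n[1] * A1 * (A0 * C2 + A2 * C0)
                  + n[2] * A2 * (A0 * C1 + A1 * C0))
            a0 = n[0] * A0 * C1 * C2 + n[1] * A1 * C0 * C2 + n[2] * A2 * C0 * C1
            if np.abs(a2) > 1e-300:
                disc = a1 * a1 - 4.0 * a2 * a0
                if disc < 0.0:
                    continue
                sq = np.sqrt(disc)
                for sign in (1.0, -1.0):
                    pi = (-a1 + sign * sq) / (2.0 * a2)
                    if 0.0 < pi < 1.0:
                        ll = (n[0] * np.log(C0 + pi * A0)
                              + n[1] * np.log(C1 + pi * A1)
                              + n[2] * np.log(C2 + pi * A2))
                        if ll > best:
                            best = ll
            elif np.abs(a1) > 1e-300:
                pi = -a0 / a1
                if 0.0 < pi < 1.0:
                    ll = (n[0] * np.log(C0 + pi * A0)
                          + n[1] * np.log(C1 + pi * A1)
                          + n[2] * np.log(C2 + pi * A2))
                    if ll > best:
                        best = ll
    return best


def bmm_grid_oracle(X: np.ndarray) -> float:
    """Exhaustive K=2 grid-search max log-likelihood (theta on a 0.01 grid).

    The instance must be F x 2 with exactly 3 distinct row patterns and no
    all-zero row.
    """
    X = np.asarray(X)
    pats, counts = np.unique(X, axis=0, return_counts=True)
    if len(pats) != 3:
        raise ValueError("oracle instance must have exactly 3 row patterns")
    n = counts.astype(np.float64)
    grid = np.clip(np.arange(101) / 100.0, EPS, 1 - EPS)
    ta, tb = np.meshgrid(grid, grid, indexing="ij")
    ta, tb = ta.ravel(), tb.ravel()
    B = np.empty((len(ta), 3))
    for p, (xa, xb) in enumerate(pats):
        B[:, p] = (ta if xa else 1 - ta) * (tb if xb else 1 - tb)
    return float(_grid_max(B, n))


def potts_energy(logr: np.ndarray, edges, labels) -> float:
    """Energy of one labeling: unary log-responsibilities + beta couplings.

    ``edges`` is a list of ``(i, j, beta)`` index pairs.
    """
    e = float(sum(logr[i, k] for i, k in enumerate(labels)))
    e += sum(beta for i, j, beta in edges if labels[i] == labels[j])
    return e


def potts_exhaustive(logr: np.ndarray, edges, K: int):
    """Globally optimal labeling by enumerating all K**n labelings."""
    n = logr.shape[0]
    return max(
        itertools.product(range(K), repeat=n),
        key=lambda lab: potts_energy(logr, edges, lab),
    )


def enrichment_enumeration(graph: nx.Graph, node_set) -> float:
    """Exact permutation p-value over all same-size node subsets."""
    k = len(node_set)
    e_obs = graph.subgraph(node_set).number_of_edges()
    sets = list(itertools.combinations(graph.nodes, k))
    hits = sum(
        1 for s in sets if graph.subgraph(s).number_of_edges() >= e_obs
    )
    return hits / len(sets)
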