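"""Shared independent oracles used by unit and acceptance tests."""

import numpy as np
from skbio import DistanceMatrix

from popgs.popstruct import _bipartitions


def brute_force_nj_topology(dm: DistanceMatrix):
    """Least-squares best of the 3 unrooted 4-taxon topologies."""
    ids = list(dm.ids)
    best, best_ss = None, np.inf
    for split in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        (a, b), (c, d) = split
        A = np.array(
            [
                [1, 1, 0, 0, 0],
                [1, 0, 1, 0, 1],
                [1, 0, 0, 1, 1],
                [0, 1, 1, 0, 1],
                [0, 1, 0, 1, 1],
                [0, 0, 1, 1, 0],
            ]
        )
        y = np.array(
            [
                dm[ids[a], ids[b]], dm[ids[a], ids[c]], dm[ids[a], ids[d]],
                dm[ids[b], ids[c]], dm[ids[b], ids[d]], dm[ids[c], ids[d]],
            ]
        )
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(np.sum((A @ x - y) ** 2))
        if resid < best_ss - 1e-12:
            best_ss, best = resid, frozenset(
                [frozenset([ids[a], ids[b]]), frozenset([ids[c], ids[d]])]
            )
    return best


def tree_quartet_split(tree):
    parts = _bipartitions(tree)
    tips = frozenset(t.name for t in tree.tips())
    for side in parts:
        if len(side) == 2:
            return frozenset([side, tips - side])
    return None


def random_additive_quartet(rng):
    """Random 4-taxon additive distance matrix with a known internal edge."""
    e = rng.uniform(0.05, 1.0, size=4)
    mid = rng.uniform(0.05, 1.0)
    ids = list("abcd")
    D = np.zeros((4, 4))
    pairs = {
        (0, 1): e[0] + e[1],
        (0, 2): e[0] + mid + e[2],
        (0, 3): e[0] + mid + e[3],
        (1, 2): e[1] + mid + e[2],
        (1, 3): e[1] + mid + e[3],
        (2, 3): e[2] + e[3],
    }
    for (i, j), v in pairs.items():
        D[i, j] = D[j, i] = v
    return DistanceMatrix(D, ids)
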