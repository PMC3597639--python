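"""Independent brute-force oracles used by the test suite.

Deliberately simple and slow implementations, kept free of the package's
own code paths so they can arbitrate correctness.
"""

from itertools import product

import numpy as np

_NEIGHBORS = {}


def _neighbors(connectivity: int):
    if connectivity not in _NEIGHBORS:
        offs = []
        for d in product((-1, 0, 1), repeat=3):
            if d == (0, 0, 0):
                continue
            manhattan = sum(abs(x) for x in d)
            if connectivity == 6 and manhattan > 1:
                continue
            if connectivity == 18 and manhattan > 2:
                continue
            offs.append(d)
        _NEIGHBORS[connectivity] = offs
    return _NEIGHBORS[connectivity]


def flood_fill_components(mask: np.ndarray, connectivity: int = 26):
    """Connected components of a 3D binary array by explicit flood fill.

    Returns a list of voxel-index sets, one per component, ordered by each
    component's smallest (z, y, x) voxel.
    """
    fg = {tuple(v) for v in np.argwhere(mask)}
    offs = _neighbors(connectivity)
    seen = set()
    comps = []
    for start in sorted(fg):
        if start in seen:
            continue
        comp = set()
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.add(v)
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if w in fg and w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(comp)
    return comps


def nnls_reference(M: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Bounded least squares via scipy's trust-region solver (independent of
    the package's active-set enumeration and of scipy.optimize.nnls)."""
    from scipy.optimize import lsq_linear

    res = lsq_linear(M, s, bounds=(0.0, np.inf), tol=1e-14)
    return res.x


def pairwise_overlap_components(objects: dict):
    """Brute-force merge oracle: objects (keyed (channel, id) -> voxel set)
    are linked when they share a voxel; returns the set partition."""
    keys = list(objects)
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if objects[a] & objects[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for k in keys:
        groups.setdefault(find(k), set()).add(k)
    return sorted(frozenset(g) for g in groups.values())
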