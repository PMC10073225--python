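"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: shortest paths are
found by enumerating every simple path, and centralities follow directly
from their definitions on those enumerations.
"""

from __future__ import annotations

import itertools

import numpy as np

_TOL = 1e-9


def _all_simple_paths(W: np.ndarray, s: int, t: int):
    """Yield every simple s→t path as a node tuple (edges where W > 0)."""
    n = W.shape[0]

    def extend(path):
        last = path[-1]
        if last == t:
            yield tuple(path)
            return
        for nxt in range(n):
            if W[last, nxt] > 0 and nxt not in path:
                yield from extend(path + [nxt])

    yield from extend([s])


def _path_dist(W: np.ndarray, path) -> float:
    return sum(1.0 / W[a, b] for a, b in zip(path, path[1:]))


def shortest_paths_exhaustive(W: np.ndarray, s: int, t: int):
    """All minimal-distance simple s→t paths and their common distance."""
    paths = [p for p in _all_simple_paths(W, s, t) if len(p) > 1]
    if not paths:
        return [], np.inf
    dists = np.array([_path_dist(W, p) for p in paths])
    dmin = dists.min()
    keep = [p for p, d in zip(paths, dists) if d <= dmin * (1 + _TOL) + _TOL]
    return keep, float(dmin)


def betweenness_exhaustive(W: np.ndarray) -> np.ndarray:
    """Normalized betweenness from full path enumeration, ties split fractionally."""
    n = W.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths, _ = shortest_paths_exhaustive(W, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm


def avg_path_length_exhaustive(W: np.ndarray) -> np.ndarray:
    """Per-node mean shortest-path distance to reachable others (NaN if none)."""
    n = W.shape[0]
    out = np.full(n, np.nan)
    for v in range(n):
        dists = []
        for u in range(n):
            if u == v:
                continue
            _, d = shortest_paths_exhaustive(W, v, u)
            if np.isfinite(d):
                dists.append(d)
        if dists:
            out[v] = float(np.mean(dists))
    return out


def random_symmetric_weights(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """A random symmetric nonnegative weight matrix with zero diagonal."""
    W = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < density:
            W[i, j] = W[j, i] = rng.uniform(0.2, 5.0)
    return W
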