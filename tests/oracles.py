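"""Independent brute-force oracles used to cross-check graph centralities.

Everything here works on a plain numpy adjacency matrix via
matrix-power geodesic counting, deliberately avoiding the graph
library the implementation uses: the number of shortest s-t paths is
(A^d)[s, t] for d the smallest power with a nonzero entry, and
betweenness quantities follow from the classical combination rule
sigma_sv * sigma_vt / sigma_st on distance-additive triples.
"""

from __future__ import annotations

import numpy as np


def distances_and_path_counts(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hop distance matrix and geodesic count matrix for an undirected graph."""
    n = len(A)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    P = np.eye(n)
    powers = [np.eye(n)]
    for d in range(1, n):
        P = P @ A
        powers.append(P.copy())
        newly = (P > 0) & np.isinf(D)
        D[newly] = d
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(D[s, t]):
                sigma[s, t] = powers[int(D[s, t])][s, t]
    return D, sigma


def oracle_closeness(A: np.ndarray) -> np.ndarray:
    """1 / mean hop distance to reachable nodes; 0 for isolated nodes."""
    D, _ = distances_and_path_counts(A)
    n = len(A)
    out = np.zeros(n)
    for v in range(n):
        d = [D[v, t] for t in range(n) if t != v and np.isfinite(D[v, t])]
        if d:
            out[v] = 1.0 / float(np.mean(d))
    return out


def oracle_node_betweenness(A: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Betweenness by explicit enumeration over unordered pairs."""
    D, sigma = distances_and_path_counts(A)
    n = len(A)
    raw = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(D[s, t]):
                    continue
                if D[s, v] + D[v, t] == D[s, t]:
                    raw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if normalized and n > 2:
        raw /= (n - 1) * (n - 2) / 2.0
    return raw


def oracle_edge_betweenness(A: np.ndarray) -> dict[tuple[int, int], float]:
    """Unnormalised edge betweenness over unordered connected pairs."""
    D, sigma = distances_and_path_counts(A)
    n = len(A)
    out: dict[tuple[int, int], float] = {}
    for u in range(n):
        for v in range(u + 1, n):
            if not A[u, v]:
                continue
            total = 0.0
            for s in range(n):
                for t in range(s + 1, n):
                    if not np.isfinite(D[s, t]) or s == t:
                        continue
                    through = 0.0
                    if D[s, u] + 1 + D[v, t] == D[s, t]:
                        through += sigma[s, u] * sigma[v, t]
                    if D[s, v] + 1 + D[u, t] == D[s, t]:
                        through += sigma[s, v] * sigma[u, t]
                    total += through / sigma[s, t]
            out[(u, v)] = total
    return out
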