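"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they verify: shortest routes by
exhaustive simple-path enumeration, partial correlations by direct matrix
inversion, Mann-Whitney U by literal pair counting, and the 2x2 Pearson
statistic via observed-vs-expected sums.
"""

from __future__ import annotations

import math

import numpy as np

TIE_TOL = 1e-9


def enumerate_shortest_paths(
    adjacency: dict[str, dict[str, float]], source: str, target: str
) -> tuple[float, list[list[str]]]:
    """All minimum-total-distance simple routes, by exhaustive recursion."""
    best = [math.inf]
    routes: list[list[str]] = []

    def recurse(node: str, dist: float, path: list[str]) -> None:
        if dist > best[0] + TIE_TOL:
            return
        if node == target:
            if dist < best[0] - TIE_TOL:
                best[0] = dist
                routes.clear()
                routes.append(list(path))
            elif abs(dist - best[0]) <= TIE_TOL:
                routes.append(list(path))
            return
        for nbr, d in adjacency.get(node, {}).items():
            if nbr not in path:
                path.append(nbr)
                recurse(nbr, dist + d, path)
                path.pop()

    recurse(source, 0.0, [source])
    return best[0], sorted(routes)


def pcor_by_inversion(S: np.ndarray) -> np.ndarray:
    """Partial correlations via plain inversion of the correlation matrix."""
    K = np.linalg.inv(S)
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def mann_whitney_u_by_counting(x, y) -> float:
    """U for group 1: pairs with x > y plus half the ties, counted directly."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def pearson_chi2_by_expected(a: int, b: int, c: int, d: int) -> float:
    """Chi-squared via sum of (observed - expected)^2 / expected."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


def random_distance_graph(
    rng: np.random.Generator, max_nodes: int = 7, discrete: bool = False
) -> dict[str, dict[str, float]]:
    """Random connected undirected graph as an adjacency-of-distances dict.

    ``discrete=True`` draws distances from an exactly-representable set so
    co-optimal ties occur and float sums stay exact.
    """
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    while True:
        adj: dict[str, dict[str, float]] = {name: {} for name in names}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    d = float(rng.choice([2.0, 4.0, 8.0])) if discrete else float(
                        rng.uniform(1.25, 5.0)
                    )
                    adj[names[i]][names[j]] = d
                    adj[names[j]][names[i]] = d
        # connectivity by hand-rolled DFS
        seen: set[str] = set()
        stack = [names[0]]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj[node])
        if len(seen) == n:
            return adj
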