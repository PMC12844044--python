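"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by enumeration or first-principles
formula, staying independent of the code path it checks.
"""

import itertools
import math

import numpy as np


def mannwhitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label assignments
    of the pooled (tie-free) sample; p = 2 * min(tail) capped at 1."""
    a, b = list(a), list(b)
    pooled = a + b
    n = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    lower = upper = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in grp for y in rest if x > y)
        total += 1
        lower += u <= u_obs
        upper += u >= u_obs
    return min(1.0, 2.0 * min(lower, upper) / total)


def spearman_brute(x, y) -> float:
    """Average-rank Spearman: explicit ranking then the Pearson formula."""

    def avg_rank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_rank(x), avg_rank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    return float((rx * ry).sum() / denom)


def betweenness_enumeration(nodes, edges) -> dict:
    """Unnormalized betweenness by exhaustive simple-path enumeration:
    for every unordered pair (s, t), find all shortest paths and credit
    interior nodes 1/#paths each."""
    adjacency = {v: set() for v in nodes}
    for i, j in edges:
        adjacency[i].add(j)
        adjacency[j].add(i)

    def all_paths(s, t):
        paths, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in adjacency[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return paths

    scores = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for path in sp:
            for v in path[1:-1]:
                scores[v] += 1.0 / len(sp)
    return scores


def ora_enumeration_p(universe, pathway, selection_size, k_obs) -> float:
    """P(hits >= k_obs) over all C(N, n) equally likely selections."""
    universe = sorted(universe)
    pathway = set(pathway)
    hits = total = 0
    for combo in itertools.combinations(universe, selection_size):
        total += 1
        hits += len(pathway & set(combo)) >= k_obs
    return hits / total


def pls1_scores(X, y):
    """Independent one-component PLS1 oracle (scikit-learn)."""
    from sklearn.cross_decomposition import PLSRegression

    pls = PLSRegression(n_components=1, scale=False)
    pls.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return pls.x_scores_[:, 0]
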