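"""Independent brute-force oracles used to verify the implementation.

Everything here is written from the definitions, deliberately ignoring the
library's own code paths: plain dynamic programming over prefixes for the
edit distances, exhaustive path enumeration for graph quantities, and raw
membership scans for contingency cells.  Slow on purpose; only run on tiny
instances.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache


def osa_reference(s: str, t: str) -> int:
    """OSA distance via memoized recursion over suffix pairs."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0 or j == 0:
            return i or j
        best = min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (s[i - 1] != t[j - 1]),
        )
        if i > 1 and j > 1 and s[i - 1] == t[j - 2] and s[i - 2] == t[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(s), len(t))


def damerau_levenshtein_unrestricted(s: str, t: str) -> int:
    """Full Damerau-Levenshtein (transpositions may be edited again)."""
    inf = len(s) + len(t)
    da: dict[str, int] = {}
    n, m = len(s), len(t)
    d = [[0] * (m + 2) for _ in range(n + 2)]
    d[0][0] = inf
    for i in range(n + 1):
        d[i + 1][0] = inf
        d[i + 1][1] = i
    for j in range(m + 1):
        d[0][j + 1] = inf
        d[1][j + 1] = j
    for i in range(1, n + 1):
        db = 0
        for j in range(1, m + 1):
            k = da.get(t[j - 1], 0)
            l = db
            if s[i - 1] == t[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            d[i + 1][j + 1] = min(
                d[i][j] + cost,
                d[i + 1][j] + 1,
                d[i][j + 1] + 1,
                d[k][l] + (i - k - 1) + 1 + (j - l - 1),
            )
        da[s[i - 1]] = i
    return d[n + 1][m + 1]


# ---------------------------------------------------------------------------
# graph oracles: adjacency given as dict node -> set of neighbors


def degree(adj: dict, v) -> int:
    return len(adj[v])


def density(adj: dict) -> float:
    n = len(adj)
    m = sum(len(nb) for nb in adj.values()) // 2
    return m / (n * (n - 1) / 2)


def shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest simple paths s -> t by breadth-first enumeration."""
    if s == t:
        return [[s]]
    frontier = [[s]]
    found: list[list] = []
    visited_depth = {s: 0}
    depth = 0
    while frontier and not found:
        depth += 1
        nxt = []
        for path in frontier:
            for nb in sorted(adj[path[-1]]):
                if visited_depth.get(nb, depth) < depth:
                    continue
                visited_depth[nb] = depth
                newp = path + [nb]
                if nb == t:
                    found.append(newp)
                else:
                    nxt.append(newp)
        frontier = nxt
    return found


def distances_from(adj: dict, s) -> dict:
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for v in frontier:
            for nb in adj[v]:
                if nb not in dist:
                    dist[nb] = dist[v] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


def components(adj: dict) -> list[set]:
    seen: set = set()
    out = []
    for v in adj:
        if v in seen:
            continue
        comp = set(distances_from(adj, v))
        seen |= comp
        out.append(comp)
    return out


def diameter_largest_component(adj: dict) -> int:
    comps = components(adj)
    giant = max(comps, key=lambda c: (len(c), sorted(map(str, c))))
    best = 0
    for s in giant:
        best = max(best, max(distances_from({v: adj[v] & giant for v in giant}, s).values()))
    return best


def betweenness(adj: dict, v) -> float:
    """Unnormalized betweenness by enumerating all shortest paths."""
    total = 0.0
    nodes = sorted(adj)
    for s, t in itertools.combinations(nodes, 2):
        if v in (s, t):
            continue
        paths = shortest_paths(adj, s, t)
        if not paths:
            continue
        through = sum(1 for p in paths if v in p[1:-1])
        total += through / len(paths)
    return total


# ---------------------------------------------------------------------------
# neighborhood-valence oracle


def neighborhood_mean(
    adj: dict,
    strength: dict,
    valence: dict,
    focus,
    variant: int,
) -> float:
    """Direct evaluation of the six neighborhood-valence definitions.

    ``strength[frozenset((a, b))]`` is the connector strength; ``valence``
    maps node -> numeric valence with ambivalent already resolved to 0 and a
    parallel ``carrier`` notion: a node carries affect iff its *original*
    valence is neither 0 nor ambivalent (callers encode this by passing the
    carrier set).
    """
    raise NotImplementedError("use neighborhood_mean_full")


def neighborhood_mean_full(
    adj: dict,
    strength: dict,
    valence: dict,
    carriers: set,
    focus,
    variant: int,
) -> float:
    dist = distances_from(adj, focus)
    n1 = sorted(v for v, d in dist.items() if d == 1)
    n2 = sorted(v for v, d in dist.items() if d in (1, 2))
    hood = n1 if variant in (1, 3, 5) else n2
    if not hood:
        return math.nan
    if variant in (1, 2):
        return sum(valence[v] for v in hood) / len(hood)
    if variant == 3:
        w = {v: abs(strength[frozenset((focus, v))]) for v in hood}
        return sum(w[v] * valence[v] for v in hood) / sum(w.values())
    if variant == 4:
        w = {}
        for v in hood:
            best = 0.0
            for path in shortest_paths(adj, focus, v):
                prod = 1.0
                for a, b in zip(path, path[1:]):
                    prod *= abs(strength[frozenset((a, b))]) / 3.0
                best = max(best, prod)
            w[v] = best
        return sum(w[v] * valence[v] for v in hood) / sum(w.values())
    cs = [v for v in hood if v in carriers]
    if not cs:
        return math.nan
    return sum(valence[v] for v in hood) / len(cs)


# ---------------------------------------------------------------------------
# 2x2 association


def phi_formula(a: int, b: int, c: int, d: int) -> float:
    return (a * d - b * c) / math.sqrt((a + b) * (c + d) * (a + c) * (b + d))


def contingency_by_scan(cam_concepts: dict, label_a: str, label_b: str) -> tuple:
    """(a, b, c, d) by scanning per-CAM concept-text sets."""
    a = b = c = d = 0
    for texts in cam_concepts.values():
        ha, hb = label_a in texts, label_b in texts
        if ha and hb:
            a += 1
        elif ha:
            b += 1
        elif hb:
            c += 1
        else:
            d += 1
    return a, b, c, d
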