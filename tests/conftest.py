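"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive exhaustive algorithms (BFS path
enumeration, triangle counting, dense eigendecomposition) so they share
no code path with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from playnet.netbuild import Animal, InteractionEvent, NetworkVariant, PlayNetwork

# ---------------------------------------------------------------------------
# oracles


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive BFS shortest-path enumeration."""
    n = adj.shape[0]
    a = (adj > 0).astype(int)

    def all_shortest_paths(s, t):
        # BFS layering, then DFS back through predecessor structure
        dist = {s: 0}
        frontier = [s]
        preds: dict[int, list[int]] = {s: []}
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if not a[u, v]:
                        continue
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        preds[v] = [u]
                        nxt.append(v)
                    elif dist[v] == dist[u] + 1:
                        preds[v].append(u)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def walk(v, acc):
            if v == s:
                paths.append([s] + acc)
                return
            for u in preds[v]:
                walk(u, [v] + acc)

        walk(t, [])
        return paths

    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    """Local clustering by direct partner-pair enumeration."""
    n = adj.shape[0]
    a = adj > 0
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if a[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for x, y in combinations(nbrs, 2) if a[x, y])
        out[v] = links / (k * (k - 1) / 2)
    return out


def brute_global_clustering(adj: np.ndarray, denominator: str = "transitivity") -> float:
    """Triad closure by exhaustive triple enumeration."""
    n = adj.shape[0]
    a = (adj > 0).astype(int)
    closed = 0
    connected_triples = 0
    total_triples = 0
    for x, y, z in combinations(range(n), 3):
        total_triples += 1
        edges = a[x, y] + a[y, z] + a[x, z]
        if edges == 3:
            closed += 1
            connected_triples += 3  # three centred paths, all closed
        elif edges == 2:
            connected_triples += 1
    if denominator == "transitivity":
        return 3 * closed / connected_triples if connected_triples else 0.0
    return closed / total_triples


def dense_eigen_oracle(adj: np.ndarray) -> np.ndarray:
    """Leading eigenvector via dense (sym)eigendecomposition, max-scaled."""
    adj = np.asarray(adj, dtype=float)
    if np.allclose(adj, adj.T):
        w, v = np.linalg.eigh(adj)
        vec = v[:, np.argmax(w)]
    else:
        w, v = np.linalg.eig(adj)
        vec = np.real(v[:, np.argmax(np.real(w))])
    vec = np.abs(vec)
    return vec / vec.max()


def ranksum_enumeration_p(soc, con) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([soc, con])
    assert len(np.unique(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    n1 = len(soc)
    w_obs = sum(ranks[v] for v in soc)
    mean_w = n1 * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for subset in combinations(pooled, n1):
        w = sum(ranks[v] for v in subset)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def make_network(adj, directed=False, weighted=False, pen_id="pen") -> PlayNetwork:
    adj = np.asarray(adj, dtype=float)
    nodes = [f"n{i}" for i in range(adj.shape[0])]
    return PlayNetwork(pen_id, NetworkVariant(directed, weighted), nodes, adj)


def random_binary_graph(rng, n: int, p: float = 0.4) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_animals() -> list[Animal]:
    """One control pen (c1, 4 animals) and one socialised pen (s1, 6
    animals split over litters LA/LB)."""
    animals = []
    for i in range(4):
        animals.append(
            Animal(f"c{i}", "penC", "LC", "male" if i % 2 else "female", "control", 1)
        )
    for i in range(6):
        litter = "LA" if i < 3 else "LB"
        animals.append(
            Animal(f"s{i}", "penS", litter, "male" if i % 2 else "female", "socialised", 1)
        )
    return animals


@pytest.fixture
def toy_events(toy_animals) -> list[InteractionEvent]:
    ev = [
        # control pen: chain c0-c1-c2 plus non-reciprocated attempt to c3
        InteractionEvent("penC", 1, "c0", "c1", True),
        InteractionEvent("penC", 2, "c1", "c2", True),
        InteractionEvent("penC", 2, "c1", "c0", True),
        InteractionEvent("penC", 3, "c0", "c3", False),
        # socialised pen: within-litter pairs + one cross-litter bout
        InteractionEvent("penS", 1, "s0", "s1", True),
        InteractionEvent("penS", 1, "s0", "s1", True),
        InteractionEvent("penS", 2, "s1", "s2", True),
        InteractionEvent("penS", 3, "s3", "s4", True),
        InteractionEvent("penS", 4, "s4", "s5", True),
        InteractionEvent("penS", 5, "s2", "s3", True),
        InteractionEvent("penS", 6, "s5", "s0", False),
    ]
    return ev
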