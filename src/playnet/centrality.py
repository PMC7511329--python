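"""Individual centrality metrics on per-pen play-fighting networks.

Degree (binary) counts distinct play partners; its weighted analogue
("strength") sums incident bout counts.  In-/out- variants split receipt
from initiation on the directed network.  Eigenvector centrality is the
leading eigenvector of the (weighted or binarised) adjacency, rescaled to
max 1.  Betweenness and the local clustering coefficient are computed on
the undirected binary variant only, matching how they are analysed here.

Degree-type metrics are normalised by the observed pen maximum of the same
quantity (not by n-1), so the most connected animal in a pen scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import NetworkVariant, PlayNetwork

__all__ = [
    "NodeCentrality",
    "degree",
    "eigenvector",
    "betweenness",
    "clustering",
    "centrality_table",
    "power_iteration",
]

POWER_TOL = 1e-10
POWER_MAX_ITER = 10_000


@dataclass
class NodeCentrality:
    """Values of one metric for every animal in a pen."""

    pen_id: str
    metric: str
    variant: NetworkVariant
    normalised: bool
    values: dict  # animal id -> value
    flags: dict = field(default_factory=dict)

    def array(self, nodes=None) -> np.ndarray:
        nodes = nodes if nodes is not None else list(self.values)
        return np.array([self.values[n] for n in nodes], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pen_id": self.pen_id,
                "animal_id": list(self.values),
                "metric": self.metric,
                "variant": self.variant.label(),
                "normalised": self.normalised,
                "value": list(self.values.values()),
            }
        )


class VariantError(ValueError):
    """Metric requested on a network variant it is not defined for."""


def degree(
    net: PlayNetwork,
    direction: str = "all",
    weighted: bool | None = None,
    normalise: bool = True,
) -> NodeCentrality:
    """Degree / strength centrality, optionally split by direction.

    ``direction`` is one of ``all``, ``in`` (bouts/partners received) or
    ``out`` (initiated); in/out require a directed network.  Normalisation
    divides by the pen maximum of the same quantity; an all-zero network
    is returned as-is (all zeros) with a warning.
    """
    if direction not in ("all", "in", "out"):
        raise ValueError(f"direction must be all/in/out, got {direction!r}")
    if direction != "all" and not net.variant.directed:
        raise VariantError(f"{direction}-degree requires a directed network")
    weighted = net.variant.weighted if weighted is None else weighted
    a = net.adjacency if weighted else (net.adjacency > 0).astype(float)
    if direction == "in":
        vals = a.sum(axis=0)
    elif direction == "out":
        vals = a.sum(axis=1)
    elif net.variant.directed:
        # total partners / bouts regardless of who initiated
        und = a + a.T
        if not weighted:
            und = (und > 0).astype(float)
        vals = und.sum(axis=1)
    else:
        vals = a.sum(axis=1)
    flags = {}
    if normalise:
        m = vals.max()
        if m > 0:
            vals = vals / m
        else:
            warnings.warn(f"pen {net.pen_id}: no edges; normalised degree is all zero", stacklevel=2)
            flags["all_zero"] = True
    metric = {"all": "degree", "in": "in_degree", "out": "out_degree"}[direction]
    variant = NetworkVariant(net.variant.directed, weighted)
    return NodeCentrality(net.pen_id, metric, variant, normalise, dict(zip(net.nodes, vals)), flags)


def power_iteration(
    a: np.ndarray, tol: float = POWER_TOL, max_iter: int = POWER_MAX_ITER
) -> np.ndarray:
    """Leading eigenvector of a nonnegative matrix by power iteration.

    Iterates x <- (A + I) x / ||.|| from a uniform start; the identity
    shift makes the iteration aperiodic so bipartite components converge.
    Returns the vector rescaled to max 1.  On a disconnected graph,
    components not attaining the leading eigenvalue decay to (numerical)
    zero, i.e. only the dominant component carries weight.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    shifted = a + np.eye(n)
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("power iteration collapsed: matrix has no edges")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.clip(x, 0, None)
    return x / x.max()


def eigenvector(
    net: PlayNetwork, weighted: bool | None = None, transpose: bool = False
) -> NodeCentrality:
    """Eigenvector centrality, rescaled so the top animal scores 1.

    For directed networks the score is the right leading eigenvector of
    the initiator->recipient adjacency: prestige accrues by *receiving*
    play from well-connected animals.  ``transpose=True`` flips the
    orientation so initiating toward central animals is rewarded instead.

    On pens with isolated piglets (disconnected graphs) the scores of
    components not attaining the leading eigenvalue are 0; the result is
    flagged ``disconnected`` when any animal has no edges at all.
    """
    weighted = net.variant.weighted if weighted is None else weighted
    a = net.adjacency if weighted else (net.adjacency > 0).astype(float)
    if a.sum() == 0:
        raise ValueError(f"pen {net.pen_id}: eigenvector centrality undefined on an empty network")
    if net.variant.directed and transpose:
        a = a.T
    vals = power_iteration(a)
    flags = {}
    deg = (a + a.T).sum(axis=1)
    if np.any(deg == 0):
        flags["disconnected"] = True
    variant = NetworkVariant(net.variant.directed, weighted)
    return NodeCentrality(net.pen_id, "eigenvector", variant, True, dict(zip(net.nodes, vals)), flags)


def _require_undirected_binary(net: PlayNetwork, what: str) -> nx.Graph:
    if net.variant.directed or net.variant.weighted:
        raise VariantError(f"{what} is defined on the undirected binary variant only")
    g = nx.Graph()
    g.add_nodes_from(range(net.n))
    rows, cols = np.nonzero(np.triu(net.adjacency))
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return g


def betweenness(net: PlayNetwork) -> NodeCentrality:
    """Shortest-path betweenness on the undirected binary network.

    For node v: sum over unordered pairs {s,t} (s,t != v) of the fraction
    of shortest s-t paths passing through v; unreachable pairs contribute 0.
    Unnormalised, so scores feed Freeman centralisation directly.
    """
    g = _require_undirected_binary(net, "betweenness")
    bc = nx.betweenness_centrality(g, normalized=False)
    values = {net.nodes[i]: bc[i] for i in range(net.n)}
    return NodeCentrality(net.pen_id, "betweenness", net.variant, False, values)


def clustering(net: PlayNetwork) -> NodeCentrality:
    """Local clustering coefficient: how close an animal's play partners
    are to forming a fully connected clique; 0 for fewer than 2 partners."""
    g = _require_undirected_binary(net, "clustering coefficient")
    cc = nx.clustering(g)
    values = {net.nodes[i]: cc[i] for i in range(net.n)}
    return NodeCentrality(net.pen_id, "clustering_coefficient", net.variant, True, values)


def centrality_table(results: list[NodeCentrality]) -> pd.DataFrame:
    """Long-format per-animal metric table (pen_id, animal_id, metric, variant, value)."""
    if not results:
        return pd.DataFrame(columns=["pen_id", "animal_id", "metric", "variant", "normalised", "value"])
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
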