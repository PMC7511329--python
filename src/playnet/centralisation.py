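"""Pen-level network structure: edge density, Freeman centralisation and
global clustering, plus socialised-vs-control rank-sum comparisons.

Freeman centralisation turns a vector of individual centrality scores into
one pen-level inequality value: the sum of differences between the most
central animal and all others, divided by the theoretical maximum of that
sum for a network of the same size.  The maximum is obtained numerically
by evaluating the same metric on the n-node star graph, the canonical
maximally centralised network; binary centralisations therefore lie in
[0, 1] while weighted ones (scored against the binary star) may exceed 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import NodeCentrality, betweenness, degree, eigenvector
from .netbuild import NetworkVariant, PlayNetwork

__all__ = [
    "edge_density",
    "freeman_centralisation",
    "star_scores",
    "global_clustering",
    "compare_treatments",
    "pen_metrics",
    "treatment_comparison",
]


def edge_density(net: PlayNetwork) -> float:
    """Realised connections (binary) or bouts (weighted) per possible dyad.

    Binary: share of dyads with at least one reciprocated bout, in [0, 1].
    Weighted: mean reciprocated-bout count per possible dyad, which may
    exceed 1 when dyads play repeatedly.
    """
    n = net.n
    if n < 2:
        raise ValueError(f"pen {net.pen_id}: edge density needs at least 2 animals")
    und = net.adjacency + net.adjacency.T if net.variant.directed else net.adjacency
    n_dyads = n * (n - 1) / 2
    if net.variant.weighted:
        # und double-counts each bout (i,j)+(j,i)
        return float(und.sum() / 2 / n_dyads)
    return float(np.count_nonzero(np.triu(und)) / n_dyads)


def _star_adjacency(n: int, orientation: str) -> np.ndarray:
    """Binary star on n nodes, hub at index 0."""
    a = np.zeros((n, n))
    if orientation in ("out", "both"):
        a[0, 1:] = 1.0
    if orientation in ("in", "both"):
        a[1:, 0] = 1.0
    return a


def _evaluate_metric(net: PlayNetwork, metric: str, weighted: bool) -> np.ndarray:
    if metric in ("degree", "in_degree", "out_degree"):
        direction = {"degree": "all", "in_degree": "in", "out_degree": "out"}[metric]
        return degree(net, direction=direction, weighted=weighted, normalise=False).array(net.nodes)
    if metric == "eigenvector":
        return eigenvector(net, weighted=weighted).array(net.nodes)
    if metric == "betweenness":
        return betweenness(net).array(net.nodes)
    raise ValueError(f"no Freeman centralisation defined for metric {metric!r}")


def star_scores(metric: str, n: int, directed: bool) -> np.ndarray:
    """Unnormalised scores of ``metric`` on the n-node binary star that
    maximises its Freeman sum (orientation chosen numerically for
    directed metrics)."""
    if n < 3:
        raise ValueError("Freeman centralisation needs a pen of at least 3 animals")
    orientations = ("in", "out", "both") if directed else ("und",)
    best = None
    for o in orientations:
        if o == "und":
            adj = _star_adjacency(n, "both")
            adj = ((adj + adj.T) > 0).astype(float)
            var = NetworkVariant(directed=False, weighted=False)
        else:
            adj = _star_adjacency(n, o)
            var = NetworkVariant(directed=True, weighted=False)
        star = PlayNetwork("star", var, [f"s{i}" for i in range(n)], adj)
        try:
            vals = _evaluate_metric(star, metric, weighted=False)
        except ValueError:
            continue
        if best is None or (vals.max() - vals).sum() > (best.max() - best).sum():
            best = vals
    if best is None:
        raise ValueError(f"cannot evaluate {metric!r} on a star graph")
    return best


def freeman_centralisation(scores: NodeCentrality, n: int | None = None) -> float:
    """Freeman centralisation of one pen's individual centrality scores.

    ``scores`` must be unnormalised for degree-type metrics (eigenvector
    scores are max-scaled by construction, and the star maximum is
    evaluated on the same scale).  Constant scores give 0 by definition.
    """
    vals = scores.array()
    n = len(vals) if n is None else n
    observed = float((vals.max() - vals).sum())
    if observed == 0:
        return 0.0
    star = star_scores(scores.metric, n, scores.variant.directed)
    denom = float((star.max() - star).sum())
    if denom == 0:
        raise ValueError(f"star maximum for {scores.metric!r} is degenerate")
    return observed / denom


def global_clustering(net: PlayNetwork, denominator: str = "transitivity") -> float | None:
    """Pen-level triad closure on the undirected binary network.

    ``denominator="transitivity"`` (default) scores closed triads against
    connected triples (standard transitivity); ``"all_triples"`` scores
    them against C(n, 3).  Returns None for pens of fewer than 3 animals.
    """
    if net.variant.directed or net.variant.weighted:
        raise ValueError("global clustering is defined on the undirected binary variant")
    n = net.n
    if n < 3:
        return None
    a = net.adjacency
    n_triangles = float(np.trace(a @ a @ a) / 6)
    if denominator == "transitivity":
        deg = a.sum(axis=1)
        open_triples = float((deg * (deg - 1) / 2).sum())  # paths of length 2, incl. closed
        if open_triples == 0:
            return 0.0
        return 3 * n_triangles / open_triples
    if denominator == "all_triples":
        return n_triangles / (n * (n - 1) * (n - 2) / 6)
    raise ValueError(f"unknown denominator {denominator!r}")


def compare_treatments(values: dict, treatments: dict) -> tuple[float, float, float]:
    """Socialised-vs-control Wilcoxon rank-sum test on a pen-level metric.

    Returns ``(W, U, p)`` where W is the rank sum of the socialised group
    (the statistic printed in the study tables) and U the corresponding
    Mann-Whitney statistic.  The p-value is two-sided and exact when there
    are no ties, otherwise a tie-corrected normal approximation.
    """
    soc = np.array([v for p, v in values.items() if treatments[p] == "socialised"], dtype=float)
    con = np.array([v for p, v in values.items() if treatments[p] == "control"], dtype=float)
    if len(soc) == 0 or len(con) == 0:
        raise ValueError("both treatment groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([soc, con]))) < len(soc) + len(con)
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(soc, con, alternative="two-sided", method=method)
    u_soc = float(res.statistic)
    n1 = len(soc)
    w = u_soc + n1 * (n1 + 1) / 2
    return w, u_soc, float(res.pvalue)


# ---------------------------------------------------------------------------
# pen-level tables

PEN_METRICS_BINARY = (
    "edge_density",
    "degree",
    "in_degree",
    "out_degree",
    "eigenvector",
    "betweenness",
    "clustering_coefficient",
)
PEN_METRICS_WEIGHTED = ("edge_density", "degree", "in_degree", "out_degree", "eigenvector")


def pen_metrics(events, animals) -> pd.DataFrame:
    """Per-pen structure table: columns pen_id, metric, variant, value.

    Computes binary and weighted edge density, Freeman centralisation of
    degree / in- / out-degree / eigenvector (binary and weighted) and of
    betweenness (binary only), and the binary global clustering
    coefficient, for every pen.
    """
    from .netbuild import build_all_networks

    rows = []
    for weighted in (False, True):
        metrics = PEN_METRICS_WEIGHTED if weighted else PEN_METRICS_BINARY
        und = build_all_networks(events, animals, NetworkVariant(False, weighted))
        dirn = build_all_networks(events, animals, NetworkVariant(True, weighted))
        for pen_id in und:
            for metric in metrics:
                net = dirn[pen_id] if metric in ("in_degree", "out_degree") else und[pen_id]
                if metric == "edge_density":
                    value = edge_density(net)
                elif metric == "clustering_coefficient":
                    value = global_clustering(net)
                elif net.adjacency.sum() == 0:
                    value = 0.0 if metric != "eigenvector" else None
                else:
                    scores = _node_scores(net, metric, weighted)
                    value = freeman_centralisation(scores, net.n)
                rows.append(
                    {
                        "pen_id": pen_id,
                        "metric": metric,
                        "variant": "weighted" if weighted else "binary",
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def _node_scores(net: PlayNetwork, metric: str, weighted: bool) -> NodeCentrality:
    if metric in ("degree", "in_degree", "out_degree"):
        direction = {"degree": "all", "in_degree": "in", "out_degree": "out"}[metric]
        return degree(net, direction=direction, weighted=weighted, normalise=False)
    if metric == "eigenvector":
        return eigenvector(net, weighted=weighted)
    if metric == "betweenness":
        return betweenness(net)
    raise ValueError(metric)


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def treatment_comparison(pen_table: pd.DataFrame, treatments: dict) -> pd.DataFrame:
    """Socialised/control medians (Tukey quartiles) and rank-sum tests for
    each (metric, variant) in a :func:`pen_metrics` table."""
    rows = []
    for (metric, variant), grp in pen_table.groupby(["metric", "variant"], sort=False):
        grp = grp.dropna(subset=["value"])
        values = dict(zip(grp.pen_id, grp.value))
        soc = np.array([v for p, v in values.items() if treatments[p] == "socialised"])
        con = np.array([v for p, v in values.items() if treatments[p] == "control"])
        w, u, p = compare_treatments(values, treatments)
        rows.append(
            {
                "metric": metric,
                "variant": variant,
                "socialised_median_iqr": _median_iqr(soc),
                "control_median_iqr": _median_iqr(con),
                "socialised_median": float(np.median(soc)),
                "control_median": float(np.median(con)),
                "W": w,
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
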