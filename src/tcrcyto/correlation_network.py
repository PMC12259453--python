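"""Thresholded Pearson correlation networks over preprocessed cytokine panels.

An edge connects two analytes when the pairwise-complete Pearson coefficient
satisfies |r| >= r_min (default 0.6) and the Benjamini-Hochberg adjusted
p-value is < alpha (default 0.05), the double-threshold rule standard for
small-cohort cytokine panels.  Analytes without any significant correlation
stay in the graph as isolated nodes.  "Clusters" are the connected components
of the thresholded graph; an optional greedy-modularity refinement is exposed
for sub-cluster inspection and is clearly heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .categories import ANALYTE_CATEGORIES


def pearson_all_pairs(matrix: pd.DataFrame, min_pairs: int = 4) -> pd.DataFrame:
    """Pearson r and two-sided p for every unordered analyte pair.

    ``matrix`` is samples x analytes, already log2(x+1)-transformed and
    Winsorized; NaN marks not-detected and pairs are computed on
    pairwise-complete samples.  Pairs with fewer than ``min_pairs`` complete
    observations, or with a zero-variance analyte, are skipped and recorded
    in the ``skipped`` attribute of the returned frame.
    """
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    mask = ~np.isnan(X)
    rows = []
    skipped: list[tuple[str, str, str]] = []
    complete = mask.all(axis=0)
    # fast path: all-complete columns in one correlation call
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            both = mask[:, i] & mask[:, j]
            n = int(both.sum())
            if n < min_pairs:
                skipped.append((cols[i], cols[j], "insufficient pairs"))
                continue
            x, y = X[both, i], X[both, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped.append((cols[i], cols[j], "zero variance"))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"analyte_a": cols[i], "analyte_b": cols[j],
                         "r": float(r), "raw_p": float(p), "n": n})
    out = pd.DataFrame(rows, columns=["analyte_a", "analyte_b", "r", "raw_p", "n"])
    out.attrs["skipped"] = skipped
    out.attrs["analytes"] = cols
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order restored."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CytokineNetwork:
    """Annotated correlation graph plus component labels and layout."""

    graph: nx.Graph
    r_min: float
    alpha: float
    clusters: dict[str, int] = field(default_factory=dict)
    layout: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"analyte_a": a, "analyte_b": b, **d}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["analyte_a", "analyte_b", "r", "raw_p",
                                           "adjusted_p", "sign", "n"])

    def degree(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), dtype=int).sort_index()


def build_network(
    pairs: pd.DataFrame,
    r_min: float = 0.6,
    alpha: float = 0.05,
    category_map: Mapping[str, str] | None = None,
    analytes: list[str] | None = None,
) -> CytokineNetwork:
    """Threshold the pair table into an undirected network.

    Edge rule: |r| >= r_min AND BH-adjusted p < alpha, adjustment run across
    all pairs of this one panel.  Node set = every analyte of the source
    matrix (isolates kept, degree 0).  Components are labelled in order of
    decreasing size, ties broken by the smallest member name.
    """
    cmap = ANALYTE_CATEGORIES if category_map is None else category_map
    if analytes is None:
        analytes = pairs.attrs.get("analytes")
    if analytes is None:
        analytes = sorted(set(pairs["analyte_a"]) | set(pairs["analyte_b"]))

    pairs = pairs.copy()
    pairs["adjusted_p"] = bh_adjust(pairs["raw_p"].to_numpy()) if len(pairs) else []

    g = nx.Graph()
    for a in analytes:
        g.add_node(a, category=cmap.get(a, "unknown"))
    for row in pairs.itertuples(index=False):
        if abs(row.r) >= r_min and row.adjusted_p < alpha:
            a, b = sorted((row.analyte_a, row.analyte_b))
            g.add_edge(a, b, r=row.r, raw_p=row.raw_p,
                       adjusted_p=float(row.adjusted_p),
                       sign="+" if row.r > 0 else "-", n=int(row.n))
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    clusters = {node: i for i, comp in enumerate(comps) for node in comp}
    for node, label in clusters.items():
        g.nodes[node]["cluster"] = label
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree(node)
    return CytokineNetwork(g, r_min, alpha, clusters)


def greedy_communities(network: CytokineNetwork) -> dict[str, int]:
    """Heuristic sub-cluster labels via greedy modularity on |r| weights."""
    g = network.graph.copy()
    for a, b, d in g.edges(data=True):
        d["weight"] = abs(d["r"])
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    return {node: i for i, comm in enumerate(comms) for node in comm}


def layout_force_directed(
    network: CytokineNetwork, seed: int, iterations: int = 200
) -> dict[str, tuple[float, float]]:
    """Deterministic Fruchterman-Reingold layout, edge weights = |r|."""
    g = network.graph
    if g.number_of_nodes() == 0:
        network.layout = {}
        return {}
    weights = {(a, b): abs(d["r"]) for a, b, d in g.edges(data=True)}
    nx.set_edge_attributes(g, weights, "weight")
    pos = nx.spring_layout(g, seed=seed, iterations=iterations, weight="weight")
    layout = {node: (float(x), float(y)) for node, (x, y) in pos.items()}
    if not all(np.isfinite(v).all() for v in pos.values()):
        raise RuntimeError("non-finite layout coordinates")
    network.layout = layout
    return layout


def network_summary(network: CytokineNetwork) -> dict:
    """Headline tallies: signed edge counts, hubs, strongest edges, category mix."""
    edges = network.edges
    n_pos = int((edges["sign"] == "+").sum()) if len(edges) else 0
    n_neg = int((edges["sign"] == "-").sum()) if len(edges) else 0
    deg = network.degree()
    top = deg.sort_values(ascending=False, kind="stable")
    top_nodes = [
        {"analyte": a, "degree": int(d)} for a, d in top.head(5).items() if d > 0
    ]

    def _extreme(sub: pd.DataFrame, best: str) -> dict | None:
        if not len(sub):
            return None
        row = sub.loc[sub["r"].abs().idxmax()] if best == "abs" else None
        return {"analyte_a": row["analyte_a"], "analyte_b": row["analyte_b"],
                "r": float(row["r"])}

    strongest_pos = _extreme(edges[edges["sign"] == "+"], "abs") if n_pos else None
    strongest_neg = _extreme(edges[edges["sign"] == "-"], "abs") if n_neg else None
    by_category: dict[str, int] = {}
    for node, data in network.graph.nodes(data=True):
        if data.get("degree", 0) > 0:
            cat = data.get("category", "unknown")
            by_category[cat] = by_category.get(cat, 0) + 1
    return {
        "n_nodes": network.graph.number_of_nodes(),
        "n_edges": network.graph.number_of_edges(),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "n_components": len(set(network.clusters.values())),
        "n_isolated": int((deg == 0).sum()),
        "top_degree": top_nodes,
        "strongest_positive": strongest_pos,
        "strongest_negative": strongest_neg,
        "connected_nodes_by_category": by_category,
    }
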