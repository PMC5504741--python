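"""Gene-mass correlation networks: thresholded graphs, communities, cliques.

Edges are Pearson correlations over the paired samples, with the t-transform
p-value and BH adjustment per edge class (gene-mass, gene-gene, mass-mass,
cross-targeted).  The global network admits nodes through strong gene-mass
edges; communities are found by seeded asynchronous label propagation and
dense co-regulation modules by maximal-clique enumeration, both on the
positive-edge subgraph (negative edges are annotation only).
"""

from __future__ import annotations

import itertools
import logging
import random
from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import OmicsMatrix, Thresholds
from .stats import adjust_fdr

logger = logging.getLogger(__name__)

EDGE_CLASSES = ("gene-mass", "gene-gene", "mass-mass", "cross-targeted")


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows of a and rows of b."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac ** 2).sum(axis=1))
    nb = np.sqrt((bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac @ bc.T) / np.outer(na, nb)
    return np.clip(r, -1.0, 1.0)


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


def pairwise_correlations(
    x: OmicsMatrix,
    y: OmicsMatrix | None = None,
    classes: tuple[str, ...] = ("gene-mass",),
) -> pd.DataFrame:
    """Edge-candidate table of Pearson correlations with adjusted p.

    ``x`` is the gene layer and ``y`` the mass layer for ``gene-mass``
    edges; ``gene-gene`` pairs come from x alone and ``mass-mass`` from y.
    Samples must be paired and n >= 4.  Constant variables are excluded
    with a log entry.  BH families are per edge class.
    """
    if y is not None and x.sample_ids != y.sample_ids:
        raise ValueError("matrices are not sample-paired")
    n = x.n_samples
    if n < 4:
        raise ValueError("need at least 4 paired samples")

    def drop_constant(m: OmicsMatrix) -> OmicsMatrix:
        sd = m.values.std(axis=1)
        if np.any(sd == 0):
            kept = [v for v, s in zip(m.variable_ids, sd) if s > 0]
            logger.info(
                "pairwise_correlations: excluded %d constant variable(s)",
                m.n_variables - len(kept),
            )
            return m.subset_variables(kept)
        return m

    x = drop_constant(x)
    y = drop_constant(y) if y is not None else None

    frames = []
    for cls in classes:
        if cls == "gene-mass" or cls == "cross-targeted":
            if y is None:
                raise ValueError(f"{cls} edges need two matrices")
            r = _corr_matrix(x.values, y.values)
            src = x.variable_ids
            dst = y.variable_ids
            ii, jj = np.meshgrid(range(len(src)), range(len(dst)), indexing="ij")
            ii, jj = ii.ravel(), jj.ravel()
        elif cls in ("gene-gene", "mass-mass"):
            m = x if cls == "gene-gene" else y
            if m is None:
                raise ValueError(f"{cls} edges need the corresponding matrix")
            r = _corr_matrix(m.values, m.values)
            src = dst = m.variable_ids
            iu = np.triu_indices(len(src), k=1)
            ii, jj = iu
        else:
            raise ValueError(f"unknown edge class {cls!r}")
        rv = r[ii, jj]
        p = _r_to_p(rv, n)
        frames.append(pd.DataFrame({
            "source": [src[i] for i in ii],
            "target": [dst[j] for j in jj],
            "edge_class": cls,
            "r": rv,
            "p_value": p,
            "p_adjusted": adjust_fdr(p),
        }))
    return pd.concat(frames, ignore_index=True)


def build_network(
    candidates: pd.DataFrame,
    th: Thresholds = Thresholds(),
    require_p_all_classes: bool = True,
) -> nx.Graph:
    """Assemble the global correlation network from an edge-candidate table.

    Node admission follows the gene-mass rule: the node set consists of the
    endpoints of gene-mass edges with r > ``edge_r`` (and, by default,
    adjusted p < ``edge_alpha``); gene-gene and mass-mass edges among those
    nodes are then added when they pass both thresholds.  Negative
    correlations never qualify here; they belong to submodule views.
    """
    gm = candidates[candidates["edge_class"] == "gene-mass"]
    pass_gm = gm["r"] > th.edge_r
    if require_p_all_classes:
        pass_gm &= gm["p_adjusted"] < th.edge_alpha
    gm = gm[pass_gm]

    g = nx.Graph()
    for _, row in gm.iterrows():
        g.add_node(row["source"], node_type="gene")
        g.add_node(row["target"], node_type="mass")
        g.add_edge(
            row["source"], row["target"],
            r=float(row["r"]), p_adjusted=float(row["p_adjusted"]),
            edge_class="gene-mass", sign=1,
        )
    members = set(g.nodes)
    within = candidates[candidates["edge_class"].isin(["gene-gene", "mass-mass"])]
    within = within[
        (within["r"] > th.edge_r) & (within["p_adjusted"] < th.edge_alpha)
    ]
    for _, row in within.iterrows():
        if row["source"] in members and row["target"] in members:
            g.add_edge(
                row["source"], row["target"],
                r=float(row["r"]), p_adjusted=float(row["p_adjusted"]),
                edge_class=row["edge_class"], sign=1,
            )
    if g.number_of_nodes() == 0:
        logger.warning("build_network: no edge passed the thresholds")
    return g


def submodule_view(
    candidates: pd.DataFrame,
    variables: list[str],
    pos_r: float = 0.75,
    neg_r: float = 0.75,
) -> nx.Graph:
    """Graph over an explicit variable list with signed edge annotation.

    Positive edges at r > ``pos_r`` (solid in the figures), negative edges
    at r < -``neg_r`` (dashed).
    """
    known = set(candidates["source"]) | set(candidates["target"])
    unknown = [v for v in variables if v not in known]
    if unknown:
        raise ValueError(f"unknown variable id(s): {unknown[:5]}")
    wanted = set(variables)
    g = nx.Graph()
    g.add_nodes_from(variables)
    sub = candidates[
        candidates["source"].isin(wanted) & candidates["target"].isin(wanted)
    ]
    for _, row in sub.iterrows():
        if row["source"] == row["target"]:
            continue
        r = float(row["r"])
        if r > pos_r:
            sign = 1
        elif r < -neg_r:
            sign = -1
        else:
            continue
        g.add_edge(
            row["source"], row["target"],
            r=r, sign=sign, edge_class=row["edge_class"],
            p_adjusted=float(row["p_adjusted"]),
        )
    return g


def positive_subgraph(graph: nx.Graph) -> nx.Graph:
    """Subgraph of positively signed edges (propagation/clique substrate)."""
    keep = [
        (u, v) for u, v, d in graph.edges(data=True) if d.get("sign", 1) > 0
    ]
    sub = nx.Graph()
    sub.add_nodes_from(graph.nodes(data=True))
    sub.add_edges_from(
        (u, v, graph.edges[u, v]) for u, v in keep
    )
    return sub


def label_propagation(
    graph: nx.Graph, seed: int, max_sweeps: int = 100
) -> dict:
    """Asynchronous label propagation communities on the positive subgraph.

    Every node starts with its own label; nodes are visited in a seeded
    random order and adopt the majority label among their neighbors, ties
    broken uniformly at random (seeded).  Sweeps repeat until every node's
    label is a weak neighborhood majority.  Returns a dict with ``labels``
    (node -> community id), ``seed`` and ``sweeps``.
    """
    g = positive_subgraph(graph)
    rng = random.Random(seed)
    labels = {node: i for i, node in enumerate(g.nodes)}
    nodes = list(g.nodes)
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        rng.shuffle(nodes)
        changed = False
        for node in nodes:
            neigh = list(g.neighbors(node))
            if not neigh:
                continue
            counts = Counter(labels[v] for v in neigh)
            top = max(counts.values())
            best = sorted(lab for lab, c in counts.items() if c == top)
            if labels[node] in best:
                continue
            labels[node] = rng.choice(best)
            changed = True
        if not changed:
            break
    # canonical community ids: 0..k-1 in order of first appearance
    remap: dict[int, int] = {}
    out = {}
    for node in graph.nodes:
        lab = labels.get(node, -1)
        if lab not in remap:
            remap[lab] = len(remap)
        out[node] = remap[lab]
    return {"labels": out, "seed": seed, "sweeps": sweeps}


def consensus_label_propagation(
    graph: nx.Graph, seeds: list[int]
) -> dict:
    """Majority-vote consensus over several label-propagation runs.

    Two nodes end up in the same consensus community when they co-occur in
    the same community in a strict majority of the runs (computed via a
    co-classification graph's connected components).
    """
    runs = [label_propagation(graph, s)["labels"] for s in seeds]
    nodes = list(graph.nodes)
    co = nx.Graph()
    co.add_nodes_from(nodes)
    half = len(runs) / 2.0
    for u, v in itertools.combinations(nodes, 2):
        agree = sum(1 for lab in runs if lab[u] == lab[v])
        if agree > half:
            co.add_edge(u, v)
    labels = {}
    for i, comp in enumerate(nx.connected_components(co)):
        for node in comp:
            labels[node] = i
    return {"labels": labels, "seeds": list(seeds), "n_runs": len(runs)}


def maximal_cliques(
    graph: nx.Graph, min_size: int = 2, require_mass: bool = False
) -> list[tuple[str, ...]]:
    """All maximal cliques of the positive subgraph, canonically ordered.

    Enumeration is Bron-Kerbosch with pivoting; output sorted by size
    (descending) then lexicographically.  ``require_mass`` keeps only
    cliques containing at least one mass-typed node.
    """
    g = positive_subgraph(graph)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= min_size]
    if require_mass:
        cliques = [
            c for c in cliques
            if any(g.nodes[v].get("node_type") == "mass" for v in c)
        ]
    return sorted(cliques, key=lambda c: (-len(c), c))


def top_genes_per_mass(candidates: pd.DataFrame, k: int = 3) -> list[str]:
    """Per mass, the k most-correlated genes; returns the gene union.

    Ties at the cutoff are broken by gene id for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    gm = candidates[candidates["edge_class"] == "gene-mass"]
    kept: set[str] = set()
    for _, sub in gm.groupby("target"):
        ranked = sub.sort_values(
            ["r", "source"], ascending=[False, True]
        )["source"].tolist()
        kept.update(ranked[:k])
    return sorted(kept)


def cross_targeted_edges(
    genes: OmicsMatrix,
    targeted: OmicsMatrix,
    r_thresh: float = 0.85,
    min_gene_connections: int = 0,
) -> pd.DataFrame:
    """Edges between clique genes and targeted metabolites at r > threshold.

    ``min_gene_connections`` filters metabolites with too few qualifying
    gene partners out of the view (0 disables).
    """
    gx, ty = (genes, targeted)
    shared = [s for s in gx.sample_ids if s in set(ty.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between gene and targeted matrices")
    gx = gx.subset_samples(shared)
    ty = ty.subset_samples(shared)
    cand = pairwise_correlations(gx, ty, classes=("cross-targeted",))
    edges = cand[cand["r"] > r_thresh].copy()
    if min_gene_connections > 0:
        counts = edges.groupby("target")["source"].nunique()
        keep = set(counts[counts >= min_gene_connections].index)
        edges = edges[edges["target"].isin(keep)]
    return edges.reset_index(drop=True)


def write_graphml(graph: nx.Graph, path, communities: dict | None = None) -> None:
    """Serialize the network as GraphML, with optional community labels."""
    g = graph.copy()
    if communities is not None:
        nx.set_node_attributes(g, communities["labels"], "community")
    nx.write_graphml(g, path)
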