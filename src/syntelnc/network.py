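"""Thresholded Pearson co-expression graph and Markov clustering.

Edges connect gene pairs whose Pearson r over per-sample TPM reaches the
threshold (default 0.95, signed: anti-correlations are discarded). The graph
is partitioned by Markov clustering (MCL): the weighted adjacency matrix plus
unit self-loops is made column-stochastic, then expansion (matrix power) and
inflation (elementwise power with renormalisation) alternate until the matrix
stops changing; clusters are read off the attractor rows. Inflation (default
2.2) controls granularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def build_graph(
    tpm: pd.DataFrame,
    nodes: Optional[Sequence[str]] = None,
    threshold: float = 0.95,
    log2p1: bool = False,
) -> nx.Graph:
    """Pearson correlation graph over genes (rows) x samples (columns).

    Genes with zero variance are excluded (their correlation is undefined);
    the count is logged. ``nodes`` restricts the gene set, e.g. to
    reproducibly expressed lncRNAs plus protein-coding genes.
    """
    if tpm.shape[1] < 3:
        raise ValueError("need >= 3 samples for a correlation graph")
    sub = tpm.loc[sorted(nodes)] if nodes is not None else tpm.sort_index()
    x = sub.to_numpy(dtype=float)
    if log2p1:
        x = np.log2(x + 1.0)
    sd = x.std(axis=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d zero-variance genes", n_dropped)
    genes = list(sub.index[keep])
    x = x[keep]
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    if len(genes) >= 2:
        r = np.corrcoef(x)
        iu, ju = np.triu_indices(len(genes), k=1)
        mask = r[iu, ju] >= threshold
        for i, j, w in zip(iu[mask], ju[mask], r[iu[mask], ju[mask]]):
            graph.add_edge(genes[i], genes[j], r=float(w))
    graph.graph["threshold"] = threshold
    return graph


@dataclass
class ClusterAssignment:
    clusters: Dict[str, int]  # gene -> cluster id (0-based, by size then name)
    inflation: float
    converged: bool
    n_iterations: int

    @property
    def sizes(self) -> Dict[int, int]:
        out: Dict[int, int] = {}
        for c in self.clusters.values():
            out[c] = out.get(c, 0) + 1
        return out

    def members(self, cluster_id: int) -> List[str]:
        return sorted(g for g, c in self.clusters.items() if c == cluster_id)


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.2,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Markov clustering of a weighted undirected graph.

    Nodes are processed in sorted order so the result is independent of
    insertion order. Non-convergence within ``max_iter`` returns the current
    clustering with ``converged=False``.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("r", data.get("weight", 1.0)))
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    np.fill_diagonal(m, 1.0)  # unit self-loops, standard MCL practice
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge within %d iterations", max_iter)

    # attractors: rows with nonzero diagonal; each attractor's support is one
    # cluster; overlapping supports merge
    attractors = [i for i in range(n) if m[i, i] > 0]
    supports = [set(np.flatnonzero(m[a] > 0)) | {a} for a in attractors]
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(supports)))
    for i in range(len(supports)):
        for j in range(i + 1, len(supports)):
            if supports[i] & supports[j]:
                overlap.add_edge(i, j)
    clusters: List[Set[int]] = [
        set().union(*(supports[i] for i in comp))
        for comp in nx.connected_components(overlap)
    ]
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})

    clusters.sort(key=lambda c: (-len(c), min(nodes[i] for i in c)))
    mapping: Dict[str, int] = {}
    for cid, members in enumerate(clusters):
        for i in members:
            if nodes[i] in mapping:  # a node attracted by two clusters
                continue
            mapping[nodes[i]] = cid
    return ClusterAssignment(mapping, inflation, converged, it)


def cluster_composition(
    assignment: ClusterAssignment,
    biotype_of: Mapping[str, str],
    pem: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-cluster size and lncRNA / protein-coding membership counts.

    ``pem``, if given (genes x tissues), adds the top tissue by mean PEM of
    cluster members.
    """
    rows = []
    for cid in sorted(set(assignment.clusters.values())):
        members = assignment.members(cid)
        n_lnc = sum(1 for g in members if biotype_of.get(g) == "lncRNA")
        n_cod = sum(1 for g in members if biotype_of.get(g) == "protein_coding")
        top_tissue = ""
        if pem is not None:
            present = [g for g in members if g in pem.index]
            if present:
                means = pem.loc[present].mean(axis=0)
                top_tissue = str(means.idxmax())
        rows.append(
            dict(
                cluster=cid,
                size=len(members),
                n_lncRNA=n_lnc,
                n_protein_coding=n_cod,
                top_tissue=top_tissue,
            )
        )
    return pd.DataFrame(rows)
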