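"""Biobank cocitation network, community structure, and category alignment.

Two biobanks are cocited when a third article cites at least one
mentioning publication of each; each such article adds one unit of edge
weight to every biobank pair it co-cites.  Communities are found by
seeded modularity optimization (Leiden), and their alignment with an
external disease-category labelling is scored with normalized mutual
information.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np

from .corpus import Corpus
from .disease import principal_category


def build_cocitation(c: Corpus, min_weight: int = 2) -> nx.Graph:
    """Weighted undirected cocitation graph over biobanks.

    For each citing article, the set of distinct biobanks whose mentioning
    publications it cites contributes +1 to every pair in that set; edges
    with weight below ``min_weight`` are dropped.  Nodes carry
    ``mention_count`` (distinct mentioning publications) and
    ``principal_category`` attributes.  Isolated biobanks remain as
    degree-0 nodes.
    """
    # document -> set of biobanks mentioning it (publications only)
    docs = c.doc_index
    banks_of_doc: dict[str, set[str]] = {}
    for m in c.mentions:
        d = docs.get(m.document_id)
        if d is not None and d.doc_type == "publication":
            banks_of_doc.setdefault(m.document_id, set()).add(m.biobank_id)

    cocited: dict[str, set[str]] = {}
    for e in c.citations:
        for b in banks_of_doc.get(e.cited_id, ()):
            cocited.setdefault(e.citing_id, set()).add(b)

    weights: dict[tuple[str, str], int] = {}
    for banks in cocited.values():
        for a, b in combinations(sorted(banks), 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1

    g = nx.Graph()
    for bank in c.biobanks:
        g.add_node(
            bank.id,
            mention_count=len(c.mentioning_documents(bank.id, ("publication",))),
            principal_category=principal_category(c, bank.id),
        )
    for (a, b), w in weights.items():
        if w >= min_weight:
            g.add_edge(a, b, weight=w)
    return g


@dataclass
class Partition:
    labels: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))


def detect_communities(g: nx.Graph, seed: int = 0) -> Partition:
    """Modularity-maximizing partition (Leiden), deterministic under seed.

    An edgeless graph partitions into singletons with modularity 0.
    """
    nodes = list(g.nodes())
    if g.number_of_edges() == 0:
        return Partition({n: i for i, n in enumerate(nodes)}, 0.0)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    w = [float(g.edges[u, v].get("weight", 1.0)) for u, v in g.edges()]
    h = ig.Graph(n=len(nodes), edges=edges)
    part = leidenalg.find_partition(
        h, leidenalg.ModularityVertexPartition, weights=w, seed=int(seed)
    )
    labels = {n: int(part.membership[index[n]]) for n in nodes}
    modularity = float(h.modularity(part.membership, weights=w))
    return Partition(labels, modularity)


def partition_nmi(
    p: Partition | dict, labels: dict, average: str = "geometric"
) -> float:
    """Normalized mutual information between a partition and a labelling.

    NMI = I(X;Y) / sqrt(H(X) * H(Y)) by default ("geometric"); an
    "arithmetic" mean normalization is also available.  By convention a
    simultaneously trivial pair (one community and one category) scores
    1.0 — the partitions are identical — while a single-cluster side
    against a non-trivial one scores 0.0 (no information).
    """
    part_labels = p.labels if isinstance(p, Partition) else p
    nodes = sorted(part_labels)
    missing = [n for n in nodes if n not in labels]
    if missing:
        raise ValueError(f"labels missing for nodes: {missing[:5]}")
    x = [part_labels[n] for n in nodes]
    y = [labels[n] for n in nodes]

    xs, ys = sorted(set(x)), sorted(set(y))
    cont = np.zeros((len(xs), len(ys)))
    xi = {v: i for i, v in enumerate(xs)}
    yi = {v: i for i, v in enumerate(ys)}
    for a, b in zip(x, y):
        cont[xi[a], yi[b]] += 1
    n = cont.sum()
    px = cont.sum(axis=1) / n
    py = cont.sum(axis=0) / n

    def entropy(p_vec):
        p_vec = p_vec[p_vec > 0]
        return float(-(p_vec * np.log(p_vec)).sum())

    hx, hy = entropy(px), entropy(py)
    if hx == 0.0 and hy == 0.0:
        return 1.0
    if hx == 0.0 or hy == 0.0:
        return 0.0
    pxy = cont / n
    mask = pxy > 0
    mi = float((pxy[mask] * np.log(pxy[mask] / np.outer(px, py)[mask])).sum())
    if average == "geometric":
        denom = float(np.sqrt(hx * hy))
    elif average == "arithmetic":
        denom = 0.5 * (hx + hy)
    else:
        raise ValueError(f"unknown average {average!r}")
    return min(1.0, max(0.0, mi / denom))


def write_graph(g: nx.Graph, path: str | Path) -> None:
    """Export as GraphML (.graphml) or a weighted edge list (anything else)."""
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(g, path)
    else:
        with path.open("w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data.get('weight', 1)}\n")
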