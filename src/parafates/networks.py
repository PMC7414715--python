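"""Family-level integration of quartet scores through two networks.

Duplication network: complete graph over species (one paralog pair each),
edges weighted by the duplication score D (support for a shared duplication).
Weighted cluster editing with the signed similarity s(i,j) = D(i,j) - theta
partitions species into blocks that share one ancestral duplication: pairs
with D above theta attract, pairs below repel, and the partition minimizes
the total violated similarity.

Fate network: graph over genes; each quartet with a resolved fate pairing
contributes two edges linking the fate-matched genes across species, weighted
by the fate similarity F (repeated observations of a gene pair are averaged).
Markov clustering (MCL) on this network yields the fates. Transitivity is the
point: genes from one duplication block co-cluster through their mutual
R/S signal, and blocks that underwent recurrent sequence evolution join the
same fate cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

DEFAULT_THETA = 0.6
DEFAULT_INFLATION = 10.0
DEFAULT_EXPANSION = 5


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class DuplicationClustering:
    """Partition of species into inferred ancestral-duplication blocks."""

    blocks: tuple[frozenset, ...]
    cost: float

    def block_of(self, species: str) -> int:
        for i, b in enumerate(self.blocks):
            if species in b:
                return i
        raise KeyError(species)

    def same_block(self, sp1: str, sp2: str) -> bool:
        return self.block_of(sp1) == self.block_of(sp2)


@dataclass(frozen=True)
class FateClustering:
    """Partition of genes into fates."""

    clusters: tuple[frozenset, ...]

    @property
    def labels(self) -> dict[str, int]:
        return {g: i for i, c in enumerate(self.clusters) for g in c}

    def fate_of(self, gene: str) -> int | None:
        return self.labels.get(gene)


def build_duplication_network(
    quartet_rows: list[dict], theta: float = DEFAULT_THETA
) -> nx.Graph:
    """Complete species graph weighted by D; degenerate quartets get weight theta.

    ``quartet_rows`` are per-quartet dicts with at least species_x, species_y
    and D (D may be None for degenerate quartets).
    """
    g = nx.Graph()
    species = set()
    for row in quartet_rows:
        species.update((row["species_x"], row["species_y"]))
    if len(species) < 2:
        raise NetworkError("duplication network needs at least two species")
    g.add_nodes_from(sorted(species))
    for row in quartet_rows:
        d = row.get("D")
        g.add_edge(
            row["species_x"], row["species_y"], weight=theta if d is None else float(d)
        )
    # missing species pairs (no quartet at all) are treated like degenerate ones
    for u, v in combinations(sorted(species), 2):
        if not g.has_edge(u, v):
            g.add_edge(u, v, weight=theta)
    return g


def _editing_cost(sim: np.ndarray, labels: np.ndarray) -> float:
    """Cluster-editing cost: violated attraction across blocks + repulsion within."""
    same = labels[:, None] == labels[None, :]
    cost = np.where(same, np.minimum(sim, 0.0) * -1.0, np.maximum(sim, 0.0))
    iu = np.triu_indices_from(cost, k=1)
    return float(cost[iu].sum())


def _partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, maxl):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxl + 1):
            labels[i] = lab
            yield from rec(i + 1, max(maxl, lab + 1))

    yield from rec(1, 1) if n > 1 else iter([labels.copy()])


def cluster_editing(
    net: nx.Graph, theta: float = DEFAULT_THETA, exact_max_n: int = 10
) -> DuplicationClustering:
    """Weighted cluster editing with signed similarity s = D - theta.

    Exact exhaustive search over set partitions for small graphs; otherwise a
    deterministic greedy pivot construction followed by single-node local
    moves until no move lowers the cost. Nodes are processed lexicographically.
    """
    nodes = sorted(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    sim = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        s = float(data.get("weight", theta)) - theta
        sim[idx[u], idx[v]] = sim[idx[v], idx[u]] = s

    if n <= exact_max_n:
        best_labels, best_cost = None, np.inf
        for labels in _partitions(n):
            c = _editing_cost(sim, labels)
            if c < best_cost - 1e-12:
                best_labels, best_cost = labels, c
        labels = best_labels
    else:
        # deterministic multi-start: two pivot orders + agglomerative merging,
        # each refined by relocate/merge/swap local search
        orders = [
            list(range(n)),
            list(np.argsort(-np.maximum(sim, 0.0).sum(axis=1), kind="stable")),
        ]
        starts = [_greedy_pivot(sim, order) for order in orders]
        starts.append(_agglomerative(sim))
        solutions = [_local_moves(sim, s) for s in starts]
        labels = min(solutions, key=lambda lab: _editing_cost(sim, lab))
        best_cost = _editing_cost(sim, labels)

    blocks: dict[int, set] = {}
    for v, lab in zip(nodes, labels):
        blocks.setdefault(int(lab), set()).add(v)
    ordered = tuple(
        frozenset(b) for b in sorted(blocks.values(), key=lambda b: min(b))
    )
    return DuplicationClustering(ordered, float(best_cost))


def _greedy_pivot(sim: np.ndarray, order=None) -> np.ndarray:
    n = sim.shape[0]
    order = list(range(n)) if order is None else order
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for pivot in order:
        if labels[pivot] >= 0:
            continue
        labels[pivot] = cluster
        for j in order:
            if labels[j] < 0 and sim[pivot, j] > 0:
                labels[j] = cluster
        cluster += 1
    return labels


def _agglomerative(sim: np.ndarray) -> np.ndarray:
    """Greedy merging of the cluster pair with the largest positive attraction."""
    labels = np.arange(sim.shape[0])
    while True:
        best, best_gain = None, 1e-12
        uniq = sorted(set(labels.tolist()))
        for ai, la in enumerate(uniq):
            for lb in uniq[ai + 1:]:
                gain = sim[np.ix_(labels == la, labels == lb)].sum()
                if gain > best_gain:
                    best_gain, best = gain, (la, lb)
        if best is None:
            return labels
        labels = np.where(labels == best[1], best[0], labels)


def _local_moves(sim: np.ndarray, labels: np.ndarray, max_rounds: int = 100) -> np.ndarray:
    """Single-node relocation + block-merge moves to a local optimum."""
    labels = labels.copy()
    n = sim.shape[0]
    for _ in range(max_rounds):
        improved = False
        cost = _editing_cost(sim, labels)
        for i in range(n):
            current = labels[i]
            candidates = set(labels.tolist()) | {labels.max() + 1}
            for lab in sorted(candidates):
                if lab == current:
                    continue
                labels[i] = lab
                c = _editing_cost(sim, labels)
                if c < cost - 1e-12:
                    cost = c
                    current = lab
                    improved = True
                else:
                    labels[i] = current
        for la in sorted(set(labels.tolist())):
            for lb in sorted(set(labels.tolist())):
                if lb <= la:
                    continue
                trial = np.where(labels == lb, la, labels)
                c = _editing_cost(sim, trial)
                if c < cost - 1e-12:
                    labels = trial
                    cost = c
                    improved = True
        for i in range(n):
            for j in range(i + 1, n):
                if labels[i] == labels[j]:
                    continue
                trial = labels.copy()
                trial[i], trial[j] = labels[j], labels[i]
                c = _editing_cost(sim, trial)
                if c < cost - 1e-12:
                    labels = trial
                    cost = c
                    improved = True
        if not improved:
            break
    return labels


def build_fate_network(quartet_rows: list[dict]) -> nx.Graph:
    """Gene graph with two fate edges per resolved quartet, weighted by F.

    Under the R-pairing the edges are (a,c) and (b,d); under S, (a,d) and
    (b,c). Tied quartets contribute nothing. Parallel observations of the
    same gene pair are averaged.
    """
    sums: dict[tuple[str, str], list[float]] = {}
    genes: set[str] = set()
    for row in quartet_rows:
        genes.update((row["gene_a"], row["gene_b"], row["gene_c"], row["gene_d"]))
        pairing = row.get("pairing")
        if pairing not in ("R", "S"):
            continue
        a, b, c, d = row["gene_a"], row["gene_b"], row["gene_c"], row["gene_d"]
        edges = [(a, c), (b, d)] if pairing == "R" else [(a, d), (b, c)]
        for u, v in edges:
            key = (u, v) if u <= v else (v, u)
            sums.setdefault(key, []).append(float(row["F"]))
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for (u, v), vals in sums.items():
        g.add_edge(u, v, weight=sum(vals) / len(vals))
    return g


def markov_clustering(
    net: nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = DEFAULT_EXPANSION,
    prune: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> FateClustering:
    """Markov clustering of the fate network.

    Builds a column-stochastic matrix from edge weights with a self-loop per
    node (weight = max incident edge weight, at least 1e-6), then alternates
    expansion (matrix power) and inflation (entrywise power + column
    renormalization) with pruning of tiny entries until the matrix is stable.
    Clusters are read off the attractors of the limit matrix; a node attracted
    to several systems goes to the strongest (ties break lexicographically).
    Nodes with no edges end up as singletons.
    """
    if net.number_of_nodes() == 0:
        raise NetworkError("empty fate network")
    nodes = sorted(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in net.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = w
    incident_max = m.max(axis=0)
    np.fill_diagonal(m, np.maximum(incident_max, 1e-6))
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded ** inflation
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        inflated /= colsum
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        import warnings

        warnings.warn("MCL did not converge; interpreting current matrix", stacklevel=2)

    # attractors: nodes with mass on their own row
    attractors = [i for i in range(n) if m[i, i] > prune]
    if not attractors:
        attractors = [int(np.argmax(np.diag(m)))]
    # attractor systems: connected components of the attractor-attractor subgraph
    asys = nx.Graph()
    asys.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > prune or m[j, i] > prune):
                asys.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(asys)]
    systems.sort(key=lambda s: s[0])

    assignment: dict[int, int] = {}
    for j in range(n):
        strengths = [sum(m[i, j] for i in sys_) for sys_ in systems]
        best = max(strengths)
        if best <= prune and j not in [i for s in systems for i in s]:
            continue  # unattracted; handled below as singleton
        assignment[j] = int(np.argmax(strengths))
    clusters: dict[int, set] = {}
    for j, s in assignment.items():
        clusters.setdefault(s, set()).add(nodes[j])
    result = [frozenset(c) for c in clusters.values()]
    clustered = set().union(*result) if result else set()
    for v in nodes:
        if v not in clustered:
            result.append(frozenset({v}))
    result.sort(key=min)
    return FateClustering(tuple(result))
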