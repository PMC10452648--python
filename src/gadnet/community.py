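"""Community detection on the weighted symptom network.

Two complementary algorithms, both via igraph: spinglass (simulated
annealing of a Potts-model Hamiltonian with a configuration null model)
and walktrap (random-walk distance agglomeration cut at maximum
modularity).  Both require non-negative weights and a connected graph —
the estimated anxiety networks here are all-positive, so a signed variant
is out of scope.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .network import SymptomNetwork


@dataclass
class Partition:
    membership: dict[str, int]
    n_communities: int
    modularity: float
    algorithm: str
    seed: int | None = None

    def groups(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_communities)]
        for node, c in self.membership.items():
            out[c].add(node)
        return out

    def to_dict(self) -> dict:
        return {
            "membership": self.membership,
            "n_communities": self.n_communities,
            "modularity": self.modularity,
            "algorithm": self.algorithm,
            "seed": self.seed,
        }


def _to_igraph(net: SymptomNetwork) -> tuple[ig.Graph, list[float]]:
    w = net.weights
    if np.any(w < 0):
        raise ValueError(
            "negative edge weights present; these algorithms need a non-negative network "
            "(signed variants are out of scope)"
        )
    edges = []
    weights = []
    p = net.p
    for i in range(p):
        for j in range(i + 1, p):
            if w[i, j] > 0:
                edges.append((i, j))
                weights.append(float(w[i, j]))
    g = ig.Graph(n=p, edges=edges)
    g.vs["name"] = list(net.labels)
    if not g.is_connected():
        raise ValueError("network is disconnected; community detection needs a connected graph")
    return g, weights


def _canonical(labels: list[str], membership: list[int]) -> dict[str, int]:
    remap: dict[int, int] = {}
    out = {}
    for lab, c in zip(labels, membership):
        if c not in remap:
            remap[c] = len(remap)
        out[lab] = remap[c]
    return out


def spinglass_partition(
    net: SymptomNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
) -> Partition:
    """Best-of-``restarts`` spinglass partition (max weighted modularity).

    The annealer is stochastic; restarting and keeping the highest-
    modularity solution makes the small-p result effectively deterministic
    for a given seed.
    """
    g, weights = _to_igraph(net)
    random.seed(seed)
    best = None
    best_q = -np.inf
    for _ in range(max(1, restarts)):
        cl = g.community_spinglass(weights=weights, spins=net.p, gamma=resolution)
        q = g.modularity(cl.membership, weights=weights)
        if q > best_q:
            best_q = q
            best = list(cl.membership)
    membership = _canonical(net.labels, best)
    return Partition(
        membership=membership,
        n_communities=len(set(best)),
        modularity=float(best_q),
        algorithm="spinglass",
        seed=seed,
    )


def walktrap_partition(net: SymptomNetwork, steps: int = 4) -> Partition:
    """Walktrap dendrogram cut at the maximum-modularity level."""
    g, weights = _to_igraph(net)
    cl = g.community_walktrap(weights=weights, steps=steps).as_clustering()
    q = g.modularity(cl.membership, weights=weights)
    membership = _canonical(net.labels, list(cl.membership))
    return Partition(
        membership=membership,
        n_communities=len(set(cl.membership)),
        modularity=float(q),
        algorithm="walktrap",
    )


def weighted_modularity(net: SymptomNetwork, membership: list[int]) -> float:
    """Newman's weighted modularity of an arbitrary assignment (oracle aid)."""
    g, weights = _to_igraph(net)
    return float(g.modularity(membership, weights=weights))


def partition_agreement(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    if set(a.membership) != set(b.membership):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(a.membership)
    return float(
        adjusted_rand_score([a.membership[v] for v in nodes], [b.membership[v] for v in nodes])
    )
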