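"""Weighted symptom-network container and edge/centrality summaries.

A :class:`SymptomNetwork` is the undirected Gaussian-graphical-model
estimate used throughout the package: a p×p symmetric matrix of
regularized partial correlations with a zero diagonal.  Expected influence
(the signed sum of a node's edge weights) is the centrality index; global
strength (the sum of absolute edge weights) is the scalar the two-group
comparison permutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: weights below this magnitude are treated as exact zeros (solver noise)
EDGE_EPS = 1e-10


@dataclass
class SymptomNetwork:
    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        w[np.abs(w) < EDGE_EPS] = 0.0
        if np.any(np.abs(w) >= 1.0):
            raise ValueError("partial correlations must have magnitude < 1")
        if not self.labels:
            self.labels = [f"V{i + 1}" for i in range(w.shape[0])]
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")
        self.weights = w

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    # ---- summaries -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.labels, columns=self.labels)

    # ---- serialization ---------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SymptomNetwork":
        df = pd.read_csv(path, index_col=0)
        m = df.to_numpy(dtype=float)
        m = np.where(np.isnan(m), 0.0, m)
        # accept a lower-triangle-only layout and mirror it
        if np.allclose(np.triu(m, 1), 0.0):
            m = m + np.tril(m, -1).T
        return cls(weights=0.5 * (m + m.T), labels=[str(c) for c in df.columns])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"labels": self.labels, "weights": self.weights.tolist()}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SymptomNetwork":
        d = json.loads(Path(path).read_text())
        return cls(weights=np.asarray(d["weights"], dtype=float), labels=list(d["labels"]))

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0.0:
                    g.add_edge(self.labels[i], self.labels[j], weight=float(self.weights[i, j]))
        nx.write_graphml(g, path)


def expected_influence(net: SymptomNetwork) -> pd.Series:
    """One-step expected influence: EI_i = Σ_j w_ij (signed row sums)."""
    return pd.Series(net.weights.sum(axis=1), index=net.labels, name="expected_influence")


def edge_census(net: SymptomNetwork) -> dict:
    """Edge count, density, mean weight over possible pairs, max edge."""
    p = net.p
    iu = np.triu_indices(p, 1)
    w = net.weights[iu]
    possible = p * (p - 1) // 2
    n_edges = int(np.count_nonzero(w))
    k = int(np.argmax(np.abs(w)))
    return {
        "n_edges": n_edges,
        "possible": possible,
        "density": n_edges / possible if possible else 0.0,
        "mean_weight": float(w.mean()) if possible else 0.0,
        "max_weight": float(w[k]),
        "max_edge": (net.labels[iu[0][k]], net.labels[iu[1][k]]),
    }


def global_strength(net: SymptomNetwork) -> float:
    """Sum of absolute upper-triangle edge weights."""
    iu = np.triu_indices(net.p, 1)
    return float(np.abs(net.weights[iu]).sum())
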