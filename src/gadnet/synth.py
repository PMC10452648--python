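"""Synthetic Likert-scale data with known network or DAG ground truth.

Two latent generative models are supported:

* a Gaussian graphical model (:class:`GgmTruth`): a sparse precision
  matrix with prescribed partial correlations, whose standardized inverse
  drives a multivariate-normal latent draw;
* a linear-Gaussian structural model (:class:`DagTruth`): latent scores
  simulated in topological order along a directed acyclic arc set.

Latent scores are discretized per item by ascending cut points into the
four GAD-7 levels {0,1,2,3}; the clinical inclusion rule (total score at
or above a threshold, 8 by default) can be applied after sampling so that
the selection bias of a screened cohort is emulated rather than avoided.

Default cut points are calibrated so that unfiltered marginal means match
the published per-item means of the reference cohort (≈1.3–1.9).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import gad7

#: lower bound imposed on the smallest precision eigenvalue
MIN_EIGENVALUE = 0.05


# ------------------------------------------------------------ ground truths


@dataclass
class GgmTruth:
    p: int
    precision: np.ndarray
    partial_corr: np.ndarray
    seed: int = 0

    def covariance(self) -> np.ndarray:
        """Standardized latent covariance (inverse precision as correlation)."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"p": self.p, "precision": self.precision.tolist(), "seed": self.seed})
        )


@dataclass
class DagTruth:
    p: int
    arcs: list[tuple[int, int]]
    coefficients: list[float]
    noise_sd: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd is None:
            self.noise_sd = [1.0] * self.p
        if len(self.coefficients) != len(self.arcs):
            raise ValueError("one coefficient per arc required")
        order = topological_order(self.p, self.arcs)  # raises on cycles
        self._order = order

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "p": self.p,
                    "arcs": [list(a) for a in self.arcs],
                    "coefficients": self.coefficients,
                    "noise_sd": self.noise_sd,
                    "seed": self.seed,
                }
            )
        )


def topological_order(p: int, arcs: list[tuple[int, int]]) -> list[int]:
    """Kahn's algorithm; raises naming an arc of a cycle if one exists."""
    indeg = [0] * p
    children: list[list[int]] = [[] for _ in range(p)]
    for a, b in arcs:
        children[a].append(b)
        indeg[b] += 1
    queue = [i for i in range(p) if indeg[i] == 0]
    order = []
    while queue:
        v = queue.pop()
        order.append(v)
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != p:
        stuck = [i for i in range(p) if indeg[i] > 0]
        bad = next((a, b) for a, b in arcs if b in stuck and a in stuck)
        raise ValueError(f"arc set contains a cycle through {bad[0]}->{bad[1]}")
    return order


@dataclass
class LikertConfig:
    n: int
    thresholds: np.ndarray  # (p, 3) ascending cut points per item
    inclusion_min_total: int | None = None
    labels: list[str] = field(default_factory=lambda: list(gad7.ITEM_LABELS))

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("thresholds must be (p, 3): three cut points per item")
        if not np.all(np.diff(t, axis=1) > 0):
            raise ValueError("cut points must be strictly increasing per item")
        self.thresholds = t
        p = t.shape[0]
        if self.inclusion_min_total is not None and not 0 <= self.inclusion_min_total <= 3 * p:
            raise ValueError("inclusion_min_total must lie in [0, 3p]")
        if len(self.labels) != p:
            self.labels = [f"V{i + 1}" for i in range(p)]


def default_thresholds(labels: tuple[str, ...] = gad7.ITEM_LABELS) -> np.ndarray:
    """Cut points reproducing the reference cohort's marginal means.

    The target distribution over {0,1,2,3} for each item is a normal with
    the item's published mean and SD, binned at half-integer boundaries
    with the tails absorbed into the end levels; its cumulative
    probabilities are mapped to standard-normal quantiles.
    """
    rows = []
    for lab in labels:
        m, s = gad7.ITEM_MEANS[lab], gad7.ITEM_SDS[lab]
        edges = np.array([0.5, 1.5, 2.5])
        cum = norm.cdf((edges - m) / s)
        cum = np.clip(cum, 1e-6, 1 - 1e-6)
        rows.append(norm.ppf(cum))
    return np.array(rows)


def default_config(
    n: int, inclusion_min_total: int | None = gad7.INCLUSION_MIN_TOTAL
) -> LikertConfig:
    return LikertConfig(n=n, thresholds=default_thresholds(), inclusion_min_total=inclusion_min_total)


# ---------------------------------------------------------- GGM construction


def build_ggm_truth(
    p: int, edges: list[tuple[int, int, float]] | dict, seed: int = 0
) -> GgmTruth:
    """Precision matrix whose implied partial correlations equal ``edges``.

    Start from the identity, write requested partial correlations into the
    off-diagonal via K_ij = −w_ij·√(K_ii·K_jj), then inflate the diagonal
    uniformly (bisection, tolerance 1e-8) until the smallest eigenvalue is
    at least ``MIN_EIGENVALUE``.  Because the off-diagonal scales with the
    diagonal, the implied partial correlations are preserved exactly;
    weight patterns that are not representable by any positive-definite
    precision fail explicitly.
    """
    if p < 2:
        raise ValueError("need p >= 2")
    if isinstance(edges, dict):
        edges = [(i, j, w) for (i, j), w in edges.items()]
    W = np.zeros((p, p))
    for i, j, w in edges:
        if i == j:
            raise ValueError("self-edges are not allowed")
        if abs(w) >= 1:
            raise ValueError(f"partial correlation magnitude {abs(w)} not < 1")
        W[i, j] = W[j, i] = w
    base = np.eye(p) - W  # c=1 member of the family K(c) = c(I − W)
    lam_min = float(np.linalg.eigvalsh(base).min())
    if lam_min <= 1e-12:
        worst = float(np.max(np.abs(W)))
        raise ValueError(
            f"requested weights (max magnitude {worst:.3f}) admit no positive-definite "
            "precision matrix"
        )
    if lam_min >= MIN_EIGENVALUE:
        K = base
    else:
        # bisect the uniform diagonal value c; eigenvalues scale linearly in c
        lo, hi = 1.0, MIN_EIGENVALUE / lam_min + 1.0
        while np.linalg.eigvalsh(hi * base).min() < MIN_EIGENVALUE:
            hi *= 2.0
        while hi - lo > 1e-8:
            mid = 0.5 * (lo + hi)
            if np.linalg.eigvalsh(mid * base).min() >= MIN_EIGENVALUE:
                hi = mid
            else:
                lo = mid
        K = hi * base
    pc = partial_corr_of_precision(K)
    return GgmTruth(p=p, precision=K, partial_corr=pc, seed=seed)


def partial_corr_of_precision(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    pc = -K / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def reference_ggm_truth(seed: int = 0) -> GgmTruth:
    """GGM truth whose partial correlations are the published GAD-7 weights."""
    return build_ggm_truth(p=7, edges=gad7.published_edges(), seed=seed)


# ------------------------------------------------------------------ sampling


def _discretize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    out = np.zeros(latent.shape, dtype=int)
    for j in range(latent.shape[1]):
        out[:, j] = np.searchsorted(thresholds[j], latent[:, j], side="right")
    return out


def sample_likert_from_ggm(
    truth: GgmTruth, config: LikertConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw latent MVN scores from the truth and discretize per item."""
    if config.thresholds.shape[0] != truth.p:
        raise ValueError("config and truth disagree on item count")
    if config.n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    cov = truth.covariance()
    latent = rng.multivariate_normal(np.zeros(truth.p), cov, size=config.n, method="cholesky")
    data = pd.DataFrame(_discretize(latent, config.thresholds), columns=config.labels)
    if config.inclusion_min_total is not None:
        data = apply_inclusion_filter(data, config.inclusion_min_total)
    return data


def sample_likert_from_dag(
    truth: DagTruth, config: LikertConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulate the linear-Gaussian structural model, then discretize.

    Each node is standardized to unit population SD (computed from the
    implied latent covariance) before the cut points are applied, so the
    same threshold calibration serves every node.
    """
    if config.thresholds.shape[0] != truth.p:
        raise ValueError("config and truth disagree on item count")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    p = truth.p
    coef = np.zeros((p, p))
    for (a, b), w in zip(truth.arcs, truth.coefficients):
        if not np.isfinite(w):
            raise ValueError("coefficients must be finite")
        coef[b, a] = w
    latent = np.zeros((config.n, p))
    noise = rng.normal(size=(config.n, p)) * np.asarray(truth.noise_sd)
    for v in truth._order:
        latent[:, v] = latent @ coef[v] + noise[:, v]
    sd = dag_latent_sd(truth)
    latent = latent / sd
    data = pd.DataFrame(_discretize(latent, config.thresholds), columns=config.labels)
    if config.inclusion_min_total is not None:
        data = apply_inclusion_filter(data, config.inclusion_min_total)
    return data


def dag_latent_covariance(truth: DagTruth) -> np.ndarray:
    """Closed-form latent covariance: Σ = (I−B)⁻¹ D (I−B)⁻ᵀ."""
    p = truth.p
    B = np.zeros((p, p))
    for (a, b), w in zip(truth.arcs, truth.coefficients):
        B[b, a] = w
    inv = np.linalg.inv(np.eye(p) - B)
    D = np.diag(np.asarray(truth.noise_sd) ** 2)
    return inv @ D @ inv.T


def dag_latent_sd(truth: DagTruth) -> np.ndarray:
    return np.sqrt(np.diag(dag_latent_covariance(truth)))


def apply_inclusion_filter(data: pd.DataFrame, min_total: int) -> pd.DataFrame:
    """Keep rows whose item total is at least ``min_total`` (order kept)."""
    p = data.shape[1]
    if not 0 <= min_total <= 3 * p:
        raise ValueError("min_total must lie in [0, 3p]")
    return data.loc[data.sum(axis=1) >= min_total].reset_index(drop=True)
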