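"""Directed-acyclic-graph learning over symptoms by BIC hill-climbing.

The score is the decomposable Gaussian BIC,
``Σ_nodes [logL(node | parents) − (k/2)·log n]`` with k counting the
node's parents plus intercept and residual variance; higher is better.
Greedy search applies the best single arc addition, deletion or reversal
until no move improves the score, then escapes local optima with random
restarts, each preceded by a batch of random legal perturbations.

Structure stability follows the bootstrap model-averaging recipe: learn a
DAG on each row-resample, tally how often each (undirected) pair appears
and in which direction, keep pairs whose frequency clears a
sensitivity/specificity-optimal cutoff, and orient each kept pair along
its majority direction — flagging it direction-uncertain when the
majority falls below 51%.  Reported per-arc strengths are ΔBIC on
deletion (negative = the arc supports the model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import topological_order

DIRECTION_MIN = 0.51


# ----------------------------------------------------------------- scoring


class GaussianBicScorer:
    """Cached per-family Gaussian BIC terms from sufficient statistics."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.n, self.p = X.shape
        if self.n < self.p + 2:
            raise ValueError("need n > p+1 rows to score families")
        Xc = X - X.mean(axis=0)
        self.S = (Xc.T @ Xc) / self.n  # MLE covariance
        self._cache: dict[tuple[int, int], float] = {}
        self._logn = math.log(self.n)

    def family(self, node: int, parent_mask: int) -> float:
        key = (node, parent_mask)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        parents = [k for k in range(self.p) if parent_mask >> k & 1]
        syy = self.S[node, node]
        if parents:
            Spp = self.S[np.ix_(parents, parents)]
            spy = self.S[parents, node]
            sigma2 = syy - float(spy @ np.linalg.solve(Spp, spy))
        else:
            sigma2 = syy
        if sigma2 <= 1e-12:
            raise ValueError(f"residual variance of node {node} is numerically zero")
        ll = -0.5 * self.n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        k = len(parents) + 2  # coefficients + intercept + variance
        val = ll - 0.5 * k * self._logn
        self._cache[key] = val
        return val

    def total(self, parent_masks: list[int]) -> float:
        return sum(self.family(v, m) for v, m in enumerate(parent_masks))


@dataclass
class DagModel:
    labels: list[str]
    arcs: list[tuple[str, str]]
    score: float
    strength: dict[tuple[str, str], float] = field(default_factory=dict)
    direction_probability: dict[tuple[str, str], float] = field(default_factory=dict)
    direction_uncertain: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        idx = {lab: i for i, lab in enumerate(self.labels)}
        topological_order(len(self.labels), [(idx[a], idx[b]) for a, b in self.arcs])

    def arc_indices(self) -> list[tuple[int, int]]:
        idx = {lab: i for i, lab in enumerate(self.labels)}
        return [(idx[a], idx[b]) for a, b in self.arcs]

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(a) for a in self.arcs}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, b in self.arcs:
            rows.append(
                {
                    "from": a,
                    "to": b,
                    "strength_bic": self.strength.get((a, b), np.nan),
                    "direction_probability": self.direction_probability.get((a, b), np.nan),
                    "direction_uncertain": (a, b) in self.direction_uncertain,
                }
            )
        return pd.DataFrame(rows, columns=["from", "to", "strength_bic", "direction_probability", "direction_uncertain"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_dot(self, path: str | Path) -> None:
        lines = ["digraph symptoms {"]
        for a, b in self.arcs:
            style = ' [style="dashed"]' if (a, b) in self.direction_uncertain else ""
            lines.append(f'  "{a}" -> "{b}"{style};')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def _has_path(parent_masks: list[int], src: int, dst: int) -> bool:
    """True if a directed path src -> ... -> dst exists."""
    p = len(parent_masks)
    children = [[c for c in range(p) if parent_masks[c] >> v & 1] for v in range(p)]
    stack = [src]
    seen = 1 << src
    while stack:
        v = stack.pop()
        if v == dst:
            return True
        for c in children[v]:
            if not seen >> c & 1:
                seen |= 1 << c
                stack.append(c)
    return False


def _legal_moves(parent_masks: list[int]) -> list[tuple[str, int, int]]:
    p = len(parent_masks)
    moves = []
    for a in range(p):
        for b in range(p):
            if a == b:
                continue
            if parent_masks[b] >> a & 1:  # arc a->b exists
                moves.append(("del", a, b))
                # reversal legal iff no alternative directed path a->b
                trial = parent_masks.copy()
                trial[b] &= ~(1 << a)
                if not _has_path(trial, a, b):
                    moves.append(("rev", a, b))
            elif not parent_masks[a] >> b & 1:
                if not _has_path(parent_masks, b, a):
                    moves.append(("add", a, b))
    return moves


def _apply(parent_masks: list[int], move: tuple[str, int, int]) -> None:
    kind, a, b = move
    if kind == "add":
        parent_masks[b] |= 1 << a
    elif kind == "del":
        parent_masks[b] &= ~(1 << a)
    else:  # reversal a->b becomes b->a
        parent_masks[b] &= ~(1 << a)
        parent_masks[a] |= 1 << b

def _move_gain(scorer: GaussianBicScorer, parent_masks: list[int], move: tuple[str, int, int]) -> float:
    kind, a, b = move
    fb = scorer.family(b, parent_masks[b])
    if kind == "add":
        return scorer.family(b, parent_masks[b] | 1 << a) - fb
    if kind == "del":
        return scorer.family(b, parent_masks[b] & ~(1 << a)) - fb
    fa = scorer.family(a, parent_masks[a])
    return (
        scorer.family(b, parent_masks[b] & ~(1 << a))
        - fb
        + scorer.family(a, parent_masks[a] | 1 << b)
        - fa
    )


def _climb(scorer: GaussianBicScorer, parent_masks: list[int], tol: float = 1e-9) -> float:
    """Greedy ascent in place; returns the final score."""
    score = scorer.total(parent_masks)
    while True:
        best_gain = tol
        best_move = None
        for move in _legal_moves(parent_masks):
            g = _move_gain(scorer, parent_masks, move)
            if g > best_gain:
                best_gain = g
                best_move = move
        if best_move is None:
            return score
        _apply(parent_masks, best_move)
        score += best_gain


def _masks_to_arcs(parent_masks: list[int], labels: list[str]) -> list[tuple[str, str]]:
    p = len(parent_masks)
    return [
        (labels[a], labels[b])
        for b in range(p)
        for a in range(p)
        if parent_masks[b] >> a & 1
    ]


def _deletion_strengths(
    scorer: GaussianBicScorer, parent_masks: list[int], labels: list[str], score: float
) -> dict[tuple[str, str], float]:
    out = {}
    for b in range(len(parent_masks)):
        for a in range(len(parent_masks)):
            if parent_masks[b] >> a & 1:
                without = scorer.family(b, parent_masks[b] & ~(1 << a))
                withit = scorer.family(b, parent_masks[b])
                out[(labels[a], labels[b])] = without - withit
    return out


def bic_score(data: pd.DataFrame | np.ndarray, dag: DagModel) -> float:
    """Total Gaussian BIC of ``dag`` on ``data`` (higher is better)."""
    X = data.to_numpy() if hasattr(data, "to_numpy") else np.asarray(data)
    scorer = GaussianBicScorer(X)
    p = X.shape[1]
    masks = [0] * p
    for a, b in dag.arc_indices():
        masks[b] |= 1 << a
    return scorer.total(masks)


def hill_climb(
    data: pd.DataFrame | np.ndarray,
    restarts: int = 50,
    perturbations: int = 100,
    seed: int = 0,
    labels: list[str] | None = None,
) -> DagModel:
    """Best-of-restarts greedy BIC search from the empty graph."""
    if hasattr(data, "to_numpy"):
        labels = labels or [str(c) for c in data.columns]
        X = data.to_numpy()
    else:
        X = np.asarray(data)
        labels = labels or [f"V{i + 1}" for i in range(X.shape[1])]
    scorer = GaussianBicScorer(X)
    p = X.shape[1]
    rng = np.random.default_rng(seed)

    masks = [0] * p
    best_score = _climb(scorer, masks)
    best_masks = masks.copy()
    for _ in range(max(0, restarts)):
        trial = best_masks.copy()
        for _ in range(max(0, perturbations)):
            moves = _legal_moves(trial)
            if not moves:
                break
            _apply(trial, moves[rng.integers(len(moves))])
        score = _climb(scorer, trial)
        if score > best_score + 1e-12:
            best_score = score
            best_masks = trial.copy()

    arcs = _masks_to_arcs(best_masks, labels)
    strengths = _deletion_strengths(scorer, best_masks, labels, best_score)
    return DagModel(labels=labels, arcs=arcs, score=best_score, strength=strengths)


# ------------------------------------------------------- bootstrap averaging


@dataclass
class DagEnsemble:
    B: int
    labels: list[str]
    presence: dict[tuple[int, int], int]  # i<j -> count of bootstraps with the pair
    forward: dict[tuple[int, int], int]  # i<j -> count oriented i->j
    seed: int

    def frequencies(self) -> dict[tuple[int, int], float]:
        return {pair: c / self.B for pair, c in self.presence.items()}

    def direction_split(self, pair: tuple[int, int]) -> tuple[float, float]:
        """(p(i->j), p(j->i)) among bootstraps containing the pair."""
        pres = self.presence.get(pair, 0)
        if pres == 0:
            return (0.0, 0.0)
        f = self.forward.get(pair, 0)
        return (f / pres, (pres - f) / pres)


def bootstrap_dags(
    data: pd.DataFrame | np.ndarray,
    B: int = 200,
    seed: int = 0,
    restarts: int = 5,
    perturbations: int = 50,
    labels: list[str] | None = None,
) -> DagEnsemble:
    """Row-resampling bootstrap of the hill-climb structure search."""
    if B < 100:
        raise ValueError("need B >= 100")
    if hasattr(data, "to_numpy"):
        labels = labels or [str(c) for c in data.columns]
        X = data.to_numpy()
    else:
        X = np.asarray(data)
        labels = labels or [f"V{i + 1}" for i in range(X.shape[1])]
    n, p = X.shape
    rng = np.random.default_rng(seed)
    presence: dict[tuple[int, int], int] = {}
    forward: dict[tuple[int, int], int] = {}
    idx_of = {lab: i for i, lab in enumerate(labels)}
    for b in range(B):
        rows = rng.integers(0, n, size=n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        model = hill_climb(
            X[rows], restarts=restarts, perturbations=perturbations, seed=sub_seed, labels=labels
        )
        for a_lab, b_lab in model.arcs:
            a, c = idx_of[a_lab], idx_of[b_lab]
            pair = (min(a, c), max(a, c))
            presence[pair] = presence.get(pair, 0) + 1
            if a < c:
                forward[pair] = forward.get(pair, 0) + 1
            else:
                forward.setdefault(pair, 0)
    return DagEnsemble(B=B, labels=labels, presence=presence, forward=forward, seed=seed)


def optimal_cutoff(frequencies: list[float] | np.ndarray) -> float:
    """Sensitivity/specificity-optimal retention threshold for frequencies.

    The empirical CDF of the pair frequencies is compared, in L1 distance
    over [0, 1], against the ideal CDF of a perfectly separated ensemble —
    a fraction ℓ of pairs with frequency 0 and the rest at 1.  The level
    ℓ̂ minimizing the distance (ties toward larger ℓ, favouring
    specificity) is mapped back through the ECDF: the cutoff is the
    ℓ̂-quantile of the observed frequencies, and pairs strictly above it
    are retained.
    """
    f = np.sort(np.asarray(frequencies, dtype=float))
    if f.size == 0:
        raise ValueError("no frequencies given")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    m = f.size
    # segment boundaries of the ECDF on [0, 1]
    xs = np.concatenate([[0.0], f, [1.0]])
    seg_len = np.diff(xs)  # length of segment with level k/m, k = 0..m
    levels = np.arange(m + 1) / m
    candidates = levels
    best_level = 0.0
    best_d = np.inf
    for ell in candidates:
        d = float(np.sum(np.abs(levels - ell) * seg_len))
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and ell > best_level):
            best_d = d
            best_level = ell
    k = int(round(best_level * m))
    if k == 0:
        return float(f[0])
    return float(f[k - 1])


def average_dag(
    ensemble: DagEnsemble,
    data: pd.DataFrame | np.ndarray,
    direction_min: float = DIRECTION_MIN,
) -> DagModel:
    """Bootstrap-averaged DAG: frequency cutoff, majority orientation.

    Pairs whose presence frequency exceeds the optimal cutoff are kept and
    oriented toward their majority bootstrap direction; arcs whose
    majority proportion falls below ``direction_min`` are retained but
    flagged direction-uncertain.  Any cycle created by majority
    orientation is broken by deleting its lowest-frequency arc.  Strengths
    are ΔBIC-on-deletion refits against the full data.
    """
    if not ensemble.presence:
        raise ValueError("ensemble is empty")
    freqs = ensemble.frequencies()
    cutoff = optimal_cutoff(list(freqs.values()))
    labels = ensemble.labels
    kept = [pair for pair, fr in freqs.items() if fr > cutoff]

    arcs_idx: list[tuple[int, int]] = []
    dir_prob: dict[tuple[int, int], float] = {}
    uncertain: set[tuple[int, int]] = set()
    for i, j in kept:
        p_fwd, p_rev = ensemble.direction_split((i, j))
        if p_fwd >= p_rev:
            arc, prob = (i, j), p_fwd
        else:
            arc, prob = (j, i), p_rev
        arcs_idx.append(arc)
        dir_prob[arc] = prob
        if prob < direction_min:
            uncertain.add(arc)

    # majority orientation can in principle create cycles; drop the
    # lowest-frequency arc of each cycle until a topological order exists
    def find_cycle(arcs: list[tuple[int, int]]) -> list[tuple[int, int]] | None:
        p = len(labels)
        children: dict[int, list[int]] = {v: [] for v in range(p)}
        for a, b in arcs:
            children[a].append(b)
        color = [0] * p
        stack_path: list[int] = []

        def dfs(v: int) -> list[int] | None:
            color[v] = 1
            stack_path.append(v)
            for c in children[v]:
                if color[c] == 1:
                    return stack_path[stack_path.index(c) :] + [c]
                if color[c] == 0:
                    got = dfs(c)
                    if got is not None:
                        return got
            stack_path.pop()
            color[v] = 2
            return None

        for v in range(p):
            if color[v] == 0:
                cyc = dfs(v)
                if cyc is not None:
                    return [(cyc[k], cyc[k + 1]) for k in range(len(cyc) - 1)]
        return None

    while True:
        cyc = find_cycle(arcs_idx)
        if cyc is None:
            break
        weakest = min(cyc, key=lambda arc: freqs[(min(arc), max(arc))])
        arcs_idx.remove(weakest)
        dir_prob.pop(weakest, None)
        uncertain.discard(weakest)

    X = data.to_numpy() if hasattr(data, "to_numpy") else np.asarray(data)
    scorer = GaussianBicScorer(X)
    p = len(labels)
    masks = [0] * p
    for a, b in arcs_idx:
        masks[b] |= 1 << a
    score = scorer.total(masks)
    strengths = _deletion_strengths(scorer, masks, labels, score)
    return DagModel(
        labels=labels,
        arcs=[(labels[a], labels[b]) for a, b in arcs_idx],
        score=score,
        strength=strengths,
        direction_probability={(labels[a], labels[b]): pr for (a, b), pr in dir_prob.items()},
        direction_uncertain={(labels[a], labels[b]) for a, b in uncertain},
    )
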