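"""EBIC-selected graphical-lasso estimation of the symptom network.

``estimate_network`` composes the full pipeline used throughout the
package: nonparanormal transform → Spearman matrix → positive-definiteness
repair → graphical-lasso path → EBIC model selection (γ = 0.5 by default)
→ partial-correlation weights.  ``estimate_weights_fast`` is the
equivalent array-only fast path used inside bootstrap and permutation
loops (Spearman of the transformed data equals Pearson on midranks, so the
transform can be skipped there without changing the estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glasso as _gl
from .network import EDGE_EPS, SymptomNetwork
from .prep import (
    CorrelationMatrix,
    ensure_positive_definite,
    nonparanormal,
    spearman_matrix,
)

DEFAULT_GAMMA = 0.5
DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 0.01


@dataclass
class GlassoPath:
    lambdas: np.ndarray  # descending
    precisions: np.ndarray  # (n_lambda, p, p)
    loglik: np.ndarray  # per-λ Gaussian log-likelihood of the penalized fit
    S: np.ndarray  # the sample correlation the path was fitted to
    n: int
    p: int
    labels: list[str]


@dataclass
class EbicSelection:
    gamma: float
    ebic: np.ndarray
    selected: int
    likelihood: str = "refit"

    @property
    def selected_lambda_index(self) -> int:
        return self.selected


def _gaussian_loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.sum(S * K)) - p * np.log(2.0 * np.pi))


def glasso_path(
    corr: CorrelationMatrix,
    n: int | None = None,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> GlassoPath:
    """Penalized precision estimates along a descending log-spaced λ grid."""
    S = np.asarray(corr.values, dtype=float)
    n = corr.n if n is None else n
    p = S.shape[0]
    if n < p + 1:
        raise ValueError(f"need n >= p+1 (= {p + 1}), got n = {n}")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("input matrix is not positive-definite; run ensure_positive_definite")
    lams = _gl.default_lambda_grid(S, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    Ks = _gl.glasso_path_kernel(S, lams)
    ll = np.array([_gaussian_loglik(S, K, n) for K in Ks])
    return GlassoPath(
        lambdas=lams, precisions=Ks, loglik=ll, S=S, n=n, p=p, labels=list(corr.labels)
    )


def _ebic_values(
    S: np.ndarray, n: int, precisions: np.ndarray, gamma: float, likelihood: str
) -> np.ndarray:
    """EBIC(λ) = −2·logL + E·log n + 4·γ·E·log p along the path.

    ``refit`` evaluates each candidate support at its support-restricted
    unpenalized MLE (the EBIC of the sparsity pattern itself — immune to
    the shrinkage bias that otherwise makes the criterion favour the
    densest fit); ``penalized`` uses the penalized estimate's likelihood.
    """
    p = S.shape[0]
    iu = np.triu_indices(p, 1)
    logn, logp = np.log(n), np.log(p)
    ebic = np.empty(precisions.shape[0])
    cache: dict[bytes, float] = {}
    for i, K in enumerate(precisions):
        nonzero = np.abs(K[iu]) > EDGE_EPS
        e = int(nonzero.sum())
        if likelihood == "penalized":
            ll = _gaussian_loglik(S, K, n)
        elif likelihood == "refit":
            key = nonzero.tobytes()
            if key in cache:
                ebic[i] = cache[key]
                continue
            support = np.eye(p, dtype=bool)
            support[iu] = nonzero
            support |= support.T
            Kr = _gl.restricted_mle(S, support)
            ll = _gaussian_loglik(S, Kr, n)
            cache[key] = -2.0 * ll + e * logn + 4.0 * gamma * e * logp
            ebic[i] = cache[key]
            continue
        else:
            raise ValueError(f"unknown likelihood variant {likelihood!r}")
        ebic[i] = -2.0 * ll + e * logn + 4.0 * gamma * e * logp
    return ebic


def ebic_select(
    path: GlassoPath, gamma: float = DEFAULT_GAMMA, likelihood: str = "refit"
) -> EbicSelection:
    """Pick the λ minimizing EBIC; ties go to the larger λ (sparser fit)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if path.precisions.shape[0] == 0:
        raise ValueError("empty path")
    ebic = _ebic_values(path.S, path.n, path.precisions, gamma, likelihood)
    # λ descending: first index achieving the minimum is the sparsest
    selected = int(np.argmin(ebic))
    return EbicSelection(gamma=gamma, ebic=ebic, selected=selected, likelihood=likelihood)


def partial_corr(precision: np.ndarray, labels: list[str] | None = None) -> SymptomNetwork:
    """w_ij = −K_ij / √(K_ii·K_jj), diagonal zeroed."""
    K = np.asarray(precision, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision must be symmetric")
    if np.linalg.eigvalsh(K).min() <= 0:
        raise ValueError("precision must be positive-definite")
    d = np.sqrt(np.diag(K))
    w = -K / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) < EDGE_EPS] = 0.0
    return SymptomNetwork(weights=0.5 * (w + w.T), labels=labels or [])


def estimate_network(
    data: pd.DataFrame,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    transform: bool = True,
    likelihood: str = "refit",
) -> SymptomNetwork:
    """Full pipeline from ordinal responses to the regularized network."""
    n, p = data.shape
    if n < p + 1:
        raise ValueError(f"need n >= p+1 (= {p + 1}), got n = {n}")
    x = nonparanormal(data) if transform else data
    corr = spearman_matrix(x)
    corr = ensure_positive_definite(corr).corr
    path = glasso_path(corr, n=n, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    sel = ebic_select(path, gamma=gamma, likelihood=likelihood)
    K = _selected_precision(path.S, path.precisions[sel.selected], likelihood)
    return partial_corr(K, labels=path.labels)


def _selected_precision(S: np.ndarray, K_pen: np.ndarray, likelihood: str) -> np.ndarray:
    """Precision reported for the selected model.

    Under refit selection the selected object is the sparsity pattern, so
    the reported weights are its support-restricted MLE (unshrunken);
    under penalized selection they are the glasso estimate itself.
    """
    if likelihood != "refit":
        return K_pen
    p = S.shape[0]
    support = np.abs(K_pen) > EDGE_EPS
    np.fill_diagonal(support, True)
    support |= support.T
    return _gl.restricted_mle(S, support)


def estimate_weights_fast(
    values: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    n_lambda: int = DEFAULT_N_LAMBDA,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    likelihood: str = "refit",
) -> np.ndarray:
    """Array-only estimate of the weight matrix (bootstrap inner loop).

    Mathematically identical to :func:`estimate_network`: the Spearman
    matrix of the rank-preserving transform is the Pearson correlation of
    columnwise midranks.
    """
    n, p = values.shape
    ranks = np.empty((n, p))
    for j in range(p):
        ranks[:, j] = stats.rankdata(values[:, j], method="average")
    sds = ranks.std(axis=0)
    if np.any(sds <= 0):
        bad = int(np.argmin(sds))
        raise ValueError(f"column {bad} has zero variance")
    S = np.corrcoef(ranks, rowvar=False)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    vals, vecs = np.linalg.eigh(S)
    if vals.min() <= 1e-8:
        S = (vecs * np.maximum(vals, 1e-8)) @ vecs.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 1.0)
    lams = _gl.default_lambda_grid(S, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    Ks = _gl.glasso_path_kernel(S, lams)
    ebic = _ebic_values(S, n, Ks, gamma, likelihood)
    best = _selected_precision(S, Ks[int(np.argmin(ebic))], likelihood)
    d = np.sqrt(np.diag(best))
    w = -best / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) < EDGE_EPS] = 0.0
    return 0.5 * (w + w.T)


def predictability(
    data: pd.DataFrame, net: SymptomNetwork, neighbors_only: bool = False
) -> pd.Series:
    """Nodewise variance explained (R²) by the other items.

    Each (transformed) node is regressed by OLS on all other nodes —
    an upper bound on controllability since edge directions are unknown.
    With ``neighbors_only``, predictors are restricted to the node's
    nonzero neighbors in the estimated network.
    """
    if list(map(str, data.columns)) != list(net.labels):
        raise ValueError("data and network labels differ")
    n, p = data.shape
    if n <= p:
        raise ValueError("need n > p for nodewise regression")
    x = nonparanormal(data).to_numpy()
    out = {}
    for j, lab in enumerate(net.labels):
        others = [k for k in range(p) if k != j]
        if neighbors_only:
            others = [k for k in others if net.weights[j, k] != 0.0]
        y = x[:, j]
        if not others:
            out[lab] = 0.0
            continue
        X = np.column_stack([np.ones(n), x[:, others]])
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise ValueError(f"singular design when predicting {lab!r}")
        resid = y - X @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        out[lab] = 1.0 - float((resid**2).sum()) / tss
    return pd.Series(out, name="predictability")
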