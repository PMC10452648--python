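"""Ingestion, scoring and pre-network transformation of Likert responses.

The pipeline mirrors the standard psychometric-network workflow for
ordinal questionnaire items: validate the 0..level_max integer matrix,
screen marginal normality (Kolmogorov–Smirnov), Gaussianize marginals with
the rank-based nonparanormal transform, build a Spearman correlation
matrix, repair it to positive definiteness if needed, and screen for
redundant ("overlapping") item pairs with a dependent-correlation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri


# ---------------------------------------------------------------- I/O


def read_likert_csv(path: str | Path, level_max: int = 3) -> pd.DataFrame:
    """Read a headered CSV of integer item responses in {0..level_max}.

    Non-integer, out-of-range or missing cells are rejected with their
    row/column coordinates.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # parse failures keep pandas' line info
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return validate_likert(df, level_max=level_max)


def write_likert_csv(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, index=False)


def validate_likert(df: pd.DataFrame, level_max: int = 3) -> pd.DataFrame:
    vals = df.to_numpy()
    for j, col in enumerate(df.columns):
        for i, v in enumerate(vals[:, j]):
            if pd.isna(v):
                raise ValueError(f"missing cell at row {i}, column {col!r}")
            fv = float(v)
            if fv != int(fv):
                raise ValueError(f"non-integer cell at row {i}, column {col!r}: {v!r}")
            if not 0 <= int(fv) <= level_max:
                raise ValueError(
                    f"out-of-range cell at row {i}, column {col!r}: {v!r} (allowed 0..{level_max})"
                )
    return df.astype(int)


def row_totals(data: pd.DataFrame) -> pd.Series:
    return data.sum(axis=1)


# ------------------------------------------------- descriptives & reliability


def descriptive_stats(data: pd.DataFrame) -> pd.DataFrame:
    """Per-item mean, SD (n−1 denominator), min and max."""
    if len(data) < 2:
        raise ValueError("need at least 2 rows for descriptive statistics")
    return pd.DataFrame(
        {
            "mean": data.mean(),
            "sd": data.std(ddof=1),
            "min": data.min(),
            "max": data.max(),
        }
    )


@dataclass
class ReliabilityResult:
    alpha: float
    n_items: int
    n: int


def cronbach_alpha(data: pd.DataFrame) -> ReliabilityResult:
    """Cronbach's α = (p/(p−1))·(1 − Σ item variances / total-score variance)."""
    n, p = data.shape
    if p < 2 or n < 2:
        raise ValueError("cronbach_alpha needs p >= 2 items and n >= 2 rows")
    item_var = data.var(ddof=1).to_numpy()
    total_var = data.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero")
    alpha = (p / (p - 1)) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(alpha=float(alpha), n_items=p, n=n)


# ------------------------------------------------------- normality screen


def ks_normality(data: pd.DataFrame) -> pd.DataFrame:
    """One-sample KS test of each item against N(sample mean, sample SD).

    Discrete 4-level items are expected to reject decisively; the screen's
    role is to justify rank-based correlations downstream.
    """
    if len(data) < 5:
        raise ValueError("need n >= 5 for the KS screen")
    rows = {}
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"item {col!r} has zero variance")
        stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
        rows[col] = {"statistic": float(stat), "p_value": float(p)}
    return pd.DataFrame(rows).T


# --------------------------------------------------- nonparanormal transform


def nonparanormal(data: pd.DataFrame, variant: str = "shrinkage") -> pd.DataFrame:
    """Rank-based marginal Gaussianization (nonparanormal transform).

    ``shrinkage``: u = midrank/(n+1), then Φ⁻¹(u), then rescale the column
    to unit sample SD.  ``truncation``: the ECDF is winsorized at
    1/(4 n^{1/4} √(π log n)) before the quantile step.  Both are strictly
    rank-preserving within columns, so Spearman correlations are unchanged.
    """
    n = len(data)
    if n < 2:
        raise ValueError("need n >= 2")
    out = {}
    for col in data.columns:
        r = stats.rankdata(data[col].to_numpy(), method="average")
        u = r / (n + 1.0)
        if variant == "truncation":
            delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
            u = np.clip(u, delta, 1.0 - delta)
        elif variant != "shrinkage":
            raise ValueError(f"unknown variant {variant!r}")
        z = ndtri(u)
        sd = z.std(ddof=1)
        out[col] = z / sd if sd > 0 else z * 0.0
    return pd.DataFrame(out, index=data.index)


# ------------------------------------------------------ correlation matrices


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    labels: list[str]
    n: int
    method: str = "spearman"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def spearman_matrix(data: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman ρ (midrank ties) = Pearson on columnwise midranks."""
    n, p = data.shape
    if n < 3:
        raise ValueError("need n >= 3 for a Spearman matrix")
    ranks = np.column_stack(
        [stats.rankdata(data[c].to_numpy(), method="average") for c in data.columns]
    )
    sds = ranks.std(axis=0)
    for j, c in enumerate(data.columns):
        if sds[j] <= 0:
            raise ValueError(f"column {c!r} has zero variance")
    m = np.corrcoef(ranks, rowvar=False)
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return CorrelationMatrix(values=m, labels=[str(c) for c in data.columns], n=n)


@dataclass
class PdRepairResult:
    corr: CorrelationMatrix
    repaired: bool
    frobenius_change: float


def ensure_positive_definite(corr: CorrelationMatrix, floor: float = 1e-8) -> PdRepairResult:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal if needed."""
    m = np.asarray(corr.values, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(m)
    if vals.min() > floor:
        return PdRepairResult(corr=corr, repaired=False, frobenius_change=0.0)
    fixed = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = 0.5 * (fixed + fixed.T)
    np.fill_diagonal(fixed, 1.0)
    change = float(np.linalg.norm(fixed - m))
    return PdRepairResult(
        corr=CorrelationMatrix(values=fixed, labels=corr.labels, n=corr.n, method=corr.method),
        repaired=True,
        frobenius_change=change,
    )


# ----------------------------------------------------------- overlap screen


def hittner_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Dependent-correlation z test (back-transformed average z variant).

    Compares r_jk with r_jh, the two correlations sharing variable j, with
    r_kh the correlation between the non-shared variables.  Returns
    (z, two-sided p).
    """
    if n < 10:
        raise ValueError("n too small for the z approximation")
    clip = lambda r: np.clip(r, -0.999999, 0.999999)
    z1 = np.arctanh(clip(r_jk))
    z2 = np.arctanh(clip(r_jh))
    rbar = np.tanh(0.5 * (z1 + z2))
    rb2 = rbar * rbar
    cov = (r_kh * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r_kh * r_kh)) / (
        (1.0 - rb2) ** 2
    )
    if z1 == z2:  # identical profiles: no difference regardless of covariance
        return 0.0, 1.0
    cov = min(cov, 1.0 - 1e-12)
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * cov))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class OverlapCandidate:
    item_a: str
    item_b: str
    correlation: float
    n_significant: int
    n_compared: int
    prop_significant: float
    flagged: bool


@dataclass
class OverlapReport:
    candidates: list[OverlapCandidate]
    min_abs_cor: float
    max_diff_prop: float
    alpha: float

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        return [(c.item_a, c.item_b) for c in self.candidates if c.flagged]

    def to_dict(self) -> dict:
        return {
            "min_abs_cor": self.min_abs_cor,
            "max_diff_prop": self.max_diff_prop,
            "alpha": self.alpha,
            "candidates": [vars(c) for c in self.candidates],
        }


def overlap_screen(
    data: pd.DataFrame,
    min_abs_cor: float = 0.50,
    max_diff_prop: float = 0.25,
    alpha: float = 0.01,
) -> OverlapReport:
    """Flag item pairs whose correlation profiles are too similar.

    For each highly correlated pair (|ρ| ≥ min_abs_cor), every third item
    yields a dependent-correlation test of ρ(a,k) vs ρ(b,k); the pair is
    flagged as overlapping when fewer than ``max_diff_prop`` of those
    profile comparisons differ significantly.
    """
    n, p = data.shape
    if p < 3:
        raise ValueError("overlap screen needs at least 3 items")
    corr = spearman_matrix(data)
    m = corr.values
    labels = corr.labels
    candidates = []
    for i in range(p):
        for j in range(i + 1, p):
            if abs(m[i, j]) < min_abs_cor:
                continue
            n_sig = 0
            n_cmp = 0
            for k in range(p):
                if k in (i, j):
                    continue
                _, pval = hittner_z(m[i, k], m[j, k], m[i, j], n)
                n_cmp += 1
                n_sig += pval < alpha
            prop = n_sig / n_cmp if n_cmp else 0.0
            candidates.append(
                OverlapCandidate(
                    item_a=labels[i],
                    item_b=labels[j],
                    correlation=float(m[i, j]),
                    n_significant=n_sig,
                    n_compared=n_cmp,
                    prop_significant=prop,
                    flagged=prop < max_diff_prop,
                )
            )
    return OverlapReport(
        candidates=candidates, min_abs_cor=min_abs_cor, max_diff_prop=max_diff_prop, alpha=alpha
    )
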