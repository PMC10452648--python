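"""Bootstrap accuracy and stability diagnostics for the symptom network.

* :func:`bootstrap_edges` — nonparametric (row-resampling) bootstrap of
  the whole estimation pipeline, yielding per-edge 95% percentile CIs.
* :func:`difference_test_edges` / :func:`difference_test_ei` — bootstrapped
  difference tests between edge weights / node expected influences.
* :func:`case_drop_cs` — case-dropping bootstrap and the correlation
  stability (CS) coefficient: the largest drop proportion at which, with
  95% certainty, subsample expected influence still correlates ≥ 0.7 with
  the full-sample values.  CS ≥ 0.5 is the conventional adequacy bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ggm import DEFAULT_GAMMA, estimate_weights_fast
from .network import SymptomNetwork

DEFAULT_DROP_PROPORTIONS = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


@dataclass
class EdgeBootstrap:
    B: int
    labels: list[str]
    point: np.ndarray  # (p, p) full-sample weights
    replicates: np.ndarray  # (B, p, p)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_skipped: int
    seed: int

    def summary(self) -> pd.DataFrame:
        """Tidy per-edge table: point estimate, bootstrap mean, 95% CI."""
        p = len(self.labels)
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "edge": f"{self.labels[i]}--{self.labels[j]}",
                        "weight": self.point[i, j],
                        "boot_mean": self.replicates[:, i, j].mean(),
                        "lower": self.ci_lower[i, j],
                        "upper": self.ci_upper[i, j],
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_edges(
    data: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    gamma: float = DEFAULT_GAMMA,
) -> EdgeBootstrap:
    """Row-resampling bootstrap of the full network-estimation pipeline."""
    if B < 100:
        raise ValueError("need B >= 100")
    values = data.to_numpy()
    n, p = values.shape
    point = estimate_weights_fast(values, gamma=gamma)
    rng = np.random.default_rng(seed)
    reps = np.empty((B, p, p))
    skipped = 0
    b = 0
    attempts = 0
    max_attempts = int(B * 1.02) + 10
    while b < B:
        if attempts >= max_attempts:
            raise RuntimeError(f"more than 1% of bootstrap replicates failed ({skipped} skipped)")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            reps[b] = estimate_weights_fast(values[idx], gamma=gamma)
        except ValueError:
            skipped += 1
            continue
        b += 1
    lower = np.percentile(reps, 2.5, axis=0)
    upper = np.percentile(reps, 97.5, axis=0)
    return EdgeBootstrap(
        B=B,
        labels=[str(c) for c in data.columns],
        point=point,
        replicates=reps,
        ci_lower=lower,
        ci_upper=upper,
        n_skipped=skipped,
        seed=seed,
    )


@dataclass
class DifferenceTestResult:
    names: list[str]
    significant: np.ndarray  # symmetric boolean, False diagonal
    alpha: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant, index=self.names, columns=self.names)


def _pairwise_difference_significance(samples: np.ndarray, alpha: float) -> np.ndarray:
    """samples: (B, m) replicate values; CI of each pairwise difference."""
    m = samples.shape[1]
    sig = np.zeros((m, m), dtype=bool)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    for a in range(m):
        diff = samples[:, a : a + 1] - samples
        lo = np.percentile(diff, lo_q, axis=0)
        hi = np.percentile(diff, hi_q, axis=0)
        sig[a] = (lo > 0) | (hi < 0)
        sig[a, a] = False
    return sig | sig.T


def difference_test_edges(boot: EdgeBootstrap, alpha: float = 0.05) -> DifferenceTestResult:
    """Bootstrapped difference test between the observed edges' weights."""
    p = len(boot.labels)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p) if boot.point[i, j] != 0.0]
    names = [f"{boot.labels[i]}--{boot.labels[j]}" for i, j in pairs]
    samples = np.column_stack([boot.replicates[:, i, j] for i, j in pairs])
    return DifferenceTestResult(
        names=names, significant=_pairwise_difference_significance(samples, alpha), alpha=alpha
    )


def difference_test_ei(boot: EdgeBootstrap, alpha: float = 0.05) -> DifferenceTestResult:
    """Bootstrapped difference test between the nodes' expected influences."""
    ei_reps = boot.replicates.sum(axis=2)  # (B, p) row sums per replicate
    return DifferenceTestResult(
        names=list(boot.labels),
        significant=_pairwise_difference_significance(ei_reps, alpha),
        alpha=alpha,
    )


@dataclass
class CsResult:
    proportions: list[float]
    correlations: dict[float, np.ndarray] = field(repr=False)
    cs: float
    threshold_cor: float
    certainty: float

    def qualifying(self) -> dict[float, float]:
        """Per proportion, the fraction of subsamples with corr ≥ threshold."""
        return {
            prop: float(np.mean(c >= self.threshold_cor))
            for prop, c in self.correlations.items()
        }


def case_drop_cs(
    data: pd.DataFrame,
    proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS,
    B: int = 1000,
    seed: int = 0,
    threshold_cor: float = 0.7,
    certainty: float = 0.95,
    gamma: float = DEFAULT_GAMMA,
) -> CsResult:
    """Case-dropping bootstrap of expected-influence stability."""
    if B < 100:
        raise ValueError("need B >= 100")
    if not all(0 < q < 0.95 for q in proportions):
        raise ValueError("drop proportions must lie in (0, 0.95)")
    values = data.to_numpy()
    n, p = values.shape
    full_ei = estimate_weights_fast(values, gamma=gamma).sum(axis=1)
    rng = np.random.default_rng(seed)
    correlations: dict[float, np.ndarray] = {}
    tested = []
    for prop in proportions:
        keep = int(round(n * (1.0 - prop)))
        if keep < p + 1:
            continue
        tested.append(prop)
        cors = np.empty(B)
        for b in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                ei = estimate_weights_fast(values[idx], gamma=gamma).sum(axis=1)
            except ValueError:
                cors[b] = np.nan
                continue
            sa, sb = ei.std(), full_ei.std()
            cors[b] = np.corrcoef(ei, full_ei)[0, 1] if sa > 0 and sb > 0 else 0.0
        correlations[prop] = cors[~np.isnan(cors)]
    cs = 0.0
    for prop in sorted(tested):
        c = correlations[prop]
        if len(c) and np.mean(c >= threshold_cor) >= certainty:
            cs = prop
    return CsResult(
        proportions=tested,
        correlations=correlations,
        cs=float(cs),
        threshold_cor=threshold_cor,
        certainty=certainty,
    )
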