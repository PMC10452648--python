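"""Reference values for the seven-item GAD-7 anxiety screener.

The GAD-7 asks how often, over the previous two weeks, the respondent was
bothered by each of seven anxiety symptoms, scored 0 ("not at all") to 3
("nearly every day"); totals of 8 or more are the screening threshold used
to define clinically relevant anxiety in the cohort this package models.

``published_network`` returns the regularized partial-correlation weights
reported for the GAD-7 in a large sample of front-line medical staff
(n = 1034, all with total score >= 8).  These published weights serve two
roles here: a realistic ground-truth structure for the synthetic-data
generator, and a worked example whose centrality and community structure
the tests verify directly.
"""

from __future__ import annotations

import numpy as np

from .network import SymptomNetwork

ITEM_LABELS = ("A1", "A2", "A3", "A4", "A5", "A6", "A7")

ITEM_DESCRIPTIONS = {
    "A1": "Feeling nervous, anxious or on edge",
    "A2": "Not being able to stop or control worrying",
    "A3": "Worrying too much about different things",
    "A4": "Trouble relaxing",
    "A5": "Being so restless that it is hard to sit still",
    "A6": "Becoming easily annoyed or irritable",
    "A7": "Feeling afraid as if something awful might happen",
}

# Published regularized partial correlations (lower triangle, rows A2..A7).
_LOWER = [
    [0.40],
    [0.10, 0.22],
    [0.06, 0.13, 0.14],
    [0.00, 0.07, 0.03, 0.19],
    [0.05, 0.00, 0.08, 0.05, 0.23],
    [0.00, 0.11, 0.10, 0.06, 0.11, 0.23],
]

# Published per-item descriptives (mean, SD) for the same cohort, and the
# sample size behind them.  Used to calibrate the synthetic generator's
# default discretization thresholds.
ITEM_MEANS = {"A1": 1.86, "A2": 1.69, "A3": 1.85, "A4": 1.80, "A5": 1.28, "A6": 1.76, "A7": 1.33}
ITEM_SDS = {"A1": 0.81, "A2": 0.78, "A3": 0.75, "A4": 0.78, "A5": 0.78, "A6": 0.82, "A7": 0.78}
N_COHORT = 1034
INCLUSION_MIN_TOTAL = 8


def published_network() -> SymptomNetwork:
    """The published GAD-7 regularized partial-correlation network."""
    p = len(ITEM_LABELS)
    w = np.zeros((p, p))
    for i, row in enumerate(_LOWER, start=1):
        for j, val in enumerate(row):
            w[i, j] = w[j, i] = val
    return SymptomNetwork(weights=w, labels=list(ITEM_LABELS))


def published_edges() -> list[tuple[int, int, float]]:
    """Nonzero (i, j, weight) pairs of the published network, i < j."""
    net = published_network()
    out = []
    p = len(net.labels)
    for i in range(p):
        for j in range(i + 1, p):
            if net.weights[i, j] != 0.0:
                out.append((i, j, float(net.weights[i, j])))
    return out
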