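"""Bootstrap accuracy and stability of the cohort network.

Nonparametric bootstrap CIs for edge weights, bootstrapped difference
tests for edges and expected influence, and the case-dropping correlation
stability (CS) coefficient.  Bootstrap counts here are desk-scale
(B = 500 accuracy / 200 case-dropping); both are configurable up to the
conventional 2000 in the library calls.
"""

from pathlib import Path

import gadnet

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    data = gadnet.read_likert_csv(OUT / "cohort.csv")

    boot = gadnet.bootstrap_edges(data, B=500, seed=SEED)
    summary = boot.summary()
    summary.to_csv(OUT / "edge_bootstrap.csv", index=False)
    widths = summary["upper"] - summary["lower"]
    print(f"edge bootstrap (B={boot.B}): mean 95% CI width {widths.mean():.3f}")

    edge_diff = gadnet.difference_test_edges(boot)
    ei_diff = gadnet.difference_test_ei(boot)
    edge_diff.to_dataframe().to_csv(OUT / "edge_difference_test.csv")
    ei_diff.to_dataframe().to_csv(OUT / "ei_difference_test.csv")
    frac = edge_diff.significant.mean()
    print(f"edge difference tests: {frac:.0%} of edge pairs significantly different")

    cs = gadnet.case_drop_cs(data, B=200, seed=SEED)
    print(f"case-dropping CS coefficient: {cs.cs:.2f} (adequate if >= 0.50)")
    qualifying = cs.qualifying()
    print("  per-proportion fraction of subsample EI correlations >= 0.7:")
    print("  " + ", ".join(f"{p:.2f}: {q:.2f}" for p, q in qualifying.items()))


if __name__ == "__main__":
    main()
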