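"""End-to-end pipeline driver and layout helper.

``run_pipeline`` chains every analysis stage on one response matrix —
descriptives and reliability, normality screen, overlap screen, network
estimation, centrality/predictability, bootstrap stability, community
detection, and the bootstrap-averaged DAG — writing each artifact plus a
structured log of stage decisions to an output directory.  When a second
matrix is supplied the two-group permutation comparison runs as well.

All randomized stages draw their seeds from one root seed through
``numpy.random.SeedSequence.spawn``, so a run is reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, comparison, dag, ggm, prep, stability
from .network import SymptomNetwork, edge_census, expected_influence, global_strength


@dataclass
class PipelineConfig:
    gamma: float = 0.5
    edge_bootstraps: int = 2000
    cs_bootstraps: int = 1000
    dag_bootstraps: int = 10000
    nct_iterations: int = 2000
    dag_restarts: int = 50
    dag_perturbations: int = 100
    dag_boot_restarts: int = 5
    dag_boot_perturbations: int = 50
    inclusion_min_total: int | None = 8
    level_max: int = 3
    seed: int = 0
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        for name in ("edge_bootstraps", "cs_bootstraps", "dag_bootstraps", "nct_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def fr_layout(net: SymptomNetwork, seed: int = 0, iterations: int = 200) -> dict[str, np.ndarray]:
    """Force-directed (Fruchterman–Reingold) coordinates on |weights|.

    Coordinates are centred on their centroid, so strongly connected nodes
    sit near the origin.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.labels)
    for i in range(net.p):
        for j in range(i + 1, net.p):
            if net.weights[i, j] != 0.0:
                g.add_edge(net.labels[i], net.labels[j], weight=abs(float(net.weights[i, j])))
    pos = nx.spring_layout(g, seed=seed, iterations=iterations, weight="weight")
    coords = np.array([pos[v] for v in net.labels], dtype=float)
    coords -= coords.mean(axis=0)
    return {lab: coords[k] for k, lab in enumerate(net.labels)}


def run_pipeline(
    input_path: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
    comparison_input: str | Path | pd.DataFrame | None = None,
) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``."""
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    seed_edges, seed_cs, seed_dag, seed_nct = (int(s.generate_state(1)[0] % 2**31) for s in seeds)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                log.append(f"[{name}] FAILED: {exc}")
                (out / "pipeline.log").write_text("\n".join(log) + "\n")
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # ---- data prep
    if isinstance(input_path, pd.DataFrame):
        data = prep.validate_likert(input_path, level_max=cfg.level_max)
    else:
        data = stage("read")(lambda: prep.read_likert_csv(input_path, level_max=cfg.level_max))
    if cfg.inclusion_min_total is not None:
        from .synth import apply_inclusion_filter

        before = len(data)
        data = apply_inclusion_filter(data, cfg.inclusion_min_total)
        log.append(f"[filter] total>={cfg.inclusion_min_total}: kept {len(data)}/{before} rows")

    desc = stage("descriptives")(lambda: prep.descriptive_stats(data))
    alpha = stage("reliability")(lambda: prep.cronbach_alpha(data))
    log.append(f"[reliability] cronbach_alpha={alpha.alpha:.3f} (p={alpha.n_items}, n={alpha.n})")
    ks = stage("ks")(lambda: prep.ks_normality(data))
    log.append(f"[ks] max p-value {ks['p_value'].max():.2e} -> rank-based correlations")
    overlap = stage("overlap")(lambda: prep.overlap_screen(data))
    log.append(f"[overlap] flagged pairs: {overlap.flagged_pairs or 'none'}")

    # ---- network
    transformed = prep.nonparanormal(data)
    corr = prep.spearman_matrix(transformed)
    pd_fix = prep.ensure_positive_definite(corr)
    log.append(
        f"[pd] repaired={pd_fix.repaired} frobenius_change={pd_fix.frobenius_change:.2e}"
    )
    path = ggm.glasso_path(pd_fix.corr, n=len(data))
    sel = ggm.ebic_select(path, gamma=cfg.gamma)
    log.append(
        f"[ebic] gamma={cfg.gamma} selected lambda={path.lambdas[sel.selected]:.4f} "
        f"(index {sel.selected}/{len(path.lambdas)})"
    )
    net = ggm.partial_corr(path.precisions[sel.selected], labels=path.labels)
    ei = expected_influence(net)
    pred = ggm.predictability(data, net)
    census = edge_census(net)
    log.append(f"[network] {census['n_edges']}/{census['possible']} edges, "
               f"global strength {global_strength(net):.3f}")

    # ---- stability
    boot = stage("bootstrap")(
        lambda: stability.bootstrap_edges(data, B=cfg.edge_bootstraps, seed=seed_edges, gamma=cfg.gamma)
    )
    cs = stage("cs")(
        lambda: stability.case_drop_cs(data, B=cfg.cs_bootstraps, seed=seed_cs, gamma=cfg.gamma)
    )
    log.append(f"[stability] CS coefficient = {cs.cs}")
    edge_diff = stability.difference_test_edges(boot)
    ei_diff = stability.difference_test_ei(boot)

    # ---- communities
    spin = stage("spinglass")(lambda: community.spinglass_partition(net, seed=cfg.seed))
    walk = stage("walktrap")(lambda: community.walktrap_partition(net))
    ari = community.partition_agreement(spin, walk)
    log.append(
        f"[community] spinglass {spin.n_communities} communities, walktrap "
        f"{walk.n_communities}, ARI {ari:.2f}"
    )

    # ---- DAG
    ens = stage("dag_boot")(
        lambda: dag.bootstrap_dags(
            data,
            B=cfg.dag_bootstraps,
            seed=seed_dag,
            restarts=cfg.dag_boot_restarts,
            perturbations=cfg.dag_boot_perturbations,
        )
    )
    avg = stage("dag_avg")(lambda: dag.average_dag(ens, data))
    log.append(f"[dag] {len(avg.arcs)} arcs after averaging; score {avg.score:.1f}")

    # ---- optional two-group comparison
    nct_result = None
    if comparison_input is not None:
        if isinstance(comparison_input, pd.DataFrame):
            data_b = prep.validate_likert(comparison_input, level_max=cfg.level_max)
        else:
            data_b = prep.read_likert_csv(comparison_input, level_max=cfg.level_max)
        if cfg.inclusion_min_total is not None:
            from .synth import apply_inclusion_filter

            data_b = apply_inclusion_filter(data_b, cfg.inclusion_min_total)
        nct_result = stage("nct")(
            lambda: comparison.nct(
                data, data_b, iterations=cfg.nct_iterations, seed=seed_nct, gamma=cfg.gamma
            )
        )
        log.append(
            f"[nct] S={nct_result.s_statistic:.3f} p={nct_result.p_strength:.3f} "
            f"M={nct_result.m_statistic:.3f} p={nct_result.p_structure:.3f}"
        )

    # ---- artifacts
    item_table = desc.copy()
    item_table["expected_influence"] = ei
    item_table["predictability"] = pred
    item_table.to_csv(out / "item_table.csv", index_label="item")
    net.to_csv(out / "network.csv")
    net.to_json(out / "network.json")
    boot.summary().to_csv(out / "edge_bootstrap.csv", index=False)
    edge_diff.to_dataframe().to_csv(out / "edge_difference_test.csv")
    ei_diff.to_dataframe().to_csv(out / "ei_difference_test.csv")
    (out / "communities.json").write_text(
        json.dumps({"spinglass": spin.to_dict(), "walktrap": walk.to_dict(), "ari": ari}, indent=1)
    )
    avg.to_csv(out / "dag.csv")
    avg.to_dot(out / "dag.dot")
    cfg.to_json(out / "config.json")
    manifest = {
        "n": int(len(data)),
        "cronbach_alpha": alpha.alpha,
        "cs": cs.cs,
        "edge_census": {k: v for k, v in census.items() if k != "max_edge"},
        "max_edge": list(census["max_edge"]),
        "global_strength": global_strength(net),
        "n_dag_arcs": len(avg.arcs),
    }
    if nct_result is not None:
        manifest["nct"] = {
            "S": nct_result.s_statistic,
            "p_strength": nct_result.p_strength,
            "M": nct_result.m_statistic,
            "p_structure": nct_result.p_structure,
        }
        (out / "nct.json").write_text(json.dumps(nct_result.to_dict(), indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "pipeline.log").write_text("\n".join(log) + "\n")

    return {
        "data": data,
        "network": net,
        "expected_influence": ei,
        "predictability": pred,
        "census": census,
        "bootstrap": boot,
        "cs": cs,
        "spinglass": spin,
        "walktrap": walk,
        "dag": avg,
        "nct": nct_result,
        "log": log,
    }
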