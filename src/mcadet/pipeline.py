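"""The end-to-end feature-selection pipeline.

Chains the stages: fuzzy coding and correspondence model -> MCA -> SNN
graph and multi-resolution Leiden clustering -> per-run distance-rank
log-ratio statistic -> Monte-Carlo null testing with the p > 0.9 filter and
Benjamini-Hochberg selection (``pvalue`` mode), or top-gamma selection on
the aggregated statistic (``topgamma`` mode).  Everything is deterministic
given the configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import graph_cluster, mca, null_test, preprocess, rank_select

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Tunable parameters of a pipeline run (defaults are the method's)."""

    K: int = 60
    knn_fraction: float = 0.01
    knn_floor: int = 10
    resolutions: list[float] = field(default_factory=graph_cluster.default_resolutions)
    T: int = 20_000
    alpha: float = 0.05
    filter_threshold: float = 0.9
    mode: str = "pvalue"       # "pvalue" or "topgamma"
    gamma: int | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("pvalue", "topgamma"):
            raise ValueError(f"mode must be 'pvalue' or 'topgamma', got {self.mode!r}")
        if self.mode == "topgamma" and self.gamma is None:
            raise ValueError("topgamma mode requires gamma")


@dataclass
class PipelineResult:
    """Selection outcome plus the intermediate quantities worth keeping."""

    selection: null_test.SelectionResult
    embedding: mca.MCAEmbedding
    runs: list[graph_cluster.ClusteringRun]
    cluster_counts: list[int]           # d_t per retained run
    dropped_genes: list[str]
    config: RunConfig

    @property
    def selected_genes(self) -> set[str]:
        sel = np.asarray(self.selection.selected)
        return {g for g, s in zip(self.selection.gene_ids, sel) if s}


def run_pipeline(counts: preprocess.CountMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Run the full feature-selection pipeline on a count matrix."""
    config = config or RunConfig()

    retained = preprocess.drop_degenerate_genes(counts)
    dropped = sorted(set(counts.gene_ids) - set(retained.gene_ids))
    Z, m1, m2 = preprocess.fuzzy_code(retained)
    model = preprocess.build_correspondence(Z, m1, m2, retained.gene_ids, retained.cell_ids)
    residuals = preprocess.pearson_residuals(model)

    n, p = retained.n_cells, retained.n_genes
    K = min(config.K, min(n, 2 * p) - 1)
    if K < config.K:
        logger.info("clamping K from %d to %d for a %d x %d input", config.K, K, n, p)
    emb = mca.decompose(residuals, model, K=K, seed=config.seed)

    k = graph_cluster.neighbor_count(n, config.knn_fraction, config.knn_floor)
    graph = graph_cluster.build_snn_graph(emb.Phi, k)
    runs = graph_cluster.leiden_partitions(graph, config.resolutions, seed=config.seed)
    logger.info(
        "k=%d; cluster counts per resolution: %s",
        k,
        {r.resolution: r.n_clusters for r in runs},
    )

    profiles: list[rank_select.RankProfile] = []
    cluster_counts: list[int] = []
    kept_runs: list[graph_cluster.ClusteringRun] = []
    for run in runs:
        if run.n_clusters < 2:
            logger.warning(
                "resolution %.2f produced a single cluster; run skipped", run.resolution
            )
            continue
        profiles.append(rank_select.profile_run(emb.Phi, emb.Gplus, run.labels))
        cluster_counts.append(run.n_clusters)
        kept_runs.append(run)
    if not profiles:
        raise RuntimeError("every clustering run produced a single cluster; cannot rank genes")
    v_agg = rank_select.aggregate_runs(profiles)

    if config.mode == "topgamma":
        idx = rank_select.select_top(v_agg, int(config.gamma))
        selected = np.zeros(p, dtype=bool)
        selected[idx] = True
        selection = null_test.SelectionResult(
            gene_ids=retained.gene_ids,
            v_agg=v_agg,
            p_values=np.full(p, np.nan),
            q_values=np.full(p, np.nan),
            selected=selected,
            alpha=config.alpha,
            filter_threshold=config.filter_threshold,
        )
    else:
        spec = null_test.NullSpec(p=p, ds=cluster_counts, T=config.T, seed=config.seed)
        samples = null_test.mc_null_sample(spec)
        pvals = null_test.pvalues(v_agg, samples)
        selection = null_test.bh_select(
            pvals,
            alpha=config.alpha,
            filter_threshold=config.filter_threshold,
            v_agg=v_agg,
            gene_ids=retained.gene_ids,
        )

    return PipelineResult(
        selection=selection,
        embedding=emb,
        runs=kept_runs,
        cluster_counts=cluster_counts,
        dropped_genes=dropped,
        config=config,
    )
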