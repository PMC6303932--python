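"""End-to-end orchestration: simulation benchmarks and data application.

``run_benchmark`` sweeps a scenario grid (topology x size x DE pattern x
effect size x sample size), simulates replicates, runs both the coherent
procedure and the network-naive baseline on each, and collects the six
evaluation metrics in a long-format table.  Runs are deterministic given a
seed — each (scenario, replicate) cell derives its own child seed — and
resumable: completed cells found in an existing output table are skipped.

``run_application`` is the workflow for user-supplied data: intersect the
expression matrix and network gene sets (collapsing duplicate gene symbols
by per-sample mean), run CoNE and the baseline, and report the component
structure, the proportions of up-regulated genes and inducing links, and
optional gene-set enrichment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .metrics import GeneSetCollection, MetricSet, enrichment, subnetwork_metrics, write_enrichment_tsv
from .network import Relationship, SignedNetwork, Subnetwork, connected_components, remove_isolated
from .procedure import ConeResult, run_cone
from .simulate import DEPatternConfig, GraphConfig, simulate_dataset
from .stats import (
    DesignSpec,
    ExpressionMatrix,
    attach_qvalues,
    baseline_de_subnetwork,
    fit_gene_models,
    stats_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["Scenario", "default_grid", "run_benchmark", "run_application", "ApplicationReport"]


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation design."""

    topology: str  # "exponential_er" | "scale_free_ba"
    v: int
    pattern: str  # "null" | "scattered" | "modular"
    fraction: float
    n_modules: int
    d: float
    n: int

    @property
    def scenario_id(self) -> str:
        return (
            f"{self.topology}-v{self.v}-{self.pattern}"
            f"-f{self.fraction:g}-k{self.n_modules}-d{self.d:g}-n{self.n}"
        )

    def graph_config(self) -> GraphConfig:
        if self.topology == "exponential_er":
            return GraphConfig(family="exponential_er", v=self.v, e=4 * self.v)
        return GraphConfig(family="scale_free_ba", v=self.v, power=1.0, m=2)

    def pattern_config(self) -> DEPatternConfig:
        if self.pattern == "null":
            return DEPatternConfig(pattern="null", fraction=0.0, d=self.d)
        return DEPatternConfig(
            pattern=self.pattern,
            fraction=self.fraction,
            n_modules=self.n_modules,
            d=self.d,
        )


#: the seven DE patterns of the small-graph design: null, scattered at
#: 1% / 10%, one module at 1% / 10%, three modules at 3% / 30%.
SMALL_GRAPH_PATTERNS: List[Tuple[str, float, int]] = [
    ("null", 0.0, 1),
    ("scattered", 0.01, 1),
    ("scattered", 0.10, 1),
    ("modular", 0.01, 1),
    ("modular", 0.10, 1),
    ("modular", 0.03, 3),
    ("modular", 0.30, 3),
]

#: large-graph design: three-module cases use 1% / 10% as well.
LARGE_GRAPH_PATTERNS: List[Tuple[str, float, int]] = [
    ("null", 0.0, 1),
    ("scattered", 0.01, 1),
    ("scattered", 0.10, 1),
    ("modular", 0.01, 1),
    ("modular", 0.10, 1),
    ("modular", 0.01, 3),
    ("modular", 0.10, 3),
]


def default_grid(
    sizes: Sequence[int] = (500, 2000),
    sample_sizes: Sequence[int] = (8, 16, 32, 64),
    effect_sizes: Sequence[float] = (4.0, 8.0, 16.0, 32.0),
    topologies: Sequence[str] = ("exponential_er", "scale_free_ba"),
) -> List[Scenario]:
    """The full factorial simulation design (ER/BA x v x 7 patterns x d x n)."""
    scenarios = []
    for topology in topologies:
        for v in sizes:
            patterns = SMALL_GRAPH_PATTERNS if v <= 500 else LARGE_GRAPH_PATTERNS
            for pattern, fraction, k in patterns:
                for d in effect_sizes:
                    for n in sample_sizes:
                        scenarios.append(Scenario(topology, v, pattern, fraction, k, d, n))
    return scenarios


def _evaluate_methods(dataset, alpha: float) -> Dict[str, MetricSet]:
    truth = dataset.truth
    design = DesignSpec.two_group(dataset.class_labels)
    cone_result = run_cone(dataset.expression, truth.network, design, alpha=alpha)
    baseline = baseline_de_subnetwork(truth.network, cone_result.gene_stats, alpha)
    return {
        "cone": subnetwork_metrics(truth.truth_subnetwork, cone_result.subnetwork, truth.network),
        "baseline": subnetwork_metrics(truth.truth_subnetwork, baseline, truth.network),
    }


def run_benchmark(
    scenarios: Sequence[Scenario],
    replicates: int,
    seed: int,
    alpha: float = 0.05,
    out_path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Run the benchmark over ``scenarios`` x ``replicates`` x 2 methods.

    Returns (and optionally appends to ``out_path``) a long-format table
    with one row per (scenario, replicate, method).  When ``out_path``
    exists, rows already present are skipped, making interrupted runs
    resumable without recomputation; the per-cell seeds depend only on
    (seed, scenario index, replicate), so resumed and fresh runs agree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    done: set = set()
    existing: Optional[pd.DataFrame] = None
    if out_path is not None and Path(out_path).exists():
        existing = pd.read_csv(out_path, sep="\t")
        done = set(zip(existing["scenario"], existing["replicate"], existing["method"]))
    rows: List[dict] = []
    for s_idx, scenario in enumerate(scenarios):
        for rep in range(replicates):
            if all((scenario.scenario_id, rep, m) in done for m in ("cone", "baseline")):
                continue
            cell_seed = np.random.SeedSequence(seed, spawn_key=(s_idx, rep))
            dataset = simulate_dataset(
                scenario.graph_config(), scenario.pattern_config(), scenario.n, seed=cell_seed
            )
            for method, ms in _evaluate_methods(dataset, alpha).items():
                if (scenario.scenario_id, rep, method) in done:
                    continue
                rows.append(
                    {
                        "scenario": scenario.scenario_id,
                        "topology": scenario.topology,
                        "v": scenario.v,
                        "pattern": scenario.pattern,
                        "fraction": scenario.fraction,
                        "n_modules": scenario.n_modules,
                        "d": scenario.d,
                        "n": scenario.n,
                        "replicate": rep,
                        "method": method,
                        **{k: (np.nan if v is None else v) for k, v in ms.as_dict().items()},
                    }
                )
    table = pd.DataFrame(rows)
    if existing is not None and not existing.empty:
        table = pd.concat([existing, table], ignore_index=True)
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False)
    return table


@dataclass
class ApplicationReport:
    """Summary bundle for a CoNE analysis of user-supplied data."""

    cone: ConeResult
    baseline: Subnetwork
    n_common_genes: int
    n_duplicate_rows_collapsed: int
    n_network_genes_dropped: int
    component_sizes: List[int]
    proportion_upregulated: Optional[float]
    proportion_inducing_subnetwork: Optional[float]
    proportion_inducing_universe: float
    enrichment_cone: Optional[list] = None
    enrichment_baseline: Optional[list] = None

    def summary(self) -> Dict[str, object]:
        sub = self.cone.subnetwork
        return {
            "n_common_genes": self.n_common_genes,
            "n_duplicate_rows_collapsed": self.n_duplicate_rows_collapsed,
            "n_network_genes_dropped": self.n_network_genes_dropped,
            "subnetwork_genes": sub.n_genes,
            "subnetwork_links": sub.n_links,
            "component_sizes": self.component_sizes,
            "proportion_upregulated": self.proportion_upregulated,
            "proportion_inducing_subnetwork": self.proportion_inducing_subnetwork,
            "proportion_inducing_universe": self.proportion_inducing_universe,
            "baseline_genes": self.baseline.n_genes,
            "baseline_links": self.baseline.n_links,
            "removed": self.cone.removal_counts(),
            "alpha": self.cone.alpha,
            "fdr_scope": self.cone.fdr_scope,
        }


def _proportion_inducing(links) -> Optional[float]:
    links = list(links)
    if not links:
        return None
    inducing = sum(1 for l in links if l.relationship is Relationship.NON_INHIBITING)
    return inducing / len(links)


def run_application(
    expr: ExpressionMatrix,
    network: SignedNetwork,
    design: DesignSpec,
    alpha: float = 0.05,
    gene_sets: Optional[GeneSetCollection] = None,
    fdr_scope: str = "all_genes",
    moderate: bool = False,
) -> ApplicationReport:
    """CoNE + baseline analysis of an expression matrix against a network."""
    n_dup = int(expr.values.index.duplicated().sum())
    if n_dup:
        logger.info("collapsing %d duplicate gene row(s) by per-sample mean", n_dup)
        expr = expr.collapse_duplicate_genes()
    common = set(expr.genes) & network.genes
    if not common:
        net_examples = sorted(map(str, list(network.genes)[:5]))
        expr_examples = sorted(map(str, expr.genes[:5]))
        raise ValueError(
            "no genes shared between expression data and network; "
            f"network identifiers look like {net_examples}, "
            f"expression identifiers look like {expr_examples}"
        )
    n_dropped = len(network.genes - common)

    result = run_cone(expr, network, design, alpha=alpha, fdr_scope=fdr_scope, moderate=moderate)
    baseline = baseline_de_subnetwork(network.restricted_to(common), result.gene_stats, alpha)

    sub = result.subnetwork
    comps = connected_components(sub)
    deltas = result.deltas
    up = [g for g in sub.genes if deltas.get(g, 0.0) > 0]
    prop_up = len(up) / sub.n_genes if sub.n_genes else None

    report = ApplicationReport(
        cone=result,
        baseline=baseline,
        n_common_genes=len(common),
        n_duplicate_rows_collapsed=n_dup,
        n_network_genes_dropped=n_dropped,
        component_sizes=[c.n_genes for c in comps],
        proportion_upregulated=prop_up,
        proportion_inducing_subnetwork=_proportion_inducing(sub.links),
        proportion_inducing_universe=_proportion_inducing(network.links) or 0.0,
    )
    if gene_sets is not None:
        collection = gene_sets.restrict_universe(common)
        report.enrichment_cone = enrichment(sub.genes, collection, alpha)
        report.enrichment_baseline = enrichment(baseline.genes, collection, alpha)
    return report


def write_application_report(
    report: ApplicationReport,
    out_prefix: Union[str, Path],
) -> None:
    """Write stats TSV, subnetwork edge list + GraphML, and a JSON summary."""
    from .network import write_graphml, write_network_tsv
    from .stats import write_stats_tsv

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_stats_tsv(report.cone.gene_stats, f"{prefix}_stats.tsv")
    write_network_tsv(report.cone.subnetwork, f"{prefix}_subnetwork.tsv")
    write_graphml(report.cone.subnetwork, report.cone.deltas, f"{prefix}_subnetwork.graphml")
    Path(f"{prefix}_report.json").write_text(json.dumps(report.summary(), indent=1))
    if report.enrichment_cone is not None:
        write_enrichment_tsv(report.enrichment_cone, f"{prefix}_enrichment_cone.tsv")
    if report.enrichment_baseline is not None:
        write_enrichment_tsv(report.enrichment_baseline, f"{prefix}_enrichment_baseline.tsv")
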