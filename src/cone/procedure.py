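"""The Coherent Network Expression (CoNE) procedure.

CoNE composes the statistics layer with the coherence primitives in four
steps:

1. fit the per-gene linear models over all network genes;
2. extract the contrast estimates ``delta_j(gamma)``;
3. classify every link as coherent or incoherent, remove incoherent links
   and any genes left isolated;
4. assess significance with Benjamini-Hochberg FDR control at ``alpha``,
   drop non-significant genes and their links, and remove newly isolated
   genes.

The result is the estimated coherent subnetwork together with a provenance
record of everything removed at each step.

The module also implements the differential link score
``(X_j^1 + w * X_k^1) - (X_j^0 + w * X_k^0)``, a magnitude-of-coherence
measure kept here as a diagnostic: a link whose genes both change by +2
scores 4 regardless of whether the per-pair scores are constant (variance
0) or spread out, which is why CoNE tests coherence and per-gene
significance instead of the score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Set

import numpy as np

from .network import (
    Gene,
    LinkKey,
    SignedLink,
    SignedNetwork,
    Subnetwork,
    coherence_filter,
    remove_isolated,
)
from .stats import (
    DesignSpec,
    ExpressionMatrix,
    GeneContrastStats,
    attach_qvalues,
    bh_adjust,
    fit_gene_models,
    moderate_variances,
    significant_genes,
)

logger = logging.getLogger(__name__)

__all__ = ["ConeResult", "LinkScoreResult", "run_cone", "differential_link_score"]

FDR_SCOPES = ("all_genes", "coherent_genes")


@dataclass
class ConeResult:
    """Estimated coherent subnetwork plus full removal provenance."""

    subnetwork: Subnetwork
    gene_stats: List[GeneContrastStats]
    link_labels: Dict[LinkKey, str]  # "coherent" | "incoherent"
    removed: Dict[str, list]
    alpha: float
    fdr_scope: str

    @property
    def deltas(self) -> Dict[Hashable, float]:
        return {s.gene: s.estimate for s in self.gene_stats}

    def removal_counts(self) -> Dict[str, int]:
        return {step: len(items) for step, items in self.removed.items()}


def run_cone(
    expr: ExpressionMatrix,
    network: SignedNetwork,
    design: DesignSpec,
    alpha: float = 0.05,
    fdr_scope: str = "all_genes",
    moderate: bool = False,
) -> ConeResult:
    """Run the four-step CoNE procedure.

    Parameters
    ----------
    expr, network, design
        Log-expression matrix, signed universe network, and design/contrast.
        The analysis runs on the genes common to ``expr`` and ``network``;
        an empty intersection is an error.
    alpha
        FDR control threshold (default 0.05).
    fdr_scope
        ``"all_genes"`` computes BH q-values over every analysed network
        gene before intersecting with the coherent subnetwork (the default,
        keeping q-values independent of the filter); ``"coherent_genes"``
        restricts BH to genes surviving the coherence step.
    moderate
        Apply empirical-Bayes variance moderation before testing.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if fdr_scope not in FDR_SCOPES:
        raise ValueError(f"fdr_scope must be one of {FDR_SCOPES}, got {fdr_scope!r}")

    expr_genes = set(expr.genes)
    common = network.genes & expr_genes
    if not common:
        examples = sorted(map(str, list(network.genes)[:3]))
        raise ValueError(
            f"no genes shared between expression data and network "
            f"(network examples: {examples})"
        )
    dropped_net_genes = sorted(map(str, network.genes - expr_genes))
    net = network.restricted_to(common) if dropped_net_genes else network
    if dropped_net_genes:
        logger.info("dropped %d network gene(s) absent from expression data", len(dropped_net_genes))

    # steps 1-2: linear models and contrast estimates over network genes
    sub_expr = expr.subset_genes(common)
    stats = fit_gene_models(sub_expr, design)
    if moderate:
        stats = moderate_variances(stats)
    deltas = {s.gene: s.estimate for s in stats}

    # step 3: coherence classification, incoherent links out, isolated out
    link_labels: Dict[LinkKey, str] = {}
    coherent = coherence_filter(net, deltas)
    for link in net.links:
        link_labels[link.key] = "coherent" if link.key in coherent.link_keys else "incoherent"
    incoherent_links = sorted(k for k, v in link_labels.items() if v == "incoherent")
    isolated_after_coherence = sorted(map(str, net.genes - coherent.genes))

    # step 4: FDR control, then prune and clean up isolation again
    if fdr_scope == "all_genes":
        stats = attach_qvalues(stats)
    else:
        in_scope = [s for s in stats if s.gene in coherent.genes]
        out_scope = [s for s in stats if s.gene not in coherent.genes]
        stats = attach_qvalues(in_scope) + out_scope
    sig = significant_genes([s for s in stats if s.q_value is not None], alpha)

    kept_genes = coherent.genes & sig
    kept_links = {
        k for k in coherent.link_keys
        if net.get_link(k).source in kept_genes and net.get_link(k).target in kept_genes
    }
    pruned = Subnetwork(net, kept_genes, kept_links)
    final = remove_isolated(pruned)

    removed = {
        "network_genes_not_in_expression": dropped_net_genes,
        "incoherent_links": incoherent_links,
        "isolated_after_coherence": isolated_after_coherence,
        "nonsignificant_genes": sorted(map(str, coherent.genes - sig)),
        "links_lost_to_significance": sorted(coherent.link_keys - kept_links),
        "isolated_after_significance": sorted(map(str, pruned.genes - final.genes)),
    }
    return ConeResult(
        subnetwork=final,
        gene_stats=stats,
        link_labels=link_labels,
        removed=removed,
        alpha=alpha,
        fdr_scope=fdr_scope,
    )


@dataclass
class LinkScoreResult:
    """Per-pair differential link scores for one link."""

    link: SignedLink
    per_sample_scores: np.ndarray
    mean_score: float
    score_variance: Optional[float]  # None when a single pair makes it undefined


def differential_link_score(
    expr_case0: Mapping[Gene, Sequence[float]],
    expr_case1: Mapping[Gene, Sequence[float]],
    link: SignedLink,
) -> LinkScoreResult:
    """Differential link score for paired case-0/case-1 observations.

    For each pair ``i`` the score is
    ``(X_j^1[i] + w * X_k^1[i]) - (X_j^0[i] + w * X_k^0[i])`` with
    ``w`` the link weight; samples are paired by index order within each
    case.  The sample variance (ddof=1) is reported alongside the mean; it
    is flagged ``None`` for a single pair.
    """
    j, k = link.source, link.target
    for gene in (j, k):
        if gene not in expr_case0 or gene not in expr_case1:
            raise KeyError(f"expression values missing for gene {gene!r}")
    x0j = np.asarray(expr_case0[j], dtype=float)
    x0k = np.asarray(expr_case0[k], dtype=float)
    x1j = np.asarray(expr_case1[j], dtype=float)
    x1k = np.asarray(expr_case1[k], dtype=float)
    lengths = {arr.size for arr in (x0j, x0k, x1j, x1k)}
    if len(lengths) != 1:
        raise ValueError(f"unequal numbers of paired observations: {sorted(lengths)}")
    n = lengths.pop()
    if n < 1:
        raise ValueError("at least one case-0/case-1 pair is required")
    w = link.weight
    scores = (x1j + w * x1k) - (x0j + w * x0k)
    variance = float(np.var(scores, ddof=1)) if n > 1 else None
    return LinkScoreResult(
        link=link,
        per_sample_scores=scores,
        mean_score=float(scores.mean()),
        score_variance=variance,
    )
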