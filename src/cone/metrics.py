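"""Evaluation of estimated subnetworks and gene-set enrichment.

Gene- and link-level sensitivity, specificity, and precision compare an
estimated subnetwork ``S_hat`` to a truth subnetwork ``S`` inside a
universe network ``G``:

    SE_genes = |V(S_hat) & V(S)| / |V(S)|
    SP_genes = 1 - |V(S_hat) \\ V(S)| / |V(G) \\ V(S)|
    PR_genes = |V(S_hat) & V(S)| / |V(S_hat)|

and analogously for links.  A metric whose denominator set is empty is
*undefined* (None) rather than forced to 0 or 1, so replicate summaries are
not biased by degenerate replicates.

Gene-set enrichment is a generic one-sided Fisher's exact test on the 2x2
membership table over a background universe, with Benjamini-Hochberg
control across the tested sets; collections are read from GMT files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .network import Gene, SignedNetwork, Subnetwork
from .stats import bh_adjust

__all__ = [
    "MetricSet",
    "GeneSetCollection",
    "EnrichmentResult",
    "subnetwork_metrics",
    "enrichment",
    "replicate_summary",
    "read_gmt",
    "metrics_frame",
]

METRIC_NAMES = ("se_genes", "sp_genes", "pr_genes", "se_links", "sp_links", "pr_links")


@dataclass(frozen=True)
class MetricSet:
    """Six evaluation metrics; None marks an undefined (empty-denominator) value."""

    se_genes: Optional[float]
    sp_genes: Optional[float]
    pr_genes: Optional[float]
    se_links: Optional[float]
    sp_links: Optional[float]
    pr_links: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    @property
    def gene_fdp(self) -> Optional[float]:
        """Gene false-discovery proportion, 1 - PR_genes (None if undefined)."""
        return None if self.pr_genes is None else 1.0 - self.pr_genes


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def subnetwork_metrics(
    truth: Subnetwork,
    estimate: Subnetwork,
    universe: SignedNetwork,
) -> MetricSet:
    """Sensitivity/specificity/precision of ``estimate`` against ``truth``.

    Link identity follows the universe's directedness: undirected universes
    compare unordered pairs.  Raises if either subnetwork is not contained
    in the universe.
    """
    for name, sub in (("truth", truth), ("estimate", estimate)):
        if not (sub.genes <= universe.genes and sub.link_keys <= universe.link_keys):
            raise ValueError(f"{name} subnetwork is not contained in the universe network")

    vs, vh, vg = truth.genes, estimate.genes, universe.genes
    es, eh, eg = truth.link_keys, estimate.link_keys, universe.link_keys
    return MetricSet(
        se_genes=_ratio(len(vh & vs), len(vs)),
        sp_genes=None if len(vg - vs) == 0 else 1.0 - len(vh - vs) / len(vg - vs),
        pr_genes=_ratio(len(vh & vs), len(vh)),
        se_links=_ratio(len(eh & es), len(es)),
        sp_links=None if len(eg - es) == 0 else 1.0 - len(eh - es) / len(eg - es),
        pr_links=_ratio(len(eh & es), len(eh)),
    )


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe (GMT semantics)."""

    sets: Dict[str, Set[Hashable]]
    descriptions: Dict[str, str]
    universe: Set[Hashable]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("background universe is empty")
        restricted = {}
        for name, genes in self.sets.items():
            inside = set(genes) & self.universe
            if not inside:
                warnings.warn(f"gene set {name!r} has no genes in the universe; dropped", stacklevel=2)
                continue
            restricted[name] = inside
        self.sets = restricted

    def restrict_universe(self, universe: Iterable[Hashable]) -> "GeneSetCollection":
        return GeneSetCollection(dict(self.sets), dict(self.descriptions), set(universe))


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    overlap: int
    set_size: int
    query_size: int
    p_value: float
    q_value: float
    covered_fraction: float
    significant: bool


def enrichment(
    query_genes: Iterable[Hashable],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """One-sided over-representation test per gene set.

    For each set the 2x2 table (in-query/in-set versus complements over the
    universe) gives a hypergeometric tail p-value — P(overlap >= observed)
    — which is exactly Fisher's one-sided test; q-values are BH over all
    tested sets.  Query genes outside the universe are dropped with a
    warning.  ``covered_fraction`` is overlap / set size in the universe.
    """
    universe = collection.universe
    query = set(query_genes)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped", stacklevel=2
        )
        query &= universe
    m = len(universe)
    names = sorted(collection.sets)
    p_values = []
    rows = []
    for name in names:
        gene_set = collection.sets[name]
        a = len(query & gene_set)
        p = float(hypergeom.sf(a - 1, m, len(gene_set), len(query)))
        p_values.append(min(p, 1.0))
        rows.append((name, a, len(gene_set)))
    q_values = bh_adjust(p_values) if p_values else np.array([])
    results = [
        EnrichmentResult(
            name=name,
            overlap=a,
            set_size=size,
            query_size=len(query),
            p_value=p,
            q_value=float(q),
            covered_fraction=a / size,
            significant=bool(q <= alpha),
        )
        for (name, a, size), p, q in zip(rows, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.name))
    return results


def replicate_summary(metric_sets: Sequence[MetricSet]) -> pd.DataFrame:
    """Median/IQR/mean per metric across replicates.

    Undefined values are excluded from the summaries; the table reports how
    many replicates were defined and undefined for each metric.
    """
    if not metric_sets:
        raise ValueError("need at least one replicate")
    rows = []
    for name in METRIC_NAMES:
        values = [getattr(ms, name) for ms in metric_sets]
        defined = np.array([x for x in values if x is not None], dtype=float)
        if defined.size:
            q1, med, q3 = np.percentile(defined, [25, 50, 75])
            mean = defined.mean()
        else:
            q1 = med = q3 = mean = np.nan
        rows.append(
            {
                "metric": name,
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
                "mean": mean,
                "n_defined": defined.size,
                "n_undefined": len(values) - defined.size,
            }
        )
    return pd.DataFrame(rows).set_index("metric")


# ---------------------------------------------------------------------------
# input / output


def read_gmt(path: Union[str, Path], universe: Iterable[Hashable]) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene...)."""
    sets: Dict[str, Set[Hashable]] = {}
    descriptions: Dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, set(universe))


def metrics_frame(metric_sets: Sequence[MetricSet], **id_columns) -> pd.DataFrame:
    """Long-format frame of metric sets, one row per replicate."""
    records = []
    for i, ms in enumerate(metric_sets):
        row = {"replicate": i, **{k: v for k, v in id_columns.items()}}
        row.update(ms.as_dict())
        records.append(row)
    return pd.DataFrame(records)


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "set": [r.name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "covered_fraction": [r.covered_fraction for r in results],
            "significant": [r.significant for r in results],
        }
    ).to_csv(path, sep="\t", index=False)
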