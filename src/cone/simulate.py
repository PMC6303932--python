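"""Gaussian-graphical-model simulation of coherent differential expression.

The generator emulates the study conditions under which coherent-subnetwork
detection is evaluated:

* a random undirected network — exponential Erdős–Rényi (``e`` links drawn
  uniformly from the ``v(v-1)/2`` unique pairs) or scale-free
  Barabási–Albert (preferential attachment, ``m`` links per new node,
  attachment probability proportional to ``degree**power + 1``);
* link relationships drawn non-inhibiting with probability
  ``p ~ U(0.72, 0.85)`` per graph, mirroring the observed proportion of
  activating regulators in eukaryotes;
* baseline mean log-expression ``mu0 ~ U(-d, d)`` per gene, and one of
  three differential-expression patterns: *null* (``mu1 = mu0``),
  *scattered* (a random gene subset gets an added ``U(-d, d)`` offset), or
  *modular* (connected modules grown by neighbourhood sampling, with signs
  ``psi`` propagated along link weights so every spanning link is coherent);
* a precision matrix built on the network skeleton — ``U(0.5, 1)`` weights,
  +1 coupling boost off the truth boundary, sign ``-w_jk``, and a diagonal
  shift ``lambda = lambda1 + lambda2`` fixing positive definiteness and a
  condition number equal to the gene count ``v``;
* log-expression sampled from ``N(mu_c, Sigma)``, ``c = 0, 1``, with half
  of the samples in each class.

All randomness flows through :class:`numpy.random.Generator` objects spawned
from a single seed, so identical seeds give bit-identical datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .network import (
    BoundarySet,
    Gene,
    Relationship,
    SignedLink,
    SignedNetwork,
    Subnetwork,
    boundary,
    is_coherent,
)
from .stats import ExpressionMatrix

__all__ = [
    "GraphConfig",
    "DEPatternConfig",
    "SimulationTruth",
    "CovarianceModel",
    "SimulatedDataset",
    "generate_graph",
    "assign_link_signs",
    "baseline_means",
    "scattered_de",
    "grow_module",
    "coherent_de",
    "modular_de",
    "build_covariance",
    "sample_dataset",
    "simulate_dataset",
]

GRAPH_FAMILIES = ("exponential_er", "scale_free_ba")
DE_PATTERNS = ("null", "scattered", "modular")


@dataclass
class GraphConfig:
    """Random-graph family and size.

    Defaults are the small-graph setting: an Erdős–Rényi graph with
    ``v = 500`` genes and ``e = 2000`` links; the scale-free alternative
    uses ``(v, power, m) = (500, 1, 2)``.
    """

    family: str = "exponential_er"
    v: int = 500
    e: int = 2000
    power: float = 1.0
    m: int = 2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in GRAPH_FAMILIES:
            raise ValueError(f"family must be one of {GRAPH_FAMILIES}, got {self.family!r}")
        if self.v < 2:
            raise ValueError("need at least two genes")
        if self.family == "exponential_er":
            max_e = self.v * (self.v - 1) // 2
            if not 0 < self.e <= max_e:
                raise ValueError(f"e must be in (0, {max_e}] for v={self.v}, got {self.e}")
        else:
            if self.m < 1:
                raise ValueError("m must be >= 1")
            if self.power <= 0:
                raise ValueError("power must be > 0")


@dataclass
class DEPatternConfig:
    """Differential-expression pattern.

    ``d`` is the effect half-range in log-expression units; offsets are
    uniform on ``(-d, d)`` (scattered) or ``psi * U(0, d)`` (modular), so
    the mean absolute differential expression is ``d / 2`` (d = 4, 8, 16,
    32 correspond to mean |dE| = 2, 4, 8, 16).
    """

    pattern: str = "modular"
    fraction: float = 0.10
    n_modules: int = 1
    d: float = 8.0

    def __post_init__(self) -> None:
        if self.pattern not in DE_PATTERNS:
            raise ValueError(f"pattern must be one of {DE_PATTERNS}, got {self.pattern!r}")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated replicate."""

    network: SignedNetwork
    truth_subnetwork: Subnetwork
    psi: Dict[Gene, int]
    mu0: pd.Series
    mu1: pd.Series
    boundary: BoundarySet
    inducing_proportion: float
    pattern: str = "modular"
    module_genes: List[List[Gene]] = field(default_factory=list)

    @property
    def deltas(self) -> pd.Series:
        return self.mu1 - self.mu0


@dataclass
class CovarianceModel:
    """Precision/covariance pair consistent with the network skeleton."""

    genes: List[Gene]
    precision: np.ndarray
    covariance: np.ndarray
    lambda1: float
    lambda2: float
    condition_number: float


@dataclass
class SimulatedDataset:
    """Sampled log-expression with class labels and the generating truth."""

    expression: ExpressionMatrix
    class_labels: pd.Series
    n: int
    truth: SimulationTruth
    covariance: Optional[CovarianceModel] = None


def _as_rng(seed: Union[None, int, np.random.Generator, np.random.SeedSequence]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gene_names(v: int) -> List[str]:
    width = max(4, len(str(v - 1)))
    return [f"g{i:0{width}d}" for i in range(v)]


# ---------------------------------------------------------------------------
# random graphs


def _er_edges(v: int, e: int, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """``e`` unordered pairs drawn uniformly without replacement from the
    ``v(v-1)/2`` possible links."""
    total = v * (v - 1) // 2
    chosen = rng.choice(total, size=e, replace=False)
    edges = []
    for t in np.sort(chosen):
        # row i of the lexicographic pair enumeration (i < j)
        i = int((2 * v - 1 - math.sqrt((2 * v - 1) ** 2 - 8 * t)) // 2)
        while i * (2 * v - i - 1) // 2 > t:
            i -= 1
        while (i + 1) * (2 * v - i - 2) // 2 <= t:
            i += 1
        j = t - i * (2 * v - i - 1) // 2 + i + 1
        edges.append((i, int(j)))
    return edges


def _ba_edges(v: int, power: float, m: int, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Preferential attachment: node ``t`` links to ``min(m, t)`` distinct
    earlier nodes with probability proportional to ``degree**power + 1``
    (unit zero-appeal, no multi-edges); total links = 1 + 2(v-2) for m=2."""
    degrees = np.zeros(v)
    edges: List[Tuple[int, int]] = []
    for new in range(1, v):
        k = min(m, new)
        w = degrees[:new] ** power + 1.0
        targets = rng.choice(new, size=k, replace=False, p=w / w.sum())
        for t in np.sort(targets):
            edges.append((int(t), new))
            degrees[t] += 1
            degrees[new] += 1
    return edges


def generate_graph(config: GraphConfig, seed=None) -> SignedNetwork:
    """Generate an undirected random network with unsigned (non-inhibiting)
    links; relationships are assigned separately by :func:`assign_link_signs`."""
    rng = _as_rng(seed if seed is not None else config.seed)
    names = _gene_names(config.v)
    if config.family == "exponential_er":
        idx_edges = _er_edges(config.v, config.e, rng)
    else:
        idx_edges = _ba_edges(config.v, config.power, config.m, rng)
    links = [SignedLink(names[i], names[j], Relationship.NON_INHIBITING) for i, j in idx_edges]
    return SignedNetwork(links, genes=names, directed=False)


def assign_link_signs(
    network: SignedNetwork,
    seed=None,
    p: Optional[float] = None,
) -> Tuple[SignedNetwork, float]:
    """Assign relationships: non-inhibiting with probability ``p``.

    ``p`` is drawn once per graph from ``U(0.72, 0.85)`` unless forced (the
    test hook).  Returns the signed network and the ``p`` used.
    """
    rng = _as_rng(seed)
    if p is None:
        p = float(rng.uniform(0.72, 0.85))
    links = []
    for link in network.links:
        rel = Relationship.NON_INHIBITING if rng.uniform() < p else Relationship.INHIBITING
        links.append(SignedLink(link.source, link.target, rel))
    return SignedNetwork(links, genes=network.genes, directed=False), p


# ---------------------------------------------------------------------------
# differential-expression patterns


def baseline_means(v: int, d: float, seed=None) -> np.ndarray:
    """Baseline mean log-expression: ``v`` draws from ``U(-d, d)``."""
    if d <= 0:
        raise ValueError("d must be > 0")
    rng = _as_rng(seed)
    return rng.uniform(-d, d, size=v)


def scattered_de(
    mu0: pd.Series,
    fraction: float,
    d: float,
    seed=None,
) -> Tuple[pd.Series, Set[Gene]]:
    """Scattered pattern: ``round(fraction * v)`` genes chosen uniformly
    without replacement each get an added ``U(-d, d)`` offset."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = _as_rng(seed)
    v = len(mu0)
    n_de = int(round(fraction * v))
    mu1 = mu0.copy()
    if n_de == 0:
        import warnings

        warnings.warn("fraction rounds to zero DE genes", stacklevel=2)
        return mu1, set()
    chosen = rng.choice(v, size=n_de, replace=False)
    genes = [mu0.index[i] for i in chosen]
    mu1.iloc[chosen] = mu0.iloc[chosen] + rng.uniform(-d, d, size=n_de)
    return mu1, set(genes)


def grow_module(
    network: SignedNetwork,
    target_size: int,
    excluded_genes: Iterable[Gene] = (),
    seed=None,
    max_restarts: int = 100,
) -> List[Gene]:
    """Grow a connected gene set of ``target_size`` by neighbourhood sampling.

    A seed gene is drawn uniformly; each subsequent gene is drawn uniformly
    from the neighbourhood of the current set, excluding ``excluded_genes``.
    Returned in addition order, so every gene after the first has an earlier
    neighbour.  If growth stalls the walk restarts from a fresh seed gene,
    up to ``max_restarts`` times.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    rng = _as_rng(seed)
    excluded = set(excluded_genes)
    candidates = sorted(map(str, network.genes - excluded))
    if len(candidates) < target_size:
        raise ValueError("not enough non-excluded genes to grow the module")
    for _ in range(max_restarts):
        start = candidates[int(rng.integers(len(candidates)))]
        module = [start]
        members = {start}
        while len(module) < target_size:
            frontier = sorted(
                {nb for g in module for nb in network.neighbors(g)} - members - excluded,
                key=str,
            )
            if not frontier:
                break
            nxt = frontier[int(rng.integers(len(frontier)))]
            module.append(nxt)
            members.add(nxt)
        if len(module) == target_size:
            return module
    raise RuntimeError(
        f"could not grow a connected module of size {target_size} "
        f"after {max_restarts} restarts"
    )


def coherent_de(
    network: SignedNetwork,
    module_genes: Sequence[Gene],
    mu0: pd.Series,
    d: float,
    seed=None,
) -> Tuple[pd.Series, Dict[Gene, int], Subnetwork]:
    """Coherent (modular) differential expression over one module.

    Signs ``psi`` start at +1; each gene after the first copies
    ``psi_k * w(k, j)`` from a uniformly chosen earlier linked neighbour
    ``k``, which makes the spanning link coherent by construction.  Effects
    are ``mu1_j = mu0_j + psi_j * U(0, d)``.  The truth subnetwork keeps
    every within-module link that is coherent under ``mu1 - mu0`` (the
    spanning links plus any coherent extras).
    """
    rng = _as_rng(seed)
    module = list(module_genes)
    if not module:
        raise ValueError("module is empty")
    psi: Dict[Gene, int] = {module[0]: 1}
    for idx in range(1, len(module)):
        gene = module[idx]
        earlier = [
            g for g in module[:idx]
            if network.canonical_key(g, gene) in network
            or network.canonical_key(gene, g) in network
        ]
        if not earlier:
            raise ValueError(
                f"gene {gene!r} has no earlier linked neighbour; module genes "
                "must be ordered by addition"
            )
        k = earlier[int(rng.integers(len(earlier)))]
        key = network.canonical_key(k, gene)
        link = network.get_link(key) if key in network else network.get_link(network.canonical_key(gene, k))
        psi[gene] = psi[k] * link.weight
    offsets = rng.uniform(0.0, d, size=len(module))
    mu1 = mu0.copy()
    for gene, off in zip(module, offsets):
        mu1.loc[gene] = mu0.loc[gene] + psi[gene] * off

    member_set = set(module)
    delta = mu1 - mu0
    truth_keys = {
        link.key
        for link in network.links
        if link.source in member_set
        and link.target in member_set
        and is_coherent(float(delta.loc[link.source]), float(delta.loc[link.target]), link.weight)
    }
    truth = Subnetwork(network, member_set, truth_keys)
    return mu1, psi, truth


def modular_de(
    network: SignedNetwork,
    mu0: pd.Series,
    fraction: float,
    n_modules: int,
    d: float,
    seed=None,
) -> Tuple[pd.Series, Dict[Gene, int], Subnetwork, List[List[Gene]]]:
    """Grow ``n_modules`` disjoint connected modules totalling
    ``round(fraction * v)`` genes (split as evenly as possible) and apply
    coherent differential expression to each."""
    rng = _as_rng(seed)
    v = len(mu0)
    total = int(round(fraction * v))
    if total < n_modules:
        raise ValueError(f"{total} DE genes cannot fill {n_modules} modules")
    base, rem = divmod(total, n_modules)
    sizes = [base + (1 if i < rem else 0) for i in range(n_modules)]

    mu1 = mu0.copy()
    psi: Dict[Gene, int] = {}
    modules: List[List[Gene]] = []
    all_keys: Set = set()
    all_genes: Set[Gene] = set()
    for size in sizes:
        module = grow_module(network, size, excluded_genes=all_genes, seed=rng)
        mu1_mod, psi_mod, truth_mod = coherent_de(network, module, mu1, d, seed=rng)
        mu1 = mu1_mod
        psi.update(psi_mod)
        modules.append(module)
        all_genes |= set(module)
        all_keys |= truth_mod.link_keys
    truth = Subnetwork(network, all_genes, all_keys)
    return mu1, psi, truth, modules


# ---------------------------------------------------------------------------
# covariance construction


def build_covariance(
    network: SignedNetwork,
    bnd: Optional[BoundarySet] = None,
    seed=None,
    link_weights: Optional[Mapping[Tuple[Gene, Gene], float]] = None,
) -> CovarianceModel:
    """Construct the precision/covariance pair on the network skeleton.

    Steps: (1) each link gets an i.i.d. ``U(0.5, 1)`` weight (overridable
    via ``link_weights``, the test hook); (2) +1 is added to every
    non-boundary link weight, coupling module genes more strongly to each
    other than to the rest of the network; (3) entries are multiplied by
    ``-w_jk`` so the partial-correlation sign matches the relationship
    (``rho_jk = -p_jk / sqrt(p_jj p_kk)``); (4) a shift
    ``lambda I = (lambda1 + lambda2) I`` is added, where ``-lambda1`` is
    the smallest eigenvalue of the step-3 matrix and ``lambda2`` solves
    condition number = ``v``; (5) the covariance is the inverse.
    """
    if network.n_genes == 0:
        raise ValueError("network is empty")
    rng = _as_rng(seed)
    genes = sorted(map(str, network.genes))
    index = {g: i for i, g in enumerate(genes)}
    v = len(genes)
    boundary_keys = bnd.boundary if bnd is not None else frozenset()

    a = np.zeros((v, v))
    for link in network.links:
        if link_weights is not None and link.key in link_weights:
            u = float(link_weights[link.key])
        else:
            u = float(rng.uniform(0.5, 1.0))
        if link.key not in boundary_keys:
            u += 1.0
        val = -link.weight * u
        i, j = index[str(link.source)], index[str(link.target)]
        a[i, j] = val
        a[j, i] = val

    eigvals = np.linalg.eigvalsh(a)
    lam_min, lam_max = float(eigvals[0]), float(eigvals[-1])
    lambda1 = -lam_min
    if v < 2:
        raise ValueError("condition-number scaling needs at least two genes")
    lambda2 = (lam_max + lambda1) / (v - 1)
    precision = a + (lambda1 + lambda2) * np.eye(v)
    cond = (lam_max + lambda1 + lambda2) / lambda2
    try:
        covariance = np.linalg.inv(precision)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"precision matrix numerically singular (lambda2={lambda2:.3g}, "
            f"condition~{cond:.3g}): {err}"
        ) from err
    return CovarianceModel(
        genes=genes,
        precision=precision,
        covariance=covariance,
        lambda1=lambda1,
        lambda2=lambda2,
        condition_number=cond,
    )


# ---------------------------------------------------------------------------
# sampling and orchestration


def sample_dataset(
    truth: SimulationTruth,
    cov: CovarianceModel,
    n: int,
    seed=None,
) -> SimulatedDataset:
    """Sample ``n`` log-expression profiles from ``N(mu_c, Sigma)`` with
    half of the samples in each class ``c``."""
    if n % 2 != 0 or n < 2:
        raise ValueError(f"n must be even and >= 2, got {n}")
    rng = _as_rng(seed)
    genes = cov.genes
    v = len(genes)
    half = n // 2
    chol = np.linalg.cholesky(cov.covariance)
    mu0 = truth.mu0.loc[genes].to_numpy()
    mu1 = truth.mu1.loc[genes].to_numpy()
    z = rng.standard_normal((v, n))
    noise = chol @ z
    x = np.empty((v, n))
    x[:, :half] = mu0[:, None] + noise[:, :half]
    x[:, half:] = mu1[:, None] + noise[:, half:]
    samples = [f"s{i:03d}" for i in range(n)]
    labels = pd.Series([0] * half + [1] * half, index=samples, name="class")
    expr = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples),
        sample_annotations=labels.to_frame(),
    )
    return SimulatedDataset(expression=expr, class_labels=labels, n=n, truth=truth)


def simulate_truth(
    graph_config: GraphConfig,
    pattern_config: DEPatternConfig,
    seed=None,
) -> Tuple[SimulationTruth, CovarianceModel]:
    """Generate network, truth, and covariance for one replicate."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_graph, rng_signs, rng_means, rng_pattern, rng_cov = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    unsigned = generate_graph(graph_config, seed=rng_graph)
    network, p = assign_link_signs(unsigned, seed=rng_signs)
    genes = sorted(map(str, network.genes))
    mu0 = pd.Series(baseline_means(len(genes), pattern_config.d, seed=rng_means), index=genes)

    pattern = pattern_config.pattern
    modules: List[List[Gene]] = []
    psi: Dict[Gene, int] = {}
    if pattern == "null":
        mu1 = mu0.copy()
        truth_sub = Subnetwork.empty(network)
        bnd = BoundarySet.empty()
    elif pattern == "scattered":
        mu1, de_genes = scattered_de(mu0, pattern_config.fraction, pattern_config.d, seed=rng_pattern)
        delta = mu1 - mu0
        keys = {
            link.key
            for link in network.links
            if link.source in de_genes
            and link.target in de_genes
            and is_coherent(float(delta.loc[link.source]), float(delta.loc[link.target]), link.weight)
        }
        truth_sub = Subnetwork(network, de_genes, keys)
        # scattered DE defines no module structure, so no link is treated
        # as a boundary link when strengthening within-module coupling
        bnd = BoundarySet.empty()
    else:
        mu1, psi, truth_sub, modules = modular_de(
            network,
            mu0,
            pattern_config.fraction,
            pattern_config.n_modules,
            pattern_config.d,
            seed=rng_pattern,
        )
        deltas = (mu1 - mu0).to_dict()
        bnd = boundary(network, truth_sub, deltas)

    truth = SimulationTruth(
        network=network,
        truth_subnetwork=truth_sub,
        psi=psi,
        mu0=mu0,
        mu1=mu1,
        boundary=bnd,
        inducing_proportion=p,
        pattern=pattern,
        module_genes=modules,
    )
    cov = build_covariance(network, bnd, seed=rng_cov)
    return truth, cov


def simulate_dataset(
    graph_config: GraphConfig,
    pattern_config: DEPatternConfig,
    n: int,
    seed=None,
) -> SimulatedDataset:
    """End-to-end replicate: graph, signs, means, covariance, sampling."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_truth, ss_sample = ss.spawn(2)
    truth, cov = simulate_truth(graph_config, pattern_config, seed=ss_truth)
    dataset = sample_dataset(truth, cov, n, seed=np.random.default_rng(ss_sample))
    dataset.covariance = cov
    return dataset


# ---------------------------------------------------------------------------
# serialization


def write_simulation(dataset: SimulatedDataset, out_dir: Union[str, Path], seed: Optional[int] = None) -> None:
    """Write a simulated replicate as plain-text files."""
    from .network import write_network_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.expression.values.to_csv(out / "expression.tsv", sep="\t")
    dataset.class_labels.to_frame().to_csv(out / "labels.tsv", sep="\t")
    write_network_tsv(dataset.truth.network, out / "network.tsv")
    write_network_tsv(dataset.truth.truth_subnetwork, out / "truth_subnetwork.tsv")
    truth = dataset.truth
    payload = {
        "seed": seed,
        "pattern": truth.pattern,
        "inducing_proportion": truth.inducing_proportion,
        "psi": {str(g): int(s) for g, s in truth.psi.items()},
        "mu0": {str(g): float(x) for g, x in truth.mu0.items()},
        "mu1": {str(g): float(x) for g, x in truth.mu1.items()},
        "truth_genes": sorted(map(str, truth.truth_subnetwork.genes)),
        "module_genes": [[str(g) for g in mod] for mod in truth.module_genes],
        "n": dataset.n,
    }
    if dataset.covariance is not None:
        payload["lambda1"] = dataset.covariance.lambda1
        payload["lambda2"] = dataset.covariance.lambda2
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
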