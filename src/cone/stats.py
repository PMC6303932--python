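"""Per-gene linear models, contrast estimates, and FDR control.

For each gene ``j`` the expected log-expression follows the general linear
model ``E(Y_j) = mu_j + delta_j W + beta_j Z`` with treatment factors ``W``
and covariates ``Z``.  A contrast ``gamma`` over the design columns yields a
per-gene estimate ``delta_j(gamma)`` whose sign drives link coherence and
whose p-value drives error control.  The default engine is per-gene
ordinary least squares with an exact t reference distribution; an optional
empirical-Bayes step shrinks residual variances toward a pooled prior in
the spirit of moderated t-statistics.  Multiple testing is controlled with
Benjamini-Hochberg step-up q-values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
from scipy import special, stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .network import Gene, SignedNetwork, Subnetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DesignSpec",
    "GeneContrastStats",
    "fit_gene_models",
    "moderate_variances",
    "bh_adjust",
    "attach_qvalues",
    "significant_genes",
    "baseline_de_subnetwork",
    "read_expression",
    "write_stats_tsv",
]


@dataclass
class ExpressionMatrix:
    """Log-expression values, genes in rows and samples in columns."""

    values: pd.DataFrame
    sample_annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if self.sample_annotations is not None:
            missing = set(self.values.columns) - set(self.sample_annotations.index)
            if missing:
                raise ValueError(f"samples without annotation: {sorted(map(str, missing))[:5]}")

    @property
    def genes(self) -> List[Hashable]:
        return list(self.values.index)

    @property
    def samples(self) -> List[Hashable]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[Hashable]) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep], self.sample_annotations)

    def collapse_duplicate_genes(self) -> "ExpressionMatrix":
        """Average rows sharing a gene identifier, per sample."""
        if not self.values.index.has_duplicates:
            return self
        collapsed = self.values.groupby(level=0, sort=False).mean()
        return ExpressionMatrix(collapsed, self.sample_annotations)

    @classmethod
    def from_frame(cls, values: pd.DataFrame, annotations: Optional[pd.DataFrame] = None) -> "ExpressionMatrix":
        if values.index.has_duplicates:
            values = values.groupby(level=0, sort=False).mean()
        return cls(values, annotations)


@dataclass
class DesignSpec:
    """A design matrix (samples x named columns) plus a contrast vector."""

    design: pd.DataFrame
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.contrast.shape != (self.design.shape[1],):
            raise ValueError(
                f"contrast length {self.contrast.shape} does not match "
                f"{self.design.shape[1]} design columns"
            )
        x = self.design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def two_group(
        cls,
        labels: Union[pd.Series, Sequence[int]],
        samples: Optional[Sequence[Hashable]] = None,
    ) -> "DesignSpec":
        """Intercept + group-indicator design; the contrast is the group
        difference (class 1 minus class 0)."""
        if isinstance(labels, pd.Series):
            idx, values = labels.index, labels.to_numpy()
        else:
            values = np.asarray(labels)
            idx = pd.Index(samples) if samples is not None else pd.RangeIndex(len(values))
        design = pd.DataFrame(
            {"intercept": np.ones(len(values)), "group": values.astype(float)},
            index=idx,
        )
        return cls(design, np.array([0.0, 1.0]))

    @property
    def n_columns(self) -> int:
        return self.design.shape[1]


@dataclass(frozen=True)
class GeneContrastStats:
    """Per-gene contrast estimate and its inference summary."""

    gene: Hashable
    estimate: float
    standard_error: float
    statistic: float  # NaN flags an undefined statistic (zero residual variance)
    p_value: float
    df: float
    residual_variance: float
    q_value: Optional[float] = None

    @property
    def sign(self) -> int:
        return (self.estimate > 0) - (self.estimate < 0)


def fit_gene_models(expr: ExpressionMatrix, design: DesignSpec) -> List[GeneContrastStats]:
    """Ordinary-least-squares fit of the linear model for every gene.

    The estimate is ``gamma' beta_hat_j``; its two-sided p-value comes from
    the exact t distribution on the residual degrees of freedom.  Genes with
    zero residual variance get an undefined (NaN) statistic and a
    conservative p-value of 1.
    """
    samples = expr.samples
    missing = [s for s in samples if s not in design.design.index]
    if missing:
        raise ValueError(f"samples absent from design: {missing[:5]}")
    x = design.design.loc[samples].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    y = expr.values.to_numpy(dtype=float)  # genes x samples

    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T  # p x n
    betas = y @ hat.T  # genes x p
    fitted = betas @ x.T
    resid = y - fitted
    df = n - p
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df
    gamma = design.contrast
    c = float(gamma @ xtx_inv @ gamma)
    estimates = betas @ gamma
    scale = max(float(np.abs(y).max()), 1.0)
    zero_var = s2 <= (np.finfo(float).eps * scale) ** 2 * 100
    se = np.sqrt(c * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, np.nan, estimates / np.where(se > 0, se, np.nan))
    p_values = np.where(np.isnan(t), 1.0, 2.0 * sp_stats.t.sf(np.abs(t), df))
    n_flagged = int(zero_var.sum())
    if n_flagged:
        logger.info("flagged %d gene(s) with zero residual variance (p set to 1)", n_flagged)

    return [
        GeneContrastStats(
            gene=g,
            estimate=float(estimates[i]),
            standard_error=float(se[i]),
            statistic=float(t[i]),
            p_value=float(min(p_values[i], 1.0)),
            df=float(df),
            residual_variance=float(s2[i]),
        )
        for i, g in enumerate(expr.genes)
    ]


def _inv_trigamma(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = max(y + dif, 1e-8)
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(raw_variances: Sequence[float], df: float) -> tuple:
    """Moment-matching estimate of the pooled variance prior.

    Models ``s_j^2 ~ s0^2 * chi^2_df / df`` given a scaled-inverse-chi-square
    prior with ``d0`` degrees of freedom on the true variances.  ``d0`` is
    obtained by matching the excess variance of ``log s_j^2`` over the
    chi-square contribution (inverse trigamma), and ``s0^2`` is the
    geometric mean of the raw variances, so identical raw variances shrink
    to themselves.  Returns ``(prior_df, prior_variance)``;
    ``prior_df = inf`` when the raw variances are no more dispersed than
    chi-square sampling alone explains.
    """
    s2 = np.asarray([v for v in raw_variances if v > 0], dtype=float)
    if s2.size < 2:
        raise ValueError("variance moderation requires at least two genes with positive variance")
    log_s2 = np.log(s2)
    excess = float(np.var(log_s2, ddof=1)) - float(special.polygamma(1, df / 2.0))
    prior_var = float(np.exp(log_s2.mean()))
    if excess <= 0:
        return math.inf, prior_var
    prior_df = 2.0 * _inv_trigamma(excess)
    return prior_df, prior_var


def moderate_variances(
    stats: Sequence[GeneContrastStats],
    raw_variances: Optional[Sequence[float]] = None,
    df: Optional[float] = None,
    prior_df: Optional[float] = None,
) -> List[GeneContrastStats]:
    """Empirical-Bayes shrinkage of residual variances toward a pooled prior.

    The moderated variance is the convex combination
    ``(d0 * s0^2 + df * s_j^2) / (d0 + df)`` and the t statistic and
    p-value are recomputed on ``df + d0`` degrees of freedom.  ``prior_df``
    overrides the estimated ``d0`` (``prior_df -> 0`` recovers the
    unmoderated fit).
    """
    if len(stats) < 2:
        raise ValueError("variance moderation requires at least two genes")
    if raw_variances is None:
        raw_variances = [s.residual_variance for s in stats]
    raw = np.asarray(raw_variances, dtype=float)
    if df is None:
        df = stats[0].df
    if prior_df is None:
        d0, s0 = estimate_variance_prior(raw, df)
    else:
        d0 = float(prior_df)
        _, s0 = estimate_variance_prior(raw, df)
    if d0 == 0:
        mod = raw.copy()
        total_df = float(df)
    elif math.isinf(d0):
        mod = np.full_like(raw, s0)
        total_df = 1e6  # effectively normal reference
    else:
        mod = (d0 * s0 + df * raw) / (d0 + df)
        total_df = float(df + d0)

    out: List[GeneContrastStats] = []
    for s, s2_raw, s2_mod in zip(stats, raw, mod):
        if s2_mod <= 0 or (math.isnan(s.statistic) and s2_raw <= 0 and s2_mod <= 0):
            out.append(s)
            continue
        se = s.standard_error * math.sqrt(s2_mod / s2_raw) if s2_raw > 0 else math.nan
        if not math.isfinite(se) or se == 0:
            # zero-raw-variance gene: rebuild se from the moderated variance
            # using the design constant embedded in any well-defined gene
            ref = next((t for t in stats if t.residual_variance > 0), None)
            if ref is None:
                out.append(s)
                continue
            c = ref.standard_error**2 / ref.residual_variance
            se = math.sqrt(c * s2_mod)
        t = s.estimate / se
        p = float(2.0 * sp_stats.t.sf(abs(t), total_df))
        out.append(
            replace(
                s,
                standard_error=float(se),
                statistic=float(t),
                p_value=min(p, 1.0),
                df=total_df,
                residual_variance=float(s2_mod),
            )
        )
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_qvalues(stats: Sequence[GeneContrastStats]) -> List[GeneContrastStats]:
    """Return a copy of ``stats`` with BH q-values over the whole collection."""
    q = bh_adjust([s.p_value for s in stats])
    return [replace(s, q_value=float(qi)) for s, qi in zip(stats, q)]


def significant_genes(stats: Sequence[GeneContrastStats], alpha: float) -> Set[Hashable]:
    """Genes whose BH q-value is at or below ``alpha``."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    missing = [s.gene for s in stats if s.q_value is None]
    if missing:
        raise ValueError(f"q-values not populated (e.g. gene {missing[0]!r}); call attach_qvalues first")
    return {s.gene for s in stats if s.q_value <= alpha}


def baseline_de_subnetwork(
    network: SignedNetwork,
    stats: Sequence[GeneContrastStats],
    alpha: float,
) -> Subnetwork:
    """Network-naive comparator: the induced subnetwork of significant genes.

    All parent links among the significant genes are kept — no coherence
    filtering and no isolated-gene removal.
    """
    sig = significant_genes(stats, alpha) & network.genes
    return network.induced_subnetwork(sig)


# ---------------------------------------------------------------------------
# input / output


def read_expression(
    path: Union[str, Path],
    annotations_path: Optional[Union[str, Path]] = None,
) -> ExpressionMatrix:
    """Read an expression TSV/CSV (first column = gene identifier) and an
    optional sample-annotation table keyed by sample identifier."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    values = pd.read_csv(path, sep=sep, index_col=0)
    annotations = None
    if annotations_path is not None:
        apath = Path(annotations_path)
        asep = "," if apath.suffix.lower() == ".csv" else "\t"
        annotations = pd.read_csv(apath, sep=asep, index_col=0)
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene row(s) by per-sample mean", n_dup)
        values = values.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(values, annotations)


def stats_frame(stats: Sequence[GeneContrastStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [s.gene for s in stats],
            "estimate": [s.estimate for s in stats],
            "se": [s.standard_error for s in stats],
            "t": [s.statistic for s in stats],
            "p": [s.p_value for s in stats],
            "q": [s.q_value for s in stats],
            "sign": [s.sign for s in stats],
        }
    ).set_index("gene")


def write_stats_tsv(stats: Sequence[GeneContrastStats], path: Union[str, Path]) -> None:
    stats_frame(stats).to_csv(path, sep="\t")
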