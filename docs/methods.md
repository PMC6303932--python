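# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of the `cone` package in the package's own terms.

## Coherence model

A signed network `G = (V, E)` carries link weights `w(j,k) ∈ {-1, +1}`
(−1 inhibiting, +1 otherwise: induction, binding, and unsigned positive
associations are all treated as non-inhibiting, following the literal
"otherwise → +1" coding). A link is coherent with respect to a contrast
`γ` iff `sign(δ̂_j(γ)) · sign(δ̂_k(γ)) · w(j,k) = 1`.

Numerical conventions:

* **sign(0)**: a zero contrast estimate makes every incident link
  incoherent (the product is 0 ≠ 1). Exact zeros are measure-zero for
  continuous data; constant genes are flagged separately by the statistics
  layer.
* **Non-finite estimates** raise immediately rather than silently
  classifying a link.
* **Direction** is preserved in storage (directed inputs keep `(j,k)` and
  `(k,j)` distinct, each evaluated independently) but ignored for coherence,
  degree/isolation, and connectivity, since the coherence rule is symmetric
  in its endpoints.
* **Duplicates**: exact duplicate links collapse with a warning;
  conflicting relationship labels on one (ordered) pair are an error, since
  silently picking one would change the analysis.

The boundary of a subnetwork `S` is `∂S = I ∪ B`: `I` the incoherent links
inside `E(S)`, `B` the links of `E(G)` with exactly one endpoint in `V(S)`.
These two sets are disjoint by construction. For truth subnetworks built by
the simulator, `E(S)` contains only coherent links, so `I = ∅` and the
boundary reduces to the crossing set.

## Statistics layer

Per-gene inference is ordinary least squares on a user-supplied design
matrix, with the contrast estimate `γᵀβ̂_j`, its standard error from
`γᵀ(XᵀX)⁻¹γ · s²_j`, and exact two-sided t p-values on the residual
degrees of freedom. Contrasts are explicit numeric vectors over named
design columns; there is no formula language. Genes with zero residual
variance get an undefined (NaN) statistic and a conservative p-value of 1,
and are counted in the log.

**Variance moderation (opt-in).** An empirical-Bayes step shrinks residual
variances toward a pooled prior: the prior variance is the geometric mean
of the raw variances and the prior degrees of freedom `d0` are estimated by
matching the excess dispersion of `log s²_j` beyond the chi-square sampling
contribution (inverse trigamma). The moderated variance is the convex
combination `(d0·s0² + df·s²_j)/(d0 + df)` with `df + d0` reference degrees
of freedom. This scheme deliberately omits the log-scale bias correction
some moderated-t implementations apply to the prior: with the correction,
a set of genes with identical raw variances would be "shrunk" to a value
above that common variance, which we consider surprising behaviour for a
shrinkage estimator; without it, identical raw variances are a fixed point,
shrinkage is monotone in the raw variance, and `d0 → 0` recovers the
unmoderated fit. Moderation is off by default: the procedure is agnostic to
the engine producing `δ̂` and p, and the default keeps the reference
distribution exact.

**FDR control** is Benjamini–Hochberg step-up (via statsmodels), validated
against a brute-force enumeration oracle. The default level is α = 0.05.

**FDR scope.** By default q-values are computed over *all* analysed network
genes before intersecting with the coherent subnetwork (`all_genes`), which
keeps q-values independent of the coherence filter and is the conservative
reading of the step ordering; a `coherent_genes` mode restricts BH to the
genes surviving the coherence step. Both are first-class because the
ordering is genuinely ambiguous; the default never rejects more genes than
an analyst running BH on the whole panel would.

**Baseline comparator**: the induced subnetwork of all BH-significant
genes, with every network link among them and isolated significant genes
retained — deliberately network-naive.

## Differential link score (diagnostic only)

The score `(X_j¹ + w·X_k¹) − (X_j⁰ + w·X_k⁰)` is reported per index-paired
sample with its mean and sample variance (ddof = 1; flagged undefined for a
single pair). It is not part of the main procedure: two links with the same
mean score can have arbitrarily different score variance, and a
variance-based test would prefer the constant case even though correlated
changes are exactly what an inducing link predicts. The implementation is
kept so this failure mode can be demonstrated
(`examples/03_link_score_diagnostic.py`).

## Simulation engine

The generator emulates two-class log-expression with a known coherent
module structure; every replicate is a draw of (network, signs, means,
covariance, data).

* **Graphs.** Erdős–Rényi: `e` links uniform without replacement over the
  `v(v−1)/2` unordered pairs (default small graph `v=500, e=2000`; large
  `v=2000, e=8000`). Barabási–Albert: nodes added one at a time, node `t`
  attaching `min(m, t)` links to distinct earlier nodes with probability
  proportional to `degree^power + 1` (unit zero-appeal, no multi-edges), so
  a `(v, m=2)` graph has exactly `1 + 2(v−2)` links (defaults
  `v∈{500,2000}, power=1, m=2`). The degree distribution of the ER family
  is Poisson with mean `2e/v` in the large-`v` limit; at small `v` the fixed
  link count makes it mildly sub-Poisson, which is why the calibration test
  runs at `v=500`.
* **Link signs.** Each graph draws a single inducing proportion
  `p ~ U(0.72, 0.85)` — matching reported activator fractions in eukaryotic
  regulatory networks — and each link is independently non-inhibiting with
  probability `p`.
* **Baseline means** `μ⁰_j ~ U(−d, d)` with effect half-range
  `d ∈ {4, 8, 16, 32}` in log-expression units. Offsets (below) then have
  mean absolute value `d/2`, so `d = 4, 8, 16, 32` corresponds to mean
  |ΔE| = 2, 4, 8, 16; the top of that range is an extreme upper limit
  rather than a realistic signal.
* **Patterns.** *Null*: `μ¹ = μ⁰`, empty truth. *Scattered*:
  `round(fraction·v)` genes uniformly without replacement get an added
  `U(−d, d)` offset (near-zero offsets are not excluded — the cost of a
  tiny offset is borne honestly by sensitivity). *Modular*: modules are
  grown by repeated uniform sampling from the neighbourhood of the current
  gene set (restarting from a fresh seed gene if growth stalls, bounded);
  for `k` modules the total `round(fraction·v)` is split as evenly as
  possible and modules are grown disjointly. Signs `ψ` start at +1 and each
  gene copies `ψ_k · w(k, j)` from a uniformly chosen earlier linked
  neighbour, so every spanning link is coherent; effects are
  `μ¹_j = μ⁰_j + ψ_j·U(0, d)`. The truth subnetwork keeps all
  *within-module* links coherent under `μ¹ − μ⁰` (spanning links plus
  coherent extras); links between distinct modules are not added to the
  truth.
* **Covariance.** On the network skeleton: `U(0.5, 1)` link weights, +1
  added to every non-boundary link weight (coupling module genes more
  tightly than the background; for null/scattered truths every link gets
  the +1), entries multiplied by `−w_jk` so the partial correlation
  `ρ_jk = −p_jk/√(p_jj p_kk)` carries the relationship's sign, and a
  diagonal shift `λI` with `λ = λ₁ + λ₂`: `−λ₁` is the smallest eigenvalue
  of the off-diagonal matrix and `λ₂ = (λ_max + λ₁)/(v−1)` solves
  condition number = `v` exactly (2-norm, ratio of extreme eigenvalues).
  The diagonal before the shift is 0 — the shift supplies it. The
  covariance is the dense inverse; at the study sizes (`v ≤ 2000`) the
  eigendecomposition and inverse are exact dense operations and the
  condition-number bound keeps the inversion well-posed by construction.
* **Sampling.** `n/2` samples per class from `N(μ^c, Σ)` via the Cholesky
  factor of `Σ`; `n` must be even (grid `{8, 16, 32, 64}`).

All randomness is spawned from a single `numpy.random.SeedSequence`, so a
replicate is bit-reproducible from its seed, and benchmark cells derive
their seeds from (root seed, scenario index, replicate) so interrupted and
resumed sweeps agree with fresh ones.

**What the generator does not emulate.** Expression is exactly multivariate
normal on the log scale with a covariance tied to the known network: there
is no dynamic/mechanistic regulation (no Markov-chain or ODE dynamics), no
network mis-specification (the analysed network is the generating one), no
technical artefacts (batch effects, missing values, count noise), and
truth modules are constructed to be perfectly coherent. Passing tests
therefore demonstrate that the procedure recovers coherent modules and
controls error *when the network model is correct and the signal is
coherent*; they say nothing about robustness to a wrong or incomplete
network, which on real data is a genuine risk the baseline comparison is
meant to expose.

## Evaluation

Gene- and link-level sensitivity, specificity, and precision follow the
set-cardinality formulas over `V(·)` and `E(·)` (links compared as
unordered pairs for undirected universes). A metric with an empty
denominator (e.g. precision of an empty estimate, sensitivity under a null
truth) is *undefined* and reported as such — forcing 0 or 1 would bias
replicate summaries; summaries report defined/undefined counts alongside
median, quartiles, and mean.

Enrichment is one-sided over-representation per gene set: a hypergeometric
tail on the 2×2 membership table over a background universe (identical to
one-sided Fisher), BH-adjusted across the tested sets, with the covered
fraction of each set reported. The background defaults to the genes shared
by the expression data and the network, but any universe can be supplied —
array-wide versus network-restricted backgrounds answer different
questions, and both are legitimate.

## Problem sizes used in the validation suites

The test and acceptance runs use desk-scale configurations chosen to keep
each Monte-Carlo check sharp at modest cost: 50 replicates for the
FDR-control study (v = 500 scale-free graph, ~5 s total), 10⁵ draws for
distributional checks, 100 graph draws for degree-distribution
calibration, and graphs of 25–500 genes elsewhere. These are the package's
default validation sizes; every replicate count and size is a visible
parameter and scales up without code changes.

## Known limitations

* Only ±1 regulatory strengths; weighted networks are out of scope.
* The network is always prior knowledge — no network inference from data.
* No count-model (negative-binomial) engine; inputs are continuous
  log-scale values.
* No maximum-scoring-subnetwork optimisation; such methods are alternative
  procedures to compare against, not part of this one.
* Identifier matching is exact-string; symbol aliasing/annotation is the
  caller's responsibility.
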