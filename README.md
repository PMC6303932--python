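# cone — Coherent Network Expression

`cone` identifies **differentially activated, regulation-coherent
subnetworks** in signed molecular interaction networks. It is aimed at
systems biologists who have (a) a log-expression matrix with a two-class or
general linear-model design and (b) prior knowledge of a regulatory network
whose links are labelled *inhibiting* or *non-inhibiting* (induction,
binding, unsigned positive association), and who want functional modules
whose expression changes respect that regulatory structure — with explicit
false-discovery-rate control, so that reported modules are real findings.

## The method

Let `G = (V, E)` be the network with link weights

```
w(j, k) = -1  if the relationship is inhibiting
           1  otherwise
```

and let `δ̂_j(γ)` be the per-gene estimate of a contrast `γ` from the linear
model `E(Y_j) = μ_j + δ_j W + β_j Z`. A link `(j, k)` is **coherent** when

```
sign(δ̂_j) · sign(δ̂_k) · w(j, k) = 1
```

— co-directed change across a non-inhibiting link, opposed change across an
inhibiting one. The procedure:

1. fit the per-gene linear models over all network genes;
2. extract the contrast estimates `δ̂_j(γ)`;
3. remove all incoherent links, then genes left with degree 0;
4. apply Benjamini–Hochberg FDR control at level `α` (default 0.05), remove
   non-significant genes and their links, and remove newly isolated genes.

The result is the estimated coherent subnetwork `Ŝ` plus a provenance record
of every removal. A network-naive baseline (the induced subnetwork of all
BH-significant genes, no coherence filtering) is provided for comparison,
and the **boundary** `∂S = I ∪ B` (incoherent internal links plus links
crossing out of `S`) supports both diagnostics and simulation.

The package also ships the full evaluation apparatus: a Gaussian
graphical model simulator (random Erdős–Rényi / Barabási–Albert networks,
null / scattered / modular differential-expression patterns with coherence
guaranteed by sign propagation, and a precision matrix built on the network
skeleton with condition number equal to the gene count), plus gene- and
link-level sensitivity / specificity / precision and generic Fisher's-exact
gene-set enrichment.

## Worked example

`examples/02_simulate_and_run.py` simulates a 200-gene scale-free network
with a planted 20-gene coherent module (10% DE, effect half-range d = 8,
n = 32 samples) and runs both procedures:

```
simulated: 200 genes, 397 links, inducing fraction p=0.734
truth module: 20 genes, 20 coherent links

coherent estimate: 19 genes, 19 links
removed per step: {'network_genes_not_in_expression': 0, 'incoherent_links': 158,
 'isolated_after_coherence': 16, 'nonsignificant_genes': 165,
 'links_lost_to_significance': 220, 'isolated_after_significance': 0}
    cone: SE_genes=0.95 SP_genes=1.000 PR_genes=1.00 SE_links=0.95 PR_links=1.00
baseline: SE_genes=0.95 SP_genes=1.000 PR_genes=1.00 SE_links=0.95 PR_links=0.83
```

19 of the 20 module genes are recovered and *everything* reported is inside
the true module (gene and link precision 1.00); the baseline matches on
genes here but admits false-positive links (link precision 0.83). The other
examples cover the coherence primitives, the differential-link-score
diagnostic, and a small benchmark sweep.

A thin command-line interface wraps the same library code:

```sh
cone simulate --config sim.yaml --out simdir/
cone run --expr expr.tsv --network net.tsv --design design.tsv \
         --contrast group --alpha 0.05 --out-prefix out/run
cone evaluate --truth truth.tsv --estimate out/run_subnetwork.tsv --network net.tsv
cone benchmark --replicates 10 --seed 1 --out bench.tsv
```

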