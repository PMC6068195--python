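# Methods

`tissuenet` implements a tissue-specific network analysis of GWAS summary
statistics: variant associations are collapsed into gene-level tests, genes
are embedded in a coexpression-filtered interaction network, dense modules
are grown from significant seeds, candidate key drivers are ranked, and the
resulting network is tested for gene-set over-representation. This note
records the statistical model behind each stage, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions that matter.

## Gene-level association

For a gene window holding variants with z-scores `z = (z_1, ..., z_m)`, the
set statistic is

    T = sum_j z_j^2 .

Under the null, `z ~ MVN(0, R)` with `R` the variants' LD correlation
matrix, so `T` is distributed as `sum_i lambda_i chi2_1` where `lambda_i`
are the eigenvalues of `R` (hence `sum_i lambda_i = m`, the trace identity
asserted in the tests). Windows extend the annotated gene body by a
symmetric flank, default 50 kb, as a closed interval `[start - flank,
end + flank]`; the annotation's BED is 0-based half-open and converted to
1-based closed coordinates on read. A variant inside several overlapping
windows contributes to every one of them — no unique assignment — which is
the behaviour of standard set-based testing tools and is why one strong SNP
can be the best variant for several neighbouring genes. Variants are first
restricted to minor allele frequency >= 1% (boundary inclusive).

The gene p-value feeds two downstream quantities:

* the score `g = Phi^-1(1 - p)`, a |z|-equivalent of the gene association.
  Since the set test is direction-free, the one-sided mapping is used, and
  scores for p > 0.5 (formally negative) are floored at 0 by default so that
  module scores cannot be rewarded for sub-null noise; the raw signed
  quantile is available via `nonnegative=False`. p is floored at 1e-300,
  capping g near 37 — this keeps extremely associated loci finite without
  changing their ranking.
* the significance flag at the Bonferroni threshold `alpha / N`, with `N`
  the number of genes actually tested in the run (not a fixed constant), the
  conservative correction appropriate when tens of thousands of genes are
  scanned. At `alpha = 0.05` and `N = 26,228` — the size of a genome-wide
  gene census — the threshold is 1.91e-6.

### Evaluating the weighted chi-squared tail

`P(sum_i lambda_i chi2_1 > T)` has no closed form for unequal weights. Four
branches, each recorded per gene:

* **exact** — all (truncated) eigenvalues equal, including the one-variant
  case: the mixture collapses to a scaled chi-squared, and the single-variant
  gene p equals the variant's two-sided normal p to machine precision.
* **imhof** — characteristic-function inversion (Imhof's representation
  `P = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u rho(u)) du`). Below a
  fifth of the null mean the integrand barely oscillates and adaptive
  quadrature on the infinite interval is used directly. Elsewhere the
  integrand oscillates with period ~ `4 pi / T` and decays like
  `u^-(1 + m/2)`: it is integrated by composite Gauss–Legendre with
  segments short enough to resolve both the oscillation (half a period) and
  the arctan phase scale (`1 / (2 lambda_max)`), truncated where a
  van-der-Corput-style bound on the oscillatory tail falls below 1e-9. The
  8- vs 16-point difference plus the truncation bound give an error
  estimate. This is accurate in absolute error, i.e. for p down to ~1e-9.
* **saddlepoint** — Lugannani–Rice tail approximation from the cumulant
  generating function, used when the inversion cannot resolve the value
  (p < 1e-9 or an unreliable error estimate beyond the mean). It is accurate
  in *relative* error deep in the tail (a few percent), which is what matters
  for ranking extremely significant genes; a 10^8-draw Monte-Carlo check at
  the branch boundary agreed with both branches within sampling error.
* **satterthwaite** — moment-matched scaled chi-squared
  (`a = sum lambda^2 / sum lambda`, `nu = (sum lambda)^2 / sum lambda^2`),
  the last-resort fallback if the other branches fail.

Eigenvalues below `1e-10 * max(lambda)` are truncated to zero before
inversion; they carry no probability mass but destabilise the integrand
for near-singular LD.

LD can come from three sources behind one callable interface: a known AR(1)
structure (matching the synthetic generator), precomputed per-gene matrices,
or a reference dosage panel (pairwise Pearson correlation, monomorphic
variants dropped with a warning).

## Tissue-specific network

Reported protein interactions are cleaned — self-loops removed, edges with
any non-human taxon removed when taxon columns exist, reciprocal duplicates
collapsed onto the canonical `gene_a < gene_b` orientation — and then
filtered by coexpression in the target tissue: an edge survives iff the two
genes' normalized expression has `|Pearson r| > 0.25`, strictly, and the
signed `r` becomes the edge weight.

"Normalized" defaults to the rank-based inverse normal transform per gene
across samples (`Phi^-1((rank - 0.5)/n)`), which makes the correlation
robust to expression outliers and heavy tails, in the spirit of standard
practice for tissue expression panels; plain Pearson and Spearman are
options. The threshold is applied to |r| because the downstream centroid
uses |w|, implying negatively correlated partners still count as
interacting; a signed mode (`r > threshold`) is available. Genes with zero
variance or expressed in fewer than half the samples are excluded before
correlation (warned), and at least 3 samples are required. Gene ids are
matched exactly between the interaction and expression sources.

## Dense-module search

Every Bonferroni-significant gene present in the network seeds one module
(significant genes absent from the network are reported and skipped). The
module score is

    Zm = sum_i g_i / sqrt(k),   k = module size.

Growth is greedy and sequential: each iteration scans all genes within
`neighbor_order` steps of the current module (default 1; 2 reaches across
one unscored bridge gene) and adds the single candidate maximizing the new
Zm, provided `Zm_new > Zm_old * (1 + r)` with improvement rate `r = 0` by
default — any strict increase. `r = 0.1` and `neighbor_order = 2`, the
defaults of the classical dense-module strategy this follows, are one
argument away. Ties are broken by higher candidate score, then
lexicographic gene id, making the result invariant to edge insertion order;
the score trajectory strictly increases, so termination is guaranteed. An
independently written rescan-everything reference implementation agrees with
the production search on random networks.

Per-seed modules overlap heavily and are merged by plain node-set union into
one combined network (the induced subgraph of the tissue network), with
per-node provenance recording which seeds contributed each gene. Network
genes lacking an association result carry `g = 0` and a `scored = False`
flag: they can enter modules only as connectivity bridges.

## Key drivers and weighted centroid

A key driver is a gene whose neighbors are enriched for high association
scores relative to a same-sized random gene set. The test compares the
neighbor score distribution against the scores of all other network genes
(focal gene excluded) with a one-sided two-sample Kolmogorov–Smirnov test —
alternative: neighbor scores stochastically larger — and flags genes with
`p < alpha / N`, `N` the network size. Genes with fewer than 3 neighbors
are marked untestable rather than dropped or errored: a KS test on one or
two points is meaningless. An explicit resampling null (`degree-matched`)
re-draws random neighbor sets of the same size and compares KS statistics,
guarding against degree confounding that the analytic background comparison
ignores; the analytic mode is the default and is calibrated (type-I error
at nominal 5% lies in [3%, 7%] in the test suite's replicates).

The weighted centroid

    C_i = g_i + sum_k |w_ik| * g_k

sums over direct neighbors only (the weights are defined on edges); an
isolated gene's centroid is its own score. Ranking is by descending C with
lexicographic tie-break. In a pipeline run the key-driver scan operates on
the merged module network; when a run produces no seed genes (a null
study), the scan falls back to the full tissue network, and the manifest
records which network was scanned.

## Over-representation analysis

The merged network's genes are tested against GMT gene sets by the
hypergeometric upper tail `P(X >= k)` with population = explicit background
universe, successes = set ∩ background, draws = query ∩ background. The
background is a required argument — the default in pipeline runs is all
annotated genes — because ORA p-values are uninterpretable without naming
the universe. Benjamini–Hochberg FDR is applied across tested sets
(Bonferroni would be needlessly conservative for correlated sets), sets are
restricted to between 3 and 2,000 background genes to avoid degenerate
tests, and the enrichment ratio is `observed / (n_query * n_set /
n_background)`. Significant means `FDR < 0.1`, strictly.

## Synthetic study generator

The generator emits every pipeline input with a known answer key. What it
emulates, and how:

* **Genome and variants** — genes laid on one linear chromosome with bodies
  separated by more than twice the flank, so window assignment is
  unambiguous by construction (overlap must be requested explicitly);
  variant counts per gene drawn uniformly from a configured range, allele
  frequencies uniform on [0.01, 0.5].
* **Summary statistics** — per-gene `z ~ MVN(mu, R)` with AR(1) LD
  `R_ij = rho^|i-j|` (default rho 0.5) and `mu = noncentrality` (default 4)
  on every variant of a causal gene, 0 elsewhere. This simulates the z/LD
  pair the set test consumes directly, the minimal sufficient structure;
  no genotypes or phenotypes are needed. A Gaussian-copula dosage-panel
  emitter with matched AR(1) latent correlation exists solely to exercise
  panel-based LD estimation (binomial marginals attenuate the correlation,
  which the tests acknowledge by checking shape, not exact values).
* **Network** — Barabási–Albert preferential attachment (m = 2) for the
  scale-free background, plus a planted module wired as a hub-and-spoke
  star with a ring through the spokes: connected, every spoke of degree
  >= 3, and a designated hub for centroid evaluation. All planted-module
  genes are causal by default (`causal_fraction = 1.0`): module recovery is
  score-driven, so an unscored planted gene would be unrecoverable by
  design, not by defect.
* **Expression** — one latent factor shared by the planted module with
  loading `a = sqrt(r/(1-r))` against unit noise, giving planted pairs
  Pearson correlation `r` in expectation (default 0.9); background genes
  are independent noise, so background edges survive the 0.25 filter only
  by sampling error (~0.1% at 173 samples, the default panel size chosen to
  mirror a real coronary-artery expression panel).
* **Gene sets** — one GMT set containing the planted module (at least 80%
  of it, topped up with random fillers to the configured size), the rest
  random draws.

A single top-level seed is split into named child streams (genome, truth,
summary stats, network, expression, sets), so regenerating one stage never
perturbs another, and a fixed config reproduces byte-identical files.

What the generator does **not** emulate: realistic human LD block structure,
allele-frequency-dependent effect sizes, population stratification or
genomic inflation, expression confounders (batch, cell-type composition),
biased or noisy interaction reporting, and overlapping gene annotations by
default. Passing tests therefore demonstrate that the machinery is correct
and calibrated under its stated model — not that real-data results of any
particular study are reproduced, which would require the original consortium
summary statistics, tissue panel and interaction database.

## Validation experiments and problem sizes

`tissuenet.validation` (driven by `scripts/acceptance.py` and the acceptance
tests) runs three experiments, sized to be decisive yet quick:

* **Set-test oracle** — 200 random 2–10-variant sets with random PSD LD;
  the analytic tail is compared with a 1e6-draw Monte-Carlo oracle. The
  observed statistic is itself one draw from the mixture, so its p is
  uniform and the MC standard error is well behaved. Pass condition: >= 99%
  of sets within 3 SE (with 200 comparisons, at least one ~3 SE excursion is
  likely by chance, so "all within 3" would be flaky by construction) and
  no deviation beyond 4 SE; single-variant sets must match the two-sided
  normal p exactly.
* **Null calibration** — 20 replicate studies of 1,000 genes with
  noncentrality 0: gene p-values uniform (KS, alpha = 0.01) and at most one
  key driver, per replicate; >= 95% of replicates must pass.
* **Planted recovery** — 20 replicate studies at the default planted
  conditions (noncentrality 4, planted edge correlation 0.9): mean recall of
  planted-module genes in the merged network >= 0.9, planted hub in the top
  5% by weighted centroid, planted gene set top-ranked by FDR in >= 95% of
  replicates.

## Known limitations

* The KS key-driver test inherits the discreteness of small-sample KS
  p-values; with very few neighbors the minimum attainable p may exceed a
  stringent Bonferroni threshold, making small-degree genes undetectable in
  principle (reported as tested but never significant).
* The analytic KS background ignores degree; the degree-matched resampling
  mode addresses this at the cost of a resampling-resolution-limited p.
* Greedy module growth is locally optimal only; it makes no claim of
  finding the globally densest subgraph, matching the sequential-addition
  strategy it implements.
* ORA treats gene sets as independent in the BH step and ignores gene-gene
  correlation within sets.
* The coexpression filter has limited power for weakly expressed genes —
  a property of correlation-based tissue evidence generally.
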