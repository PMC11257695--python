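# Methods

`scbinsim` links quantitative scRNA-seq measurements with the Boolean
activity states used by logical models of gene regulation. It does two
things with one learnt object: it coarse-grains log pseudocounts into
three-valued activity calls, and it generates synthetic pseudocount
matrices from Boolean network traces. This note records the model, the
estimation choices, the defaults and their rationale, and what the
synthetic benchmarks do and do not demonstrate.

## Data model and preprocessing contract

All matrices are cells x genes. Expression values are log pseudocounts
`x_cg = log(x_cg^norm + 1)` where the normalisation is any fixed
size-factor scheme `x^norm = x^raw / S_c`; the package computes
counts-per-million natively (`normalize_log1p`, `S_c = sum_g x_cg / 1e6`)
and ingests any pre-normalised matrix. The log transform stabilises the
variance and reduces skewness, which is what makes one- and
two-component Gaussian descriptions of per-gene distributions usable.

The reference matrix is expected to contain highly variable genes
(plus any markers the analyst adds). This is a documented contract,
not an enforced check: HVG selection belongs to upstream tools
(scanpy and friends), and its purpose here is to ensure that a binary
view of each gene is biologically meaningful. Query matrices passed to
`binarize` must use the same normalisation as the reference; the
package cannot detect a mismatch, so this too is part of the contract.

## Per-gene statistics and classification

For each gene the model computes the dropout rate (fraction of zeros)
and amplitude (max - min) on all values, and the remaining statistics —
mean, variance, median, skewness, excess kurtosis, Hartigan's dip test
p-value, Bimodality Index, kernel-density peak — on the strictly
positive values. Computing shape statistics on non-zero data matters:
dropout zeros otherwise deflate means and inflate variances enough to
ruin Gaussian descriptions of the non-zero signal.

The classification cascade is fixed-order:

1. **discarded** if dropout rate > 0.95 (configurable; 0.99 is a
   common permissive variant), or amplitude < median amplitude / 10,
   or fewer than 10 non-zero observations (which would starve the EM
   and dip test);
2. **bimodal** if the dip test rejects unimodality at alpha = 0.05
   *and* the Bimodality Index exceeds 1.5, the conventional cut-off
   for calling two components well separated;
3. **zero-inflated** if the kernel-density peak (Gaussian kernel,
   Silverman bandwidth, 512-point grid) of the full distribution lies
   within the lowest 10% of the gene's amplitude — an excess of zeros
   dominates the distribution;
4. **unimodal** otherwise.

Kurtosis and the density peak are computed and reported for every gene,
but only the dip/BI pair and the peak location gate the cascade; the
other statistics are diagnostics.

The Bimodality Index is `delta * sqrt(p(1-p))` with
`delta = (mu2 - mu1) / sigma_pooled` from a provisional two-component
fit, `sigma_pooled^2 = phi1 sigma1^2 + phi2 sigma2^2`. EM fits (and the
provisional fit behind the BI) sort the input values first, so every
learnt quantity is invariant to cell ordering; components are always
relabelled so that `mu2 > mu1`.

### The dip statistic

No dip-test implementation ships with the scientific Python stack, so
the statistic is implemented here from its definition: the dip of a
distribution function F is the smallest sup-norm distance between F
and the class of unimodal distribution functions (convex up to the
mode, concave after it, with at most one atom, at the mode). For an
empirical CDF the mode can be restricted to the observed support; with
the mode fixed, each branch must thread the tube `F_n ± eps`, which
reduces to greatest-convex-minorant / least-concave-majorant
feasibility conditions plus a meeting condition at the mode derived
from chord-extension bounds. The final computation binary-searches the
dip value itself, with an O(k log k) feasibility sweep per candidate
value (convex-hull tangents plus Li Chao line envelopes), and is exact:
the test suite checks it against a linear-programming oracle written
directly from the definition (exhaustive over mode placements) and
against an exhaustive per-mode scan, as well as against analytic values
(0.25 for two equal atoms, 1/(2n) for evenly spread distinct points).

P-values use a Monte-Carlo table of the null distribution for uniform
samples — the standard calibration — with 10,000 replicates per
tabulated sample size (10 to 2000), frozen in `_dip_table.py` and
regenerable with `scripts/make_dip_table.py`. Between tabulated sizes
the quantiles are interpolated on the `sqrt(n)`-scaled dip; beyond
n = 2000 the largest tabulated row is used on the scaled axis, which is
the statistic's asymptotic regime. A seeded bootstrap
(`dip_pvalue(..., method="bootstrap")`) is available when an exact
finite-n null is wanted; it is not the default because it costs seconds
per gene at scRNA-seq sizes. P-values below the table's resolution are
reported as 5e-4.

## Parametric fits

* **bimodal**: two-component univariate Gaussian mixture by EM
  (k-means initialisation, 5 restarts, tolerance 1e-6, up to 500
  iterations, small covariance floor); a degenerate fit (collapsing
  variance) is retried with new initialisations up to 5 times before
  erroring.
* **unimodal**: mean and standard deviation of the non-zero values plus
  an empirical quantile table (linearly interpolated "type 7"
  quantiles on a 201-point probability grid, exact at multiples of
  0.005 — the default binarisation quantiles — and compact to
  serialise).
* **zero-inflated**: the non-zero sub-distribution is re-tested for
  bimodality with the same dip/BI criteria and fitted as the
  corresponding sub-case; the profile records which sub-case applies.
  The inflation of zeros itself is carried by the dropout model, not by
  the parametric fit.

## Dropout model

The probability that gene g's prior pseudocount x is observed as zero
is an exponential decay, clipped to one:

    P(x_obs = 0 | x) = min(1, beta_g * exp(-lambda_g * x))

* `lambda_g = ln(2) / mean_nz(g)`: the decay's half-life is set to the
  gene's non-zero reference mean, so a typical cell loses the gene with
  probability beta/2.
* `beta_g = n * tau_g_ref / sum_c exp(-lambda_g x_c)`, computed **per
  generated batch** from that batch's sampled prior pseudocounts. The
  dropout count across cells is Poisson-binomial (independent Bernoulli
  trials with unequal probabilities), and this beta makes its
  expectation equal the target rate exactly whenever no pointwise
  probability clips at 1. tau_ref is stored in the profile; beta is
  ephemeral.

Clipping is this implementation's resolution of the decay exceeding 1
at small x for large beta: probabilities are capped rather than the
rate renormalised, and under active clipping the realised rate falls
short of the target (the expected shortfall is computable with
`expected_dropout_rate` and is exercised in the tests). Existing zeros
get `p = min(1, beta)` like any x = 0 and remain zero regardless of the
draw: dropout never creates positive values and never alters surviving
ones.

## Binarisation

Category-dependent, deterministic, three-valued:

* **bimodal** — posterior component membership
  `p(C_i | x) = phi_i N(x | mu_i, sigma_i^2) / sum_j ...` (computed in
  log space) against a confidence threshold theta, default 0.95: call 0
  if `p(C1|x) >= theta`, 1 if `p(C2|x) >= theta`, undetermined
  otherwise. The branches are mutually exclusive for theta > 0.5. With
  unequal component variances the posterior is not monotone in x far
  from the modes; the rule is applied exactly as stated, without
  monotonisation.
* **unimodal** — Tukey-style fences on the non-zero empirical
  quantiles: 0 below `Q(q) - alpha*IQR`, 1 above `Q(1-q) + alpha*IQR`
  (defaults q = 0.05, alpha = 0). Quantiles are computed on non-zero
  values, consistent with all other non-zero statistics; zeros of a
  unimodal gene then fall below the lower fence whenever the gene's
  support is positive. The rule is nonparametric, so genes that remain
  skewed after the log transform binarise just as well (the log-normal
  fixture exercises this).
* **zero-inflated** — zero-or-not: positive values are active; zeros
  take the label z, by default undetermined (their technical/biological
  cause is unknown), optionally 0 when zeros are treated as signal.

Discarded genes are removed from the output (with the discard reason
logged); `keep_discarded=True` restores them as all-undetermined
columns.

The overall determined fraction is estimated by
`xi (1 - tau) + b p* + eta 2q`, with xi, b, eta the category
proportions among kept genes, tau the mean reference dropout rate of
the zero-inflated genes (the only genes whose determined fraction
depends on their zeros when z is undetermined; with z = 0 the first
term is xi), and p* the mean probability mass of the fitted mixtures in
the regions where the bimodal rule decides, obtained by numeric
integration per gene. p* is not otherwise defined by the rule set, so
this estimator is a documented choice.

## Synthetic generation from Boolean states

For each Boolean sample row and each mapped gene,
`n_samples_per_state` cells are drawn from the part of the gene's fit
matching the activation state:

* unimodal (and zero-inflated with unimodal sub-fit):
  `mu + |N(0, sigma^2)|` when active, `mu - |N(0, sigma^2)|` when
  inactive — half-normals on either side of the mean;
* bimodal: `N(mu2, sigma2^2)` when active, `N(mu1, sigma1^2)` when
  inactive.

Draws are clipped at zero (all categories alike, including inactive
half-normals that cross zero), then dropout is simulated with the
gene's lambda and a batch-solved beta targeting the reference rate
(`learned`), a caller-supplied rate (`user_rates` — the decay shape and
gene-specific lambda are kept, only the expected rate is retargeted, so
arbitrary rate distributions can be imposed while preserving the
within-gene mean-dropout decay), or skipped (`none`). Rows are indexed
`<state_id>::<replicate>`. Per-gene random substreams are derived from
the seed and the node id, so output is reproducible and independent of
column order; generation is state-major, gene-minor.

Boolean inputs must be strictly binary. Undetermined entries are
rejected with guidance, because sampling under "?" has no defined
semantics; `boolean_states_from_binary` is provided as a pragmatic
closure (fill an undetermined call by comparing the expression value to
the gene's non-zero median) for feeding a dataset's own binarisation
back into the generator, and is not part of the binarisation contract.

## Matching Boolean nodes to reference genes

Artificial models' nodes are not genes, so each node is classified as
unimodal / bimodal / zero-inflated and then assigned a distinct
reference gene of that category. Features are the first four moments
(mean, variance, skewness, excess kurtosis), min-max scaled per moment
on the reference and fed to a k-nearest-neighbours classifier (k = 5,
Euclidean, both configurable) trained on the reference labels.

The embedding is the one genuinely open design point. Raw pseudocount
moments of genes are incommensurate with the moments of 0/1 node
vectors (a gene mean lives on a 0-8 log scale, a node mean in [0, 1]),
and min-max scaling does not repair that: with raw-moment features a
balanced node lands nearest the zero-inflated genes. Instead each
reference gene is embedded by the Bernoulli moments of its *learnt
activity fraction* — the active component weight phi2 for bimodal
genes, the non-zero fraction `1 - tau_ref` for unimodal and
zero-inflated genes — and node columns by the Bernoulli closed forms at
their activity fraction (identical to the 0/1 sample moments away from
degeneracy). Genes and nodes then live on the same one-parameter moment
curve, and proximity in scaled-moment space means similarity of
activity patterns: mostly-active nodes sit next to the always-on
unimodal genes, balanced nodes next to even-weight bimodal genes,
rarely-active nodes next to heavily dropped-out zero-inflated genes.
Activity fractions are clamped to [0.02, 0.98] before computing shape
moments because Bernoulli skewness and kurtosis diverge at the
endpoints and would otherwise dominate the scaled distances; degenerate
moments arising elsewhere (zero-variance vectors) are imputed as 0 and
flagged by a NaN-free scaled table.

Assignment within a category is greedy nearest-first over all
remaining (node, gene) pairs, with lexicographic (node id, gene id)
tie-breaks: deterministic, injective by construction, and an error
naming the category when nodes outnumber available genes. Optimal
bipartite matching would minimise the total distance instead; the
greedy rule is kept for transparency and noted as a possible extension.

## Boolean networks

Networks are parsed from BoolNet text ("targets, factors" with `!`,
`&`, `|`, parentheses, constants) or built from explicit truth tables;
the writer emits the original expressions or a DNF reconstruction, and
parse-write-parse is a fixpoint. Supported dynamics: synchronous
iteration and the fully asynchronous random walk (one uniformly chosen
unstable node flips per step, stopping at a fixed point or a step cap).
Influence graphs enumerate all configurations exhaustively (guarded to
n <= 20 nodes) and record a positive edge j -> i when some
configuration has `f_i` increasing in `x_j` and a negative edge when
decreasing; both can coexist for non-monotone dependencies. The
most-permissive update mode is not implemented. Three demonstration
models ship as code: a star network (a self-sustaining TF activating
independent genes — the asynchronous walk from "TF on, genes off"
activates genes one per step in random order and stops at the
all-active fixed point), a bistable reprogramming switch (a common
state destabilised by a perturbation input into two mutually exclusive
fates), and a tri-stable two-level differentiation model (fate A
competes with an intermediate that opens a second branch point between
fates B and C).

## Synthetic reference fixtures

`synthetic.generate_reference_fixture` draws each declared gene from
its parametric model (normal / two-component mixture / low-mean normal
for zero-inflated genes; a shifted log-normal variant for the
misspecified-tails fixture), clips at zero and applies the dropout
model targeting a declared rate — exactly the data-generating process
the learning side assumes. This is deliberate: recovery tests then
isolate implementation errors from model misspecification, and the
log-normal fixture separately exercises the nonparametric binarisation
path. What passing these tests does *not* show: robustness to real
data's cell-to-cell covariance structure, batch effects, library-size
dependent dropout, UMI discreteness, or mixtures with more than two
modes — none of which the generator emulates.

Default study conditions (used by the test suite and the acceptance
script): 2000 cells; 10 unimodal genes (mu from 4.0 to 6.7, sigma from
0.50 to 0.95, no dropout, so their determined fraction isolates the 2q
fence law), 10 bimodal genes (component means near 1.2-1.9 and 5.0-6.8,
sigmas 0.45/0.55, weights 0.35-0.62, dropout targets 0.10-0.28), 10
zero-inflated genes (non-zero mean 1.2-1.74, sigma 0.4, dropout targets
0.55-0.73). The calibration fixture spans dropout targets 0.1-0.8 on
tight normals (mu = 2, sigma = 0.15); the spread is chosen so that no
pointwise dropout probability clips at 1 (roughly
`3.3 sigma < ln(1/tau)/lambda`), which is the regime where the
Poisson-binomial expectation equals the target exactly.

## Numerical and reproducibility choices

* One seed per top-level operation; per-gene/per-node substreams are
  derived from it and a CRC of the gene id, so results are invariant to
  column order and to adding unrelated genes.
* Variance of non-zero values uses ddof = 1 (a sample estimate of the
  fit's sigma^2); full-matrix moment summaries use population formulae
  (ddof = 0) so Boolean columns reproduce Bernoulli closed forms.
* Binarisation consumes no randomness and is bit-identical across runs.
* The dip inner loops are JIT-compiled (numba) with a pure-Python
  fallback; the first call in a fresh environment pays a one-time
  compilation cost of a few minutes, cached on disk afterwards.
* Undetermined activity is NaN in memory; on disk the token is
  configurable ("?" default, "NA" dialect) at the I/O boundary only.

## Known limitations

* The dropout model is gene-wise: no cell-level (library-size)
  covariates, no gene-gene dependence of dropout events.
* Clipping of dropout probabilities biases realised rates downward for
  genes whose targets are unreachable given their expression range;
  the gap is quantifiable but not corrected.
* Mixtures are limited to two components; multimodal genes beyond two
  modes are forced into the bimodal description.
* The unimodal binarisation depends on reference quantiles only, so it
  presumes query data share the reference's normalisation and dynamic
  range.
* Node-gene matching is greedy, not globally optimal, and its
  activity-fraction embedding compresses each gene's distribution to a
  single number; models with many nodes of nearly identical activity
  fractions may be assigned interchangeably.
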