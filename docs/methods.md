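# Methods

## Model and scope

The package infers undirected association networks among microbial taxa
from compositional 16S count tables and compares them between study
groups. The statistical object is a sparse Gaussian graphical model on
centered log-ratio (CLR) coordinates: an edge means a non-zero partial
correlation between two taxa's CLR abundances given all others. Estimation
is node-wise (Meinshausen–Bühlmann neighbourhood selection) rather than a
full inverse-covariance fit: per-node lasso regressions are cheap, behave
well when taxa outnumber what a joint fit can support, and are the
"neighbourhood" variant of the compositionally robust inference used in
microbiome work.

Two network levels are produced. The population network (MNP) is the
pipeline applied to all samples of a group. The single-sample network
(MNI) is the signed difference between the MNP and a leave-one-out refit:
`gained` edges (present only with the sample included), `lost` edges
(present only without it), and weight deltas on shared edges. The MNI is
stored as that difference object, not a bare graph, so the subtraction is
lossless: patching the leave-one-out network with the MNI reproduces the
full MNP exactly (edge sets exact, weights to 1e-8; enforced by tests).

## Preprocessing

- **Taxon filter.** Keep a taxon iff its mean per-sample relative
  abundance is ≥ `rel_abund_min` (default 1e-4, i.e. 0.01%) AND its
  prevalence (fraction of samples with count > 0) is ≥ `prevalence_min`
  (default 0.37). The two thresholds combine with AND; the abundance
  summary statistic is the mean across samples, with `max` available via
  `abundance_stat`. Prevalence is assessed on the un-rarefied counts by
  default.
- **Rarefaction** (default off for network inference): subsample each
  sample to `rarefaction_depth` (default 50,000) reads without
  replacement via multivariate hypergeometric draws; samples below the
  depth are dropped and logged, never up-sampled. Rarefaction is applied
  only when `rarefy_enabled` is set, since the network pipeline's CLR
  step does not require a common depth; both orders (filter → rarefy →
  CLR and filter → CLR) are reachable through the configuration.
- **CLR transform.** `ln(x + c) − mean ln(x + c)` with pseudocount
  `c = 1`. Rows sum to zero by construction; on strictly positive rows the
  transform is invariant to scaling counts and pseudocount together
  (property-tested). Multiplicative replacement is not implemented.

## Network inference

- **Penalty path.** λ_max is the largest absolute pairwise correlation of
  the column-standardized CLR matrix (the lasso KKT bound at which every
  neighbourhood is empty); the path is 20 log-spaced values down to
  `lambda_min_ratio · λ_max` with `lambda_min_ratio = 0.01`.
- **Neighbourhood regressions** standardize predictors and response, so
  coefficients are on the correlation scale; zero-variance taxa are
  excluded with a warning. The lasso is solved by coordinate descent
  (scikit-learn `lasso_path`, tolerance 1e-6, max 10,000 iterations);
  a brute-force coordinate-descent oracle in the test suite checks the
  coefficients along the path to 1e-5.
- **StARS.** Networks are re-estimated on `n_subsamples = 50` subsamples
  of fraction 0.8 drawn without replacement (the 80% level mirrors the
  bootstrap fraction used elsewhere in the pipeline). Mean edge
  instability D̄(λ) ∈ [0, 0.5] is monotonized by running maximum walking
  from λ_max toward denser models, and the smallest λ (densest graph)
  with monotonized instability ≤ 0.05 is selected. If no λ qualifies, the
  sparsest is returned with a `no_stable_lambda` flag. Note that with the
  0.8 subsample fraction the subsamples overlap heavily, so a handful of
  dataset-level spurious correlations can stay "stable"; on
  column-permuted data the expected edge count is a few edges regardless
  of sample size, which is only a small fraction of the signal when the
  true network is moderately large (the permutation sanity test uses
  p = 20 taxa, 600 samples, where the ratio is ≈ 4–5%).
- **Symmetrization.** OR rule by default (edge present if either directed
  coefficient is non-zero), AND available; edge weight is the mean of the
  two directed coefficients, with a missing direction counting as zero
  under OR. Edge `stability` records the StARS selection frequency at the
  selected λ.

## Single-sample networks and ensembles

- **Pinned λ (default).** Leave-one-out refits reuse the full-data
  selected λ, so an MNI reflects the removed sample rather than
  re-selection noise, and the refit is a deterministic point estimate.
  `free` mode re-runs StARS per leave-out.
- **MNI summary metrics.** Degree, edge and node counts are taken on the
  perturbation support — taxa incident to a gained, lost, or changed edge
  (|Δweight| > 1e-8) — because they describe the perturbation itself.
  Robustness and natural connectivity are assessed on the perturbation
  graph over the *full* taxon set (isolated taxa included): connectivity
  robustness is a community-level property, and scoring it on the support
  alone rewards small concentrated perturbations over large connected
  ones (a normalization artifact we measured and rejected).
- **Bootstrap ensembles** re-infer the network on `n_networks`
  (default 1000) random 80% sample subsets drawn without replacement from
  the sorted sample ids (so the ensemble is invariant to row order), each
  replicate seeded by its draw index. By default each replicate is a
  point fit at the full-data λ; `free` mode re-runs StARS per replicate
  at ~50× the cost.

## Attack robustness

Nodes are removed in decreasing betweenness centrality, ties broken by
degree and then node id, with the ranking computed once on the intact
graph (static attack; a recompute-per-step mode exists). After each
removal the largest-component size and the natural connectivity
`NC = ln((1/n) Σ exp(μ_i))` are recorded (computed via `logsumexp`; the
"mean of adjacency eigenvalues" reading is degenerate — it is identically
zero for simple graphs — so the standard exponential-mean definition is
used). Robustness is the trapezoidal AUC of the largest-component
*fraction of all nodes* against the fraction removed. For connected graphs
this equals normalizing by the initial response; for disconnected graphs
it correctly scores fragmentation as lost robustness, and it makes the
complete graph provably maximal among graphs of equal order (any graph
after k removals is a subgraph of K_{n−k}). The natural-connectivity
response (normalized by its intact value) is available as an alternative;
fragility is reported as 1 − robustness so that decreased fragility means
increased robustness.

## Cohort statistics

- **Bootstrap mean test**: both groups shifted to the pooled mean,
  resampled with replacement within groups, two-sided p from the
  studentized statistic with the +1/(B+1) correction. The studentized form
  is used because the raw mean-difference comparison is anti-conservative
  at small n (measured type-I ≈ 0.07 at n = 15–35 vs ≈ 0.045
  studentized). The reported statistic is the observed mean difference.
- **Paired Wilcoxon**: zero differences dropped (Wilcoxon's rule; Pratt
  available), ties mid-ranked; the exact two-sided null is computed by
  dynamic programming over doubled mid-ranks for n ≤ 25 and matches full
  sign enumeration (oracle-tested to n = 10); a tie-corrected normal
  approximation (no continuity correction) is used above.
- **Pearson correlation** with `t = r√((n−2)/(1−r²))` and the two-sided
  Student-t p-value.
- **Change summaries**: fold change follow-up/baseline and percent change;
  `percent_change = 100·(fold_change − 1)` holds exactly; presentation
  rounding (2 dp fold changes, integer percents) lives in dedicated
  properties, never in the stored values.

## Synthetic data generator

The generator emulates a two-timepoint skin-swab cohort: defaults of 36
baseline and 34 post samples; read depths from a log-normal law
(σ = 0.5 on the log scale, mean 326,333) truncated to [63,892, 975,103],
matching the study-style depth spread; 30–60 species-level taxa with a
mildly uneven base composition (log-normal offsets, σ = 1 — real skin
communities are uneven, and a perfectly flat composition would flatter
the inference).

Ground-truth graphs: band (k nearest index-neighbours), Erdős–Rényi with
an *exact* edge count (pairs sampled without replacement, so densities
are deterministic and testable), preferential attachment, and a
three-block cluster topology. The precision matrix places couplings of
magnitude 0.3 with per-edge Rademacher signs on the support (microbial
associations are both positive and negative; sign cancellation also keeps
the coupling spectrum small, so dense graphs do not force vanishing
partial correlations — with uniformly positive couplings the
positive-definiteness ceiling caps partial correlations at ≈ 1/|λ_min(A)|,
which decays with density) and a uniform diagonal shift targeting
condition number 10, floored so the matrix is always positive definite.
Counts are multinomial draws from softmax-transformed latent Gaussians
with covariance = inverse precision. All randomness flows from one integer
seed through keyed `SeedSequence` splits, so every artifact is a pure
function of (parameters, seed).

For two-arm cohorts both arms share one diagonal shift (the larger of the
two arms' condition-target shifts): otherwise the denser arm's edges are
systematically weaker and the density contrast is confounded with edge
strength in the wrong direction (we measured exactly this before fixing
it).

What the generator does **not** model: read-level artifacts (chimeras,
taxonomy mis-assignment), overdispersion beyond the logistic-normal,
zero-inflation beyond multinomial sampling, subject-level pairing between
timepoints, or batch effects. Passing tests therefore demonstrate that the
pipeline recovers known structure under its own model assumptions, not
that real skin data satisfy those assumptions.

## Problem sizes and what the checks show

- Band-graph recovery: p = 30 taxa, n = 300 samples, depth 50,000,
  10 seeds; mean F1 ≈ 0.83–0.91 against the true support.
- MNI reconstruction: 20-sample, 20-taxon cohort; the patch identity is
  exact for every sample.
- Two-arm contrast: 20 + 20 samples, p = 30, true densities 0.05 vs 0.15.
  At this deliberately small size StARS detects only a fraction of the
  true edges, and the *estimated* density ordering matches the truth in
  roughly two-thirds of realizations; the packaged test runs one fixed
  seed, and the acceptance script reports the contrast averaged over five
  replicate cohorts. At the study-scale simulation (36 + 34 samples,
  60 taxa) the individual-level contrast is significant for all four
  metrics while node counts at the population level do not move — the
  motivating pattern for single-sample networks.
- Bootstrap calibration: 500 same-distribution replicates at n = 35 per
  group, B = 2000 resamples; rejection rate ≈ 0.05 within [0.03, 0.07].

## Known limitations

- Neighbourhood selection with 80% subsampling keeps a few spurious edges
  stable on null data (see above); canonical StARS subsample sizes
  (~10√n) would be stricter but are not what the pipeline mirrors.
- The MNI difference object is defined relative to the pinned-λ refit;
  under `free` λ mode the reconstruction identity still holds, but MNI
  size mixes sample influence with re-selection variability.
- Network weights are correlation-scale lasso coefficients, not partial
  correlations; magnitudes are comparable within a fit, not across
  different λ selections.
- `paired_wilcoxon` requires ≥ 5 non-zero differences (exact inference is
  meaningless below that); degenerate inputs return flagged results
  rather than raising wherever a defined value exists (all-zero
  differences → p = 1).
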