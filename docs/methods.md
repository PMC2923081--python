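# Methods

This note documents the models implemented in `pgpscan`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Axis profiles and binarization

All spatial quantities live on a 100-bin discretization of the
anterior–posterior axis (bin 1 = most anterior).  Raw intensity traces
(e.g. 320-point image-derived profiles) are averaged into 100
equal-width bins with fractional-overlap weighting, and a bin is called
expressed when its mean exceeds `threshold_frac` (default 0.25) times
the maximum bin mean.  The threshold-on-fraction-of-peak rule is this
package's own choice of a simple, scale-free binarization; contiguous
runs of expressed bins are reported as domains.  An all-zero trace
yields an all-zero profile rather than an error.

## HMM motif scoring

The window score is the log-likelihood ratio of a two-state generative
model against an order-0 background.  At each decision point the
process emits one background base (probability 1−q) or a complete
motif occurrence of width W drawn from the PWM, on the forward or
reverse strand with probability q/2 each.  Occurrences therefore
cannot overlap; the forward recursion over likelihood *ratios*

    g[j] = logaddexp( g[j−1] + log(1−q),  g[j−W] + log(q/2) + lm[j−W] )

(`lm` = log of forward+reverse site likelihood ratios) runs entirely
in log space, so arbitrarily long windows cannot underflow.

Choices:

- **q is profiled out by maximum likelihood** over [0, q_max] with
  q_max = 0.1, by a vectorized grid (32 points, one recursion pass
  evaluates all of them) plus two local refinement passes.  Since q = 0
  reproduces the null, the fitted score is ≥ 0 by construction.
- **N bases** are emitted with probability 1 under both states and
  contribute nothing to the ratio; an all-N window scores exactly 0.
- **Strand symmetry** holds exactly whenever the background is
  complement-symmetric (p(A)=p(T), p(C)=p(G)), which includes the
  uniform default.
- For a PWM identical to the background the likelihood is strictly
  decreasing in q for W ≥ 2, so the fitted score is exactly 0 on any
  sequence.  For an informative PWM a background window usually scores
  0 but can pick up a small positive score from a chance site; this is
  a property of the model, not noise in the implementation.
- Defaults: 500 bp windows with 250 bp shift for genome-style
  profiles; whole-window scoring for CRMs and 1 Kbp scan windows.
  Only an order-0 background is implemented (extension point:
  `MotifModel.background`).

Window z-scores are taken against the mean and population SD of all
windows in a profile, with support categories significant (z > 2),
weak (0 < z ≤ 2), absent (z ≤ 0).

## Brownian-motion tree averaging

Orthologous window scores are combined either by the arithmetic mean
or as E[(1/T)∫ X(t) dt | leaf values] for a Brownian motion X on the
phylogeny (T = total branch length).  Conditional on the data, the
expectation of X at interior time points along a branch interpolates
linearly between the endpoint posterior means, so the average reduces
to Σ_b τ_b (m_parent + m_child)/2 / Σ_b τ_b.  Posterior means come
from Gaussian message passing (one upward, one downward pass — O(n))
under a **diffuse root prior**; this makes the answer independent of
the BM rate, since σ² cancels from conditional means.  Unobserved
leaves are marginalized, zero-length branches tie parent and child.
The O(n²) oracle conditions explicitly on the joint Gaussian
(cov = shared root path length, GLS root mean) and exists for
cross-validation only.

A consequence worth noting: on any two-leaf tree the temporal average
equals the plain mean of the two values — the inverse-branch-length
precision weighting of the root estimate exactly cancels the
branch-length weighting of the integrals.  Weighting effects appear
only with ≥ 3 leaves and asymmetric topologies (a clade of close
relatives is down-weighted relative to a distant lineage).

## Expression model

`Ê_{l,b} = σ(α_l + Σ_i w_i (c_{i,b} S_{i,l})^{k_i})` with k ∈ {1, 2};
squared terms are restricted to factors that also carry a linear term
(used for the steep anterior gradient).  Binary targets are fit under
a Bernoulli likelihood by IWLS with:

- **ridge 1e-6**: small binary datasets separate easily; the penalty
  keeps all coefficients finite while perturbing non-separable fits
  negligibly.  Separation is additionally flagged
  (`separation_flagged`).
- **step-halving**: undamped Newton steps oscillate on separable
  data; with step-halving the penalized objective is concave and the
  iteration converges globally (verified against L-BFGS to ~1e-10 in
  the objective).
- convergence at relative objective change < 1e-8 or 100 iterations;
  zero-variance covariates are dropped with a warning.

Fit statistics: RMSE over all CRM × bin cells; mean per-CRM Pearson
correlation (CRMs with a constant prediction or target are excluded
and counted); AIC = 2k − 2·loglik with k = #TF terms + #baselines.
z = w/SE with SEs from the penalized Fisher information.

Cross-validation follows the replicated half/half cell-split design:
each replicate holds out a random 1/folds of the CRM × bin cells,
trains on the rest, and reports test RMSE; shuffle mode first permutes
the CRM↔profile matching.

## PGP

reward = mean prediction over expressed bins, penalty = mean over
silent bins, PGP = 0.5 + 0.5(reward − 3·penalty).  The penalty weight
3 is a named constant (`PENALTY_WEIGHT`).  For multi-domain patterns,
the non-empty subset of domains maximizing PGP is selected, with
unselected domains' bins excluded from **both** terms ("don't care").
Counting them as non-expression instead would penalize a CRM for
domains it does not drive, defeating the purpose of sub-domain
matching.  Since the penalty term does not depend on the selection,
maximization effectively picks the domain(s) with the highest mean
prediction; ties prefer fewer domains, then the anterior-most
(deterministic, seedless).  Subset search is exhaustive up to 12
domains and greedy add-one beyond.

## Discovery

Scan windows have no trained baseline; they are predicted with the
mean of the trained per-CRM baselines (the least-informative choice).
Window 1000 / step 500 (the 50% overlap is this package's default;
only the window size is canonical).  Empirical p-values use the
add-one rule p = (1 + #{null ≥ x})/(1 + N), which is never 0 and
uniform on (0,1] under the null regardless of the null distribution.
The null set is a background window scan supplied by the caller
(genome-wide and exon-masked in production; synthetic background loci
in the tests).  Calls require p < 0.015 and at least one activator
with window z > 0, and overlapping qualifying windows merge to the
best-p representative.

## Network inference

Edge test: permute the TF's 100 concentration bins (without
replacement), re-predict, and rank the wild-type RMSE with
p = (1 + #{null ≤ RMSE_wt})/(1 + n_perm).  Ties count as extreme, so
a TF with zero motif score — whose permutations cannot change the
prediction — gets p = 1 exactly and never earns an edge.  One RNG
stream per (tf, crm) pair is derived from the master seed via a CRC of
the pair label, so results are reproducible under any execution order.
Default 1,000 permutations, edges at p < 0.05, sign from the fitted
weight.

Positional summaries average a TF's motif score over the CRMs active
in each bin and correlate that vector with the TF's concentration
(positive for activators, negative for repressors; bins with no active
CRM are missing).  Incongruous occupancy flags a (CRM, repressor) pair
when measured occupancy coincides with CRM activity inside the
repressor's own expression domain (defaults: GT bins 20–40 and 70–80,
KR 40–60, KNI 60–70), annotated with the motif-support category.

## Synthetic data: what it emulates and what it does not

Generators produce PWMs with a target per-position information
content (mixture of consensus and background, bisected to the target
relative entropy), background sequence of specified composition,
planted non-overlapping PWM-sampled sites, concentration shapes
matching the canonical patterning classes (anterior/posterior
gradients, interior stripes with exact support, complementary
terminal-high/terminal-low pairs), forward-simulated binary patterns
(threshold at 0.5 with the ≥ convention, optional independent bin-flip
noise), and Jukes–Cantor ortholog sets without indels (so orthology
maps stay positional).  Baselines are placed at minus the median of
the summed covariate contribution so that simulated patterns have both
expressed and silent bins.

Problem sizes used by the test suite: the training compendium is
simulated at 10 TFs × 46 CRMs × 100 bins; discovery runs on a 3-TF
model trained on 12 scored 1 Kbp CRMs, with 6 Kbp loci, a 12-locus
background null scan, 20 planted and 20 background test loci; network
recovery uses a 3 TF × 6 CRM wiring at 1,000 permutations and 200
simulations for null calibration.  These sizes were chosen so the full
suite completes in under a minute while every statistical claim is
still tested at meaningful power.

What passing tests do **not** show about real data: synthetic
backgrounds are i.i.d. (no repeats, composition heterogeneity, or
exons), planted sites never overlap or turn over across species, true
expression is exactly realizable by the model family, and concentration
profiles are noise-free.  Real-genome performance additionally depends
on motif quality, image-derived pattern accuracy, and alignment of
orthologous regions, none of which are modeled here.

## Known limitations

- Order-0 background only; no higher-order Markov background.
- No cooperative binding, site-arrangement, or thermodynamic terms in
  the expression model.
- Orthology maps are an input; whole-genome alignment is out of scope.
- The multi-domain subset selection maximizes PGP; alternative
  selection rules (e.g. coverage-based) are not implemented.
- The binarization threshold rule is a stand-in for image-pipeline
  specific discretization procedures.
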