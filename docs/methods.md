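# Methods

## The model

Hi-C summarizes proximity-ligation sequencing as a contact matrix: for a
partition of each chromosome into intervals ("bins"), entry (i, j) holds the
count y_ij of unique read pairs joining bins i and j.  Most counts reflect
random polymer ligation, whose rate decays with genomic distance and is
modulated by GC content, mappability and (for uniform bins) the restriction
site density of the bins.  The package estimates this background
distribution and calls as significant the bin pairs whose counts are
unexpectedly large under it.

The background law is a hurdle zero-truncated negative binomial (ZTNB):

* a Bernoulli gate produces a zero with probability
  `pi0_ij = logistic(gamma' x_ij)` — modelling the "drop-out" of interactions
  that are never captured in a library of finite complexity;
* conditional on crossing the hurdle, the count follows a zero-truncated
  NB2 with mean `mu_ij = exp(beta' x_ij)` and a single dispersion `alpha`
  per chromosome (variance mu + alpha·mu²).

Both linear predictors use the same design `x_ij`: a B-spline basis in the
midpoint distance d_ij plus standardized log products of the two bins' GC
content and mappability (and effective-fraction products in uniform-bin
mode).  The count part and the zero part factorize, so they are fit
separately by maximum likelihood.

The upper-tail P value of a record is `P(Y >= y_ij)` under its fitted hurdle
law (1 for y = 0, `1 - pi0` for y = 1), and Benjamini–Hochberg adjustment —
pooled genome-wide over chromosomes by default — yields q values.  O/E
normalization divides y by the full hurdle mean
`(1 - pi0)·mu / (1 - NB(0; mu, alpha))`.

## Distance spline

"Third order" B-spline here means spline order 3 (degree 2, quadratic): with
six degrees of freedom the number of inner knots is df − order = 3, placed
at the 25/50/75% quantiles of the training distances, with boundary knots at
0 and the enumeration cap (2 Mb by default) at full multiplicity (= order).
This yields exactly six basis functions that form a partition of unity, so
the basis at d = 0 is (1, 0, 0, 0, 0, 0).  Because the basis sums to one,
its span already contains the constant function; the fitted design therefore
carries **no separate intercept column** (an explicit intercept plus the
full basis would be rank-deficient).  The fitted mean function is identical
to the intercept-plus-reduced-basis parameterization.

Covariate standardization (log products z-scored per chromosome) is computed
over **all** enumerated records, not the training sample, so covariates do
not depend on the sampling seed.

## Two-pass training

Per chromosome: (1) draw a seeded simple random sample of records (default
1%; small worlds should use larger fractions — the fit needs at least
10× the parameter count); (2) fit; (3) remove sampled records whose observed
count lies in the extreme upper tail of their fitted law
(P(Y ≥ y) < 1 − outlier_q, default 2.5%) as potential true interactions;
(4) refit with the same knots.  On data that actually contain enriched
contacts, pass 2 strips their upward bias from the null.

A consequence worth knowing: on *pure null* data the trimmed refit is
slightly conservative-in-mean (it tracks a top-trimmed sample, so expected
counts are underestimated by a few percent, most visibly at large distances
where means are small and the discrete trim threshold bites).  Calibration
statements about the ML fit itself (P value super-uniformity, O/E unit
means, Wald coverage) are therefore checked against the one-pass fit; the
trimming pass is validated separately for what it is designed to do.

Quantitatively, for alpha ≈ 0.3 the plain trimmed refit shifts fitted means
down by ~4–5% regardless of depth, which is the same order as the upward
bias induced by mild contamination (1% of records at 5× their null mean).
Under such mild contamination the refit therefore does not reliably land
closer to the generating coefficients than the first pass; its benefit
materializes when enrichment is stronger or more prevalent, as in real
contact maps.  A truncation-corrected refit (conditioning the likelihood on
the trim threshold) would remove this bias but is deliberately not what the
procedure specifies.

## Fitting and numerics

* Zero part: ridge-guarded IRLS (ridge 1e-6) for the logit model on
  P(zero); the ridge keeps separated data (e.g. no zeros) finite.
* Count part: L-BFGS-B on (beta, log alpha) with analytic gradient,
  followed by Newton polishing with a finite-difference Hessian;
  convergence requires per-observation gradient max-norm < 1e-6 and
  relative log-likelihood change < 1e-8.  log alpha is bounded to
  [−20, 10]; initial beta from a Poisson IRLS on the positives, alpha
  from 0.5.
* Dispersion below 1e-8 collapses to the Poisson limit — beyond that point
  gammaln round-off at r = 1/alpha exceeds the NB/Poisson difference.
* Wald standard errors come from the inverse observed information (count
  part: finite-difference Hessian at the optimum; zero part: IRLS weights).
* A `family="poisson"` variant (zero-truncated Poisson count part) exists
  to demonstrate the P value inflation incurred by ignoring
  overdispersion; it is not meant for calling.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| merge_n | 10 | restriction fragments per bin (non-uniform mode) |
| uniform width | off (5 kb typical) | fixed-width binning; adds effective-space covariate |
| flank | 500 bp | reach of a restriction site: read filter + effective regions |
| max_distance | 2 Mb | enumeration cap = right boundary knot (inclusive) |
| sample_frac | 0.01 | training sample fraction (seeded, without replacement) |
| outlier_q | 0.975 | trim threshold: remove tail P < 1 − outlier_q |
| fdr | 0.01 | q-value cutoff for significant calls |
| df / order | 6 / 3 | spline degrees of freedom and order |

## Synthetic worlds

The generator emulates exactly the features the model conditions on:
restriction sites placed by exponential fragment lengths around a target
spacing of 256 bp (a 4-cutter's 4^4 expectation), with accidental motif
occurrences scrubbed so site density is controlled; a sinusoidal GC field
(base 0.42, amplitude 0.08, period 50 kb, per-kb noise) that induces a
realistic GC gradient across bins; a blocky mappability track (baseline
0.95 with 2 kb dips to 0.4); and counts drawn from the hurdle law itself on
the same spline + bias design, with truth coefficients giving short-range
means of ~30 reads per record decaying to ~1 at the cap and drop-out
probabilities rising from ~3% to ~70% with distance (overall mean ~2.5
reads per record, comparable to deep published maps binned at 10-RE
resolution).  Spikes redraw 1% of records in a stated distance window
through the same hurdle gate with the count mean multiplied by 5, so
fold = 1 is a no-op.

The default world is one 800 kb chromosome with the enumeration cap at
750 kb (~50 000 records).  The cap deliberately binds *inside* the
chromosome so that training distances span the full spline support up to
the right boundary knot — mirroring real chromosomes, which extend far
beyond the 2 Mb cap — otherwise the last spline coefficient sits on
unsupported basis mass and is unidentifiable.

What the generator does **not** emulate: TADs and hierarchical contact
structure (counts are independent across records given covariates),
distance-varying dispersion, inter-chromosomal contacts, fragment-length
bias, and duplicate/artifact structure in raw reads (read-pair export jitters
ends uniformly within the site flank).  A green calibration or recovery test
therefore establishes correctness of the estimator under its own
assumptions, not robustness to the spatial dependence present in real data.

## Design choices where the procedure was genuinely open

* Per-bin GC/mappability are combined across the two bins of a record by
  **product**, log-transformed (so the model sees the sum of logs), then
  z-scored.  Mean vs product is not distinguishable up to scaling once
  logged; the product convention matches the covariate construction this
  family of regression-based corrections inherited.
* The zero part uses the **same covariates** as the count part with a logit
  link — the default of the hurdle-regression framework; nothing in the
  procedure pins down a different zero-part design.
* Outlier threshold: 97.5% (the "top 3%" phrasing that circulates for this
  procedure is read as rounding).
* BH is pooled genome-wide after per-chromosome fitting; a per-chromosome
  mode exists behind a flag.
* Diagonal (d = 0) records are included in fitting by default and excludable
  by flag (they must be dropped when comparing against callers that cannot
  score them).
* Distance cap boundary is inclusive; pair end position is the 5' mapped
  coordinate; duplicate collapse is exact coordinate+strand identity after
  canonical end ordering.
* Degenerate bins (no restriction site, all-N effective region, zero
  mappability) stay in the bin table but their records are excluded from
  fitting and reported with NA P values.

## Known limitations

* A single dispersion per chromosome; real dispersion varies with distance.
* No modelling of spatial dependence between records (TAD hierarchy), so
  P values near strong structures are conservative for "corner" detection
  purposes only in aggregate.
* Inter-chromosomal records are tallied and discarded.
* The trimmed refit's few-percent conservative bias on pure-null data (see
  above) is inherent to trimming without truncation-correcting the
  likelihood.
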