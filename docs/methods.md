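# Methods

This note documents the statistical model behind `chipnorm`, the choices
made where the procedure is genuinely open, what the synthetic generator
does and does not emulate, and the numerical conventions.

## Model

An observed bin count is viewed as a deterministic transform of the true
modification level, multiplied by a local bias shared with the input-DNA
control, plus stochastic background. The three terms are attacked
separately: the background by a null model and FDR threshold, the local
bias by control normalization, and the (never explicitly estimated)
transform by quantile normalization, which equalizes its effect across the
two libraries.

### Amplified binomial null

Non-specific antibody capture scatters *n₀* fragments uniformly over *B*
bins, so a background bin count is Binomial(*n₀*, 1/*B*); constant-factor
PCR amplification multiplies every count by *a* ≥ 1. Both parameters are
identified without fitting: amplification leaves the set of empty bins
unchanged and scales the total *N*, hence

  n₀ = ln(Z₀/B) / ln(1 − 1/B),  a = N / n₀,

with *Z₀* the observed zero-bin count. Numerical conventions:

* *n₀* is real-valued; the binomial tail is evaluated through the
  regularized incomplete beta function, P(X ≥ k) = I_p(k, n₀−k+1) with
  p = 1/B, which extends the tail smoothly to non-integer *n₀*.
* Counts stay on the observed (amplified) integer scale; the threshold is
  rescaled instead: P(aX ≥ c) = P(X ≥ ⌈c/a⌉).
* An *a* estimate below 1 (possible under sampling noise) is clamped to 1
  with a warning — amplification cannot shrink a library.
* *Z₀* = 0 (no empty bins) makes the null unidentifiable and is an error;
  the remedy is smaller bins or a larger genome, not a default.
* The null is deliberately conservative on signal-bearing libraries:
  signal concentrates fragments and deepens the zero tail, so *n₀* is
  under- and *a* over-estimated, which raises the significance threshold.

The empirical FDR at an integer count threshold *c* is
min(1, B·P(aX ≥ c) / #{nᵢ ≥ c}); the significant set uses the smallest *c*
with FDR ≤ 0.05 (the field's standard target). All *B* bins enter the
expected-null term. No per-bin p-values are produced; the procedure is a
tail-ratio, not a Benjamini–Hochberg correction.

### Iterative control normalization

The control is mapped onto the data distribution by rank matching: sorted
control values pair with sorted data values, tied control values take the
mean of their paired data values, evaluation interpolates linearly and
extrapolates flat. Bins with data/mapped-control ≥ 2 are flagged as
enriched. Because enriched bins can exceed half the genome, a single fit
is distorted toward them; the map is therefore refitted on unflagged bins
only, re-applied to all bins, and the flagging repeated. Flagged bins are
removed from every later fit and stay flagged, so the enriched set grows
monotonically and each refit can only rescue bins the distorted map had
missed. Defaults: fold threshold 2.0 (the smallest conventional enrichment
cut above 1; the source procedure does not fix a value) and 2 iterations
(the first refit captures most of the correction; more iterations keep
helping when enrichment is heavy and are exposed as `--control-iters`).
Zero conventions: mapped control 0 with data > 0 counts as enriched (fold
+∞); data 0 gives fold 0. The data library itself is never transformed in
this stage.

### Quantile normalization and calling

Both libraries' stage-2 bin values get a fitted inverse CDF: a monotone
piecewise-cubic (PCHIP) interpolant through evenly spaced percentile knots
(101 by default) of the empirical quantiles. PCHIP cannot overshoot, so
the map stays monotone and invertible. Decile-spaced knots were
considered and rejected: bin counts are discrete, their inverse CDF is a
staircase, and coarse knots smooth it so strongly that the transformed
sample visibly departs from the target distribution (KS error ≈ 0.04–0.07
on negative-binomial counts). Percentile inversion returns the midpoint
of a flat stretch, so an atom's mass is centred rather than pushed to one
edge; even so, no deterministic value map can split an atom, which bounds
the achievable KS distance from below by roughly half the largest atom
mass. At the count depths the pipeline operates on (tens per bin and up)
this floor is well under 0.02.

Calling conventions:

* Library 1 is mapped onto library 2's scale (y₁ = F₂⁻¹(F₁(x₁))); both
  DHE directions and CHE compare y₁ with x₂.
* The percentile gate (default 0.5) is evaluated on the candidate
  library's own inverse CDF. The alternative — requiring both libraries
  above the cutoff for DHE — would forbid calling a bin differential
  precisely when the other library lacks it, so the one-sided gate is
  used.
* The median cutoff follows from the union construction: if the two
  libraries' enriched-significant sets overlapped only by chance, about
  half the stage-2 bins would be enriched in any one library, and the
  median separates them.
* Fold with a zero denominator is +∞, no pseudocounts — stage-1 filtering
  makes true zeros rare in the stage-2 set; two zeros give NONE.
* Label swap symmetry is exact when the two libraries differ by a pure
  scale factor (the quantile map is then linear). A non-linear
  distribution difference bends the map, and because the fold is measured
  on library 2's scale, threshold-edge bins may flip to NONE under a
  library swap; the two directions never contradict each other. This is a
  property of the asymmetric construction, not of the implementation.

## Baselines

Unit-mean divides each library by its trimmed mean (mean of non-zero
bins); quantile-only applies the stage-2 transform genome-wide with no
filtering and no percentile gate; rank normalization replaces values by
decile indices (ordinal ranks split ties) and thresholds the per-bin
decile difference — differences are measured in decile units, the natural
reading of a rank method; two-stage unit-mean restricts unit-mean to the
stage-2 set. All label symmetrically under library swap (quantile-only up
to the map-bending caveat above).

## Synthetic data

The generator emulates exactly the nuisance structure the method targets.
Fragment destinations are multinomial with probability ∝
bias × (background + signal), so totals are exact and per-bin background
is binomial marginally, consistent with the null; the control draws from
the bias alone; amplification is a deterministic constant factor.

Study conditions (defaults, chosen once as a realistic operating point):

* 50,000 bins of 1 kb (one 50-Mb synthetic chromosome — 50 windows of
  1 Mb for density analyses); mean background depth 10 fragments per bin
  before amplification, the regime of a typical deeply sequenced library
  binned at 1 kb.
* Planted enrichment ~100× the per-bin background weight with lognormal
  spread 0.25 — strong histone domains sit one to two orders of magnitude
  above background at this resolution — and a planted fold of 4 between
  conditions for differential bins.
* 500 differential bins per direction and 100 shared bins, so ~55% of the
  stage-2 set is enriched per library, matching the union/independence
  argument behind the median gate. With a large shared fraction the gate
  structurally removes the bottom (stage2/2 − n_low)/n_high of the
  enriched cloud — a property of the method worth knowing when most
  domains are shared.
* The *noisy* preset (bias experiments) instead plants broad,
  mostly-shared domains over ~16% of the genome with gene-density-like
  gradient placement, five-fold background in library 2 and a four-fold
  amplification mismatch; the *amp-asymmetric* preset keeps backgrounds
  equal and varies only amplification; *replicate* redraws one condition
  twice.
* A shared open-chromatin bias (5% of bins, 4×) multiplies both each
  library and its control.

Genes are placed with TSSs centred on planted bins whose neighbours carry
no conflicting label (promoter windows span adjacent bins), and expression
opposes the repressive-mark truth with configurable strength.

Not emulated: fragment-length distributions, sequence- or GC-dependent
efficiency, stochastic PCR, read-level mappability, and correlated
(domain-shaped) background. Passing tests therefore demonstrate the
statistical machinery under the assumed noise model, not performance on
any particular real dataset.

## Problem sizes

Tests and the acceptance script use 10⁴–10⁵-bin genomes, 10–20 seeds per
stochastic check, and 10⁴-point samples for distribution tests — sizes at
which every check completes in seconds while keeping Monte-Carlo error
well inside the asserted margins.

## Known limitations

* The zero-bin estimator needs empty bins; very deep libraries at coarse
  bins must be re-binned finer.
* The empirical-FDR threshold is genome-wide; no local (window-level)
  nulls.
* Only pairwise comparisons; multi-library joint normalization is out of
  scope.
* The percentile gate costs recall on true differential bins lying below
  the stage-2 median of their own library; this is inherent to the
  published construction.
* External caller output is integrated only as labeled BED via the generic
  reader; no external tools are re-implemented or invoked.
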