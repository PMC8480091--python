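# Methods

## Model and procedure

`glscan` treats each diallelic site's genotypes as Binomial(2, π_ij)
draws, where the individual allele frequency π_ij carries population
structure, and works from genotype likelihoods P(X_ij | G_ij = g) rather
than called genotypes. The fit alternates four exact steps:

1. posterior dosage E[G_ij | X_ij, π̂_ij] under a Binomial(2, π̂_ij) prior;
2. standardization y_ij = (E[G|·] − 2f̂_j)/√(2f̂_j(1−f̂_j)) using the
   *population* frequency f̂_j in both the centering and the variance —
   structure must remain in y for the SVD to find it, so π̂ never enters
   the standardization;
3. truncated SVD of the N×M matrix Y, keeping K components;
4. π̂ update by inverting step 2 on the rank-K reconstruction, clipped to
   [clip, 1−clip].

Iteration starts at π̂⁰_ij = f̂_j and stops when the RMS change of π̂
falls below `tol` (default 1e-5, cap 100 iterations); one final pass
recomputes dosage, Y and the SVD at the converged π̂. Convergence is
measured on π̂ rather than on the factors because the factors are only
identified up to sign and rotation within degenerate singular values.

Missing observations are encoded as three equal likelihoods; Bayes' rule
then returns the prior, so their dosage is exactly 2π̂_ij — imputation by
population structure with no special-casing downstream.

## Allele frequencies and site filtering

Population frequencies are per-site maximum-likelihood estimates under
HWE. The EM iteration f ← (1/2N) Σ_i E[G_ij | X_ij, f] is the workhorse,
but two guards surround it:

* the per-site likelihood in f is a ratio of polynomials and can be
  genuinely multimodal for noisy likelihood triples; a coarse symmetric
  51-point scan selects the basin before EM starts;
* on small panels the likelihood can be so flat near the optimum that EM
  increments drop below `tol` while the maximizer is still ~1e-3 away; a
  bracketed golden-section step (±0.025) after EM resolves this.

The scan grid and the bracket are symmetric in f ↔ 1−f, so allele
relabeling maps f̂ → 1−f̂ exactly (to numerical tolerance).

Variable sites are identified by a likelihood-ratio test of f̂ against
the better of the two monomorphic models (f = 0 and f = 1), referred to
χ²₁; the default threshold is p < 1e-6. The minor-allele-frequency bound
(default 0.05) is strict: f̂ = 0.05 is excluded. When hard genotypes are
supplied the sites are taken as already called and only the MAF filter
applies.

## Selection statistics

**S1.** d_jk = v_jk √M per component; since each column of V has unit
norm, Σ_j d²_jk = M holds identically — the statistic is calibrated by
construction and is reported without genomic control.

**S2.** β_j = S V_j are the least-squares coefficients of y_j on U (U has
orthonormal columns, so no refit is performed); z_j = β_j /
√(RSS_j/(N−K)) with RSS from the rank-K residual. The squared robust
Mahalanobis distance of the z_j over sites is referred to χ²_K after
division by the genomic inflation factor λ = median(D²)/median(χ²_K), so
the corrected statistics have exactly the null median. The robust
location/scatter is minimum covariance determinant (support fraction
0.75, fixed seed); if the MCD scatter is singular the classical
mean/covariance is used with a warning, and a singular classical
covariance is a fatal error. Sites whose residual is exactly zero (y_j in
the span of U, possible only in degenerate data) cannot be scored; they
receive the largest finite statistic and are flagged in the output
(`s2_zero_rss`) rather than crashing a scan.

P-values are χ² survival probabilities; underflow is reported as the
smallest positive double, never 0. Bonferroni uses the retained-site
count: threshold = α / M_retained, strict inequality.

### Finite-sample tails of S2

z_j is a coefficient over an estimated standard error, so z² has
F(1, N−K) rather than χ²₁ tails. At N = 100 the difference is invisible
in the bulk (λ ≈ 1) but is ~9% at p ≈ 1e-5, which is enough to produce
occasional Bonferroni exceedances on a perfectly neutral panel of 5000
sites. Median-based genomic control cannot repair tails. This is a
property of the statistic at small N, not of the implementation; at the
sample sizes and thresholds of real genome-wide panels (hundreds of
individuals, millions of sites) the effect is negligible relative to the
Bonferroni margin.

## Numerical choices

* Likelihood triples are accepted unnormalized and normalized only where
  absolute log-likelihoods are compared; every statistic is invariant to
  per-observation scaling.
* Truncated SVD is computed by a dense LAPACK decomposition cut to K.
  N is at most a few hundred in every supported regime, so the dense
  route is exact, fast, and deterministic across platforms; the `seed`
  argument is accepted for interface stability with randomized backends.
* Sign convention: each component is oriented so the largest-|·| entry of
  its U column is positive (ties to the lowest index).
* π̂ clipping bound `clip` defaults to 1e-4, keeping the Binomial priors
  non-degenerate.
* K is user-supplied; no automatic selection of the number of components
  is attempted.

## The synthetic-data generator

Ancestral frequencies are Uniform(0.05, 0.95); population frequencies
follow the Balding–Nichols model Beta(p(1−F)/F, (1−p)(1−F)/F), giving
mean p and variance F·p(1−p), with F = 0 degenerating to p exactly.
Structure is either discrete equal-sized groups or a two-population cline
q_i = i/(N−1). Genotypes are Binomial(2, π_ij) with π = admixture ×
population frequencies. Sequencing is read-level: Poisson(depth) reads
per observation, each carrying the minor allele with probability
g/2·(1−e) + (1−g/2)·e, and the likelihood of a hypothetical genotype is
the product of per-read probabilities. Zero reads give the equal triple.

Loci under divergent selection are emulated by elevated drift (a larger F
for the flagged sites) rather than explicit selection coefficients: the
statistics test for excess differentiation along structure axes, and
elevated drift produces exactly that signal. A consequence worth knowing:
because the Beta draws are independent per population, a locus simulated
at selected F = 0.3 frequently lands with a *small realized* frequency
difference between populations (P(|Δf| < 0.1) ≈ 0.2 at p = 0.5). Power
measured against the "selected" flag therefore saturates well below 100%
even for a perfect method at high depth — roughly half of flagged loci
rank in the S1 top 1% on a cline of N = 200 at depth 6, and far fewer
clear a Bonferroni bar — and power numbers from this generator should be
read as averages over realized drift, not as per-locus detection rates at
a guaranteed effect size.

The generator does not emulate linkage, related individuals, batch or
read-length artifacts, or reference bias; passing tests say nothing about
robustness to those.

## Problem sizes

The test suite and the acceptance script run simulations at N = 100–200
individuals and M = 2000–5000 sites with 5–20 replicate seeds per
regime — large enough that the calibration quantities (type-I rate,
λ, medians) are stable to a few percent, and deliberately desk-scale:
the package itself handles arbitrarily larger panels, with memory the
only constraint (the likelihood array is N×M×3 doubles).

## Known limitations

* The iterative fit is transductive: PC scores exist only for the fitted
  individuals; there is no projection of new samples.
* Major/minor allele assignment is taken from the input file and never
  inferred.
* Relatedness and admixture-aware HWE deviations are out of scope; kin
  pairs will distort the PCs and hence both statistics.
* The χ²_K reference for S2 is a large-N approximation (see above).
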