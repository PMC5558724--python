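# Methods

This note records the statistical model, the algorithmic choices that
were genuinely open, the numerical safeguards, and what the synthetic
data do and do not establish.

## Model and estimands

The data model is `y = Xβ + Zg + Wv + e` on n weighted records of q
animals with m variants. X carries the mean, breed and sex indicators,
and optionally the dosages of named variants fitted as fixed effects
(removed from the random set). Z is the standardized dosage matrix;
missing calls are mean-imputed (zero after centring) and monomorphic
variants excluded before standardization. The SNP-effect prior is the
four-class scale mixture with variances γ = {0, 10⁻⁴, 10⁻³, 10⁻²} times
a scale σ²g, mixing proportions Pr with a flat Dirichlet(1,1,1,1)
prior, plus a pedigree polygenic term v ~ N(0, Aσ²a) and heterogeneous
residuals e ~ N(0, Eσ²e) with E = diag(1/wᵢ) from the bull/cow record
weights. σ²g and σ²a are fixed inputs; σ²e is estimated (sampled in the
MCMC, ML-updated in the EM).

Estimands: per-variant posterior mean effects and class probabilities
P(i,k); posterior mixing proportions; genomic values Zg (GEBV), with
the polygenic component optionally added via a flag; prediction
accuracy (Pearson correlation of GEBV with held-out trait deviations)
and bias (slope of phenotype on GEBV).

## GBLUP and PEV

The mixed-model equations are built with full precisions (E⁻¹/σ²e,
G⁻¹/σ²g, A⁻¹/σ²a) and solved by dense factorization; the u-block of the
inverted coefficient matrix is the prediction error variance
Var(u − û) used by the EM stage. G = ZZ′/m with a 1e−6 ridge; dividing
by the variant count (rather than the record count) makes the expected
diagonal ≈ 1 and keeps G consistent with the standardized Z. Animals
without phenotypes are predicted by the conditional mean
G_val,ref G⁻¹_ref,ref û rather than entering the equations. Under
near-infinite record precision the PEV vanishes only orthogonally to
span(X): u remains confounded with the fixed effects along X, which the
tests account for explicitly.

## Gibbs sampler

Each iteration applies, in order: a weighted-least-squares update of β
on its partial residual (flat prior, point update), a sweep over all
SNPs in input order, a Dirichlet draw of Pr from the class counts, the
multivariate-normal full conditional of v, and a scaled
inverse-chi-square draw of σ²e with ν₀ = −2, S₀ = 0 (flat on σ²e). The
SNP full conditional uses the standard collapsed form: with
r_i = Z_i′E⁻¹(e + Z_i g_i) and l_i = Z_i′E⁻¹Z_i, class k has log weight
`log Pr_k − ½log((l_i σ²_k + σ²e)/σ²e) + ½ r_i² σ²_k /(σ²e (l_i σ²_k + σ²e))`
(zero extra terms for the spike), and the effect given a slab class is
N(r_i/(l_i + σ²e/σ²_k), σ²e/(l_i + σ²e/σ²_k)). Residuals are updated
incrementally and re-synchronized (with a warning) if drift exceeds
1e−6; in practice drift stays below 1e−8, which the suite asserts.

Defaults mirror the reference analysis: five chains of 40,000
iterations with 20,000 burn-in, chain c seeded base+c, summaries
averaged over chains. The polygenic full conditional is sampled through
a one-off eigendecomposition of D^{−1/2}A⁻¹D^{−1/2} (D = E⁻¹), so each
draw costs two matrix–vector products even though σ²e moves. Numba
compiles the sweep; the genotype matrix is kept Fortran-ordered so the
per-SNP inner loops stream contiguous memory.

## EM stage and the PEV correction

The EM treats each SNP's (class, effect) pair as a local variational
factor: the E-step computes responsibilities from the same collapsed
likelihood with an *effective* precision l_i + pev_i/σ²e, and the
M-step sets g_i to the responsibility-weighted posterior mean. The
per-SNP scalar pev_i = (E⁻¹Z_i)′ PEV_u (E⁻¹Z_i) is computed once at
startup from the GBLUP fit and held fixed; it discounts the apparent
information in the backfitted residual for the uncertainty of all other
SNPs' estimates. Initialization is g = 0.01, Pr = {0.5, 0.487, 0.01,
0.003}; proportions update by Dirichlet-MAP (column means of P under
the flat prior); σ²e by its M-step; convergence when
(ĝ_q − ĝ_{q−1})′(ĝ_q − ĝ_{q−1}) / ĝ_q′ĝ_q < 10⁻¹⁰ (strict), with at
most 1000 iterations.

Two design points were genuinely open and are resolved as follows.

*The genetic-value correction u.* An early variant refreshed u each
iteration by GBLUP on the current residual signal. That scheme is
unstable: u absorbs residual noise, the σ²e M-step shrinks, and the
feedback drives σ²e → 0 and g → 0. The backfitted residual already
carries every other SNP's point estimate, so subtracting a refreshed u
double-counts signal. The implementation therefore uses the PEV term
only — uncertainty enters as precision inflation, û is kept as a
startup diagnostic — which is stable and matches the per-SNP update
contract exactly.

*The monitored objective.* With a point-mass spike the joint log
posterior is not directly evaluable, so the monitor is the variational
free energy of the factorized approximation (residual quadratic plus
Σ l_i·Var(g_i) carry-over, class and slab prior/entropy terms, and the
polygenic prior term). The PEV-off updates are exact coordinate ascent
on this objective — any decrease beyond 1e−6 aborts the run — and the
σ²e M-step includes the Σ l_i·Var(g_i) carry-over so it is the exact
argmax. With PEV inflation on, the update is deliberately more
conservative than the free-energy argmax, and dips on the order of
1e−3 (against a scale of hundreds) occur near convergence; they are
logged, and the tests require the trace to stay within 1% of its
running peak. On the relative-change criterion itself: a pure-noise
dataset decays g geometrically toward zero, so the ratio never falls
below 10⁻¹⁰; run_em then returns the best state with a warning, and an
exactly-zero g is declared converged by convention.

## Hybrid schedule and exclusion rule

The hybrid runs EM to convergence, copies (g, class, β, v, Pr, σ²e)
into a single Gibbs chain, and samples 4000 iterations with 1000
burn-in (the warm start needs little). At iteration 500 every variant
whose running frequency of spike membership exceeds 0.90 is zeroed
(residuals restored) and skipped thereafter; frozen variants keep g ≡ 0
and spike class in all subsequent samples, which the suite asserts
iteration-by-iteration. The running probability is accumulated over the
MCMC iterations 1–500, not carried from EM responsibilities. The MCMC
stage runs the marker model without the u device; its residual signal
is re-absorbed by the sampled effects. With the default burn-in
(1000 > 500) posterior summaries contain only post-freeze samples; a
shorter burn-in would mix pre-freeze draws into the averages.

## QTL mapping

The mapping signal is P(i,4) alone (not P(i,3)+P(i,4)): the report
threshold is the N₄-th largest value with N₄ = round(Pr̄₄·m), so the
number of reported variants is at most N₄ plus ties. An optional
fixed-kb window aggregation (max P(i,4), summed |g|) is available but
off by default.

## Synthetic data

Genotypes are sums of two haplotypes from a Gaussian-copula first-order
Markov chain: a latent AR(1) with autocorrelation ld_rho thresholded at
Φ⁻¹(p_i), p_i ~ U(maf, 1−maf), chains restarting at chromosome
boundaries. Thresholding attenuates dosage r² well below ld_rho²
(ld_rho = 0.9 yields adjacent r² ≈ 0.25), which suffices for
LD-proxy detection studies. Effects are drawn from the four-class
mixture verbatim; a single global rescale then pins the realized genic
variance Var(Zg) to the target σ²g. Without it, the default
99/0.7/0.2/0.1% architecture leaves the genic variance dominated by a
handful of large effects, with ~60% replicate-to-replicate spread; the
rescale is a pure change of the mixture scale, recorded as
`truth.mixture_scale`, so the generative prior remains an exact
four-class mixture. Residuals are drawn as N(0, σ²e/wᵢ) with weights
from simulated sexes (25% bulls, 20–300 daughters; cows with 1–6
records, t = 0.6, c = 0.1), or unit weights on request. σ²e is backed
out of the target h², so realized h² lands on target by construction;
the per-record noise floor under daughter-deviation weighting is
σ²g(c + 3/d) and does not vanish as h² → 1.

Two scales coexist deliberately: `vc.sigma_g2` is the total additive
genetic variance (the REML-style input used by GBLUP, h², and the
weights), while the mixture's own scale parameter is free. Matched-prior
studies (calibration, architecture recovery) pass
`MixturePrior(sigma_g2=truth.mixture_scale)`; planted-QTL studies use
`vc.sigma_g2`, since a planted effect is not a mixture draw. On real
data the two coincide by the method's convention (class variances are
fractions of the REML genetic variance).

What the simulations do not emulate: breed structure and admixture,
realistic LD decay or demography, imputation error, genotype–
environment interaction, and selection. Passing tests therefore
establish internal correctness of the estimators under the model's own
assumptions, not field performance on real cattle data.

## Problem sizes and test design

The default generator scenario is n = 2000, m = 5000,
Pr = (0.99, 0.007, 0.002, 0.001), h² = 0.4. The package's own
acceptance studies run desk-scale versions chosen to keep a full run in
minutes on one CPU: the hybrid/full-sampler agreement study uses
n = 1500, m = 3000 with a 16,000-iteration reference chain (hybrid at
its default 4000); the sparse-architecture comparison 10 replicates at
n = 1000, m = 2000; QTL detection 20 replicates at n = 1500, m = 1200;
architecture recovery 10 replicates at n = 800, m = 4000 (the rare-class
estimate's small upward bias decays with m, so the variant count stays
near the default scenario). Oracle tests pin the math: dense GLS for
the mixed-model equations (1e−8), conjugate closed forms and 10⁵-draw
frequency checks for the Gibbs full conditionals, numerical integration
for single-SNP posteriors and responsibilities, the explicit
linear-predictor map for PEV, and hand-decoded bytes for the PLINK
reader. Simulation-based calibration checks that 90% posterior
intervals for g cover ~90% across replicates.

## Numerical choices and degenerate inputs

Class weights are computed in log space with max-subtraction; a zero
proportion maps to −∞ and drops out. Monomorphic or all-missing
variants are excluded up front; standardization refuses them otherwise.
G carries a 1e−6 ridge; A is built by the tabular method and rejects
pedigree cycles; unknown parents are unrelated founders. Weight
denominators are validated (the cow formula turns non-positive for
h² near 1 or many low-repeatability records, and raises with a
diagnostic). Collinear fixed-effect columns are pruned with a warning,
keeping earlier columns. σ²g = 0 shrinks u to zero and returns the
weighted-least-squares β; σ²a = 0 drops the polygenic block
deterministically. Seeds: chains use base+chain; the compiled kernel
RNG and the numpy Generator are seeded separately from the same base;
identical seeds reproduce every output bitwise.

## Known limitations

σ²g and σ²a are never re-estimated (by design, matching the fixed-input
convention); the exclusion threshold is global rather than
trait-adaptive; multi-allelic variants and X-dosage compensation are
out of scope; the dense MME/PEV path is practical to roughly 20k
animals; and the EM free-energy guarantee is exact only with the PEV
inflation off.
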