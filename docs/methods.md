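# Methods

## Generative model

A tumour sequenced at N somatic loci across M longitudinal samples is treated
as a mixture of a diploid normal population and, per locus, reference and
variant cancer populations. With purity ρ_j, shared local total copy number
D_ij (the standard no-subclonal-CNV simplification) and multiplicity d_ij,
the expected VAF of mutation i in sample j is θ_ij = ζ_ij φ̃_ij with
ζ_ij = d_ij ρ_j / (2(1−ρ_j) + D_ij ρ_j). The general three-population form
(distinct reference/variant copy numbers) is implemented alongside and agrees
with the linearized form whenever the copy numbers coincide.

When multiplicity is not supplied, it is estimated by the closest-integer
rule applied to u_ij = θ_ij ρ_j⁻¹ (2(1−ρ_j) + D_ij ρ_j): d = [u] if u ≥ 1,
else 1. Two refinements are ours: half-way ties round away from zero (the
bracket notation does not define them) and the estimate is clamped to
[1, D_ij], since noisy VAFs can push u above the local copy number. By
default the observed VAF entering this rule is pooled across samples with
depth weights, keeping d constant over time — consistent with the assumption
that copy-number state does not change subclonally; per-sample estimation is
available via a flag.

Mutations cluster through a truncated stick-breaking Dirichlet process:
u_k ~ Beta(1, α), w_k = u_k Π_{l<k}(1−u_l), p(α) ∝ (1+α)⁻² (equivalently,
uniform on 1/(1+α)). Truncation is K = 20 by default; the residual stick is
assigned to the final component (u_K ≡ 1) so weights form an exact simplex.

Cluster CCF trajectories are modelled on the logit scale. The Flat baseline
takes φ_jk iid uniform — equivalently standard-logistic ψ_jk — and ignores
the temporal ordering of samples. The GP families put zero-mean Gaussian
process priors on ψ_k(t) over normalized time t ∈ [0, 1]:

- GP0: one shared kernel h² g_τ for all clusters (columns independent);
- GP1: separable multi-output kernel g_τ(t,t′) Σ_K with Σ_K = diag(h_k²);
- GP2: Σ_K = D C D, D = diag(h_k), C a correlation matrix with LKJ(η) prior,
  η = 2 by default (mass concentrated near the identity);
- GP3: block-diagonal covariance with per-cluster kernels h_k² g_{τ_k}.

Kernels: Exp e^{−τ|Δt|}; Mat32 (1+√3τ|Δt|)e^{−√3τ|Δt|}; Mat52
(1+√5τ|Δt|+5τ²Δt²/3)e^{−√5τ|Δt|}; ExpQ e^{−τΔt²/2} — increasing smoothness
at the origin. Hyper-priors h², τ ~ Gamma(1, 1). Observation families are
binomial and beta-binomial with shapes (v_j θ, v_j(1−θ)) and the prior
1/(1+v_j) ~ U(0,1); the precision is per-sample by default and can be shared
when data are thin. An optional symmetric sequencing-error adjustment
θ′ = ε(1−θ) + (1−ε)θ is available; its functional form is a documented
stand-in chosen for symmetry and the identity at ε = 0, not a calibrated
error profile.

## Inference

All 17 configurations (Flat + {GP0..GP3}×{4 kernels}) are fit by
stochastic-gradient variational inference with a mean-field Gaussian family
on unconstrained transforms: logit for stick fractions and (Flat) CCFs, log
for α, h², τ and v, identity for ψ, and tanh-transformed canonical partial
correlations mapped through a Cholesky construction for the GP2 correlation
matrix (the transform's log-Jacobian, derived in `priors.py`, is included in
the density). Cluster assignments are marginalized analytically
(log-sum-exp over components), which is what makes the objective
differentiable.

The engine is written directly in numpy/scipy. Reparameterization gradients
of the joint log density are analytic for the large blocks — responsibilities
weight the digamma-based derivatives of the count likelihood with respect to
trajectories, stick fractions and dispersions; the GP prior contributes
−Λ⁻¹vec(Ψ) through matrix-normal identities — and central finite differences
(step 1e−5) for the small kernel-hyperparameter block, whose prior term costs
only one or two tiny Cholesky factorizations per evaluation. Optimization
uses Adam (default learning rate 0.02, one Monte-Carlo sample per step, at
most 20 000 iterations). Variational means for the trajectories are
initialized at the observed logit-CCFs of randomly chosen anchor mutations,
which breaks label symmetry and speeds up separation of components.

Convergence is declared when the relative change of a 500-iteration moving
average of the ELBO falls below 1e−4. Because the per-iteration trace is a
noisy one-sample estimate, the reported final ELBO is the mean of 500 fresh
draws of log p − log q, with its Monte-Carlo standard error; these draws also
provide the energy/entropy decomposition. Model comparison sorts by this
final ELBO and always reports the SE so near-ties are visible. Fits are
bit-reproducible given (data, spec, config, seed). Numerical guards: θ is
clipped to [1e−9, 1−1e−9] before likelihood evaluation (with gradients
masked at the clip), Gram matrices get a 1e−6·h² diagonal jitter, and a
non-finite ELBO gradient aborts with the offending parameter block named.

## Post-processing

Soft memberships are Bayes-rule probabilities per posterior draw, summarized
by the elementwise median and renormalized; hard labels take the argmax, with
exact ties resolved toward the heavier cluster. Clusters are kept if their
posterior median weight is ≥ 0.02 (the default "major cluster" threshold —
deliberately a reporting choice, not a model parameter) or if they own at
least one hard-assigned mutation; both posterior-median and empirical
(assignment-fraction) weights are reported since the two summaries can
legitimately differ. Trajectories are reconstructed on a 101-point grid by
drawing from the pointwise GP conditional given each draw's ψ values and
hyperparameters, then mapping through the inverse logit; bands are central
95% intervals. Flat-model "trajectories" are straight-line interpolations of
the per-sample draws and are flagged as non-inferential between samples.
Posterior predictive VAF densities use each sample's median depth and median
ζ, extend the count pmf continuously in r = vaf·depth, and are renormalized
by the trapezoid rule.

## Synthetic data

The simulator draws weights from a symmetric Dirichlet (concentration 2),
trajectories from the GP prior (Mat32, h² = 4, τ = 2 by default — CCFs
mostly within ~0.1–0.9 with visible temporal movement) or iid uniform for
Flat-style data, assigns mutations multinomially, and generates counts
through the same ζ-correction used in fitting. Purities are uniform on
(0.6, 1.0); depths are negative-binomial (default mean 100, shape 5,
spanning the WGS-to-targeted range when configured from 40 to 1000);
copy number defaults to diploid with multiplicity 1 (the common case for
SNV panels), with a configurable distribution over {1..4} and uniform
multiplicities available. A rejection-sampled separation control (mean
pairwise |Δφ| ≥ 0.1 by default; recovery benchmarks use 0.2) makes dataset
difficulty reproducible; if the target is infeasible the best candidate is
returned with a warning rather than looping forever.

What the simulator does **not** emulate: mutation-specific copy-number
segments shared across samples of a real genome, subclonal CNV, purity
estimation error, mapping artefacts, or phylogenetic constraints between
cluster trajectories (trajectories are drawn independently, so "crossing"
lineages that would violate a tree are possible). Passing recovery tests
therefore demonstrates correctness of the statistical machinery under its
own assumptions, not robustness to the full messiness of patient data.

## Problem sizes used in tests

The test and acceptance suites run fits at N ≤ 100 mutations, M ≤ 6 samples,
truncation 5–20 and 200–3000 iterations; the recovery benchmark uses five
simulated datasets at M=6, N=100, K_true=3, depth 500 with separation 0.2,
and the Occam comparison fits GP0 and GP2 at truncation 8 on Flat-generated
two-cluster data. These sizes were chosen to match the scale of the
longitudinal studies the package targets while keeping a full test run in a
few minutes.

## Known limitations

- Mean-field VI underestimates posterior correlations; credible bands are
  typically slightly narrow, and ELBO gaps of a few nats between models
  should be read together with their Monte-Carlo SEs.
- The DP truncation makes empty-component weights sensitive to K for very
  small N; the default pruning threshold was chosen for K = 20.
- Multiplicity estimation is biased toward 1 for subclonal mutations on
  amplified loci (u < 1 forces d = 1), an inherent property of the
  closest-integer rule.
- No phylogeny is derived; cluster CCFs can be passed to dedicated tree
  reconstruction tools downstream.
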