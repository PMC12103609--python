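# Methods

This note records the statistical model, the estimator conventions, the
synthetic-data generator and the numerical choices behind `coralpp`, in
the order the pipeline uses them.

## Observation model

A site is one 1.75 m × 1.75 m quadrat (area 3.0625 m²) with the positions
of every individual of each morph recorded in cm, origin at the
lower-left corner, y up. Patterns with fewer than 30 individuals are
excluded from spatial analysis (too few points to constrain second-order
structure); the threshold is applied identically at read time and in the
pipeline. Substrate is an optional three-category classification
(boulder / flat rock / debris-filled gulley) on a raster aligned with the
quadrat, default cell 0.5 cm.

## PCF estimation

The estimator is the kernel PCF with pair-distance divisor,

    ĝ(r) = |W|²/(n(n−1)) · Σ_{i≠j} k_h(r − d_ij) / (2π d_ij w_ij) / c(r),

with

* Epanechnikov kernel `k_h` of half-width h = 5 cm (the study's "5 cm
  smoothing" is read as the kernel support half-width);
* grid r = 0.1, 0.2, …, 50 cm (the estimator diverges at r = 0, so the
  first grid cell is the smallest reported radius; r_max beyond half the
  shorter window side triggers a warning and truncation);
* translation edge correction w_ij = (W−|Δx|)(H−|Δy|) by default — exact
  on rectangles — or Ripley's isotropic correction by flag;
* boundary renormalisation c(r): the kernel mass falling on non-negative
  distances. Without it every radius below h is biased low (E ĝ ≈ 0.86
  averaged over (0, 5] cm under CSR); with it the CSR expectation is
  exactly 1 at every r. This matters because the cluster-model fit range
  starts at 0.1 cm.

For the inhomogeneous PCF (used by the HTC model) the global intensity is
replaced by plug-in per-point intensities λ(x_i) from the HP fit, with an
n/(n−1) factor so a constant plug-in surface reproduces the homogeneous
estimator exactly.

Nearest-neighbour distances are plain Euclidean minima within a morph's
pattern; no edge correction is applied, matching how the study summaries
are defined.

## Cluster-model fitting

The Thomas process PCF is g(r) = 1 + exp(−r²/4σ²)/(4πκσ²). (κ, σ) are
fitted by minimum contrast: minimise ∫ (ĝ(r)^q − m_θ(r)^q)² dr over the
fit range with q = 1/4 (the conventional variance-stabilising transform)
and default fit range (0.1, 25) cm — half the estimated range, beyond the
aggregation scales seen in the data. μ̂ = λ̂/κ̂ exactly, so μ̂κ̂ = λ̂ by
construction.

**Smoothed model curve.** When the empirical PCF carries a nonzero
bandwidth, the model curve m_θ is the estimator's *expectation* under the
model — the closed form convolved with the same boundary-renormalised
kernel — rather than the raw closed form. With h = 5 cm and σ ≈ 2 cm the
raw closed form differs from the estimator's expectation by ~25% at small
r; comparing like with like removes that bias, and parameter recovery at
study-like densities (κ = 0.004/cm², σ = 2 cm, μ = 3, ~370 points) shows
median relative errors of ~14% (κ), ~8% (σ) and ~13% (μ). With
bandwidth 0 the raw curve is used, so a noise-free closed-form input is
recovered exactly (to optimiser tolerance, ≲1e−8 relative).

**Optimiser.** Deterministic bounded L-BFGS-B over (log κ, log σ) from a
moment-based start (κ₀ from the peak excess, σ₀ from its half-decay
radius) plus four fixed fallback starts; bounds κ ∈ [1e−6, 1] /cm²,
σ ∈ [0.1, 50] cm. A solution on a bound is flagged non-converged. Fits
are invariant to point order up to float-summation noise (~1e−6
relative).

**HP / HTC.** The heterogeneous Poisson intensity is piecewise constant
per substrate category, λ_c = n_c/area_c (maximum likelihood); the
covariate is exactly a three-category classification, so no kernel
smoothing of intensity is used. HTC fits (κ, σ) on the inhomogeneous PCF
and simulates as a Thomas process at the maximum category intensity
thinned by the normalised category intensities. With a uniform mask HP
reduces to CSR and HTC to TC (asserted numerically to 1e−6).

**Reproductive diagnostics.** The mean number of settled offspring in a
non-empty cluster is the zero-truncated Poisson mean μ/(1−e^(−μ)) of the
fitted μ (the raw μ is also reported, since either reading of "offspring
from the cluster fit" can then be checked); the probability that an
individual belongs to a cluster is 1 − e^(−μ), the Palm probability of
having at least one sibling.

## Envelopes and goodness of fit

Each fitted model is re-simulated in the observation window and every
replicate's PCF is computed with identical estimator settings. Pointwise
envelopes take the (n_drop+1)-th order statistic per tail per radius;
study mode is 9999 simulations with 500 trimmed per tail (5%), tests and
examples run 99–199 simulations. A replicate with fewer than 2 points
records ĝ ≡ 1 (the CSR reference) with a logged warning so envelopes have
no holes.

Diggle's test uses u_i = ∫ (ĝ_i − ḡ_{−i})² dr with the leave-one-out mean
ḡ_{−i} (Diggle's original form; the grand-mean variant differs only by a
monotone rescaling of u), trapezoid integration on the grid, and the
plus-one Monte Carlo rank p_d = #{u_sim ≥ u_obs}/(n_sims+1) floored at
1/(n_sims+1); ties therefore give p_d = n/(n+1), and the reported
p_d < 0.001 resolution requires ≥ 999 simulations. Under the null
(CSR data tested against CSR at 99 simulations) p_d is uniform: KS
statistic 0.06 over 500 replicate studies.

CSR, HP and HTC are tested over the full (0.1, 50) cm range; TC over
restricted (0.1, 10) and (0.1, 20) cm ranges, because recruitment-driven
aggregation concentrates below 10 cm. The best model per pattern is the
arg-max of p_d, with the 10 cm value as the TC headline (both stored).
TC envelopes condition on the fitted (κ̂, σ̂, μ̂), not on the observed
count, as the model implies.

## Community statistics

Group assignment clusters per-site morph *proportions* (no pseudo-counts;
a single-morph site is (1, 0) or (0, 1)) with Bray–Curtis distance and
average linkage, cut at k = 3; clusters are labelled O / M / P by
decreasing mean orange proportion. Assignment is invariant to site input
order.

The nearest-neighbour comparison between groups uses per-site medians as
the sampling unit (pooling individual distances would pseudo-replicate)
and a two-sided Wilcoxon rank-sum test: exact enumeration when the
combined sample is ≤ 25 with no ties, tie-corrected normal approximation
otherwise (an exact null with ties is not well defined for the rank-sum
statistic). Report tables round densities and distances to 1 dp and
offspring to 2 dp; stored CSVs keep full precision.

## Synthetic data generator

Simulators: CSR by Poisson counts + uniform positions; Thomas with
parents on the window dilated by 4σ (edge guard against deflated cluster
density near borders; parents are latent, only in-window offspring are
returned) and per-axis Gaussian sd σ — the convention matching the closed
form above; heterogeneous Poisson by thinning a homogeneous proposal at
the maximum intensity. All generators are pure functions of (parameters,
seed); one global seed fans out through fixed-key `SeedSequence`
substreams (morph codes, site indices, model codes), so adding a morph or
reordering sites never perturbs other substreams.

Default whole-study rates emulate the motivating data: three community
types (orange-dominant, pink-dominant, mixed), per-morph Thomas rates set
so expected counts match the observed group medians (≈44 orange in O,
≈127 pink in P, ≈55 each in M), raw μ set so zero-truncated offspring
means span ~1.5–1.9, and σ (4.8–8 cm) set so simulated site NN medians
land at ~6–9 cm, with the pink morph dispersing further in mixed sites
than when dominant. A lognormal per-site abundance factor (log-sd 0.45 by
default) spreads site densities over roughly 10–145 individuals/m².

What the generator does **not** emulate: multi-generation (stepping-stone)
dispersal, interactions *between* morphs, non-Gaussian dispersal kernels,
within-site substrate preference unless explicitly switched on, and any
observation error in annotation. Passing tests therefore demonstrate
correct recovery of single-event Thomas structure under the stated
conditions, not that real corals follow that model. One consequence worth
noting: at the weakly clustered mixed-site settings (n ≈ 50, cluster
excess ≈ 1), the full-range CSR goodness-of-fit test has limited power —
in synthetic study runs only ~60% of such patterns reject CSR at 0.05,
whereas strongly clustered patterns (excess ≈ 10) reject in 100% of
seeds. The field data's universal CSR rejection implies stronger
aggregation than a Thomas process calibrated to its NN medians alone.

## Problem sizes and reproducibility

Tests and the acceptance script run the Monte Carlo stages at reduced but
statistically meaningful sizes (99–199 simulations per envelope, 100–500
replicate studies, 36-site synthetic studies); study mode (9999
simulations) is a config change, not a code path change. Every pipeline
output except timestamps is a deterministic function of (inputs, config,
seed); re-running a study with the same seed reproduces `summary.csv`
byte-for-byte.

## Known limitations

* Minimum contrast inherits the usual weak identifiability of (κ, μ) when
  clustering is weak (ĝ ≈ 1): κ̂ then drifts toward its bound and the fit
  is flagged non-converged. The integrated fitted excess remains a
  reliable "no clustering" signal.
* The isotropic edge correction is implemented for rectangles only.
* Recovered μ is biased low when the true dispersal scale approaches the
  fit-range radius (σ ≳ 8 cm), because the cluster hump is truncated.
* p_d with estimated parameters is only approximately exchangeable; at
  the tested sizes the deviation from uniformity is within KS 0.06–0.07.
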