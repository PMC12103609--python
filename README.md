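# coralpp

Spatial point process analysis of sessile benthic organisms in fixed
seabed quadrats.

`coralpp` implements the analysis pipeline used to infer dispersal and
competition dynamics of solitary cup corals from annotated seabed
photographs: each individual inside a 1.75 m × 1.75 m sample quadrat is a
point, and second-order spatial statistics link the observed pattern to
the biological process that generated it. The package is aimed at benthic
ecologists working with photo-quadrat annotations of sessile organisms
(two colour morphs per site in the motivating data set), but the
statistical core is generic.

## The statistics at its core

**Pair correlation function (PCF).** For a point process of intensity λ,
g(r) measures the relative density of point pairs at inter-point distance
r: g ≡ 1 under complete spatial randomness (CSR), g(r) > 1 means
aggregation and g(r) < 1 segregation at scale r. `coralpp` estimates g on
a 0.1 cm grid up to 50 cm with an Epanechnikov kernel of 5 cm half-width,
translation (or isotropic) edge correction, and a boundary
renormalisation that keeps the CSR expectation exactly 1 at radii below
the kernel width.

**Candidate models.** Four generative models compete for each pattern:

* CSR — homogeneous Poisson (no structure);
* HP — heterogeneous Poisson with piecewise-constant intensity over three
  substrate categories (boulder, flat rock, debris-filled gulley);
* TC — Thomas cluster process: Poisson parents of intensity κ, Poisson(μ)
  offspring per parent, isotropic Gaussian dispersal of scale σ, with

      g(r) = 1 + exp(−r² / 4σ²) / (4π κ σ²);

* HTC — Thomas clusters thinned by the substrate intensities.

(κ, σ) are estimated by minimum contrast on the (inhomogeneous) PCF with
the conventional fourth-root transform, and μ = λ/κ. Two reproductive
diagnostics derive from μ: the mean number of settled offspring in a
non-empty cluster (the zero-truncated Poisson mean μ/(1−e^(−μ))) and the
probability that an individual belongs to a cluster (1 − e^(−μ)).

**Goodness of fit.** Each fitted model is simulated many times (9999 in
study mode, with the 500 highest/lowest values per radius trimmed for the
pointwise envelope), and Diggle's rank test converts the integrated
squared discrepancy between each curve and the mean of the others into
p_d ∈ (0, 1]: p_d ≈ 0 is a poor fit, p_d ≈ 1 a good one. The TC model is
additionally scored over restricted 10 cm and 20 cm ranges, where
recruitment-driven aggregation lives.

**Community level.** Sites are grouped into orange-dominant / pink-
dominant / mixed assemblages by average-linkage hierarchical clustering
of morph proportions (Bray–Curtis distance, tree cut at 3), and per-group
medians of counts, densities, nearest-neighbour distances and offspring
numbers are compared (Wilcoxon rank-sum for between-group shifts).

A synthetic-data module generates single patterns (CSR, Thomas,
heterogeneous Poisson by thinning) and whole multi-site studies with the
observed structure, so every stage is testable offline.

## Worked example

```python
from coralpp import Window, pair_correlation, fit_thomas_min_contrast
from coralpp.simulate import simulate_thomas

w = Window()                          # 175 cm x 175 cm quadrat
pat = simulate_thomas(w, kappa=0.004, sigma=2.0, mu=3.0, seed=1)
g = pair_correlation(pat)             # 0.1 cm grid, 5 cm smoothing
fit = fit_thomas_min_contrast(g)
print(f"n = {pat.n}")
print(f"kappa = {fit.kappa_:.5f} parents/cm^2, sigma = {fit.sigma_:.2f} cm, mu = {fit.mu_:.2f}")
print(f"offspring per parent in a non-empty cluster = {fit.offspring_nonempty_:.2f}")
print(f"P(individual belongs to a cluster) = {fit.prob_in_cluster_:.3f}")
```

prints

```
n = 370
kappa = 0.00379 parents/cm^2, sigma = 2.05 cm, mu = 3.19
offspring per parent in a non-empty cluster = 3.33
P(individual belongs to a cluster) = 0.959
```

A pattern simulated with κ = 0.004 parents/cm², σ = 2 cm and μ = 3
offspring per parent is recovered to within a few percent: 370 corals
whose clustering implies ~3.3 settled offspring around each reproducing
parent, with 96% of individuals belonging to a cluster.

The same analysis runs end-to-end from the shell:

```sh
coralpp simulate study/ --seed 3            # synthetic multi-site study
coralpp analyze study/ --out results/ --n-sims 199 --seed 3
coralpp summarize results/                  # per-group medians + Wilcoxon
```

`analyze` writes `summary.csv` (one row per site × morph with counts,
densities, group, p_d per model, κ̂, σ̂, μ̂, offspring and
nearest-neighbour medians), per-pattern PCF/envelope curves, figures and
a manifest; real annotation tables (CSV with `site_id, morph, x_cm,
y_cm`) are analysed the same way. Patterns with fewer than 30 individuals
are excluded, mirroring the minimum-points rule of the study design.

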