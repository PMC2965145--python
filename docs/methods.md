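# Methods

## The statistical problem

In a fragmented landscape, local abundance and richness of habitat
specialists may depend on patch size — but whether they do is itself
hypothesised to depend on the landscape's total remaining vegetation.
`fragfit` encodes competing versions of that dependence as a fixed
catalogue of eight candidate count models over three fragmented
landscapes ordered by forest cover, fits each by maximum likelihood,
and compares them with small-sample-corrected AIC. The design the
package assumes (and its generator emulates) is an even-effort survey:
identical trapping effort at every site, so raw counts are comparable
across sites and no effort covariate is needed.

## Responses and offsets

For each guild (forest specialist / generalist) and site:

* **abundance** y = total individuals over the two sampling years,
  modelled directly (offset 1);
* **richness response** y = sum of the two per-year species counts
  (always an integer, equal to twice the mean yearly richness), modelled
  with a multiplicative offset of 2. Averaging over years avoids
  overstating the number of species present simultaneously; the offset
  keeps the fitted mean on the per-year scale.

Every surveyed site contributes a row, zero-filled when the guild was
not caught there; dropping zeros would bias the constant-model means
upward. Control sites (continuous forest, no patch area) are used only
by the diversity statistics, never in model fitting.

## Candidate models and error distributions

Components are constant (μ = offset·e^c) or linear in x = log₁₀ area
(μ = offset·e^(a+bx)) under the default log link. The catalogue
{A, B, C, D, D2, E, E2, F} is described in the README; coefficient
sharing is explicit in the parameter names (e.g. `b_shared` in D and E).
Two structural choices were genuinely open and are resolved as follows:

* In model F the two constants (most-forested, most-deforested) are
  separate parameters — the regimes they describe (saturated landscape
  vs. post-collapse) have no reason to share a level.
* E and E2 give the below-threshold landscapes separate intercepts;
  E shares one slope, E2 frees it per landscape. Together with D/D2
  this realises "the strength of the patch-area effect may depend on
  landscape context" as distinct candidates, which is the minimal
  reading that yields exactly eight models.

Abundance in models with no patch-area effect (A, C) is
negative-binomial in the mean–dispersion form (variance μ + μ²/k, one
dispersion parameter shared across components, counted in K); all other
abundance models, and richness in all models, are Poisson. A
consequence worth noting: one selection table mixes Poisson and
negative-binomial candidates; AICc comparisons across distributions are
performed as specified, and the likelihoods are all on the same count
scale. An alternative convention — per-component negative-binomial
errors inside mixed models — is not implemented.

The link is configurable (`OptimizerConfig(link="identity")`) for the
literal straight-line reading of the component sketches; the identity
link floors the mean at 1e−9. The log link is the default because it
guarantees positive means under unconstrained optimisation and is the
standard choice for counts.

## Fitting

The whole-model NLL is the sum of component NLLs. Models whose
components are all constant are solved exactly: for both Poisson and
negative-binomial likelihoods the mean MLE of a constant component is
its sample mean (the mean score is zero there for any fixed dispersion),
so only the NB dispersion needs a numerical step — a bounded Brent
search on log k over [−10, 16], tolerance 1e−10. All other models use
Nelder–Mead with 5 starts: one at moment estimates (component means;
least-squares slope of log(y+0.5) on log₁₀ area; method-of-moments
dispersion), four jittered around it (sd 0.3 per coordinate, scaled by
coefficient magnitude, from a seeded generator so fits are
reproducible). Convergence tolerance 1e−8 on the NLL and parameters,
at most 2000 iterations per start. Coefficients are boxed at ±30 on the
link scale during the search; a component whose data are all zeros is
fitted at the box edge and the fit is flagged `degenerate`. The
returned NLL can never exceed the moment-start value because that start
is always included. Non-converged fits carry `converged=False` and are
excluded from selection tables with a warning.

## Selection

AICc = −2 log L + 2K + 2K(K+1)/(n−K−1) with n = number of fragmented
sites in the fit (whole-model n); the correction is undefined for
n ≤ K+1 and such models are skipped with a warning. Weights are
computed shift-stabilised. Plausibility uses the strict rule
ΔAICc < 2. Ties in AICc are broken lexicographically by model id so
reports are deterministic.

## Diversity statistics

* **Rarefaction.** The sample-based (Mao Tau) expectation
  τ(h) = S_obs − Σᵢ C(H−Hᵢ, h)/C(H, h) is exact for subsampling h of H
  sites without replacement. The variance is also exact, computed from
  the pairwise joint-absence counts (the number of sites containing
  neither species i nor j), rather than a species-independence
  approximation; hence sd(H) = 0 identically and the curve matches
  Monte-Carlo subsampling to within simulation error. The 95% band is
  normal-approximation (±1.96 sd), the conventional choice when nothing
  else is stated.
* **Richness estimators.** Chao2 classic (S_obs + q₁²/2q₂), switching
  to the bias-corrected form S_obs + q₁(q₁−1)/(2(q₂+1)) when q₂ = 0;
  first-order jackknife S_obs + q₁(H−1)/H. Both are reported; neither
  is privileged, since incidence-based "estimated richness" can mean
  either in the field literature.
* **Similarity / representation.** Bray–Curtis on presence/absence
  (2a/(2a+b+c), ≡ Sørensen) in percent, and the percentage of a paired
  control landscape's species pool present in its fragmented landscape.
  Species found only in controls remain in the universe.

## The synthetic-data generator

The generator emulates the study design, not the field system: three
fragmented landscapes (default 50/30/10% cover — nominal labels for
49/31/11-type gradients), 17 surveyed patches each with patch areas
drawn log-uniformly on (2, 300) ha (a shared size distribution across
landscapes, so landscape and patch-size effects are not confounded),
one paired control landscape with 6 sites per pair, and two sampling
years. Per-site guild totals are Poisson — or negative-binomial with
dispersion k when overdispersion is wanted — around the generating
model's mean; the total is split multinomially among the guild's
species (geometric relative-abundance profile, ratio 0.75, 27
specialist / 12 generalist species) and binomially (p = 0.5) across
years. Because the fitted models act on guild totals, the species and
year partitions do not alter the modelled distributions; they exist so
that richness, rarefaction and composition statistics have realistic
inputs.

Preset coefficients are illustrative effect sizes chosen from the
regimes' qualitative structure and typical small-mammal capture totals
(per-patch generalist means of roughly 4/13/27 across a deforestation
gradient motivated `generalist_release`), not estimates from any
dataset: e.g. `regime_shift` is model F with mean 30 at 50% cover,
intercept 1.0 and slope 1.0 (log link, per log₁₀ ha) at 30%, and mean 3
at 10%. One seed governs a generation call; per-site sub-streams are
spawned deterministically from it, so output is bit-identical per seed.

What the generator does **not** emulate: spatial configuration,
dispersal, temporal dynamics, species-level habitat preferences within
a guild, or detection failure. Passing generate-and-refit tests
therefore demonstrates that the estimation and selection machinery
recovers the generating structure at realistic sample sizes — not that
any field system follows these models.

## Problem sizes and numerical checks

The test suite validates the likelihood kernels against independent
pmf evaluations, the optimiser against 5-point-per-dimension grid
searches on a 30-site dataset (fitted NLL ≤ grid optimum + 1e−6),
rarefaction against 10,000-draw Monte-Carlo subsampling on 10×8
incidence matrices (within 3 MC standard errors), and closed-form
identities (constant-Poisson MLE = sample mean to 1e−8; NB → Poisson
at k = 10⁸ to 1e−4). Model recovery uses 100 replicates at the default
design (17 patches × 3 landscapes) with a fixed seed list: the
regime-shift preset must be selected best in ≥ 80% of replicates, and
under the null preset the null model must remain in the ΔAICc < 2 set
in a majority. `scripts/acceptance.py` re-runs the same experiments
with seeds derived from its `--seed` argument.

## Known limitations

* The catalogue is fixed to three fragmented landscapes; it does not
  generalise to other designs or continuous cover gradients.
* No standard errors, profile intervals or model-averaged predictions
  are produced — selection tables and MLEs only.
* The AICc n is the whole-model site count; per-component sample sizes
  are not used.
* Identity-link fits can sit on the mean floor for strongly negative
  linear predictors; the log link is recommended.
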