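# fragfit

**Landscape-dependent patch-area multimodel inference for fragmented
landscapes.**

`fragfit` is for ecologists analysing even-effort surveys of habitat
patches across landscapes that differ in total remaining native
vegetation — the classic design for testing whether species–patch-area
effects depend on landscape context (fragmentation thresholds, and the
regime-shift hypothesis that patch-area effects appear *only* at
intermediate levels of habitat loss, vanishing again once the landscape
species pool has collapsed).

## What it computes

Given a site table (patch areas in ha, landscape membership), a
species-trait table (forest specialist vs. generalist) and a capture
table (site × species × year counts), the package:

1. **Builds per-site responses** per guild: total *abundance* over the
   two sampling years, and the *richness response* — twice the mean
   yearly species count, modelled with a fixed offset of 2 so
   coefficients are on the per-year scale.
2. **Fits eight structured candidate models** by maximum likelihood.
   Each model is a set of per-landscape component functions, constant or
   linear in log₁₀ patch area, for the three fragmented landscapes
   ordered by forest cover:

   | id | hypothesis |
   |----|------------|
   | A  | null: one constant everywhere |
   | B  | patch-area effect only: one shared line |
   | C  | landscape-context effect: one constant per landscape |
   | D  | context + area: per-landscape intercepts, shared slope |
   | D2 | as D with per-landscape slopes |
   | E  | area effect only beyond a fragmentation threshold (constant in the most forested landscape; shared slope below) |
   | E2 | as E with separate slopes |
   | F  | regime shift: area effect only at *intermediate* cover; constants at the extremes |

   Abundance is negative-binomial (variance μ + μ²/k) in models without
   patch-area effects (A, C) and Poisson otherwise; richness is Poisson
   throughout. The whole-model negative log-likelihood is the sum over
   component functions; constant-only models are solved in closed form,
   the rest by multistart Nelder–Mead.
3. **Ranks the candidates** by AICc = −2 log L + 2K + 2K(K+1)/(n−K−1),
   with ΔAICc, Akaike weights wᵢ, and the ΔAICc < 2 plausibility rule.
4. **Summarises gamma diversity**: sample-based rarefaction (analytic
   Mao Tau expectation with exact subsampling variance and 95% CI),
   Chao2 and first-order jackknife richness estimators, Bray–Curtis
   presence/absence similarity (≡ Sørensen), and the percentage of each
   control landscape's species pool represented in its paired fragmented
   landscape.
5. **Generates synthetic studies** with the design's structure (three
   fragmented landscapes at 50/30/10% cover, 17 patches each with a
   shared log-uniform size distribution, paired 6-site controls, two
   years) under any of the eight generating models, for power analysis
   and generate-and-refit validation.

## Worked example

```python
from dataclasses import replace
from fragfit import preset_scenarios, generate, fit_candidate_set
from fragfit.selection import format_selection_table

scenario = replace(preset_scenarios()["regime_shift"], seed=7)
study = generate(scenario)                       # synthetic capture tables
fits, table = fit_candidate_set(study, "specialist", "abundance")
print(format_selection_table(table))
```

```
M	K	logL	AICc	dAICc	Wi
F	4	-131.0166	270.9027	0.0000	0.4592
D2	6	-128.7008	271.3107	0.4080	0.3745
E2	5	-130.8003	272.9339	2.0312	0.1663
E	4	-143.5593	295.9882	25.0855	0.0000
D	4	-151.1482	311.1659	40.2632	0.0000
C	4	-153.4742	315.8179	44.9152	0.0000
A	2	-189.6615	383.5729	112.6702	0.0000
B	2	-338.2344	680.7187	409.8160	0.0000
```

The data were generated under model F (a positive patch-area effect
only in the 30%-cover landscape) and F attains the lowest AICc; D2 and
E2, which nest F, are its only near-competitors and pay the extra-
parameter penalty. The fitted coefficients recover the generating ones
(truth c_L50 = 3.401, a_L30 = 1.0, b_L30 = 1.0, c_L10 = 1.099):

```
F  {'c_L50': 3.349, 'a_L30': 0.748, 'b_L30': 1.106, 'c_L10': 1.174}
```

The same pipeline runs from the shell:

```bash
fragfit simulate --preset regime_shift --seed 7 --out-dir data/
fragfit fit --sites data/sites.csv --species data/species.csv \
        --captures data/captures.csv --landscapes data/landscapes.csv \
        --out-dir reports/
fragfit recover --preset regime_shift --replicates 100 --seed 1 --out recovery.tsv
```

`fit` writes one Fig.-4-style selection table per guild × response,
coefficient tables, the diversity report (accumulation curves, richness
estimators, similarity and representation matrices) and a run log;
reruns with the same config and seed are byte-identical.

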