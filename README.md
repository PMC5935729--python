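# sedch4

**Plant-litter phenols and methane production in lake sediments — an
end-to-end, testable analysis pipeline.**

Littoral lake sediments are a major natural CH₄ source, and what grows on the
shoreline decides what decomposes in them. Water-soluble phenols leached from
forest litter inhibit methanogenesis, while emergent-macrophyte litter
(*Typha latifolia*, cattail) does not — so sediment chemistry, set by the
surrounding plant community, can swing areal CH₄ production by orders of
magnitude. `sedch4` reimplements the full chain of evidence for that
mechanism as a reusable Python package, for biogeochemists and environmental
microbiologists who want to run the same analyses on their own incubation,
fluorescence, qPCR or lake-survey data:

1. **`sedch4.gasflux`** — cumulative CH₄/CO₂ production per incubation jar
   from periodic headspace measurements, correcting for the N₂
   injection/withdrawal at every sampling event (total = final headspace
   mass + Σ removed masses), normalized to mg m⁻² of sediment.
2. **`sedch4.eem`** — fluorescence excitation–emission matrices: inner-filter
   correction `F_corr = F_obs · 10^{(A_ex + A_em)/2}`, a nonnegative PARAFAC
   decomposition `X_ijk ≈ Σ_f a_if b_jf c_kf` written as a
   `ParafacModel(...).fit() → ParafacResults` pair, split-half validation by
   Tucker congruence, matching of components to reference fluorophores, and
   the relative phenol index (proportional phenol-leachate fluorescence ×
   porewater DOC).
3. **`sedch4.qpcr`** — absolute quantification of the *mcrA* methanogen
   marker: standard curve `Ct = β₀ + β₁ log₁₀(copies)` with efficiency
   `E = 10^{-1/β₁} − 1`, copies per g dry sediment, and geometric-mean
   treatment fold-differences.
4. **`sedch4.stats`** — the one-way amendment × spike ANOVA with
   baseline-relevelled group separation, and the log–log model
   `log(CH₄) = β₀ + β₁ log(phenol index)` whose slope is the elasticity of
   production with respect to phenols.
5. **`sedch4.upscale`** — ecosystem-scale projection for Boreal Shield
   lakes: per-lake production = rate × (P_occ × 28% of lake area), scaled by
   the surficial-sediment fraction (70%), in CO₂ equivalents (1 kg CH₄ =
   25 kg CO₂), with Monte-Carlo propagation of rate and climate-ensemble
   (5 GCMs × 3 RCPs) uncertainty.
6. **`sedch4.synth`** — seeded generators for every input above, with the
   underlying truths stored alongside, so the whole pipeline runs and is
   tested without any external download.

## Worked example

Generate a synthetic study (4 replicate jars × 4 amendments × spike arm ×
3 organic-matter levels, 150-day incubation) and run every stage:

```bash
sedch4 synth --seed 1 --out-dir data
sedch4 gasflux data/headspace.csv -o res
sedch4 eem data -o res --seed 1
sedch4 qpcr data/qpcr.csv -o res
sedch4 stats res/production.csv res/phenol_index.csv -o res
sedch4 upscale data/lakes.csv -o res --n-mc 500 --seed 1
```

The EEM stage prints the fitted five-component model — the components are
the two humic-like, tryptophan-like and tyrosine-like fluorophores plus the
phenol-leachate component, recovered at their reference peak positions:

```
Nonnegative PARAFAC decomposition
  samples: 48   components: 5
  explained variance: 99.9903%
  converged: True (iterations: 3592)

  comp   ex peak (nm)   em peak (nm)   total score
  C1          310            414        249.176
  C2          345            462        190.039
  C3          275            318        151.212
  C4          280            354        128.311
  C5          270            306         98.866

  split-half congruence (min over splits): 0.9999 (pass)
```

The statistics stage separates the amendment × spike cells (8 groups, 32
jars at 20% OM, so F has (7, 24) degrees of freedom) and fits the
phenol–CH₄ power law across the amended sediments:

```
One-way ANOVA over amendment x spike cells (log scale, OM 20%)
  F(7, 24) = 1905.41, p = 2.36e-31

Log-log model: log(CH4 production) ~ log(phenol index)
  slope (elasticity): -2.449  [-3.309, -1.589] 95% CI
  R^2: 0.496   n = 36 (0 nonpositive rows excluded)
```

The negative slope is the core finding in miniature: jars whose porewater
carries more litter-derived phenols produce less CH₄. Finally the upscaling
stage projects the consequence of macrophyte spread across a synthetic lake
population:

```
Boreal-Shield CH4 upscaling (Monte Carlo, 500 draws, 15 scenarios)
  current total:  727,261 kg CH4 (18,181,528 kg CO2-eq)
  future total:   1,230,332 kg CH4 [859,889, 1,827,042]
  percent change: +69.8% [+29.3%, +137.9%]
  ensemble minimum change: +29.3%
```

i.e. if emergent macrophytes occupy the habitat the climate ensemble makes
suitable, seasonal sediment CH₄ production from these lakes rises by tens of
percent even under the most conservative ensemble member, with the rate
uncertainty widening — but never sign-flipping — the projection.

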