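# Methods

This note documents the models behind each `sedch4` module, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical and design choices made where the design was open. Nothing
here states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Headspace gas accounting (`gasflux`)

**Model.** A sealed jar (default headspace ≈ 123 mL: a 250 mL jar minus a
4.5 cm sediment plug of 28.3 cm²) accumulates gas between sampling events.
Each event injects 10 mL of N₂, homogenizes, and withdraws a 10 mL aliquot.
The recorded concentration (ppmv) is interpreted as the **post-injection
mixed state**: the wording of the sampling protocol (N₂ homogenized into the
headspace *before* the aliquot is drawn) implies dilution precedes
measurement. A `measure_state="pre"` flag provides the opposite convention,
since the instrument plumbing could in principle be read either way; the
generators use "mixed", so the two conventions are distinguishable in tests.

For event *k* with pre-injection volume *V_k*: the measured concentration
maps to a headspace mass *m_k* via the ideal gas law at 20.5 °C and
101.325 kPa (molar masses 16.04 and 44.01 g mol⁻¹ for CH₄ and CO₂); the
withdrawal removes *r_k = m_k · w/(V_k + i)*; cumulative production is the
final remaining mass plus all removed masses, i.e. the "add back what was
withdrawn" bookkeeping. Totals divide by the sediment area (28.3 cm² =
2.83 × 10⁻³ m²) to give mg m⁻² over the 150-day window.

**Assumptions.** Isothermal, isobaric, ideal gas; no Henry's-law
partitioning into porewater; instantaneous homogenization. An implied
negative interval production (a concentration drop larger than removals can
explain) is flagged per jar and never silently clamped; flagged jars are
excluded from summaries only under `strict=True`.

**Exactness.** The inversion is the algebraic inverse of the event forward
model, so recovery of a simulated trajectory is exact to floating-point
(tested at 10⁻¹⁰ relative over 200 random trajectories).

## EEM processing and PARAFAC (`eem`)

**Grids.** Excitation 250–450 nm in 5 nm steps (41 points), emission
300–600 nm in 2 nm steps (151 points).

**Inner-filter correction** multiplies each pixel by
`10^((A(λ_ex)+A(λ_em))/2)` with absorbance measured in a 1 cm cuvette and
interpolated linearly onto the EEM grids. Samples with max A > 1.5 are
flagged as beyond the correction's validity (the approximation degrades at
high optical density) but still corrected. Missing absorbance rejects the
sample.

**PARAFAC.** The trilinear model with nonnegativity on all three modes is
fitted by column-wise alternating least squares (HALS): each factor column
update is the exact minimizer of the residual sum of squares given
everything else, projected onto `[ε, ∞)` with ε = 10⁻¹², so the objective is
non-increasing at every sweep (asserted per iteration in tests). The small
positive floor, rather than zero, keeps starved components alive — a column
at exactly zero can never re-enter a column-wise scheme — while leaving the
monotonicity argument intact. At fit finalization, score entries below
10⁻⁹ of the maximum score are snapped to exact zero: the floor is an
optimization device, not a detection.

Multi-start strategy: one start from the positive parts of the leading
singular vectors of the two spectral unfoldings (scores from one
nonnegative LS pass), the rest dense random; each start runs at most
`max_iter` (2000) sweeps; the best three by explained variance are then
refined to the relative-fit tolerance (10⁻⁸) under a larger budget
(`refine_max_iter` = 20000 total sweeps). Overlapping fluorophores (the
tyrosine-like 270/306 and phenol-leachate 275/318 components are nearly
collinear in both spectral modes) put ALS in long, nearly flat "swamps";
the variance ranking at the 2000-sweep cap is unreliable there, and a
per-iteration change tolerance can trigger inside a swamp, which is why
more than one candidate gets the longer leash. Fits that exhaust the budget
are returned flagged `converged=False`, never truncated. Everything is
deterministic given the seed.

Scale indeterminacy is fixed by normalizing loading columns to unit maximum
after every fit, with magnitude carried by the scores; the reconstruction is
invariant under this choice. Components are ordered by total score.
Missing pixels (NaN) are handled by expectation-style imputation with the
current model each sweep; the optional scatter excision masks ±10 nm around
first-order Rayleigh (off by default — the pipeline's reference workflow
does not prescribe a scatter treatment, so it is exercised only when the
generator simulates ridges).

**Validation and matching.** Split-half validation randomly halves the
samples, fits each half independently and matches components greedily by
Tucker congruence (uncentred cosine) of the concatenated excitation+emission
loadings; the default pass threshold is 0.95, standard practice for
split-half comparisons. Matching against the five Gaussian reference
fluorophores uses the same congruence, greedily with exclusion so the
assignment is a bijection; ties break by component index.

**Phenol index.** Per sample, the proportional fluorescence of the
phenol-leachate component (score / Σ scores, defined as 0 when all scores
are 0) times porewater DOC (mg L⁻¹). The index is relative — it is an
optical proxy, not a phenol concentration in mass units.

## qPCR quantification (`qpcr`)

The standard curve is an ordinary least squares of mean triplicate Ct on
log₁₀ copies; at least 3 dilution points spanning ≥ 2 orders of magnitude
are required, and a non-negative slope (an inverted assay) is rejected.
Efficiency is `10^(-1/slope) − 1`; the default generator slope of −3.391
corresponds to ≈ 97.2%. Unknowns are inverted through the curve and
normalized: `copies_gdw = copies_rxn · (elution/template) / (dry_mass ·
yield)`, with defaults 100 µL elution, 2 µL template, 0.25 g dry mass,
yield 1 — the normalization constants are configuration values since assays
differ, and extraction yield enters only as a supplied factor. Cts beyond
the standard range extrapolate with a warning rather than failing (samples
far below the lowest standard are common with strongly inhibited
communities).

Treatment fold differences vs a reference treatment are combined across
organic-matter levels as **geometric** means with the SE computed on the
log₁₀ scale and back-transformed, because abundances span orders of
magnitude and arithmetic averaging would be dominated by the largest level.

## Statistical layer (`stats`)

**ANOVA.** One-way over the 8 amendment × spike cells at one OM level,
performed on log production by default: production spans nearly four orders
of magnitude between macrophyte- and forest-litter sediments, so raw-scale
homoscedasticity is untenable; a raw-scale flag exists for comparison.
Zero responses are offset by half the smallest positive value before the
log. Pairwise separation re-levels the baseline cell and reads each
difference off the coefficient table (pooled error); cells not separated at
α = 0.05 are merged transitively (connected components), and groups are
numbered by descending mean. NaN p-values (zero residual variance) cannot
separate a pair.

**Log–log model.** OLS of log CH₄ production on log phenol index (natural
logs internally; the slope is base-invariant), with coefficient CIs and a
95% mean-prediction band over the observed range. Rows with nonpositive
production or index are excluded — the log is undefined there, which is
also why the fit spans the amended sediments: un-amended controls carry no
phenol-leachate signal. CI calibration is verified by simulation (coverage
0.95 ± 0.03 over 1000 replicates at n = 36).

## Upscaling (`upscale`)

Per lake: `coverage_m2 = P_occ × 0.28 × area_km2 × 10⁶` (28% is the maximum
emergent-macrophyte coverage for boreal lakes of 0.1–1000 km²; occurrence
probability 1 colonizes exactly that fraction) and
`production_kg = rate × coverage × 10⁻⁶ / 0.70` (the incubated 5 cm
surficial layer represents 70% of whole-profile production). CO₂
equivalents use GWP 25. The Monte Carlo draws, per iteration, one
production rate from a zero-truncated Normal(mean, SE) — the macrophyte
treatment default is 7.22 × 10³ mg m⁻² with SE set at 10% of the mean, a
configuration value since the rate uncertainty depends on the user's own
incubation — and one future scenario column uniformly from the 5 GCM × 3 RCP
ensemble (a uniform mixture rather than a hierarchical model: simple,
reproducible, and faithful to "the ensemble is the uncertainty"). Current
and future totals share the draw's rate, so the percent change is rate-free
by construction (asserted per draw in tests); a zero current total with
nonzero future is reported as an undefined-change flag, not infinity.
Because "likely to be colonized" has no canonical threshold, both
definitions are provided: the expected count (sum of probabilities, the
default) and a threshold count (P ≥ 0.5). The per-scenario deterministic
table and its minimum change accompany the Monte-Carlo quantiles, since a
conservative reader will want the worst ensemble member rather than the
median.

## Synthetic data (`synth`)

The generators emulate the study design: 4 replicate jars per amendment
(CTR, CON, DEC, TYP) × spike combination, OM levels 10/20/40% (the spike
arm duplicates only the 20% setup), sampling to day 150.

* **Incubation.** Cumulative production follows a logistic reaching 99% of
  its asymptote at day 150 (the observed curves plateau; the exact shape is
  not published, so the steepness is a configurable shape parameter),
  normalized so the stored day-150 truth is hit exactly. Treatment means
  come from the reported rates and fold ratios: TYP 7.22 × 10³ and DEC
  2.63 mg m⁻² as printed; CON = TYP/400 and CTR = TYP/1400 from the printed
  fold statements. The spike doubles TYP, leaves CON/DEC unchanged, and
  multiplies CTR by 4 (the strongest observed response; no value is
  printed, so 4 is this package's choice). Between-jar variation is
  log-normal with CV 0.15 — the study shows error bars but no variance, so
  this is a free knob chosen to give visible but not overwhelming scatter.
  CO₂ is generated at a common rate across amendments (decomposition
  proceeds regardless of methanogenesis inhibition).
* **EEMs.** Trilinear mixtures of five Gaussian fluorophores (σ_ex 15 nm,
  σ_em 25 nm — peaks are published, widths are not) with
  treatment-structured scores: phenol-leachate exactly 0 in CTR, lowest in
  TYP, highest in DEC; 1% multiplicative noise clipped at zero; and, by
  default, inner-filter attenuation from a CDOM-like exponential absorbance
  spectrum (a₃₅₀ proportional to DOC, spectral slope 0.018 nm⁻¹) — measured
  EEMs are attenuated, and the pipeline's correction step is its exact
  inverse, so the default emulates what the correction exists for. Scatter
  ridges are off by default.
* **qPCR.** Ct values from the log-linear model with slope −3.391 and
  intercept 38 (≈ 97.2% efficiency). Standards carry a replicate Ct SD of
  0.3 (which reproduces the printed R² ≈ 0.999 naturally); unknowns default
  to SD 0.2. Treatment abundances anchor TYP at 10⁸ copies g⁻¹ (absolute
  abundance is not printed; only folds are compared downstream) with the
  printed fold-deficits 1.72 × 10² (CON) and 1.33 × 10⁴ (DEC).
* **Lakes.** log₁₀ areas ~ Normal(−0.5, 0.8) truncated to 0.1–1000 km²
  (most mass at small lakes, as in real size distributions); current
  occurrence probabilities Beta(1.2, 4); future columns apply an
  RCP-specific mean uplift (1.4 / 1.75 / 2.2 for RCP 2.6 / 4.5 / 8.5 — the
  midpoint consistent with a roughly doubling colonization) with GCM-level
  and lake-level log-normal spread, clipped to [0, 1].

Same seed ⇒ byte-identical output for every generator, and every generator
stores its truths so recovery tests never re-derive them.

**What passing tests do not show.** The generators are structurally
faithful but idealized: no GC drift or calibration error, no EEM scatter by
default, no pipetting or plate-position effects, perfectly log-linear
amplification, occurrence probabilities drawn from a smooth family rather
than a species distribution model's spatial field. Tests passing on this
data demonstrate that the estimators invert the assumed measurement models
correctly and calibrate as claimed — not that those models capture every
artifact of real instruments, nor that the real-data headline figures
(which require the original jar data and the GLWD/MaxEnt rasters) are
reproduced.

## Problem sizes

Default test and acceptance runs use desk-scale inputs chosen to exercise
every code path at full fidelity: 32–48-sample EEM cubes on the full
41 × 151 grid, 24-sample cubes for split-half work, 7-point dilution
standards with 36 unknown wells, 128 headspace series, 100–2000-lake
tables, and 10³ Monte-Carlo draws or simulation replicates where a
calibration is asserted.

## Known limitations

* The PARAFAC solver handles missing data by imputation, which is adequate
  for narrow scatter bands but slow for heavily masked cubes.
* The tyrosine-like and phenol-leachate components are spectrally close;
  at noise well above a few percent, or with score patterns lacking
  contrast (e.g. all samples near-proportional), their separation degrades
  first.
* The ANOVA's transitive grouping can chain overlapping pairs into one
  group (the usual caveat of letter-display style summaries).
* The upscaling treats lakes independently and ignores temperature
  response, littoral geometry beyond the single habitat fraction, plant
  gas transport, and production-to-emission losses.
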