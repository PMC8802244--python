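# Methods

This note records the model conventions, parameter defaults and design
choices behind `agestruct`, and what the test suite does and does not
establish.

## Life tables

Tables use integer age classes 1..ω with annual survival s_x (from class x
to x+1) and non-negative relative fecundity f_x.  Survival at the maximum
age is always zero — a hard truncation at the lifespan — and fecundity is
zero below the age at first maturity unless a caller explicitly disables
the mask (the forward simulator does so by default, see below).

**Fractional maturity.**  Several species mature at non-integer ages (0.5,
1.5, 7.5 years).  Annual projection needs integer classes, so the
fecundity mask and the adult census both use ⌈maturity⌉.  This is a
convention, not a fact about the species: a fish maturing at 7.5 first
counts as an adult in class 8.

**Empirical route.**  Growth is Von Bertalanffy,
L(a) = L∞(1 − e^{−K(a−t₀)}), fitted by least squares (`scipy.curve_fit`)
with a data-driven start; t₀ defaults to 0 when the data cannot identify
it.  Instantaneous natural mortality at age is the length-based relation
m_a = (L_a/L∞)^{−1.5}·K — mortality equals K at the asymptotic length and
rises steeply for small fish — and annual survival is s_a = e^{−m_a}.
Fecundity-at-length uses a power law F = αL^β by default, with
exponential and linear alternatives; negative linear predictions clamp to
zero with a warning.

**Theoretical route.**  Survivorship is Weibull, S(t) = exp(−(t/b)^c).
The shape c selects the curve type: c < 1 concentrates mortality in the
first year(s) of life (type III, fish-like), c = 1 gives constant annual
mortality (type II), c ≫ 1 defers mortality to the end of life (type I).
The scale is b = lifespan·(−ln 0.01)^{−1/c}, so exactly 1% of a cohort
born at age 0 is alive at the lifespan; "log 0.01" is the natural
logarithm — the only reading under which the 1% constraint holds.  Yearly
mortality is evaluated on the intervals [x, x+1) starting at age 0 and
mapped to the 1-based table by cumulative products, so age class 1 carries
the first-year juvenile mortality: s_x = S(x)/S(x−1).  Age-fecundity
models (constant, exponential e^{f·age}, power-law age^f, linear,
polynomial) are max-scaled to 1; only relative values matter downstream.

**Component toggles.**  Sixteen variants switch the four biological
components (maturity, age-specific survival, age-specific fecundity,
sex-specific differences) on and off in binary order; model 1 is the null
model (maturity 1, constant survival leaving 0.01% of a cohort at the
maximum age, constant fecundity, identical sexes) and model 16 is fully
biological.  The null survival rate supports two readings — a per-species
rate solving s^{ω−1} = 10⁻⁴, and a single shared rate set by the
longest-lived species and truncated at each species' ω.  Both are
implemented (`shared_max_lifespan`); the shared rate is used by the
pipeline because it reproduces the narrow published range of null-model
Ne/N ratios, whereas the per-species rate spans nearly the whole unit
interval.

## The effective-size engine

For each sex, fecundities are rescaled so a newborn expects exactly 2
lifetime offspring (the stable-population constraint), giving schedules
l_x, b_x.  The lifetime offspring count K of a newborn has mean 2 and, by
the law of total variance over the age at death,

    Vk = Σ_x d_x [ Σ_{j≤x} φ_j·b_j + (K_x − 2)² ].

φ is the within-age variance-to-mean ratio of annual offspring numbers.
The phrase "equal contribution of same-age individuals" is read as the
absence of extra sweepstakes overdispersion, i.e. Poisson reproduction
(φ = 1), not literally zero variance: φ = 0 would push Ne above N for
near-semelparous schedules, contradicting every observed ratio below 1.
φ is an explicit parameter; the Monte-Carlo cohort oracle supports 0
and 1.  Reproduction is independent across years given survival (no
persistent individual quality, no heritability of vital rates).

Two sexes are combined by sex-ratio-weighted averaging of per-sex Vk and
T (both sexes share k̄ = 2, so there is no between-sex mean component at a
0.5 ratio), then a single Hill-type formula:

    Ne = 4·N₁·T / (Vk + 2),      Ne/N = Ne / N_adult,

with N_adult the annual census of classes at or above ⌈maturity⌉
(`adult_census="all"` counts every class).  The ratio is provably
independent of N₁; the suite asserts this to 10⁻¹².  A maturity-1
semelparous Poisson table collapses to Wright–Fisher (ratio exactly 1),
and φ = 0 gives Ne = 2N₁.  The result also carries the per-year variant
Ne/(N_adult·T) as `ratio_annual` (the annual effective size over the
annual adult census).

**Validation.**  An independent Monte-Carlo cohort simulator draws
individual life histories (yearly Poisson reproduction, then a survival
trial) and is required to agree with the analytic (k̄, Vk) within three
bootstrap standard errors on 50 random tables spanning c ∈ [0.01, 30];
the forward simulator (below) provides a second, fully independent check
through the 4·Ne·μ equilibrium prediction.

## Forward simulation

The individual-based simulator keeps N_total diploids with bit-packed
haplotypes of L biallelic sites.  Yearly cycle: every individual
reproduces (parents drawn proportionally to age- and sex-specific
fecundity; dying individuals still breed in their final year), deaths are
drawn from the age- and sex-specific survival probabilities, and exactly
as many newborns replace them — population size is constant by
construction.  Offspring inherit one intact haplotype from each parent
(no within-locus recombination: heterozygosity summaries are
recombination-insensitive under neutrality) plus Poisson(μL) mutations
that flip alleles at uniform sites; at the default 4Nμ ≈ 10⁻³ per locus
the recurrent-mutation bias of the finite-sites model is negligible
relative to the stochastic error (equilibrium H = θ/(1+2θ) rather than
θ, a 0.2% effect).  Per-individual heterozygous-site counts are updated
incrementally, so recording the yearly population mean is O(N).  Age at
maturity is ignored by default (`ignore_maturity=True` back-fills the
juvenile fecundity mask), mirroring how the per-species simulations were
configured; the Wright–Fisher control uses a single age class in which
everyone breeds equally and dies, making years coincide with generations.

Defaults follow the study conditions: 2000 individuals, equilibrium
averaged over a trailing 10 000-year window, 50 replicates.  Tests and
the acceptance script run rescalings that preserve 4Nμ = 8×10⁻⁴ (125–200
individuals with μ raised accordingly, a 10⁴-site locus, burn-in of at
least 20·4N generations, and a trailing window spanning many multiples of
the 2N-year coalescent correlation time, over 10–16 replicates) —
desk-scale runs whose expected equilibrium is identical.  A linear-trend t-test on the trailing window flags
non-convergence; runs whose burn-in is shorter than 8N years are marked
non-equilibrated.  With a single non-recombining locus the time-averaged
heterozygosity of one replicate is dominated by a handful of effectively
independent genealogies, so replicate-to-replicate spread of a few
percent is expected and the acceptance comparison uses replicate means.

## Beta regression

Diversity is modelled as a proportion in (0, 1) (printed percentages
divided by 100) with a beta likelihood parameterized by a logit-link mean
and a single constant precision φ, the convention under which the
published slope magnitudes arise.  Estimation is maximum likelihood over
(β, log φ): analytic gradient, BFGS with OLS-on-logit starting values, an
L-BFGS-B pass and a damped Newton polish; every fit self-checks that the
gradient norm is below 10⁻⁶.  If logit(y) is exactly affine in the
design, the precision diverges and the fit is returned as a flagged
degenerate perfect fit.  The pseudo-R² is the squared Pearson correlation
between logit(y) and the fitted linear predictor; Wald p-values use the
observed-information covariance (numerical Hessian of the analytic
gradient).  `statsmodels`' independent beta-regression implementation is
used in the tests as a cross-check, never as the estimator.

Max-scaled responses (diversity and Ne/N divided by their maxima, as in
the component-toggle comparisons) put one observation on the boundary;
the pipeline compresses with y' = (y(n−1)+0.5)/n and refits — scaling is
never applied to fitted coefficients.

The leave-out analysis enumerates all C(16,11) = 4368 species subsets
exhaustively and reports empirical 2.5/97.5 percentiles of the slope and
pseudo-R² distributions.  Interaction tests compare the model with a
brooding indicator and its product with the covariate against the
covariate-only model by likelihood ratio (the exact reduced model behind
the published interaction p-values is not recoverable; the suite asserts
the qualitative pattern — strong significance for lifespan measures and
body size, none for hermaphroditism — which is stable across the
plausible nestings).

## Survivorship-fecundity grid

For every (c, f) on a default grid of 60 log-spaced c in [0.01, 30]
(plus the printed anchors 0.01, 0.1, 1.03) and 41 linear f in [−1, 1],
sixteen theoretical species are built with the fixture's real maturities
and lifespans, and the OLS slope, R² and p of Ne/N against adult lifespan
(lifespan − maturity, non-integer) summarize the cell.  Failed cells are
recorded, never dropped; the stage is fully deterministic.

**Ratio basis.**  The grid regresses the per-year ratio
Ne/(N_adult·T) rather than the per-generation ratio.  With the
per-generation basis, the generation length T (which grows with lifespan
and maturity) inflates Ne for long-lived late-maturing species and
flattens or even reverses the lifespan relation; the per-year basis
yields the published qualitative structure — steepest negative slopes for
type III curves, an R² peak near c ≈ 1, significant positive slopes only
for strongly type I curves with rising fecundity — and is the closest
reconstruction of the published grid summaries found in a systematic
sweep of table and census conventions.  Both bases are computed by the
engine and the choice is a `GridSpec.ratio_basis` flag.  Because the
original tool's exact internals (age-interval mapping, census definition,
handling of fractional maturity) are not fully recoverable, residual
quantitative deviations of order 10–25% in individual grid summaries are
expected and documented rather than calibrated away; the engine itself is
validated independently by the Monte-Carlo oracle and the forward
simulator.

## Synthetic data

The generators emulate the pipeline's inputs with the statistical
structure the estimators assume: Von Bertalanffy age-length samples with
independent Gaussian noise (default noise a few cm, the scale of otolith
length-at-age scatter), and species sets whose diversity is beta
distributed around a logit-linear function of adult lifespan — the same
mean/precision parameterization as the regression model, so recovery
tests are conjugate and meaningful.  Default cohort: lifespans uniform on
3–21 years (the fixture's range), maturity = max(0.5, 0.2·lifespan)
(mimicking the fixture's maturity/lifespan ratios), slope −0.10 per year
and precision 800 (diversity noise comparable to the fixture's
between-species scatter).  What the generators do *not* emulate:
phylogenetic correlation between species, demographic history,
intraspecific spatial structure, and estimation error in the trait values
themselves — passing recovery tests therefore shows the estimators are
correct for the assumed sampling model, not that real trait tables
satisfy it.

## Known limitations

- Vital rates are constant in time; no temporal fluctuation of Ne, no
  heritable fitness, no persistent individual quality beyond the scalar φ.
- The forward simulator has no recombination, selection or demography
  changes; its mutation model is finite-sites with allele flips.
- The engine's census and age-interval conventions are reconstructions
  (see the grid section); species-level results that depend on
  unpublished per-species growth and fecundity inputs can only be checked
  qualitatively.
- Species are treated as independent points; no phylogenetic comparative
  correction.
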