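# agestruct

Age-specific survival and fecundity shape how much genetic diversity a
species can maintain.  `agestruct` links the two quantitatively for
iteroparous species with overlapping generations — marine fishes being the
motivating case: it builds life tables from growth and fecundity relations,
computes the lifetime variance in reproductive success and the resulting
effective-to-census population-size ratio, simulates neutral heterozygosity
to mutation–drift equilibrium with an individual-based forward model, and
fits beta regressions of observed genome-wide diversity on life-history
traits.  A 16-species marine-teleost trait table (median genome-wide
heterozygosity plus body size, trophic level, fecundity, propagule size,
maturity, lifespan, parental care and hermaphroditism) ships with the
package, so every analysis runs out of the box.

## The model

At neutral mutation–drift equilibrium, heterozygosity is θ = 4·Ne·μ.  Age
structure depresses Ne below the adult census size N through the lifetime
variance in reproductive success V_k.  With a stable population in which a
cohort of N₁ newborns enters each year, fecundities rescaled so each
newborn expects k̄ = 2 lifetime offspring, survivorship l_x and scaled
fecundities b_x, the engine computes (per sex)

    V_k = Σ_x d_x [ Σ_{j≤x} φ_j b_j + (K_x − 2)² ],
    T   = Σ_x x·l_x·b_x / 2,
    Ne  = 4·N₁·T / (V_k + 2),        Ne/N = Ne / Σ_{x≥maturity} N₁·l_x,

where d_x = l_x − l_{x+1} is the probability that x is the final age,
K_x = Σ_{j≤x} b_j, and φ is the within-age variance-to-mean ratio (1 for
Poisson reproduction).  Survivorship curves are either empirical — from
Von Bertalanffy growth L(a) = L∞(1 − e^{−K(a−t₀)}) and the length-based
natural mortality m_a = (L_a/L∞)^{−1.5}·K, s_a = e^{−m_a} — or theoretical,
from a Weibull curve S(t) = exp(−(t/b)^c) scaled so 1% of a cohort reaches
the maximum age, with shape c spanning type III (c < 1, fish-like), type II
(c = 1) and type I (c > 1, mammal-like) survivorship, combined with
age-fecundity models such as F(a) = e^{f·a}.

## Worked example

```python
import numpy as np
import agestruct as ag

# beta regression of diversity on adult lifespan, 16 packaged species
df = ag.table1_frame()
fit = ag.fit_formula(df, "diversity ~ adult_lifespan")
print(f"slope = {fit.coefficients[1]:.4f}  pseudo-R2 = {fit.pseudo_R2:.3f}")

# Ne/N of a long-lived type III species with fecundity rising with age
table = ag.build_theoretical_life_table(
    maturity=7.5, lifespan=21, c=0.5,
    fec_model=ag.AgeFecundityModel("exponential", f=0.142),
)
res = ag.effective_size_ratio(table, table)
print(f"Vk = {res.Vk_f:.2f}  T = {res.T:.2f} y  Ne/N = {res.ratio:.3f}")
```

prints

```
slope = -0.0889  pseudo-R2 = 0.427
Vk = 124.12  T = 14.54 y  Ne/N = 1.079
```

The first line says each extra year of adult lifespan lowers expected
diversity by 0.089 on the logit scale across the 16 species (about an 8.5%
relative drop per year at these diversity levels).  The second line shows
the engine's decomposition for a single species: a lifetime
reproductive-success variance sixty times the Poisson value of 2 (few
survivors of the heavy type III juvenile mortality monopolize
reproduction), a generation length of 14.5 years, and a per-generation
effective size of about the adult census — the per-year basis
`res.ratio_annual` (0.074 here) is the variant that declines steeply with
adult lifespan.

A command-line interface mirrors the library:

```bash
agestruct regress --formula "diversity ~ adult_lifespan" --subset-scan 11
agestruct build-theoretical --maturity 2 --lifespan 10 --c 0.5 --out sp.tsv
agestruct agene --tables tables_dir/
agestruct grid --model exponential
agestruct run empirical --out out/
```

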