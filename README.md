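# nichepart

Spatial and dietary niche overlap between two groundfish predators, and the
correlation between the two as a test of resource partitioning.

## The problem

When two large mobile predators — think Pacific Halibut and Arrowtooth
Flounder on the Gulf of Alaska shelf — are suspected of competing, classical
niche theory predicts *resource partitioning*: coexisting competitors should
differentiate their use of space, time or food. Operationally, where the two
species co-occur the most, their diets should diverge the most, which shows
up as a **negative correlation between spatial overlap and dietary overlap**
across locations and years. `nichepart` implements that full analysis for
bottom-trawl survey and stomach-content data, for anyone studying pairwise
predator interactions from fishery-independent surveys.

## The method

1. **Ingest & filter.** Tows missing depth or bottom temperature are
   excluded. Analyses are restricted to fish of 30–69 cm fork length:
   haul-level CPUE (number/ha) is multiplied by the subsample proportion of
   fork lengths inside that interval, and presence means adjusted CPUE > 0.
2. **Delta (hurdle) species distribution models.** Per species, two GAMs:

   * presence/absence: `logit P(present) = y_i + f1(φ, λ) + f2(z) + f3(T)`
   * positive catch: `ln CPUE = y_i + f1(φ, λ) + f2(z) + f3(T) + ε`

   with survey year `y_i` a fixed factor, a bivariate smooth of longitude φ
   and latitude λ, smooths of depth `z` and bottom temperature `T` (the
   temperature basis is limited to four dimensions), penalized B-splines
   whose smoothing is chosen by GCV. All-subsets AIC comparison (`dredge`)
   ranks the 16 term subsets by ΔAIC and Akaike weight.
3. **Gridded spatial overlap.** On a uniform 100 km × 100 km
   transverse-Mercator grid, per survey year `i` and cell `j`:
   `A[s,i,j] = PO · PA`, standardized by the species maximum
   (`stdA = A / max A`, so values lie in [0, 1]); cells below 0.25 for both
   species in every year are dropped as unsuitable habitat; spatial overlap
   is `S[i,j] = stdA_PH · stdA_ATF ∈ [0, 1]`.
4. **Dietary overlap.** Stomachs are pooled by year × cell (≥ 3 non-empty
   stomachs per predator required); prey-weight proportions `W_t` give
   Schoener's similarity `D = 1 − ½ Σ_t |W_PH,t − W_ATF,t| ∈ [0, 1]`, plus
   Shannon `H′`, Pielou `J′` and rarefaction curves for diet breadth.
5. **Partitioning statistics.** ANCOVA (area as factor, year as covariate,
   sequential SS, α = 0.1) with Tukey HSD post hocs, and the Pearson
   correlation of S against D over the paired year-cells — the resource
   partitioning test.

A first-class synthetic-data module generates trawl surveys and stomach
contents with known response surfaces and compositions, so every stage is
verifiable against truth at desk scale.

## Worked example

Run the whole pipeline on a small synthetic Gulf-of-Alaska-like survey
(4 survey years × 400 hauls, two species `PH` and `ATF`):

```yaml
# demo.yaml
output_dir: demo_out
scenario: default
seed: 7
hauls_per_year: 400
years: [1999, 2003, 2007, 2011]
```

```bash
nichepart run --config demo.yaml
```

prints

```json
{
  "dietary_overlap_mean": 0.2597070379168005,
  "dietary_overlap_sd": 0.13278721539831187,
  "n_dietary_year_cells": 100,
  "n_excluded_cells": 34,
  "n_hauls_input": 1600,
  "n_hauls_retained": 1477,
  "n_paired_year_cells": 97,
  "n_spatial_year_cells": 656,
  "pearson_df": 95,
  "pearson_p": 0.08286627852420361,
  "pearson_r": -0.1769920647442192,
  "pearson_t": -1.752777620771245,
  "seed": 7,
  "spatial_overlap_mean": 0.11284239000109768,
  "spatial_overlap_sd": 0.14358552564989133
}
```

Reading this: 1,477 of 1,600 simulated tows had complete covariates; the
delta models predicted abundance for 656 year-cell combinations (34 whole
cells dropped by the 0.25 habitat rule); spatial overlap averaged
0.11 ± 0.14 SD and dietary overlap 0.26 ± 0.13 SD; over the 97 year-cells
with both indices, S and D correlate at r = −0.18 (t₉₅ = −1.75, p = 0.083)
— a weak partitioning signal, emergent in this scenario because smaller,
invertebrate-eating size classes dominate where the two species co-occur.
The `partitioning` scenario builds a strong negative coupling in deliberately
(`nichepart run` with `scenario: partitioning` recovers r ≈ −0.6); with
independent S and D the test rejects at its nominal rate.

Per-stage subcommands (`nichepart simulate|ingest|fit|overlap|diet|stats`)
operate file-to-file on the same plain-CSV dialects, which mirror the public
bottom-trawl survey and food-habits downloads (see `nichepart/io.py` for the
column schemas). Supplying real survey tables in those dialects reruns the
full analysis unchanged.

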