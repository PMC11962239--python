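# seabirdniche

Multi-stage niche-partitioning analysis for sympatric central-place foraging
seabirds, built around a guild of three species breeding on one island colony
in a western-boundary-current hotspot: a wide-ranging flyer (crested tern), a
short-range swimmer (little penguin) and a generalist flyer that also uses
terrestrial subsidies (silver gull).

The pipeline answers three questions: *where* do the species forage (spatial
niche), *under which ocean conditions* (environmental niche), and *on what*
(trophic niche) — and how strongly these niches overlap from year to year as
warm, nutrient-poor current water (the "EAC" probability field) pushes into
the shelf.

## Stages

1. **Track standardisation** — raw GPS fixes (4-min or 30-s programming) are
   reduced to one centroid per 12-min window, so tracks are comparable across
   field seasons; trip statistics are computed as haversine distances from
   the colony.
2. **Kernel utilisation distributions (KUD)** — daily species-level space use
   is a Gaussian-kernel density on the 0.1° analysis grid with the reference
   bandwidth `h = σ̂·n^(−1/6)`; the 95% volume contour (minimal
   highest-density cell set holding 95% of the mass) is the home-range
   boundary and its area in km² the space-use response.
3. **Habitat selection** — cells inside the 95% KUD are "presence", the rest
   of the study area "absence"; both models share the structure

   ```
   y ~ species × EAC_prob + species × SST_SD + (1 | day) + offset(log10 N)
   ```

   with a binomial (logit) response for presence/absence and a Gaussian
   response for log10 daily KUD area. The binomial random-intercept model is
   fitted by Gauss–Hermite-quadrature maximum likelihood in-package; the
   Gaussian models use statsmodels `MixedLM`. Daily EAC dominance (% of
   cells with EAC probability > 0.5) and mean SST SD are compared across
   years by ANOVA with Tukey HSD.
4. **Environmental niche overlap** — cell-day environments (lat, lon, EAC
   probability, SST SD, standardised) are reduced by PCA; species'
   occurrence-weighted densities on the (PC1, PC2) plane give Schoener's
   `D = 1 − 0.5·Σ|p₁ − p₂|` per species pair and year. Because sampling is
   unbalanced, overlaps are recomputed on 100 subsamples of 8 individuals
   (with replacement) and a three-factor ANOVA (pair, year, iteration)
   verifies the resampling itself explains nothing.
5. **Trophic niche** — feather δ13C/δ15N pairs are modelled per element
   (species fixed, year random) and summarised per species-year by the
   standard ellipse area `SEA = π·√det(Σ̂)`, its small-sample correction
   `SEAc = SEA·(n−1)/(n−2)`, and a Bayesian posterior `SEA_B` sampled
   exactly from the conjugate inverse-Wishart marginal (100,000 draws).

A synthetic-data module generates ocean fields (warm-tongue intrusions whose
EAC probability is a logistic transform of the SST anomaly), biased
correlated-random-walk tracks with daily central-place return and logistic
habitat avoidance, and bivariate-normal isotope clusters — all with known
ground truth, so every stage has a parameter-recovery test.

## Worked example

```
seabirdniche run-all --seed 1 --outdir runs/demo
```

runs the full synthetic study (3 year-regimes × 15 days, 10 birds per
species-year) and writes, among others, `habitat_model_terms.csv`:

```
Model,Variables,Type,Est,SE,t,p
Presence/absence,crested_tern x EAC probability,Fixed,-2.60305,0.318135,-8.18223,2.78648e-16
Presence/absence,little_penguin x EAC probability,Fixed,-0.894917,0.558098,-1.60351,0.108821
...
```

The tern's EAC slope of −2.6 (p < 0.001) says the odds of a cell lying
inside the tern's daily home range fall steeply as the cell's probability of
being EAC-origin water rises — the fish specialists avoid the warm,
nutrient-poor intrusion. `overlap_summary.csv` holds the pair-year mean
Schoener's D (e.g. penguin–gull D ≈ 0.22–0.36, the most separated pair,
consistent with their opposite north/south foraging sectors), and
`ellipse_summary.csv` the trophic niches (gull SEA_B ≈ 3.2–5.8 ‰², several
times the fish specialists' ellipses, reflecting its generalist diet).

Programmatic use mirrors the CLI:

```python
from seabirdniche.pipeline import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(seed=1, outdir="runs/demo"))
```

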