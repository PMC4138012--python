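# batscape

Probabilistic breeding-origin assignment of bat casualties from fur
deuterium.

Wind turbines kill large numbers of bats, and for migratory species such as
the noctule (*Nyctalus noctula*) the carcasses found under a turbine may be
local animals or long-distance migrants from populations hundreds of
kilometres away. Because bats moult in their breeding area, the stable
hydrogen isotope ratio of fur keratin (δ²H_f, ‰ vs VSMOW) records the
precipitation isotope signal (δ²H_p) of the moult site, which in Europe
declines smoothly toward the north. `batscape` implements the full
inference chain that turns a table of carcass fur values into (a) a
migrant/sedentary classification, (b) a mixed-effects analysis of what
drives fur-isotope variation, and (c) sex-stratified probability-of-origin
maps — together with a synthetic-data generator that makes every stage
testable against known ground truth.

It is aimed at movement ecologists and conservation analysts working with
keratin isoscape assignment.

## The model

**Calibration and classification.** A reduced major axis (RMA) regression
links fur to precipitation deuterium,

    δ²H_f = a + b·δ²H_p,   b = sign(r)·SD(δ²H_f)/SD(δ²H_p),

fitted to sedentary calibration animals or supplied as published
parameters. For a carcass at a site with local value δ²H_p, the expected
fur interval is `a + b·δ²H_p ± t_{1-α/2, n-2}·σ` (σ = calibration residual
SD). Individuals inside the closed 95 % interval are classified
*sedentary*, outside *migratory*, keeping the side (below = origin in a
more depleted, typically more northern region).

**Covariate model.** δ²H_f is modelled with a linear mixed model: fixed
terms season (day of year), sex, migratory status, latitude, longitude and
their interaction; a random intercept chosen by REML/AIC among {none,
sampling site, macrochore}; fixed terms pruned backward by likelihood-ratio
tests under ML; the final model refitted by REML and its residuals checked
with a Monte-Carlo Lilliefors normality test.

**Origin maps.** Each migrant's fur value is inverted through the
calibration, `δ²H_p = (δ²H_f − a)/b`, and 10,000 candidate precipitation
values are simulated (normal around the inverted value, SD drawn from a
gamma distribution to propagate calibration uncertainty). The standardized
kernel density of the draws reclassifies the δ²H_p isoscape into an isotope
origin-probability raster **PM_Iso**. Point-inverted autumn banding
bearings give a von Mises density of spring headings that scores each cell
by its great-circle bearing from the sampling site (**PM_Ang**). Site maps
are merged weighted by sample size, and the refined breeding-origin map is
the cellwise product

    PM_Breed = PM_Iso × PM_Ang,

with PM_Iso and PM_Breed min–max standardized to [0, 1] over unmasked
cells. All of this is run separately for females and males.

## Worked example

Generate a synthetic study world (45 wind-farm sites, 99 local + 37 migrant
casualties on a 60×60-cell isoscape), fit the calibration, classify, and
map:

```sh
batscape simulate --seed 1 --out demo
batscape calibrate --pairs demo/calibration.csv --out demo/rma.yaml
batscape classify --records demo/records.csv --sites demo/sites.csv \
    --isoscape demo/isoscape.asc --rma demo/rma.yaml --out demo/classified.csv
batscape assign --records demo/records.csv --sites demo/sites.csv \
    --isoscape demo/isoscape.asc --rma demo/rma.yaml \
    --bearings demo/bearings.csv --draws 2000 --seed 7 --out demo/maps
```

which prints

```
RMA: slope 1.6399, intercept 15.63, residual SD 7.45 (n=50, r=0.793)
32/136 migratory (23.5%)
wrote 6 maps to demo/maps
```

The calibration slope says fur deuterium changes ~1.6 ‰ per ‰ of
precipitation deuterium in this world; 32 of 136 carcasses fall outside
their site's 95 % fur interval and are flagged as migrants (the world was
generated with 37 true migrants, 27.2 %); the six ASCII rasters are PM_Iso,
PM_Ang and PM_Breed for each sex, each in [0, 1] with 1 marking the most
plausible breeding-origin cells. `batscape all --config pipeline.yaml` runs
the same chain plus the mixed-model protocol and writes a manifest with
seeds and SHA-256 hashes of every artifact.

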