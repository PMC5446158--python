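# prairiefp

Flowering-potential analysis for factorial nutrient-addition grassland
experiments.

Eutrophication can reorganize not just *which* plants dominate a
grassland but *when* the community flowers. `prairiefp` is a tested
pipeline for asking that question from standard distributed-experiment
data (NutNet-style plot × species percent-cover surveys plus a species
flowering-trait catalog). It is aimed at community ecologists and
biostatisticians working with factorial N/P/K(+micronutrient) designs
across sites and ecoregions.

## What it computes

**Flowering potential (FP).** For plot *i* and month *m*,

    FP_im = Σ_s r_is · w_sm

where `r_is` is species *s*'s relative cover (percent cover divided by
the plot total — totals may exceed 100% from canopy overlap) and
`w_sm` ∈ {0, 1} indicates whether month *m* lies in the species'
published flowering interval. FP is the share of the analyzable canopy
expected to flower in that month. Subset profiles (exotic/native
provenance; C3 graminoid, C4 graminoid, forb, legume functional
groups) zero the weights outside the subset without re-normalizing, so
they partition the total profile.

**Flowering volume.** The trapezoidal area under a plot's 12-month FP
curve (percent scale, unit month spacing) — the total seasonal
flowering window.

**Mixed models and contrasts.** FP over the growing season
(May–October) is modeled as

    fp ~ P × K × N × Month × Ecoregion  +  (1 | site)  +  (1 | site:block)

by REML, with marginal F tests under sum-to-zero coding and
containment-style denominator df; the volume model drops the month
factor. Nitrogen effects are localized with Bonferroni-corrected
N_added − N_free contrasts per month (or per ecoregion × month).

**Synthetic data.** A generator produces complete factorial designs
with realistic species pools (phenology-structured flowering windows,
long-tailed abundances, provenance/functional labels) and known
multiplicative nitrogen effects, returning the exact expected FP
difference (`SyntheticTruth`) for power and calibration studies. See
`docs/methods.md` for the model details and design choices.

## Worked example

The canonical single-species check (`examples/01_worked_example.py`):
a bee balm holding 0.117 of a plot's relative cover and flowering
June–August contributes exactly 0.117 to those months' FP and nothing
to May:

```
month  total FP   (Monarda's share)
    5     0.883   (0.000)
    6     0.117   (0.117)
    7     0.117   (0.117)
    8     0.117   (0.117)
```

End to end (`examples/03_mixed_model_contrasts.py`): simulate a
6-site factorial experiment with the default injected nitrogen effect
(early-flowering exotics ×1.8 and C3 graminoids ×1.6, late-flowering
C4 graminoids ×0.6, tallgrass stratum), fit the mixed model, and test
nitrogen by month:

```
                           term  ndf  ddf         F          p
                      N * Month    5  432     107.1  2.358e-73
          N * Month * Ecoregion   10  432     102.2 3.264e-107

tallgrass N_added - N_free contrasts (% cover), Bonferroni m=18:
ecoregion  month  estimate       SE    p_raw    p_adj  m stars
tallgrass      5      15.3     0.85 2.46e-54 4.43e-53 18   ***
tallgrass      6      16.2     0.85 3.11e-59 5.61e-58 18   ***
tallgrass      7      9.57     0.85  5.8e-26 1.04e-24 18   ***
tallgrass      8    -0.202     0.85    0.812        1 18
tallgrass      9     -16.4     0.85 1.88e-60 3.38e-59 18   ***
tallgrass     10     -16.4     0.85 4.62e-60 8.31e-59 18   ***
```

The significant N × Month (and three-way) terms say nitrogen shifts
the flowering profile; the starred contrasts locate the shift —
FP up ~15 percentage points in May–June, down in September–October,
exactly the injected spring-ward shift. Each `examples/` script is a
short narrative of one capability (profiles, volumes, contrasts).

## Command line

A thin CLI wraps the same pipeline functions:

```sh
prairiefp simulate --out run/ --seed 3            # cover.csv, traits.csv, truth.json
prairiefp analyze  --config config.yaml           # fp_long, anova_*, contrasts_*, volume, summary
prairiefp all      --preset paper-scale --out run/
```

Subcommands: `simulate`, `fp`, `volume`, `analyze`, `all`; options
`--config PATH`, `--out DIR`, `--seed INT`, `--preset
{default,paper-scale}` (the paper-scale preset generates the 11-site
6/2/3 ecoregion layout).

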