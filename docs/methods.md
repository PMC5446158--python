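# Methods

## The flowering-potential statistic

Grassland cover surveys score each species once per season, at peak
biomass, yet species flower at different times. The flowering
potential (FP) statistic redistributes that single snapshot across the
calendar: for plot *i* and month *m*,

    FP_im = Σ_s  r_is · w_sm ,      w_sm = 1 if month m lies in species
                                    s's published flowering interval,
                                    else 0,

where `r_is` is the relative cover of species *s* in plot *i*
(absolute percent cover divided by the plot total; totals can exceed
100% because canopies overlap, so relative cover is the meaningful
share). FP is therefore the fraction of the analyzable canopy expected
to be in flower in a given month, bounded by [0, 1] and reported on
the percent scale.

Subset profiles (exotic, native; C3 graminoid, C4 graminoid, forb,
legume) zero the weight outside the subset but keep the *same*
relative covers — nothing is re-normalized within a subset. This makes
the provenance profiles an exact partition of the total profile
(exotic + native = total whenever provenance is known) and lets
functional-group profiles sum to the total on fully classified
herbaceous communities. A re-normalized variant would instead measure
phenology *within* the subset and would not add up; it is deliberately
not offered.

Exclusion rules are applied before relativization: taxa identified
only to genus, tree seedlings, and taxa without a trait record are
dropped first, so relative covers sum to one over the community that
is actually analyzed. Whether to relativize before or after exclusion
is genuinely open; this order was chosen because it keeps the
composition closed and every FP identity exact.

## Trait catalog

Each species carries: a flowering-month set parsed from flora-style
interval strings (lists, inclusive ranges, wrap-around ranges like
Nov–Feb), a provenance label (native/exotic/unknown), a functional
group with the C3/C4 pathway pre-assigned for graminoids (pathway is
an input column from published classifications, never inferred), and a
lifeform flag. Genus-only placeholders and tree seedlings stay in the
catalog but are marked non-includable so the exclusion rule lives in
one place. Species present in the cover data but absent from every
consulted flora are excluded with a logged warning; "unknown"
provenance species count in total FP but in neither provenance subset.

## Flowering volume

Per plot, the volume is the trapezoidal area under the FP-versus-month
curve, months 1–12 on the percent scale, unit spacing on the month
index, no extrapolation past January or December. A constant-100%
profile bounds it at 1100 %-months. Month lengths are treated as
equal; a day-count x-axis was considered and rejected as spurious
precision given monthly-resolution floras.

## Statistical models

FP (growing season, May–October) is modeled with a linear mixed model:

    fp_pct ~ P * K * N * Month * Ecoregion   (all factorial interactions)
    random intercepts: site, block nested within site

fitted by REML (statsmodels `MixedLM`, Powell optimizer first — it
handles variance components on the zero boundary best — falling back
to L-BFGS and the default optimizer, with the best-likelihood
non-converged fit used only if all three stall). Flowering volume uses
the same structure without the month factor.

F tests are marginal (each term adjusted for all others) under
sum-to-zero coding; on a complete balanced factorial these coincide
with sequential tests, and the table is verified against an
independent R `nlme` REML fit in the test suite (agreement to ~1e-6 on
every term of a balanced design). Denominator degrees of freedom use a
containment-style approximation: the ecoregion main effect — a purely
between-site comparison — is tested at the site stratum
(n_sites − n_ecoregions); every other term at the residual stratum
(n_obs − fixed-effect rank). Kenward–Roger/Satterthwaite adjustments
are out of scope.

Months within a plot are treated as independent residuals (no
plot-level random effect across months). This mirrors the residual
degrees of freedom structure of the original analysis tradition for
this design and is a known pseudo-replication caveat: the six monthly
FP values of one plot derive from one survey and one trait table, so
the residual df are optimistic.

Nitrogen contrasts are model-based N_added − N_free mean differences
averaged over the P and K levels, per month (pooled over ecoregions,
family m = 6) or per ecoregion × month (m = 18). Raw p-values use the
residual-stratum t distribution; Bonferroni adjustment is
min(1, m·p) with the family defined as the set of contrasts produced
by one call — never pooled across response subsets. Stars: *** <0.001,
** <0.01, * <0.05 on adjusted p. On balanced data the contrast
estimates equal raw group-mean differences (asserted to 1e-6 in
tests).

## Synthetic data generator

The generator emulates a distributed factorial nutrient-addition
experiment: three prairie ecoregions, a configurable number of sites
each (default 3/2/3 tall/mixed/short; the `paper_scale` preset uses
6/2/3 = 11 sites), 3 blocks per site, and all 8 N×P×K(+μ)
combinations in every block.

Species pools (default 40 per ecoregion, plus 3 genus-only
placeholders to exercise exclusions):

- **Flowering windows.** Cool-season C3 graminoids and exotics start
  April–May with 2–4 month windows (Poa/Bromus-type phenology);
  warm-season C4 graminoids start August–September with 3–4 month
  windows (Andropogon/Sorghastrum-type); other groups start May–August
  with 1–4 month windows. These choices anchor the boosted class in
  May–June flowering and the suppressed class in September–October
  flowering, the temporal structure the injected effect targets.
- **Abundances.** Baseline weights are log-normal with sigma 0.8 — a
  long-tailed but moderately even rank-abundance curve typical of
  grassland plots.
- **Labels.** Exotic fraction 0.3; functional-group mix 40% forb, 20%
  C3 graminoid, 20% C4 graminoid, 10% legume, 5% woody, 5% other.

Treatment effects are multiplicative on *expected absolute cover*:
under added N (in the configured effect stratum, default tallgrass
only), early-flowering exotics ×1.8, early-flowering C3 graminoids
×1.6, late-flowering C4 graminoids ×0.6. Because relativization
happens downstream, the compositional trade-off — boosted groups
displacing everything else in relative cover — emerges rather than
being hard-coded. Observation noise is log-normal per species per plot
(sigma 0.25, roughly the repeat-survey CV of percent-cover estimates);
plot totals are scaled into an 80–160% band so the over-100%
relativization path is always exercised. Every pool species occurs in
every plot of its ecoregion, which keeps the analytic ground truth
exact: the expected N-effect on FP by ecoregion and month
(`SyntheticTruth`) is computed from the baseline weights and
multipliers and is the exact noise-free limit of the empirical group
difference (a convergence test asserts this at sigma = 1e-3).

What the generator does **not** emulate: species presence/absence
turnover between plots, spatial autocorrelation, climate covariates,
multi-year dynamics, observer rounding to whole percent, and
zero-inflation of rare species. Passing recovery tests therefore show
the pipeline detects compositional phenology shifts of the injected
kind under idealized sampling, not that any field dataset has such
shifts.

## Problem sizes and calibration checks

The simulation suites use a reduced design — 1 site per ecoregion, 2
blocks, i.e. 48 plots and 288 growing-season observations per
replicate — which keeps one generate-fit-contrast replicate near 0.25 s
and makes large replicate counts routine:

- **Null calibration:** 500 replicates with all multipliers at 1; the
  family-wise rate of any significant pooled Bonferroni N contrast
  must stay within the two-standard-error binomial envelope of the
  nominal 5%.
- **Effect recovery:** 200 replicates with the default multipliers;
  ≥80% must yield adjusted-significant, correctly signed May, June,
  September, and October tallgrass contrasts, with off-target
  (mixed/short-grass) detections at the nominal false-positive level.
  Observed rates in development runs were ~95% recovery with no
  off-target excess.

## Numerical and degenerate-input choices

- Relative covers validated to sum to 1 within 1e-9; FP cells clamped
  by validation, not by arithmetic (violations raise).
- Singular fixed-effect designs (rank-deficient factorial) and
  zero-variance responses raise `FitError` with diagnostics instead of
  silently dropping terms.
- A single-site-per-ecoregion design leaves the site stratum with 0
  df; the Ecoregion F is still reported but its p-value is NaN.
- Ties/order: months are integer-indexed 1–12 everywhere; output rows
  are sorted by plot key and month, making repeated runs byte-identical.
- All generator randomness flows from one `numpy` `default_rng(seed)`
  stream in a fixed iteration order.

## Known limitations

- Monthly resolution only; floras rarely support finer phenology.
- The 0/1 flowering weight ignores flowering intensity within the
  window.
- Containment ddf are approximate; exact ddf depend on data dimensions
  and are not reproduced.
- The FP mixed model treats a plot's monthly values as independent
  (see above); a plot-level random effect would be the conservative
  alternative.
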