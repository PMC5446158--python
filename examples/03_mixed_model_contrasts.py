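"""Fit the FP mixed model and test nitrogen effects month by month.

Simulates an experiment with the default injected nitrogen effect in
the tallgrass stratum, fits the linear mixed model (P x K x N x Month x
Ecoregion fixed effects; site and block-within-site random intercepts),
prints the fixed-effect F table rows that involve nitrogen, and the
Bonferroni-corrected N_added - N_free contrasts by ecoregion and month.
"""

from prairiefp import SyntheticConfig, anova_table, apply_exclusions, fit_fp_lmm, \
    fp_matrix, generate, n_by_month_contrasts, relativize_all

config = SyntheticConfig(
    seed=7,
    n_sites_per_ecoregion={"tallgrass": 2, "mixedgrass": 2, "shortgrass": 2},
    n_blocks=2,
)
dataset = generate(config)
included, _ = apply_exclusions(dataset.cover, dataset.catalog)
matrix = fp_matrix(relativize_all(included), dataset.catalog)

handle = fit_fp_lmm(matrix.to_long())
table = anova_table(handle)
n_terms = table[table["term"].str.contains("N")]
print("nitrogen-involving fixed-effect tests:")
print(n_terms.to_string(index=False, float_format=lambda x: f"{x:9.4g}"))

contrasts = n_by_month_contrasts(handle, by_ecoregion=True)
tall = contrasts[contrasts["ecoregion"] == "tallgrass"]
print("\ntallgrass N_added - N_free contrasts (% cover), Bonferroni m=18:")
print(tall.to_string(index=False, float_format=lambda x: f"{x:8.3g}"))

# A significant N * Month (and N * Month * Ecoregion) term says nitrogen
# shifts the flowering profile across the season; the starred contrasts
# locate the shift: positive in May-June, negative in September-October,
# in the tallgrass stratum where the effect was injected.
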