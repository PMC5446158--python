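"""Flowering volume: area under each plot's 12-month FP curve.

Computes per-plot flowering volumes (trapezoidal area under FP versus
month, January-December, percent scale) for a simulated experiment and
fits the volume mixed model (P x K x N x Ecoregion fixed effects, same
random structure, no month term) to ask whether nutrients change the
total seasonal flowering window rather than just shifting it.
"""

from prairiefp import SyntheticConfig, apply_exclusions, fit_volume_lmm, fp_matrix, \
    generate, plot_volumes, relativize_all

config = SyntheticConfig(seed=11)  # default scale: 8 sites, 192 plots
dataset = generate(config)
included, _ = apply_exclusions(dataset.cover, dataset.catalog)
matrix = fp_matrix(relativize_all(included), dataset.catalog)

volumes = plot_volumes(matrix)
mean = volumes["volume_pct_month"].mean()
se = volumes["volume_pct_month"].sem()
print(f"flowering volume over {len(volumes)} plots: "
      f"{mean:.1f} +/- {se:.1f} %-cover x months (mean +/- SE)")

handle, table = fit_volume_lmm(volumes)
print("\nvolume model fixed-effect tests:")
print(table.to_string(index=False, float_format=lambda x: f"{x:9.4g}"))

# The injected nitrogen effect shifts cover between early- and
# late-flowering species but conserves total cover, so the volume model's
# nutrient terms should generally stay non-significant: the flowering
# window moves, it does not shrink or grow.
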