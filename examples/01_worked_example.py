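"""Flowering potential of a single plot, species by species.

Builds a tiny two-species plot by hand and shows how each species'
relative cover is allocated to the months of its published flowering
window: a bee balm covering 11.7% of the plot's relative canopy that
flowers June-August adds exactly 0.117 to the June, July, and August
flowering potential (FP) and nothing to May.
"""

from prairiefp import PlotComposition, SpeciesTrait, TraitCatalog, monthly_fp

catalog = TraitCatalog(
    [
        SpeciesTrait(taxon="Monarda fistulosa",
                     flowering_months=frozenset({6, 7, 8}),
                     provenance="native", functional_group="forb",
                     source="regional flora"),
        SpeciesTrait(taxon="Companion vernalis",
                     flowering_months=frozenset({5}),
                     provenance="native", functional_group="forb",
                     source="regional flora"),
    ]
)

plot = PlotComposition(
    site="chic", ecoregion="tallgrass", block="1", plot="61",
    trt_N=False, trt_P=False, trt_K=False,
    rel_cover={"Monarda fistulosa": 0.117, "Companion vernalis": 0.883},
)

print("month  total FP   (Monarda's share)")
for month in (5, 6, 7, 8):
    fp = monthly_fp(plot, catalog, month)
    monarda = 0.117 if month in (6, 7, 8) else 0.0
    print(f"{month:>5}  {fp:8.3f}   ({monarda:.3f})")

# May FP is entirely the spring companion (0.883); June through August FP
# is entirely Monarda (0.117): each species' relative cover appears only
# in the months its flora says it flowers.
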