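"""Secretory annotation, the three-way comparison screen and enrichment.

DEGs from three contrasts (obese vs lean in FAPs-high regions, FAPs-high
vs FAPs-low regions, obese vs lean in FAPs nuclei) are flagged secreted
by location lookup and intersected into common/unique partitions; the
up-regulated region DEGs are then tested for gene-set over-representation
with the hypergeometric upper tail and BH correction.
"""

from spatniche.secretome_enrich import hypergeom_enrich, screen_comparisons

# The two six-gene breed-direction lists of known muscle secretory proteins,
# screened as (region contrast) x (breed contrast):
up_obese = {"SPARC", "CST3", "COL15A1", "CFD", "GPX3", "COL4A2"}
up_lean = {"GSN", "ANXA2", "FN1", "COL14A1", "MGP", "COL1A2"}
screen = screen_comparisons(
    {
        "faps_high_vs_low": {"up": up_obese | up_lean, "down": set()},
        "obese_vs_lean_faps": {"up": up_obese, "down": up_lean},
    }
)
print(f"common secretory genes across both contrasts: {len(screen.common)}")
print(f"  up in obese: {sorted(screen.comparisons['obese_vs_lean_faps']['up'])}")
print(f"  up in lean:  {sorted(screen.comparisons['obese_vs_lean_faps']['down'])}")

# Enrichment of a query against sets drawn from a 2,000-gene universe:
universe = [f"G{i:05d}" for i in range(2000)] + sorted(up_obese | up_lean)
sets = {
    "extracellular_region": sorted(up_obese | up_lean) + [f"G{i:05d}" for i in range(50)],
    "random_decoy": [f"G{i:05d}" for i in range(100, 160)],
}
records = hypergeom_enrich(sorted(up_obese | up_lean), universe, sets)
for r in records:
    print(
        f"{r.set_name}: overlap {r.overlap}/{r.set_size}, rich factor "
        f"{r.rich_factor:.3f}, p={r.p_value:.2e}, q={r.q_value:.2e}, "
        f"significant={r.significant}"
    )
# The extracellular set should be strongly enriched (all 12 screened genes are
# members); the decoy should not.
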