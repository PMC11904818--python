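"""Generate a synthetic two-breed muscle study and inspect its ground truth.

The study bundles a labelled single-nucleus reference (8 cell
populations, NB counts), one Visium-like section per breed whose spots
mix the cell-type signatures with spatially smooth proportions, a
UniProt-style subcellular-location table and a GMT gene-set collection.
"""

from spatniche.synthdata import StudySpec, simulate_study

study = simulate_study(StudySpec(seed=0))

print(f"reference: {study.reference.n_obs} nuclei x {study.reference.n_genes} genes")
print("cell types:", ", ".join(sorted(set(study.labels))))
for sid, (m, geom, truth) in study.spatial.items():
    fap = truth.proportions["FAPs"]
    print(
        f"sample {sid}: {m.n_obs} spots, median library "
        f"{int(m.library_sizes().mean())}, true FAPs proportion "
        f"{fap.mean():.3f} (range {fap.min():.3f}-{fap.max():.3f})"
    )
print("planted region-level correlations:", study.truth.rho)
n_secreted = sum(any("Secreted" in s for s in l) for l in study.locations.values())
print(f"location table: {n_secreted}/{len(study.locations)} genes annotated secreted")
# The planted rho values are what the random-region correlation stage is
# expected to recover; the proportions are what deconvolution is scored against.
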