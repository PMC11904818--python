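# spatniche

Integrated single-nucleus + spatial-transcriptome analysis of skeletal muscle,
built around the question of how stromal cells shape the metabolic
microenvironment of myofibers. Fibro/adipogenic progenitors (FAPs) are the
interstitial stromal population (PDGFRA+, COL1A1+, DCN+) that secretes much of
the muscle extracellular milieu; `spatniche` provides the full analysis chain
for linking FAPs-derived secretory proteins to myofiber-type and metabolic gene
expression in space:

1. **QC & normalization** — nucleus filters (detected genes > 500,
   mitochondrial fraction < 25%, genes detected in ≥ 1 kept nucleus), log2-CPM
   normalization, pseudo-bulk aggregation.
2. **Markers & DE** — one-vs-rest Wilcoxon rank-sum marker detection (expressed
   in > 10% of a cluster, |log2FC| > 0.26; exact permutation enumeration for
   groups ≤ 8), and two-group DE by a negative-binomial Wald test with
   method-of-moments dispersion (p < 0.05, |log2FC| > 0.26).
3. **Secretome screening** — secreted-protein annotation by subcellular-location
   lookup, multi-comparison screening of signed DEG sets, hypergeometric
   gene-set enrichment (`P(X ≥ k)`, BH-corrected, rich factor `k/K`).
4. **Deconvolution & regions** — per-spot cell-type proportions by non-negative
   least squares against marker-restricted mean-CPM signatures; FAPs-high /
   FAPs-low region delineation at quartile thresholds; region-contrast DE.
5. **Random-region correlation** — the core procedure: sample many equal-area
   regions (a seed spot plus its 24 nearest in-tissue neighbours, 200 regions
   per sample), build region pseudo-bulk log2-CPM profiles, and correlate
   secretory genes against myofiber-type / metabolism genes across regions
   with Pearson's r, flagging |r| > 0.4 with p < 0.05 (standard tier) and
   |r| > 0.5 with p < 0.001 (strict tier).

A first-class synthetic-data generator (`spatniche.synthdata`) emulates the
study design — a two-breed (obese vs lean) pig study with an 8-population
single-nucleus reference and one Visium-like section per breed — with known
ground-truth signatures, spot proportions and *planted* secretory↔target gene
correlations, so every stage is testable end-to-end without any download.

## Worked example

```python
from spatniche.synthdata import StudySpec, simulate_study
from spatniche.niche_correlation import (
    CorrelationParams, RegionProfiles, correlate_gene_sets, sample_regions,
)

study = simulate_study(StudySpec(seed=0))     # 4,000 nuclei; 3,969 + 1,806 spots
params = CorrelationParams(seed=0)            # 200 regions/sample, 25 spots each
parts = [
    sample_regions(geom, counts, params, sample_id=sid, seed=100 + k)
    for k, (sid, (counts, geom, _)) in enumerate(sorted(study.spatial.items()))
]
profiles = RegionProfiles.concat(parts)
records = correlate_gene_sets(
    profiles, ["SPARC", "CST3", "GSN"], ["IRS1", "SLC38A2", "GLUL"], params,
    sample_conditions=study.sample_conditions,
)
```

Printing the top pairs (see `examples/05_region_correlation.py`) gives:

```
planted truth: {('SPARC', 'IRS1'): 0.7, ('CST3', 'SLC38A2'): 0.5, ('GSN', 'GLUL'): 0.4}
SPARC ~ IRS1: r=0.512 (p=3.9e-28, standard tier=True) per breed [Duroc: 0.74, TB: 0.73]
CST3 ~ SLC38A2: r=0.476 (p=4.9e-24, standard tier=True) per breed [Duroc: 0.60, TB: 0.55]
GSN ~ GLUL: r=0.335 (p=6.4e-12, standard tier=False) per breed [Duroc: 0.44, TB: 0.32]
```

The per-breed estimates recover the planted correlations; the pooled SPARC~IRS1
value sits below them because SPARC also differs between breeds, which dilutes
a correlation computed across both sections — exactly why the module reports
stratified r alongside the pooled value.

The other `examples/` scripts each demonstrate one capability (simulation, QC +
markers, deconvolution + regions, the secretome screen, the full pipeline); all
run in seconds from the repository root.

## Command line

The pipeline is also runnable as a tool:

```bash
spatniche run --config config.yaml          # full analysis, deterministic
spatniche simulate --out fixtures --seed 0  # write a synthetic study
spatniche qc|markers|deconv|nichecorr ...   # individual stages
```

`spatniche run` writes per-stage outputs (QC report, marker/DE tables,
proportions, region labels, screen, enrichment, correlations) plus a
machine-readable `manifest.json`; a rerun with the same config and seed
reproduces every file byte-for-byte.

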