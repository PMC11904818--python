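# Methods

This note documents the models, numerical choices and limitations behind
`spatniche`. Notation: a study has a single-nucleus reference (nuclei × genes
UMI counts with cell-type labels) and one or more Visium-style spatial samples
(spots × genes counts on a hex grid), one per condition (e.g. an obese and a
lean pig breed).

## Quality control and normalization

Nucleus QC applies, in order: keep nuclei with detected-gene count strictly
greater than `min_genes_per_nucleus` (default 500); keep nuclei with
mitochondrial fraction strictly below `max_mito_fraction` (default 0.25,
computed over genes whose *name* starts with `MT-`); then keep genes detected
in at least `min_cells_per_gene` (default 1) of the **kept** nuclei. Both
per-nucleus bounds are read as strict inequalities ("over 500", "< 25%") and
are configurable. The gene rule is stated ambiguously in common usage
("expressed in less than one cell"); it is implemented as detection in ≥ 1 kept
nucleus, threshold configurable. Spot matrices skip the mitochondrial filter by
default (a spot pools many cells; no spot-level mitochondrial threshold is
standard) and drop out-of-tissue spots via the geometry table. An optional
maximum-counts cap (default off) stands in for doublet removal, which is out of
scope.

Normalization is log2 counts-per-million with pseudocount 1:
`log2(count / libsize * 1e6 + 1)`. A variance-stabilizing regression
(SCTransform-style) is deliberately not re-implemented; log-CPM is used
uniformly for nuclei, spots and region pseudo-bulk, which keeps every
downstream quantity interpretable on one scale. This is a documented deviation
from pipelines that normalize spatial data with regularized NB regression.

## Marker detection and differential expression

Markers are one-vs-rest per cluster. A gene is a candidate when detected
(count > 0) in more than `min_expr_fraction` (default 0.10) of the cluster's
cells and |log2FC| > `min_abs_log2fc` (default 0.26), where the fold change is
computed on de-logged (CPM-scale) group means with pseudocount 1 — the
FindAllMarkers-style convention. Candidates are tested with the two-sided
Wilcoxon rank-sum test:

- **Exact path** (both groups ≤ 8): the p-value is the permutation tail
  `P(|W − μ| ≥ |W_obs − μ|)` over all `C(n1+n2, n1)` assignments, with midranks
  for ties and `μ = n1(N+1)/2`. This definition is symmetric and exact under
  ties, and is what the test suite checks against independent enumeration to
  1e-12.
- **Normal approximation** (larger groups): `z = (W − μ)/σ` with the
  tie-corrected variance `σ² = n1·n2/12·[(N+1) − Σ(t³−t)/(N(N−1))]` and no
  continuity correction (matching the common single-cell implementations, which
  the suite cross-checks against).

Two-group DE on counts uses a negative-binomial Wald test: counts are
library-size scaled to the mean library, the NB dispersion α is estimated by
pooled method-of-moments
`α = max(0, Σ_i (n_i−1)(s_i² − m_i) / Σ_i (n_i−1) m_i²)`, and the statistic is
`t = ln((m1+c)/(m2+c)) / SE` with `SE² = v1/(n1(m1+c)²) + v2/(n2(m2+c)²)`,
`v_i = m_i + α m_i²` (floored at c for all-zero groups) and offset `c = 0.5`.
The reference distribution is Student's t with `n1+n2−2` degrees of freedom: a
pilot of the null (NB mean 5, dispersion 2, 50 vs 50) showed the plain normal
reference mildly anti-conservative at this sample size, and the t reference
brings the type-I rate to the nominal 5% (the acceptance suite asserts
0.05 ± 0.01 and ≥ 90% power for 2-fold changes at the stated thresholds). This
is a stand-in for shrinkage-based NB frameworks, which are cited by the field
but not part of this package's scope; the Wilcoxon path is used for
expression-level contrasts (spot regions), where the unit of replication is
the spot. Genes with zero counts in both groups are flagged untestable
(p = 1, log2FC = 0). Benjamini–Hochberg q-values are always reported; the pass
flag uses the raw p together with the fold-change threshold, matching the
printed filtering convention.

## Secretome annotation, screening, enrichment

A gene is *secreted* when any of its subcellular-location strings contains a
secreted keyword (case-insensitive substring; default `{"Secreted"}`). The
location table is a file input (UniProt-style strings); annotation is an
identifier lookup, not a sequence search, so results do not depend on a
database version. Genes absent from the table are flagged distinctly rather
than silently treated as non-secreted.

The comparison screen takes ≥ 2 named signed DEG sets, validates that no gene
is both up and down within one comparison, and reports the common set (present
in all comparisons), its direction-consistent subset, per-comparison unique
sets, and counts. When records pooled over several samples are screened, genes
whose direction conflicts between samples are dropped as non-robust before the
intersection.

Enrichment is the hypergeometric upper tail `p = P(X ≥ k)` for
`X ~ Hypergeom(N, K, n)` (identical to R's `phyper(k−1, …, lower.tail=FALSE)`),
with gene sets intersected with the universe first, BH correction across tested
sets, significance at q < 0.05, and `rich factor = k/K`. The default universe
is the set of genes surviving QC in the contrasted dataset; whether to use the
whole annotation instead is exposed as an argument, since either convention is
defensible.

## Deconvolution and region delineation

Cell-type signatures are mean per-nucleus CPM over labelled nuclei, restricted
to the union of the top-k markers per type (k = 25 by default, ranked by
p then |log2FC|). Each spot's full-library CPM profile, restricted to the same
genes, is fitted by non-negative least squares against the signature rows; the
coefficients are normalized to sum to one and the relative residual norm is
stored. All-zero spots get uniform proportions and a flag. NNLS against mean
signatures is the simplest faithful stand-in for topic-model deconvolution:
only the per-spot proportion output drives the downstream analysis, and the
module equally accepts an externally produced proportion table.

FAPs-high/low regions are per-spot labels from empirical quantile thresholds
of the target-type proportion over in-tissue spots (defaults: upper and lower
quartiles). The threshold is the order statistic at `floor(q·(n−1))` (lower
interpolation); ties at a threshold go to the extreme class, with *high*
taking precedence, so `high_quantile = 0` labels every spot high. The
delineation is invariant to monotone rescaling of the proportion column. No
threshold for "high" exists in the field; the quartile default is a package
choice and the suite exercises sensitivity to it.

## Random-region correlation

A region is a seed spot plus its `region_size − 1` nearest in-tissue
neighbours by Euclidean pixel distance (ties broken by lexicographic barcode),
so every region has exactly 25 spots by default — the "equal area" reading of
region sampling on a hex grid that tolerates tissue-edge irregularity. Seed
spots are drawn uniformly without replacement (with replacement, flagged, only
if more regions than spots are requested); regions may overlap, which is
unavoidable at 200 regions × 25 spots on a ~1,800-spot section. Region
profiles are log2-CPM of summed member counts.

For every (secretory candidate, target) pair, Pearson's r is computed across
region profiles, p from the t transform `t = r·sqrt((n−2)/(1−r²))` with
`n` = number of regions, BH q across pairs. Tier flags follow the study
thresholds — standard: |r| > 0.4 and p < 0.05; strict: |r| > 0.5 and
p < 0.001 — on the raw p (q is reported, not used for the flags). Pairs with a
zero-variance gene are flagged undefined, never given a fabricated r. When
sample metadata distinguishes conditions, per-condition r is reported next to
the pooled value; pooled r is attenuated for genes with a between-condition
mean shift, which is why both are emitted. No spatial-autocorrelation
correction of the degrees of freedom is attempted (overlapping regions make
the nominal p anti-conservative for inference across regions of one section;
the tier thresholds are used as printed).

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions for
every recovery test.

**Reference.** `n_celltypes` populations (default 8, named for the canonical
muscle populations: MuSCs, myoblasts, slow/fast myonuclei, FAPs, pericytes,
endothelial, myeloid) × `n_nuclei_per_type` (default 250) nuclei over `n_genes`
(default 2,000) genes. Counts are negative binomial (dispersion `size = 2`);
marker gene g of type t has mean `baseline_mean · 2^marker_log2fc`
(defaults 0.5 and 2.0) in t and baseline elsewhere; marker blocks are disjoint;
13 mitochondrial genes (`MT-` names) sit at 5× baseline. A small share of
nuclei emulate failed capture (4% with means × 0.3) or stressed nuclei (4%
with mitochondrial means × ~15), so QC removes ~7–9% of nuclei, mirroring
realistic single-nucleus bookkeeping. Condition (breed) effects are global
per-gene log2 shifts applied to one condition's reference and signatures; the
defaults place effects on secreted FAPs markers and a few background secretory
genes so the three-way screen has a non-empty, direction-structured core.

**Spatial samples.** A 10x-dialect hex grid (row r holds array columns
`2c + r mod 2`; pixel coordinates are an affine map with 100 px pitch). The
default two samples are 63×63 (obese-like, 15,000 reads/spot) and 43×42
(lean-like, 20,000 reads/spot) — the ~2× spot-count and ~1.5× depth asymmetry
of a real two-section comparison at desk scale. Per-spot proportions are a
Dirichlet-ized exponentiated Gaussian blur of white noise per cell type
(blur σ = 2.5 grid units, amplitude 1): positive, summing to one, spatially
autocorrelated. Amplitude 0 gives the degenerate constant field. The slow/fast
myonuclei fields are constructed anti-correlated (shared field with opposite
sign, mixing 0.9) so the two myofiber-type marker gradients run against each
other. Spot expression means are the proportion-weighted mixture of
row-normalized signatures scaled to `reads_per_spot`; counts are Poisson
(spots pool many cells, so the cell-level NB overdispersion is largely
averaged out; this is the standard capture model and keeps count noise at the
region scale small relative to the planted biology).

**Planted correlations.** Each planted pair (a, b, ρ) receives multiplicative
lognormal factors `exp(s·g − s²/2)` on the two genes' spot means, with latent
Gaussian fields g sharing a common component. Two calibrations make the
region-level Pearson target exact rather than approximate: (1) the Gaussian
mixing correlation is set to `ρ' = log(1 + ρ(e^{s²} − 1))/s²`, which makes the
per-spot correlation of the lognormal factors exactly ρ (undoing the lognormal
distortion analytically); (2) the three latent fields are Gram–Schmidt
orthogonalized across spots, so the realized field correlation equals the
target in every dataset, not just in expectation. Planted genes' base means are
boosted 4× (well-expressed secreted genes) so Poisson noise attenuates the
region-level r by < 3%. Negative ρ is bounded below by the bivariate-lognormal
floor `−e^{−s²}`; the per-pair amplitude is shrunk automatically to keep the
target reachable. The amplitude (s = 0.5) and latent smoothness (σ = 2) were
fixed by a design-stage pilot to keep the exp-nonlinearity bias of the
region-level estimate under ~0.02 and the seed-to-seed spread of the null
(ρ = 0) estimate near 0.06; with these defaults the pooled 400-region estimate
recovers ρ ∈ {0, 0.4, 0.7} within ±0.15 in ≥ 95% of 50 generation seeds, which
the acceptance suite asserts.

**What the generator does not emulate:** batch effects, doublets, ambient RNA,
segmentation/histology structure, UMI-level read noise, spatially varying
capture efficiency, and gene–gene correlation beyond the planted pairs and the
compositional structure. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative model, not
robustness to real-data artifacts.

## Problem sizes and determinism

Desk-scale defaults (4,000 nuclei, 2,000 genes, 3,969 + 1,806 spots) keep a
full pipeline run under ~20 s and the entire test suite a few minutes while
preserving the study's structure (two conditions, asymmetric sections,
200 regions per sample, 25-spot regions). All randomness flows from
`numpy.random.default_rng` seeds; the pipeline derives per-stage seeds from
one global seed by stage-name hashing (CRC32), so stages are independently
reproducible and a rerun with the same config produces byte-identical outputs
(writers emit sorted rows, fixed column orders and no timestamps).

## Known limitations

- Log-CPM in place of variance-stabilizing normalization slightly
  overweights highly expressed genes in signatures and profiles.
- NNLS deconvolution assumes spot profiles are convex mixtures of mean
  signatures; strong within-type expression gradients would bias it.
- The region-correlation p-values ignore region overlap (effective sample
  size < n); the tier flags are threshold conventions, not calibrated tests.
- The NB Wald test with MoM dispersion is anti-conservative for very low
  counts (< ~1 per group mean); the offset mitigates but does not remove this.
- `screen_comparisons` treats DEG sets as given; it does not model the
  correlation between the contrasts that produced them.
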