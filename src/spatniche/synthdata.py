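"""Synthetic snRNA-seq references and Visium-like spatial datasets with known truth.

The generator emulates the structure of a two-breed pig skeletal-muscle
study: a single-nucleus reference with a configurable number of cell
populations (default 8: muscle stem cells, myoblasts, slow/fast
myonuclei, FAPs, pericytes, endothelial and myeloid cells) carrying
disjoint marker-gene blocks, and hex-grid spatial samples whose spots
are mixtures of the cell-type signatures with spatially autocorrelated
proportions.  Ground truth (signatures, per-spot proportions, planted
correlations) is returned alongside every dataset so recovery can be
asserted exactly.

Planted gene-pair correlations
------------------------------
Each planted pair (secretory gene a, target gene b, rho) receives
multiplicative lognormal factors ``exp(s*g - s^2/2)`` driven by latent
Gaussian fields sharing a common component.  Because the correlation of
two lognormals is a distorted image of their Gaussian correlation, the
Gaussian mixing weight is calibrated analytically:

    rho_gauss = log(1 + rho * (e^{s^2} - 1)) / s^2

which makes the per-spot factor correlation exactly ``rho``; summation
over region spots then preserves it (CLT), up to a small count-noise
attenuation.  The latent fields are empirically orthogonalized
(Gram-Schmidt across spots) so the realized field correlation equals the
target exactly in every dataset, not just in expectation.  Negative rho
is bounded below by the lognormal floor ``-e^{-s^2}``; the per-pair
amplitude is shrunk automatically when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .types import CountMatrix, SpotGeometry

__all__ = [
    "ReferenceSpec",
    "SpatialSpec",
    "GroundTruth",
    "simulate_reference",
    "simulate_visium",
    "simulate_location_table",
    "simulate_gene_sets",
    "StudySpec",
    "SimulatedStudy",
    "simulate_study",
    "DEFAULT_CELLTYPES",
    "DEFAULT_MARKER_NAMES",
]

DEFAULT_CELLTYPES = (
    "MuSCs",
    "myoblasts",
    "myofibers_type1",
    "myofibers_type2",
    "FAPs",
    "pericytes",
    "endothelial",
    "myeloid",
)

# canonical markers used to name the first genes of each population's block
DEFAULT_MARKER_NAMES = {
    "MuSCs": ["PAX7"],
    "myoblasts": ["MYOD1", "MYOG"],
    "myofibers_type1": ["MYH7"],
    "myofibers_type2": ["MYH1", "MYH4"],
    "FAPs": ["PDGFRA", "COL1A1", "DCN", "COL14A1", "FN1", "MGP", "COL4A2", "COL15A1"],
    "pericytes": ["RGS5", "ACTA2"],
    "endothelial": ["PECAM1", "TEK"],
    "myeloid": ["MRC1", "CSF1R"],
}

# background genes that get stable symbols so planted pairs, location tables
# and examples can refer to them by name
NAMED_BACKGROUND_GENES = (
    "SPARC",
    "CST3",
    "GPX3",
    "CFD",
    "GSN",
    "ANXA2",
    "IGFBP5",
    "IRS1",
    "SLC38A2",
    "GLUL",
    "PLPP1",
    "FOXO1",
    "SORBS1",
    "EGF",
    "IGF2",
)

_MITO_BASE_MULT = 5.0  # mitochondrial genes are expressed above background


@dataclass
class ReferenceSpec:
    """Parameters of the synthetic single-nucleus reference."""

    n_celltypes: int = 8
    n_genes: int = 2000
    n_nuclei_per_type: int = 250
    markers_per_type: int = 25
    marker_log2fc: float = 2.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0  # NB size parameter
    mito_gene_count: int = 13
    seed: int = 0
    celltypes: tuple = ()
    gene_log2fc: dict = field(default_factory=dict)  # gene name -> global log2 shift
    # a small share of nuclei emulate failed capture (shrunken library) or
    # stressed/lysed nuclei (inflated mitochondrial content) so QC has work to do
    low_quality_fraction: float = 0.04
    low_quality_scale: float = 0.3
    high_mito_fraction: float = 0.04
    high_mito_boost: float = 15.0

    def __post_init__(self) -> None:
        for name in ("n_celltypes", "n_genes", "n_nuclei_per_type", "markers_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.mito_gene_count < 0:
            raise ValueError("mito_gene_count must be >= 0")
        if self.markers_per_type * self.n_celltypes > self.n_genes - self.mito_gene_count:
            raise ValueError(
                "infeasible spec: markers_per_type * n_celltypes exceeds available genes"
            )
        if not self.celltypes:
            if self.n_celltypes == len(DEFAULT_CELLTYPES):
                self.celltypes = DEFAULT_CELLTYPES
            else:
                self.celltypes = tuple(f"celltype_{i}" for i in range(self.n_celltypes))
        elif len(self.celltypes) != self.n_celltypes:
            raise ValueError("celltypes length must equal n_celltypes")


@dataclass
class GroundTruth:
    """True signatures, spot proportions and planted correlations."""

    signatures: pd.DataFrame | None = None  # celltype x gene mean matrix
    proportions: pd.DataFrame | None = None  # spot x celltype, rows sum to 1
    rho: dict = field(default_factory=dict)  # (gene_a, gene_b) -> rho

    def __post_init__(self) -> None:
        if self.proportions is not None:
            sums = self.proportions.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("true proportions rows must sum to 1")


def _gene_tables(spec: ReferenceSpec) -> tuple[np.ndarray, dict]:
    """Build the gene-name table and marker-block assignment.

    Layout: mitochondrial genes first (MT- prefix), then one marker block
    per cell type, then background genes.  Canonical symbols are used for
    the leading markers of each default population and for a fixed set of
    named background genes; all other genes get synthetic G names.
    """
    names: list[str] = [f"MT-G{i}" for i in range(spec.mito_gene_count)]
    marker_idx: dict[str, np.ndarray] = {}
    cursor = spec.mito_gene_count
    counter = 0
    for ct in spec.celltypes:
        idx = np.arange(cursor, cursor + spec.markers_per_type)
        marker_idx[ct] = idx
        canonical = DEFAULT_MARKER_NAMES.get(ct, [])
        for j in range(spec.markers_per_type):
            if j < len(canonical):
                names.append(canonical[j])
            else:
                names.append(f"MK-{ct}-{j}")
        cursor += spec.markers_per_type
    n_background = spec.n_genes - cursor
    for j in range(n_background):
        if j < len(NAMED_BACKGROUND_GENES):
            names.append(NAMED_BACKGROUND_GENES[j])
        else:
            names.append(f"G{counter:05d}")
        counter += 1
    return np.array(names, dtype=object), marker_idx


def _mean_matrix(spec: ReferenceSpec) -> tuple[pd.DataFrame, dict]:
    """Expected celltype x gene NB mean matrix implied by the spec."""
    names, marker_idx = _gene_tables(spec)
    means = np.full((spec.n_celltypes, spec.n_genes), spec.baseline_mean)
    means[:, : spec.mito_gene_count] = spec.baseline_mean * _MITO_BASE_MULT
    for t, ct in enumerate(spec.celltypes):
        means[t, marker_idx[ct]] = spec.baseline_mean * 2.0**spec.marker_log2fc
    for gene, lfc in spec.gene_log2fc.items():
        j = np.where(names == gene)[0]
        if len(j) == 0:
            raise ValueError(f"gene_log2fc refers to unknown gene {gene!r}")
        means[:, j[0]] *= 2.0**lfc
    sig = pd.DataFrame(means, index=list(spec.celltypes), columns=list(names))
    return sig, marker_idx


def expected_signatures(spec: ReferenceSpec) -> pd.DataFrame:
    """The celltype x gene NB mean matrix a reference spec implies (no sampling)."""
    sig, _ = _mean_matrix(spec)
    return sig


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_reference(
    spec: ReferenceSpec, sample_prefix: str = "REF"
) -> tuple[CountMatrix, pd.Series, GroundTruth]:
    """Simulate an NB-count single-nucleus reference with cell-type labels.

    Marker gene g of type t has mean ``baseline_mean * 2**marker_log2fc``
    in t and baseline elsewhere; marker blocks of distinct types are
    disjoint.  Identical spec + seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    sig, _ = _mean_matrix(spec)
    means = sig.to_numpy()
    blocks, labels = [], []
    mito = np.arange(spec.mito_gene_count)
    for t, ct in enumerate(spec.celltypes):
        mu = np.tile(means[t], (spec.n_nuclei_per_type, 1))
        u = rng.random(spec.n_nuclei_per_type)
        low_q = u < spec.low_quality_fraction
        high_m = (u >= spec.low_quality_fraction) & (
            u < spec.low_quality_fraction + spec.high_mito_fraction
        )
        mu[low_q] *= spec.low_quality_scale
        if spec.mito_gene_count:
            mu[np.ix_(high_m, mito)] *= spec.high_mito_boost * np.exp(
                0.3 * rng.standard_normal((int(high_m.sum()), 1))
            )
        blocks.append(_nb_sample(rng, mu, spec.dispersion))
        labels.extend([ct] * spec.n_nuclei_per_type)
    counts = np.vstack(blocks)
    n = counts.shape[0]
    barcodes = np.array([f"{sample_prefix}-N{i:06d}" for i in range(n)], dtype=object)
    m = CountMatrix(
        values=sp.csr_matrix(counts),
        obs_ids=barcodes,
        gene_ids=sig.columns.to_numpy(),
        gene_names=sig.columns.to_numpy().copy(),
        obs_kind="nucleus",
        sample_id=sample_prefix,
    )
    label_series = pd.Series(np.array(labels, dtype=object), index=pd.Index(barcodes), name="celltype")
    return m, label_series, GroundTruth(signatures=sig)


# ----------------------------------------------------------------------
# Spatial simulation
# ----------------------------------------------------------------------

HEX_PITCH_PX = 100.0  # center-to-center distance between adjacent spots, pixels


@dataclass
class SpatialSpec:
    """Parameters of one synthetic Visium-like sample."""

    sample_id: str = "S1"
    grid_rows: int = 40
    grid_cols: int = 40
    reads_per_spot: float = 20000.0
    proportion_smoothness: float = 2.5  # gaussian blur sigma, in grid units
    proportion_amplitude: float = 1.0
    fap_celltype: str = "FAPs"
    planted_pairs: tuple = ()  # ((gene_a, gene_b, rho), ...)
    planted_gene_boost: float = 4.0
    latent_amplitude: float = 0.5  # lognormal scale s of planted factors
    latent_smoothness: float = 2.0
    anticorrelated_types: tuple = ("myofibers_type1", "myofibers_type2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 25:
            raise ValueError("grid must hold at least 25 spots")
        for a, b, rho in self.planted_pairs:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"planted rho for ({a}, {b}) must be in [-1, 1]")


def hex_grid_geometry(
    sample_id: str, grid_rows: int, grid_cols: int, in_tissue: np.ndarray | None = None
) -> SpotGeometry:
    """Build a 10x-dialect hex grid: row r holds array columns 2c + (r % 2)."""
    rows, cols = np.meshgrid(np.arange(grid_rows), np.arange(grid_cols), indexing="ij")
    rows = rows.ravel()
    cols = cols.ravel()
    array_col = 2 * cols + (rows % 2)
    barcodes = np.array(
        [f"{sample_id}-S{r:03d}x{c:03d}" for r, c in zip(rows, array_col)], dtype=object
    )
    if in_tissue is None:
        in_tissue = np.ones(len(rows), dtype=int)
    return SpotGeometry(
        barcodes=barcodes,
        in_tissue=in_tissue,
        array_row=rows,
        array_col=array_col,
        pxl_row=1000.0 + rows * (HEX_PITCH_PX * np.sqrt(3.0) / 2.0),
        pxl_col=1000.0 + array_col * (HEX_PITCH_PX / 2.0),
    )


def _smooth_field(rng: np.random.Generator, shape: tuple, sigma: float) -> np.ndarray:
    """Standardized Gaussian-blurred white-noise field over the grid."""
    raw = rng.standard_normal(shape)
    if sigma > 0:
        raw = gaussian_filter(raw, sigma=sigma, mode="reflect")
    raw = raw - raw.mean()
    sd = raw.std()
    if sd > 0:
        raw = raw / sd
    return raw


def _orthonormalize(fields: np.ndarray) -> np.ndarray:
    """Gram-Schmidt across spots: exactly zero-mean, unit-sd, mutually orthogonal."""
    out = []
    for f in fields:
        v = f - f.mean()
        for u in out:
            v = v - (v @ u) / (u @ u) * u
        v = v - v.mean()
        sd = v.std()
        if sd == 0:
            raise ValueError("degenerate latent field")
        out.append(v / sd)
    return np.array(out)


def _rho_gauss(rho: float, s: float) -> float:
    """Gaussian mixing correlation that yields lognormal correlation rho."""
    if rho == 0.0 or s == 0.0:
        return 0.0
    return float(np.log(1.0 + rho * np.expm1(s * s)) / (s * s))


def _pair_amplitude(rho: float, s: float) -> float:
    """Shrink the lognormal amplitude when rho is below the achievable floor."""
    if rho >= 0:
        return s
    s_max = 0.95 * np.sqrt(np.log(1.0 / abs(rho))) if abs(rho) > 0 else s
    return float(min(s, s_max)) if s_max > 0 else s


def simulate_visium(
    spec: SpatialSpec,
    signatures: pd.DataFrame,
) -> tuple[CountMatrix, SpotGeometry, GroundTruth]:
    """Simulate one spatial sample from cell-type signatures.

    Per-spot proportions are a Dirichlet-ized exponentiated Gaussian
    blur of white noise per cell type (positivity, sum-to-one, tunable
    autocorrelation); spot expression means are the proportion-weighted
    signature mixture scaled to ``reads_per_spot``; counts are Poisson.
    Planted pairs receive calibrated shared lognormal factors (see
    module docstring).
    """
    rng = np.random.default_rng(spec.seed)
    geom = hex_grid_geometry(spec.sample_id, spec.grid_rows, spec.grid_cols)
    n_spots = len(geom)
    celltypes = list(signatures.index)
    gene_ids = signatures.columns.to_numpy()
    n_genes = len(gene_ids)
    if spec.fap_celltype not in celltypes:
        raise ValueError(f"fap_celltype {spec.fap_celltype!r} not in signatures")

    # --- proportions -------------------------------------------------
    shape = (spec.grid_rows, spec.grid_cols)
    fields = {}
    for ct in celltypes:
        fields[ct] = _smooth_field(rng, shape, spec.proportion_smoothness)
    t1, t2 = spec.anticorrelated_types
    if t1 in fields and t2 in fields:
        # slow/fast myofiber gradients run against each other
        extra = _smooth_field(rng, shape, spec.proportion_smoothness)
        fields[t2] = -0.9 * fields[t1] + np.sqrt(1 - 0.9**2) * extra
    logits = np.stack([fields[ct].ravel() for ct in celltypes], axis=1)
    weights = np.exp(spec.proportion_amplitude * logits)
    proportions = weights / weights.sum(axis=1, keepdims=True)

    # --- expected expression -----------------------------------------
    rel_sig = signatures.to_numpy() / signatures.to_numpy().sum(axis=1, keepdims=True)
    mu = proportions @ rel_sig  # rows sum to 1
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    for a, b, _rho in spec.planted_pairs:
        for g in (a, b):
            if g not in gene_pos:
                raise ValueError(f"planted gene {g!r} absent from signatures")
            mu[:, gene_pos[g]] *= spec.planted_gene_boost
    mu = mu / mu.sum(axis=1, keepdims=True) * spec.reads_per_spot

    # --- planted correlation factors ----------------------------------
    true_rho = {}
    for a, b, rho in spec.planted_pairs:
        s = _pair_amplitude(rho, spec.latent_amplitude)
        rg = _rho_gauss(rho, s)
        if not (-1.0 <= rg <= 1.0):
            raise ValueError(
                f"planted rho {rho} unreachable at amplitude {s}; lower latent_amplitude"
            )
        raw = np.array(
            [
                _smooth_field(rng, shape, spec.latent_smoothness).ravel()
                for _ in range(3)
            ]
        )
        z, ea, eb = _orthonormalize(raw)
        c = np.sqrt(abs(rg))
        ga = c * z + np.sqrt(1.0 - abs(rg)) * ea
        gb = np.sign(rg) * c * z + np.sqrt(1.0 - abs(rg)) * eb if rg != 0 else eb
        mu[:, gene_pos[a]] *= np.exp(s * ga - s * s / 2.0)
        mu[:, gene_pos[b]] *= np.exp(s * gb - s * s / 2.0)
        true_rho[(a, b)] = rho

    counts = rng.poisson(mu)
    m = CountMatrix(
        values=sp.csr_matrix(counts),
        obs_ids=geom.barcodes,
        gene_ids=gene_ids,
        gene_names=gene_ids.copy(),
        obs_kind="spot",
        sample_id=spec.sample_id,
    )
    truth = GroundTruth(
        signatures=signatures,
        proportions=pd.DataFrame(
            proportions, index=pd.Index(geom.barcodes), columns=celltypes
        ),
        rho=true_rho,
    )
    return m, geom, truth


# ----------------------------------------------------------------------
# Annotation tables and gene sets
# ----------------------------------------------------------------------

_LOCATION_POOL = (
    "Cytoplasm",
    "Nucleus",
    "Mitochondrion",
    "Membrane; Single-pass type I membrane protein",
    "Endoplasmic reticulum membrane",
    "Golgi apparatus",
    "Lysosome",
    "Cell membrane; Peripheral membrane protein",
)

SECRETED_LOCATION = "Secreted, extracellular space"


def simulate_location_table(
    genes: Sequence[str],
    secreted_fraction: float = 0.1,
    seed: int = 0,
    always_secreted: Sequence[str] = (),
) -> dict[str, set]:
    """Assign one UniProt-style location string per gene.

    The number of secreted genes is ``round(secreted_fraction * n)``
    (within 1/n of the target fraction), and the ``always_secreted``
    genes are secreted regardless.
    """
    if not (0.0 <= secreted_fraction <= 1.0):
        raise ValueError("secreted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    always = [g for g in always_secreted if g in set(genes)]
    n_target = int(round(secreted_fraction * len(genes)))
    secreted = set(always)
    pool = [g for g in genes if g not in secreted]
    if n_target > len(secreted):
        extra = rng.choice(len(pool), size=n_target - len(secreted), replace=False)
        secreted |= {pool[i] for i in extra}
    table = {}
    for g in genes:
        if g in secreted:
            table[g] = {SECRETED_LOCATION}
        else:
            table[g] = {_LOCATION_POOL[rng.integers(len(_LOCATION_POOL))]}
    return table


def simulate_gene_sets(
    genes: Sequence[str],
    secreted_genes: Sequence[str],
    seed: int = 0,
    n_random_sets: int = 5,
    random_set_size: int = 50,
) -> dict[str, set]:
    """Gene-set collection: an extracellular set (the secreted genes), two
    metabolism sets anchored on canonical targets, and random decoys."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets: dict[str, set] = {"CC_extracellular_region": set(secreted_genes) & set(genes)}
    anchors = {
        "KEGG_insulin_signaling": ["IRS1", "FOXO1", "SORBS1"],
        "KEGG_nitrogen_metabolism": ["SLC38A2", "GLUL"],
    }
    for name, core in anchors.items():
        members = {g for g in core if g in set(genes)}
        extra = rng.choice(len(genes), size=random_set_size, replace=False)
        members |= {genes[i] for i in extra}
        sets[name] = members
    for k in range(n_random_sets):
        idx = rng.choice(len(genes), size=random_set_size, replace=False)
        sets[f"RANDOM_SET_{k}"] = {genes[i] for i in idx}
    return sets


# ----------------------------------------------------------------------
# Whole-study convenience
# ----------------------------------------------------------------------

DEFAULT_CONDITION_EFFECTS = {
    # positive = up in the obese (TB-like) condition.  Secreted FAPs markers
    # carry breed effects so the three-way screen (region contrast x breed
    # contrasts) has a non-empty common core, as in real muscle secretome
    # screens; a few background secretory genes differ between breeds too.
    "TB": {
        "COL1A1": 0.8,
        "DCN": 0.7,
        "COL15A1": 0.8,
        "COL4A2": 0.7,
        "FN1": -0.8,
        "COL14A1": -0.7,
        "MGP": -0.8,
        "SPARC": 1.0,
        "CST3": 0.8,
        "GPX3": 0.8,
        "CFD": 0.7,
        "GSN": -1.0,
        "ANXA2": -0.9,
    },
    "Duroc": {},
}

DEFAULT_PLANTED_PAIRS = (
    ("SPARC", "IRS1", 0.7),
    ("CST3", "SLC38A2", 0.5),
    ("GSN", "GLUL", 0.4),
)


@dataclass
class StudySpec:
    """A full two-condition study: reference per breed plus one spatial sample each.

    Defaults emulate the study structure at desk scale: 8 cell types,
    2,000 genes, ~2,000 nuclei per breed, a 63x63-spot obese (TB-like)
    section and a 43x42-spot lean (Duroc-like) section with differing
    library sizes.
    """

    reference: ReferenceSpec = field(default_factory=ReferenceSpec)
    condition_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITION_EFFECTS.items()}
    )
    spatial: dict = field(
        default_factory=lambda: {
            "TB": SpatialSpec(
                sample_id="TB",
                grid_rows=63,
                grid_cols=63,
                reads_per_spot=15000.0,
                planted_pairs=DEFAULT_PLANTED_PAIRS,
            ),
            "Duroc": SpatialSpec(
                sample_id="Duroc",
                grid_rows=43,
                grid_cols=42,
                reads_per_spot=20000.0,
                planted_pairs=DEFAULT_PLANTED_PAIRS,
            ),
        }
    )
    sample_conditions: dict = field(
        default_factory=lambda: {"TB": "TB", "Duroc": "Duroc"}
    )
    secreted_fraction: float = 0.1
    seed: int = 0


@dataclass
class SimulatedStudy:
    reference: CountMatrix
    labels: pd.Series
    conditions: pd.Series  # per-nucleus condition
    spatial: dict  # sample_id -> (CountMatrix, SpotGeometry, GroundTruth)
    sample_conditions: dict
    locations: dict
    gene_sets: dict
    truth: GroundTruth


def _derive_seed(seed: int, tag: str) -> int:
    import zlib

    return (seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def simulate_study(spec: StudySpec | None = None) -> SimulatedStudy:
    """Generate the full synthetic study: references, spatial samples, tables."""
    if spec is None:
        spec = StudySpec()
    refs, labels, conds = [], [], []
    signatures = {}
    conditions = sorted(spec.condition_effects)
    for cond in conditions:
        rspec_kwargs = {**spec.reference.__dict__}
        rspec_kwargs["gene_log2fc"] = {
            **spec.reference.gene_log2fc,
            **spec.condition_effects[cond],
        }
        rspec_kwargs["seed"] = _derive_seed(spec.seed, f"ref:{cond}")
        rspec = ReferenceSpec(**rspec_kwargs)
        m, lab, truth = simulate_reference(rspec, sample_prefix=cond)
        refs.append(m)
        labels.append(lab)
        conds.extend([cond] * m.n_obs)
        signatures[cond] = truth.signatures
    merged = CountMatrix(
        values=sp.vstack([r.values for r in refs]).tocsr(),
        obs_ids=np.concatenate([r.obs_ids for r in refs]),
        gene_ids=refs[0].gene_ids,
        gene_names=refs[0].gene_names,
        obs_kind="nucleus",
        sample_id="reference",
        obs_sample=np.array(conds, dtype=object),
    )
    all_labels = pd.concat(labels)
    cond_series = pd.Series(np.array(conds, dtype=object), index=all_labels.index, name="condition")

    spatial = {}
    for sample_id, sspec in spec.spatial.items():
        cond = spec.sample_conditions[sample_id]
        skwargs = {**sspec.__dict__}
        skwargs["seed"] = _derive_seed(spec.seed, f"visium:{sample_id}")
        spatial[sample_id] = simulate_visium(SpatialSpec(**skwargs), signatures[cond])

    gene_ids = list(refs[0].gene_ids)
    planted_secretory = sorted(
        {a for sspec in spec.spatial.values() for a, _b, _r in sspec.planted_pairs}
    )
    fap_markers = [g for g in DEFAULT_MARKER_NAMES.get("FAPs", []) if g in gene_ids]
    locations = simulate_location_table(
        gene_ids,
        spec.secreted_fraction,
        seed=_derive_seed(spec.seed, "locations"),
        always_secreted=planted_secretory + fap_markers + ["IGFBP5", "CFD", "ANXA2"],
    )
    secreted_genes = [g for g, locs in locations.items() if SECRETED_LOCATION in locs]
    gene_sets = simulate_gene_sets(
        gene_ids, secreted_genes, seed=_derive_seed(spec.seed, "genesets")
    )
    rho = {}
    for _sid, (_m, _g, t) in spatial.items():
        rho.update(t.rho)
    truth = GroundTruth(signatures=signatures[conditions[0]], rho=rho)
    return SimulatedStudy(
        reference=merged,
        labels=all_labels,
        conditions=cond_series,
        spatial=spatial,
        sample_conditions=dict(spec.sample_conditions),
        locations=locations,
        gene_sets=gene_sets,
        truth=truth,
    )
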