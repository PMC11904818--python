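"""Random-region resampling and secretory-gene / target-gene correlation.

The defining procedure: draw many equal-area regions at random from a
spatial sample (a region is a seed spot plus its ``region_size - 1``
nearest in-tissue neighbours by Euclidean pixel distance, ties broken
by lexicographic barcode), form each region's pseudo-bulk log2-CPM
profile from summed counts, and compute Pearson correlations between a
set of secretory candidate genes and a set of myofiber-type / metabolic
target genes across regions.  Pass tiers follow the study thresholds:
standard |r| > 0.4 with p < 0.05 and strict |r| > 0.5 with p < 0.001,
using the raw two-sided p from the t transform
``t = r * sqrt((n - 2) / (1 - r^2))``.  Benjamini-Hochberg q-values are
reported alongside but do not gate the tiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CorrRecord, CountMatrix, RegionSample, SpotGeometry
from .qc_norm import normalize_log_cpm

__all__ = [
    "CorrelationParams",
    "RegionProfiles",
    "extract_region",
    "sample_regions",
    "correlate_gene_sets",
    "spatial_aggregation_map",
]


@dataclass
class CorrelationParams:
    n_regions_per_sample: int = 200
    region_size: int = 25
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    strict_r_threshold: float = 0.5
    strict_p_threshold: float = 0.001
    mtc: str = "bh"  # reported, never used for the tier flags
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_size < 1:
            raise ValueError("region_size must be >= 1")
        for name in ("p_threshold", "strict_p_threshold"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("r_threshold", "strict_r_threshold"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class RegionProfiles:
    """A list of sampled regions with their pseudo-bulk profile matrix."""

    regions: list  # of RegionSample
    gene_ids: np.ndarray
    matrix: np.ndarray  # n_regions x n_genes log2-CPM
    sample_ids: np.ndarray
    with_replacement: bool = False

    def __len__(self) -> int:
        return len(self.regions)

    @staticmethod
    def concat(parts: Sequence["RegionProfiles"]) -> "RegionProfiles":
        if not parts:
            raise ValueError("nothing to concatenate")
        g0 = parts[0].gene_ids
        for p in parts[1:]:
            if not np.array_equal(p.gene_ids, g0):
                raise ValueError("gene tables differ between region sets")
        return RegionProfiles(
            regions=[r for p in parts for r in p.regions],
            gene_ids=g0,
            matrix=np.vstack([p.matrix for p in parts]),
            sample_ids=np.concatenate([p.sample_ids for p in parts]),
            with_replacement=any(p.with_replacement for p in parts),
        )


def extract_region(
    geom: SpotGeometry, seed_spot: str, region_size: int
) -> tuple:
    """Seed spot plus its nearest in-tissue neighbours by pixel distance.

    Returns exactly ``region_size`` barcodes including the seed; raises
    if the sample has fewer in-tissue spots.  Distance ties are broken
    by lexicographic barcode so membership is deterministic.
    """
    in_mask = geom.in_tissue == 1
    barcodes = geom.barcodes[in_mask]
    if region_size > len(barcodes):
        raise ValueError(
            f"region_size {region_size} exceeds {len(barcodes)} in-tissue spots"
        )
    pos = np.where(barcodes == seed_spot)[0]
    if len(pos) == 0:
        raise KeyError(f"seed spot {seed_spot!r} not an in-tissue spot")
    px = geom.pxl_row[in_mask]
    py = geom.pxl_col[in_mask]
    d2 = (px - px[pos[0]]) ** 2 + (py - py[pos[0]]) ** 2
    order = np.lexsort((barcodes.astype(str), d2))
    return tuple(barcodes[order[:region_size]])


def sample_regions(
    geom: SpotGeometry,
    counts: CountMatrix,
    p: CorrelationParams | None = None,
    sample_id: str | None = None,
    seed: int | None = None,
) -> RegionProfiles:
    """Draw ``n_regions_per_sample`` regions with uniform random seeds.

    Seed spots are drawn without replacement among in-tissue spots
    (with replacement, flagged, when more regions than spots are
    requested); regions may overlap.  Profiles are log2-CPM of summed
    member counts.  A fixed seed gives bit-identical output.
    """
    if p is None:
        p = CorrelationParams()
    if sample_id is None:
        sample_id = counts.sample_id or "S"
    rng = np.random.default_rng(p.seed if seed is None else seed)
    in_barcodes = np.sort(geom.in_tissue_barcodes().astype(str))
    n = p.n_regions_per_sample
    if n == 0:
        return RegionProfiles(
            regions=[],
            gene_ids=counts.gene_ids,
            matrix=np.zeros((0, counts.n_genes)),
            sample_ids=np.array([], dtype=object),
        )
    if len(in_barcodes) < p.region_size:
        raise ValueError("too few in-tissue spots for the requested region size")
    replace = n > len(in_barcodes)
    seeds = rng.choice(in_barcodes, size=n, replace=replace)

    pos = {b: i for i, b in enumerate(counts.obs_ids)}
    regions, rows_profiles = [], []
    for i, seed_spot in enumerate(seeds):
        members = extract_region(geom, seed_spot, p.region_size)
        rows = np.array([pos[b] for b in members])
        summed = np.asarray(counts.values[rows].sum(axis=0)).ravel().astype(float)
        total = summed.sum()
        profile = np.log2(summed / total * 1e6 + 1.0) if total > 0 else np.zeros_like(summed)
        gsel = np.isin(geom.barcodes, members)
        centroid = (float(geom.pxl_row[gsel].mean()), float(geom.pxl_col[gsel].mean()))
        regions.append(
            RegionSample(
                region_id=f"{sample_id}_r{i:04d}",
                sample_id=sample_id,
                seed_spot=str(seed_spot),
                members=members,
                centroid=centroid,
                profile=profile,
            )
        )
        rows_profiles.append(profile)
    return RegionProfiles(
        regions=regions,
        gene_ids=counts.gene_ids,
        matrix=np.vstack(rows_profiles),
        sample_ids=np.array([sample_id] * n, dtype=object),
        with_replacement=replace,
    )


def _pearson_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between columns of a and columns of b (NaN when degenerate)."""
    n = a.shape[0]
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    sa = az.std(axis=0)
    sb = bz.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az.T @ bz) / n / np.outer(sa, sb)
    r[:, sb == 0] = np.nan
    r[sa == 0, :] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def correlate_gene_sets(
    profiles: RegionProfiles,
    set_a: Sequence[str],
    set_b: Sequence[str],
    p: CorrelationParams | None = None,
    sample_conditions: Mapping[str, str] | None = None,
) -> list[CorrRecord]:
    """Pearson r over regions for every (a, b) gene pair.

    p-values come from the t transform with n = number of regions; BH q
    is computed across defined pairs; tier flags use |r| with the raw p.
    When ``sample_conditions`` distinguishes groups (e.g. breeds),
    per-group r is reported alongside the pooled value.
    """
    if p is None:
        p = CorrelationParams()
    measured = set(map(str, profiles.gene_ids))
    genes_a = [g for g in dict.fromkeys(set_a) if g in measured]
    genes_b = [g for g in dict.fromkeys(set_b) if g in measured]
    if not genes_a or not genes_b:
        raise ValueError("gene sets empty after intersecting with measured genes")
    gene_pos = {g: j for j, g in enumerate(profiles.gene_ids)}
    n = len(profiles)
    if n < 3:
        raise ValueError("need at least 3 regions to correlate")
    mat_a = profiles.matrix[:, [gene_pos[g] for g in genes_a]]
    mat_b = profiles.matrix[:, [gene_pos[g] for g in genes_b]]
    r_mat = _pearson_matrix(mat_a, mat_b)

    groups = {}
    if sample_conditions:
        conds = np.array([sample_conditions.get(s, s) for s in profiles.sample_ids])
        for c in sorted(set(conds)):
            rows = conds == c
            if rows.sum() >= 3:
                groups[c] = _pearson_matrix(mat_a[rows], mat_b[rows])

    records: list[CorrRecord] = []
    flat_p, flat_idx = [], []
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            r = r_mat[i, j]
            defined = np.isfinite(r)
            if defined:
                rr = min(abs(r), 1.0 - 1e-15)
                t = r * np.sqrt((n - 2) / (1.0 - rr * rr))
                pval = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            else:
                pval = float("nan")
            rec = CorrRecord(
                gene_a=ga,
                gene_b=gb,
                r=float(r) if defined else float("nan"),
                p_value=pval,
                q_value=float("nan"),
                n_regions=n,
                passes_standard=bool(
                    defined and abs(r) > p.r_threshold and pval < p.p_threshold
                ),
                passes_strict=bool(
                    defined
                    and abs(r) > p.strict_r_threshold
                    and pval < p.strict_p_threshold
                ),
                defined=bool(defined),
                r_by_group={
                    c: (float(g[i, j]) if np.isfinite(g[i, j]) else None)
                    for c, g in groups.items()
                },
            )
            if defined:
                flat_p.append(pval)
                flat_idx.append(len(records))
            records.append(rec)
    if flat_p and p.mtc == "bh":
        q = multipletests(np.array(flat_p), method="fdr_bh")[1]
        for qi, ri in zip(q, flat_idx):
            records[ri].q_value = float(qi)
    return records


def spatial_aggregation_map(
    counts: CountMatrix,
    geom: SpotGeometry,
    gene_pair: tuple,
) -> pd.DataFrame:
    """Per-spot normalized expression of a gene pair joined to coordinates.

    Inspection/plotting output for spatial co-aggregation; no statistic
    beyond the correlation already computed.
    """
    gene_a, gene_b = gene_pair
    pos = {g: j for j, g in enumerate(counts.gene_ids)}
    for g in (gene_a, gene_b):
        if g not in pos:
            raise KeyError(f"gene {g!r} not measured")
    expr = normalize_log_cpm(counts)
    cols = np.asarray(expr[:, [pos[gene_a], pos[gene_b]]].todense())
    df = pd.DataFrame(
        {
            "barcode": counts.obs_ids,
            gene_a: cols[:, 0],
            gene_b: cols[:, 1],
        }
    )
    geo = geom.to_frame()[["barcode", "in_tissue", "pxl_row_in_fullres", "pxl_col_in_fullres"]]
    return df.merge(geo, on="barcode", how="inner")
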