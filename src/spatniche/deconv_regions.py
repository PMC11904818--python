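"""Spot deconvolution, FAPs-high/low region delineation and region-contrast DE.

Deconvolution is non-negative least squares (NNLS) of each spot's CPM
profile against cell-type mean-CPM signature rows restricted to a
marker-informed gene subset, with coefficients normalized to sum to
one.  Spots are then classified as high / low / intermediate for a
target cell type (FAPs by default) using empirical quantile thresholds
over in-tissue spots, and the two extreme classes are contrasted by
spot-level differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .markers_de import DEParams, find_markers, de_between_groups
from .qc_norm import cpm, normalize_log_cpm
from .types import CountMatrix, DERecord, ProportionMap, SignatureMatrix, SpotGeometry

__all__ = [
    "RegionParams",
    "build_signatures",
    "deconvolve_spots",
    "classify_regions",
    "region_de",
]


@dataclass
class RegionParams:
    """Thresholds for target-cell-type region delineation."""

    target_celltype: str = "FAPs"
    high_quantile: float = 0.75
    low_quantile: float = 0.25
    region_size: int = 25
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("high_quantile", "low_quantile"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.low_quantile > self.high_quantile:
            raise ValueError("low_quantile must not exceed high_quantile")
        if self.region_size < 1:
            raise ValueError("region_size must be >= 1")


def build_signatures(
    ref: CountMatrix,
    labels: pd.Series,
    top_k_markers: int = 25,
    de_params: DEParams | None = None,
) -> SignatureMatrix:
    """Mean-CPM cell-type signatures restricted to a marker-informed gene subset.

    Row t is the mean of per-nucleus CPM over nuclei labelled t; the
    gene subset is the union of the top ``top_k_markers`` markers per
    type ranked by (p, -|log2FC|) from :func:`find_markers`.
    ``top_k_markers=0`` keeps all genes.
    """
    labels = labels.reindex(ref.obs_ids)
    if labels.isna().any():
        missing = np.asarray(ref.obs_ids)[labels.isna().to_numpy()][:5]
        raise ValueError(f"nuclei missing labels: {', '.join(missing)}")
    celltypes = sorted(set(labels))
    dense_cpm = cpm(ref.values)
    rows = []
    for ct in celltypes:
        members = labels.to_numpy() == ct
        if members.sum() == 0:
            raise ValueError(f"cell type {ct!r} has no nuclei")
        rows.append(dense_cpm[members].mean(axis=0))
    sig = np.vstack(rows)

    gene_idx = np.arange(ref.n_genes)
    if top_k_markers > 0:
        expr = normalize_log_cpm(ref)
        records = find_markers(
            expr, labels.to_numpy(), de_params or DEParams(), gene_ids=ref.gene_ids
        )
        frame = pd.DataFrame(
            [(r.group, r.gene_id, r.p_value, abs(r.log2fc)) for r in records],
            columns=["group", "gene", "p", "alfc"],
        )
        chosen: set = set()
        for ct, sub in frame.groupby("group"):
            sub = sub.sort_values(["p", "alfc", "gene"], ascending=[True, False, True])
            chosen |= set(sub["gene"].head(top_k_markers))
        pos = {g: j for j, g in enumerate(ref.gene_ids)}
        gene_idx = np.array(sorted(pos[g] for g in chosen))
        if len(gene_idx) == 0:
            raise ValueError("no marker genes found to build signatures")
    return SignatureMatrix(
        values=sig[:, gene_idx],
        celltypes=np.array(celltypes, dtype=object),
        gene_ids=ref.gene_ids[gene_idx],
        provenance=ref.sample_id,
    )


def deconvolve_spots(spots: CountMatrix, sig: SignatureMatrix) -> ProportionMap:
    """Per-spot NNLS of the CPM profile against signature rows.

    Coefficients are normalized to sum to one; the relative residual
    norm is stored per spot.  All-zero spots get uniform proportions
    and are flagged.
    """
    shared = [g for g in sig.gene_ids if g in set(spots.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between spots and signatures")
    spot_pos = {g: j for j, g in enumerate(spots.gene_ids)}
    sig_pos = {g: j for j, g in enumerate(sig.gene_ids)}
    cols_spot = np.array([spot_pos[g] for g in shared])
    cols_sig = np.array([sig_pos[g] for g in shared])

    # CPM computed on the full library, then restricted to shared genes
    libsize = spots.library_sizes().astype(float)
    sub = np.asarray(spots.values[:, cols_spot].todense(), dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        b_mat = np.where(libsize[:, None] > 0, sub / np.maximum(libsize, 1)[:, None] * 1e6, 0.0)
    a_mat = sig.values[:, cols_sig].T  # genes x celltypes

    n_spots, n_types = spots.n_obs, len(sig.celltypes)
    props = np.zeros((n_spots, n_types))
    residual = np.zeros(n_spots)
    flagged = np.zeros(n_spots, dtype=bool)
    for i in range(n_spots):
        b = b_mat[i]
        bn = np.linalg.norm(b)
        if bn == 0:
            props[i] = 1.0 / n_types
            residual[i] = 0.0
            flagged[i] = True
            continue
        x, rnorm = scipy.optimize.nnls(a_mat, b)
        total = x.sum()
        if total == 0:
            props[i] = 1.0 / n_types
            flagged[i] = True
        else:
            props[i] = x / total
        residual[i] = rnorm / bn
    return ProportionMap(
        values=props,
        barcodes=spots.obs_ids,
        celltypes=sig.celltypes,
        residual=residual,
        flagged=flagged,
    )


def _order_stat_threshold(values: np.ndarray, q: float) -> float:
    """Empirical quantile as the order statistic at floor(q * (n - 1))."""
    v = np.sort(values)
    idx = int(np.floor(q * (len(v) - 1)))
    return float(v[idx])


def classify_regions(
    pm: ProportionMap,
    geom: SpotGeometry,
    p: RegionParams | None = None,
) -> pd.Series:
    """Label each in-tissue spot high / low / intermediate for the target type.

    Thresholds are empirical quantiles of the target-type proportion
    over in-tissue spots; ties at a threshold go to the extreme class
    (high is >= the high threshold, low is <= the low threshold, high
    takes precedence).  Constant proportions yield all-intermediate
    with a warning.
    """
    if p is None:
        p = RegionParams()
    target = pm.column(p.target_celltype)
    in_tissue = set(geom.in_tissue_barcodes())
    mask = np.array([b in in_tissue for b in pm.barcodes])
    vals = target[mask]
    if len(vals) == 0:
        raise ValueError("no in-tissue spots to classify")
    labels = np.full(len(pm.barcodes), "intermediate", dtype=object)
    if np.ptp(vals) == 0:
        warnings.warn("constant proportions; all spots labelled intermediate")
    else:
        thr_high = _order_stat_threshold(vals, p.high_quantile)
        thr_low = _order_stat_threshold(vals, p.low_quantile)
        labels[mask & (target >= thr_high)] = "high"
        labels[mask & (target <= thr_low) & (target < thr_high)] = "low"
    out = pd.Series(labels, index=pd.Index(pm.barcodes), name="region")
    return out[mask]


def region_de(
    spots: CountMatrix,
    high_barcodes,
    low_barcodes,
    p: DEParams | None = None,
) -> list[DERecord]:
    """Differential expression between high- and low-region spots.

    Spot-level Wilcoxon on log2-CPM by default.  Both classes need at
    least 3 spots; overlapping classes are refused.
    """
    if p is None:
        p = DEParams(test="wilcoxon")
    high = list(dict.fromkeys(high_barcodes))
    low = list(dict.fromkeys(low_barcodes))
    overlap = set(high) & set(low)
    if overlap:
        raise ValueError(f"spots assigned to both classes: {sorted(overlap)[:5]}")
    if len(high) < 3 or len(low) < 3:
        raise ValueError(
            f"each class needs >= 3 spots (high={len(high)}, low={len(low)})"
        )
    pos = {b: i for i, b in enumerate(spots.obs_ids)}
    unknown = [b for b in high + low if b not in pos]
    if unknown:
        raise KeyError(f"unknown spot barcodes: {unknown[:5]}")
    rows = np.array([pos[b] for b in high] + [pos[b] for b in low])
    sub = spots.subset_obs(rows)
    group = np.array(["high"] * len(high) + ["low"] * len(low), dtype=object)
    return de_between_groups(sub, group, p, groups=("high", "low"))
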