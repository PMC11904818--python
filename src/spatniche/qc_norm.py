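"""Quality-control filtering, log-CPM normalization and pseudo-bulk aggregation.

Nucleus QC applies three rules, in order: (1) keep nuclei detecting
strictly more than ``min_genes_per_nucleus`` genes; (2) keep nuclei with
mitochondrial fraction strictly below ``max_mito_fraction``; (3) keep
genes detected in at least ``min_cells_per_gene`` of the *kept* nuclei.
Both per-nucleus bounds are strict inequalities.  For spot matrices the
mitochondrial filter is off by default (spots pool many cells and no
spot-level mitochondrial threshold applies); out-of-tissue spots are
dropped via :func:`drop_out_of_tissue`.

Normalization is log2 counts-per-million: ``log2(count / libsize * 1e6
+ pseudocount)``.  This is used everywhere a normalized value is needed
(nuclei, spots and region pseudo-bulk profiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .types import CountMatrix, SpotGeometry

__all__ = [
    "QCParams",
    "QCReport",
    "mito_fraction",
    "filter_matrix",
    "drop_out_of_tissue",
    "normalize_log_cpm",
    "pseudobulk",
]


@dataclass
class QCParams:
    """Thresholds for nucleus/gene filtering.

    ``min_genes_per_nucleus`` and ``max_mito_fraction`` are exclusive
    bounds: a nucleus is kept when detected genes > 500 and
    mitochondrial fraction < 0.25 (the defaults).
    """

    min_genes_per_nucleus: int = 500
    max_mito_fraction: float = 0.25
    min_cells_per_gene: int = 1
    mito_prefix: str = "MT-"
    max_counts: float | None = None  # optional cap, default off

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_genes_per_nucleus < 0 or self.min_cells_per_gene < 0:
            raise ValueError("count thresholds must be >= 0")


@dataclass
class QCReport:
    n_input_obs: int
    n_kept_obs: int
    n_input_genes: int
    n_kept_genes: int
    n_removed_low_genes: int
    n_removed_high_mito: int
    n_removed_high_counts: int
    n_removed_low_cell_genes: int

    def __post_init__(self) -> None:
        assert self.n_kept_obs <= self.n_input_obs
        assert self.n_kept_genes <= self.n_input_genes
        assert (
            self.n_input_obs
            - self.n_removed_low_genes
            - self.n_removed_high_mito
            - self.n_removed_high_counts
            == self.n_kept_obs
        )
        assert self.n_input_genes - self.n_removed_low_cell_genes == self.n_kept_genes

    def to_dict(self) -> dict:
        return asdict(self)


def mito_fraction(m: CountMatrix, mito_prefix: str = "MT-") -> np.ndarray:
    """Per-observation fraction of counts on genes whose *name* starts with the prefix.

    Observations with zero total counts get fraction 0.
    """
    is_mito = np.array([str(n).startswith(mito_prefix) for n in m.gene_names])
    total = m.library_sizes().astype(float)
    mito = np.asarray(m.values[:, is_mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
    return frac


def filter_matrix(m: CountMatrix, p: QCParams | None = None) -> tuple[CountMatrix, QCReport]:
    """Apply the nucleus and gene quality filters; return the kept matrix and a report.

    Filter order: nucleus filters first (detected genes, then
    mitochondrial fraction, then the optional counts cap), then the gene
    filter recomputed on kept nuclei only.  For ``obs_kind == "spot"``
    the mitochondrial filter is skipped.
    """
    if p is None:
        p = QCParams()
    detected = np.asarray((m.values > 0).sum(axis=1)).ravel()
    keep_obs = detected > p.min_genes_per_nucleus
    n_removed_low = int((~keep_obs).sum())

    n_removed_mito = 0
    if m.obs_kind == "nucleus":
        frac = mito_fraction(m, p.mito_prefix)
        mito_ok = frac < p.max_mito_fraction
        n_removed_mito = int((keep_obs & ~mito_ok).sum())
        keep_obs = keep_obs & mito_ok

    n_removed_cap = 0
    if p.max_counts is not None:
        cap_ok = m.library_sizes() <= p.max_counts
        n_removed_cap = int((keep_obs & ~cap_ok).sum())
        keep_obs = keep_obs & cap_ok

    kept = m.subset_obs(keep_obs)
    cells_per_gene = np.asarray((kept.values > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= p.min_cells_per_gene
    out = kept.subset_genes(keep_genes)

    report = QCReport(
        n_input_obs=m.n_obs,
        n_kept_obs=out.n_obs,
        n_input_genes=m.n_genes,
        n_kept_genes=out.n_genes,
        n_removed_low_genes=n_removed_low,
        n_removed_high_mito=n_removed_mito,
        n_removed_high_counts=n_removed_cap,
        n_removed_low_cell_genes=int((~keep_genes).sum()),
    )
    if out.n_obs == 0 or out.n_genes == 0:
        warnings.warn("QC filtering produced an empty matrix", stacklevel=2)
    return out, report


def drop_out_of_tissue(m: CountMatrix, geom: SpotGeometry) -> CountMatrix:
    """Remove spots whose geometry flags them as outside the tissue section."""
    if m.obs_kind != "spot":
        raise ValueError("drop_out_of_tissue applies to spot matrices")
    in_tissue = set(geom.in_tissue_barcodes())
    keep = np.array([b in in_tissue for b in m.obs_ids])
    return m.subset_obs(keep)


def normalize_log_cpm(m: CountMatrix, pseudocount: float = 1.0) -> sp.csr_matrix:
    """log2(count / library_size * 1e6 + pseudocount), sparse when pseudocount == 1.

    With the default pseudocount of 1, zero counts map to 0 so sparsity
    is preserved and a csr matrix is returned; other pseudocounts yield
    a dense array.
    """
    libsize = m.library_sizes().astype(float)
    zero = np.where(libsize == 0)[0]
    if len(zero):
        raise ValueError(
            f"zero library size for observation(s): {', '.join(m.obs_ids[zero[:5]])}"
        )
    if pseudocount == 1.0:
        out = m.values.tocsr().astype(float).copy()
        row_scale = 1e6 / libsize
        # scale each stored entry by its row's factor, then log1p in base 2
        expanded = np.repeat(row_scale, np.diff(out.indptr))
        out.data = np.log2(out.data * expanded + 1.0)
        return out
    dense = np.asarray(m.values.todense(), dtype=float)
    cpm = dense / libsize[:, None] * 1e6
    return np.log2(cpm + pseudocount)


def cpm(values, libsize: np.ndarray | None = None) -> np.ndarray:
    """Counts-per-million as a dense array (helper for signatures/deconvolution)."""
    dense = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    if libsize is None:
        libsize = dense.sum(axis=1)
    libsize = np.asarray(libsize, dtype=float)
    out = np.zeros_like(dense)
    nz = libsize > 0
    out[nz] = dense[nz] / libsize[nz, None] * 1e6
    return out


def unlog_cpm(values, pseudocount: float = 1.0) -> np.ndarray:
    """Invert log2-CPM back to CPM scale (dense)."""
    dense = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    return np.power(2.0, dense) - pseudocount


def pseudobulk(
    m: CountMatrix,
    grouping: pd.Series,
    drop_unmapped: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum counts over observation groups; returns (group x gene frame, group sizes).

    ``grouping`` maps observation id -> group label.  Observations absent
    from the mapping raise unless ``drop_unmapped``; groups listed in the
    mapping but matching no observation are retained as all-zero rows and
    flagged by a zero group size.  Group order is sorted.
    """
    grouping = pd.Series(grouping)
    mapped = pd.Index(m.obs_ids).isin(grouping.index)
    if not mapped.all():
        if not drop_unmapped:
            missing = np.asarray(m.obs_ids)[~mapped][:5]
            raise KeyError(f"observations missing from grouping: {', '.join(missing)}")
        m = m.subset_obs(mapped)
    labels = grouping.reindex(m.obs_ids).to_numpy()
    groups = sorted(set(grouping.to_numpy()))
    gidx = {g: i for i, g in enumerate(groups)}
    rows = np.array([gidx[l] for l in labels])
    indicator = sp.csr_matrix(
        (np.ones(len(rows)), (rows, np.arange(len(rows)))),
        shape=(len(groups), m.n_obs),
    )
    sums = np.asarray((indicator @ m.values).todense())
    sizes = pd.Series(np.bincount(rows, minlength=len(groups)), index=groups)
    frame = pd.DataFrame(sums, index=groups, columns=list(m.gene_ids))
    return frame, sizes
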