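"""Core in-memory containers shared across the pipeline.

The two primary containers are :class:`CountMatrix` (a sparse
observations x genes UMI count matrix with identifier tables, used for
both single-nucleus and spatial-spot data) and :class:`SpotGeometry`
(the hex-grid coordinates of Visium-style capture spots).  Result-record
types (differential expression, correlation, enrichment) are plain
dataclasses convertible to pandas DataFrames for writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "SpotGeometry",
    "ProportionMap",
    "SignatureMatrix",
    "RegionSample",
    "DERecord",
    "CorrRecord",
    "EnrichmentRecord",
    "records_to_frame",
]


def _as_str_array(values: Iterable[str]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=object)
    return arr


@dataclass
class CountMatrix:
    """Sparse non-negative integer count matrix, observations x genes.

    ``obs_kind`` distinguishes single nuclei from spatial spots; some
    operations (e.g. the mitochondrial QC filter) behave differently for
    the two kinds.  ``gene_ids`` are the primary key (unique); duplicate
    ``gene_names`` are permitted and used only for reporting.
    """

    values: sp.csr_matrix
    obs_ids: np.ndarray
    gene_ids: np.ndarray
    gene_names: np.ndarray
    obs_kind: str = "nucleus"  # "nucleus" | "spot"
    sample_id: str = ""
    obs_sample: np.ndarray | None = None  # per-observation sample id (multi-sample)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.obs_ids = _as_str_array(self.obs_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.gene_names = _as_str_array(self.gene_names)
        if self.obs_kind not in ("nucleus", "spot"):
            raise ValueError(f"obs_kind must be 'nucleus' or 'spot', got {self.obs_kind!r}")
        n_obs, n_genes = self.values.shape
        if len(self.obs_ids) != n_obs:
            raise ValueError(
                f"obs_ids length {len(self.obs_ids)} != matrix rows {n_obs}"
            )
        if len(self.gene_ids) != n_genes or len(self.gene_names) != n_genes:
            raise ValueError("gene id/name table length does not match matrix columns")
        if len(set(self.obs_ids)) != n_obs:
            raise ValueError("duplicate observation barcodes")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if self.values.nnz:
            data = self.values.data
            if data.min() < 0:
                raise ValueError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integral counts")
        if self.obs_sample is not None:
            self.obs_sample = _as_str_array(self.obs_sample)
            if len(self.obs_sample) != n_obs:
                raise ValueError("obs_sample length mismatch")

    # -- convenience -------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def obs_index(self) -> pd.Index:
        return pd.Index(self.obs_ids)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def subset_obs(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            values=self.values[idx],
            obs_ids=self.obs_ids[idx],
            gene_ids=self.gene_ids,
            gene_names=self.gene_names,
            obs_kind=self.obs_kind,
            sample_id=self.sample_id,
            obs_sample=None if self.obs_sample is None else self.obs_sample[idx],
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            values=self.values[:, idx],
            obs_ids=self.obs_ids,
            gene_ids=self.gene_ids[idx],
            gene_names=self.gene_names[idx],
            obs_kind=self.obs_kind,
            sample_id=self.sample_id,
            obs_sample=self.obs_sample,
        )

    def __eq__(self, other) -> bool:  # value equality, used in roundtrip tests
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
            and np.array_equal(self.obs_ids, other.obs_ids)
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.gene_names, other.gene_names)
            and self.obs_kind == other.obs_kind
        )


@dataclass
class SpotGeometry:
    """Visium-style spot geometry: tissue flag plus array/pixel coordinates.

    Array coordinates are 0-based and follow the 10x hex dialect in which
    ``array_row + array_col`` has constant parity; pixel coordinates are
    an affine image of the array coordinates and are kept as floats.
    """

    barcodes: np.ndarray
    in_tissue: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    pxl_row: np.ndarray
    pxl_col: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = _as_str_array(self.barcodes)
        self.in_tissue = np.asarray(self.in_tissue, dtype=int)
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        self.pxl_row = np.asarray(self.pxl_row, dtype=float)
        self.pxl_col = np.asarray(self.pxl_col, dtype=float)
        n = len(self.barcodes)
        for name in ("in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"geometry column {name} length mismatch")
        if len(set(self.barcodes)) != n:
            raise ValueError("duplicate barcodes in geometry")
        if not np.isin(self.in_tissue, (0, 1)).all():
            raise ValueError("in_tissue must be 0/1")

    def __len__(self) -> int:
        return len(self.barcodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "in_tissue": self.in_tissue,
                "array_row": self.array_row,
                "array_col": self.array_col,
                "pxl_row_in_fullres": self.pxl_row,
                "pxl_col_in_fullres": self.pxl_col,
            }
        )

    def in_tissue_barcodes(self) -> np.ndarray:
        return self.barcodes[self.in_tissue == 1]


@dataclass
class SignatureMatrix:
    """Cell-type x gene mean expression matrix on CPM scale."""

    values: np.ndarray  # (n_celltypes, n_genes), non-negative
    celltypes: np.ndarray
    gene_ids: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.celltypes = _as_str_array(self.celltypes)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.values.shape != (len(self.celltypes), len(self.gene_ids)):
            raise ValueError("signature shape mismatch")
        if (self.values < 0).any():
            raise ValueError("negative signature entries")
        if (self.values.sum(axis=1) == 0).any():
            raise ValueError("all-zero cell-type signature row")


@dataclass
class ProportionMap:
    """Per-spot cell-type composition; rows sum to one."""

    values: np.ndarray  # (n_spots, n_celltypes)
    barcodes: np.ndarray
    celltypes: np.ndarray
    residual: np.ndarray | None = None  # relative least-squares residual per spot
    flagged: np.ndarray | None = None  # spots with degenerate (all-zero) profiles

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.barcodes = _as_str_array(self.barcodes)
        self.celltypes = _as_str_array(self.celltypes)
        if self.values.shape != (len(self.barcodes), len(self.celltypes)):
            raise ValueError("proportion map shape mismatch")
        if (self.values < -1e-12).any():
            raise ValueError("negative proportions")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("proportion rows do not sum to 1")

    def column(self, celltype: str) -> np.ndarray:
        idx = np.where(self.celltypes == celltype)[0]
        if len(idx) == 0:
            raise KeyError(f"cell type {celltype!r} not in proportion map")
        return self.values[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.celltypes))
        df.insert(0, "barcode", self.barcodes)
        if self.residual is not None:
            df["residual"] = self.residual
        return df


@dataclass
class RegionSample:
    """One randomly extracted equal-area spot region with its pseudo-bulk profile."""

    region_id: str
    sample_id: str
    seed_spot: str
    members: tuple  # barcodes, length == region_size, includes seed_spot
    centroid: tuple  # (pxl_row, pxl_col)
    profile: np.ndarray  # log2-CPM over summed member counts, aligned to gene_ids


@dataclass
class DERecord:
    """One gene's result from a marker or two-group differential test."""

    gene_id: str
    group: str  # cluster name or "group1_vs_group2" contrast label
    log2fc: float
    expr_fraction_1: float
    expr_fraction_2: float
    p_value: float
    q_value: float
    direction: str  # "up" | "down"
    passes_filter: bool
    secreted: bool = False
    in_location_table: bool = True
    testable: bool = True


@dataclass
class CorrRecord:
    """Pearson correlation of one (secretory, target) gene pair over regions."""

    gene_a: str
    gene_b: str
    r: float
    p_value: float
    q_value: float
    n_regions: int
    passes_standard: bool  # |r| > 0.4 and p < 0.05 (defaults)
    passes_strict: bool  # |r| > 0.5 and p < 0.001 (defaults)
    defined: bool = True
    r_by_group: dict = field(default_factory=dict)


@dataclass
class EnrichmentRecord:
    """Hypergeometric over-representation result for one gene set."""

    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    q_value: float
    rich_factor: float
    significant: bool


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert a list of result dataclasses to a DataFrame (deterministic columns)."""
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([asdict(r) for r in records])
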