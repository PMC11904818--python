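"""Readers and writers for the on-disk formats the pipeline touches.

10x-style count directories (MatrixMarket + features/barcodes TSV,
genes x observations on disk), Visium ``tissue_positions`` CSV (with or
without a header line), GMT gene-set collections, label/location TSVs
and deterministic result tables.  All readers validate rather than
silently coerce; all writers emit deterministic byte streams so reruns
can be compared byte-for-byte.
"""

from __future__ import annotations

import gzip
import io
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import CountMatrix, SpotGeometry

__all__ = [
    "read_counts_10x",
    "write_counts_10x",
    "read_tissue_positions",
    "write_tissue_positions",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "write_labels",
    "read_locations",
    "write_locations",
    "write_table",
    "read_table",
    "read_json",
    "write_json",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}(.gz) not found in {dir_path}")


# ----------------------------------------------------------------------
# 10x count directories
# ----------------------------------------------------------------------

def read_counts_10x(dir_path, obs_kind: str = "nucleus", sample_id: str = "") -> CountMatrix:
    """Read a 10x-style directory (matrix.mtx, features.tsv, barcodes.tsv).

    The on-disk matrix may be genes x observations (the 10x convention)
    or observations x genes; orientation is normalized to
    observations x genes using the feature/barcode table lengths.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    feat_path = _find(dir_path, "features.tsv")
    bc_path = _find(dir_path, "barcodes.tsv")

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] == 1:
        gene_ids = feats[0].to_numpy()
        gene_names = gene_ids.copy()
    else:
        gene_ids = feats[0].to_numpy()
        gene_names = feats[1].to_numpy()
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].to_numpy()

    try:
        with _open_maybe_gzip(mtx_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except ValueError as exc:
        raise FormatError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)

    n_genes, n_obs = len(gene_ids), len(barcodes)
    if mat.shape == (n_genes, n_obs):
        mat = mat.T
    elif mat.shape == (n_obs, n_genes):
        pass
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither genes x obs "
            f"({n_genes} x {n_obs}) nor obs x genes"
        )
    return CountMatrix(
        values=sp.csr_matrix(mat),
        obs_ids=barcodes,
        gene_ids=gene_ids,
        gene_names=gene_names,
        obs_kind=obs_kind,
        sample_id=sample_id,
    )


def write_counts_10x(m: CountMatrix, dir_path) -> None:
    """Write a CountMatrix as matrix.mtx / features.tsv / barcodes.tsv.

    The matrix is stored genes x observations with integer entries,
    mirroring CellRanger/SpaceRanger exports.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(m.values.T.astype(np.int64))
    # mmwrite via a text buffer so the byte stream is stable across scipy versions
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    (dir_path / "matrix.mtx").write_bytes(buf.getvalue())
    feats = pd.DataFrame(
        {0: m.gene_ids, 1: m.gene_names, 2: ["Gene Expression"] * m.n_genes}
    )
    feats.to_csv(dir_path / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.obs_ids).to_csv(dir_path / "barcodes.tsv", sep="\t", header=False, index=False)


# ----------------------------------------------------------------------
# Tissue positions
# ----------------------------------------------------------------------

_TP_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def read_tissue_positions(csv_path) -> SpotGeometry:
    """Read a 6-column Visium tissue-positions CSV (header optional)."""
    csv_path = Path(csv_path)
    with _open_maybe_gzip(csv_path) as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().lower() == "barcode"
    df = pd.read_csv(
        csv_path,
        header=0 if has_header else None,
        dtype=str,
    )
    if df.shape[1] != 6:
        raise FormatError(f"tissue positions must have 6 columns, got {df.shape[1]}")
    df.columns = _TP_COLUMNS
    for col in ("in_tissue", "array_row", "array_col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals.dropna() % 1, 0):
            raise FormatError(f"non-integer values in column {col}")
        df[col] = vals.astype(int)
    if not df["in_tissue"].isin((0, 1)).all():
        raise FormatError("in_tissue must be 0 or 1")
    return SpotGeometry(
        barcodes=df["barcode"].to_numpy(),
        in_tissue=df["in_tissue"].to_numpy(),
        array_row=df["array_row"].to_numpy(),
        array_col=df["array_col"].to_numpy(),
        pxl_row=df["pxl_row_in_fullres"].astype(float).to_numpy(),
        pxl_col=df["pxl_col_in_fullres"].astype(float).to_numpy(),
    )


def write_tissue_positions(geom: SpotGeometry, csv_path, header: bool = True) -> None:
    geom.to_frame().to_csv(csv_path, index=False, header=header)


# ----------------------------------------------------------------------
# GMT gene sets
# ----------------------------------------------------------------------

def read_gmt(path) -> dict[str, set]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate set names are an error; duplicate members within a set are
    deduplicated (set semantics).
    """
    sets: dict[str, set] = {}
    with _open_maybe_gzip(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"GMT line {lineno}: fewer than 2 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for name in sorted(sets):
        desc = (descriptions or {}).get(name, "na")
        members = sorted(set(sets[name]))
        lines.append("\t".join([name, desc] + members))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Labels, locations, result tables
# ----------------------------------------------------------------------

def read_labels(path) -> pd.Series:
    """Read a two-column TSV (observation id, label) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    if df.iloc[0, 0] in ("barcode", "obs_id"):
        df = df.iloc[1:]
    if df.shape[1] != 2:
        raise FormatError("labels file must have exactly 2 columns")
    if df[0].duplicated().any():
        raise FormatError("duplicate observation ids in labels file")
    return pd.Series(df[1].to_numpy(), index=pd.Index(df[0].to_numpy()), name="label")


def write_labels(labels: pd.Series, path) -> None:
    df = pd.DataFrame({"obs": labels.index, "label": labels.to_numpy()})
    df = df.sort_values("obs", kind="mergesort")
    df.to_csv(path, sep="\t", header=False, index=False)


def read_locations(path) -> dict[str, set]:
    """Read a gene -> subcellular-location table (gene_id TAB pipe-joined locations)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str).fillna("")
    if df.iloc[0, 0].lower() in ("gene_id", "gene"):
        df = df.iloc[1:]
    if df[0].duplicated().any():
        raise FormatError("duplicate gene ids in location table")
    out: dict[str, set] = {}
    for gene, locs in zip(df[0], df[1] if df.shape[1] > 1 else [""] * len(df)):
        out[gene] = {s.strip() for s in str(locs).split("|") if s.strip()}
    return out


def write_locations(table: Mapping[str, Sequence[str]], path) -> None:
    lines = []
    for gene in sorted(table):
        lines.append(f"{gene}\t{'|'.join(sorted(set(table[gene])))}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path, sort_by: Sequence[str] | None = None) -> None:
    """Write a result table as TSV with deterministic row and column order."""
    df = df.copy()
    for col in df.columns:
        if df[col].map(lambda v: isinstance(v, (dict, list, tuple, set))).any():
            df[col] = df[col].map(
                lambda v: json.dumps(v, sort_keys=True) if isinstance(v, dict) else "|".join(map(str, v))
                if isinstance(v, (list, tuple, set))
                else v
            )
    if sort_by is None:
        sort_by = [c for c in df.columns if df[c].dtype == object][:2]
    if len(df) and sort_by:
        df = df.sort_values(list(sort_by), kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
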