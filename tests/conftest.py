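"""Shared fixtures: small synthetic datasets and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from spatniche.types import CountMatrix


def make_count_matrix(
    counts,
    obs_kind: str = "nucleus",
    gene_names=None,
    prefix: str = "OBS",
    sample_id: str = "S",
) -> CountMatrix:
    counts = np.asarray(counts)
    n, g = counts.shape
    gene_ids = np.array([f"g{j}" for j in range(g)], dtype=object)
    if gene_names is None:
        gene_names = gene_ids.copy()
    return CountMatrix(
        values=sp.csr_matrix(counts),
        obs_ids=np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
        gene_ids=gene_ids,
        gene_names=np.asarray(gene_names, dtype=object),
        obs_kind=obs_kind,
        sample_id=sample_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_reference():
    """A small labelled reference used across deconvolution/marker tests."""
    from spatniche.synthdata import ReferenceSpec, simulate_reference

    spec = ReferenceSpec(
        n_celltypes=4,
        n_genes=300,
        n_nuclei_per_type=60,
        markers_per_type=10,
        seed=7,
        low_quality_fraction=0.0,
        high_mito_fraction=0.0,
    )
    return simulate_reference(spec)


# ----------------------------------------------------------------------
# Independent oracles (pure python, no shared code with the implementation)
# ----------------------------------------------------------------------

def oracle_ranksum_exact_p(x, y) -> float:
    """Exact two-sided rank-sum tail by brute-force enumeration.

    Midranks computed by hand; p = fraction of group assignments whose
    rank-sum deviates from the permutation mean at least as much as the
    observed one.
    """
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0  # average of 1-based positions i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = mid
        i = j
    n1 = len(x)
    n = len(pooled)
    mu = n1 * (n + 1) / 2.0
    w_obs = sum(ranks[:n1])
    dev = abs(w_obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        w = sum(ranks[i] for i in combo)
        if abs(w - mu) >= dev:
            count += 1
    return count / total


def oracle_qc_filter(counts, gene_names, min_genes, max_mito, min_cells, prefix="MT-"):
    """Naive per-nucleus scan applying the three QC rules in order."""
    counts = np.asarray(counts)
    kept_rows = []
    for i in range(counts.shape[0]):
        row = counts[i]
        n_detected = sum(1 for v in row if v > 0)
        total = row.sum()
        mito = sum(v for v, name in zip(row, gene_names) if str(name).startswith(prefix))
        frac = mito / total if total > 0 else 0.0
        if n_detected > min_genes and frac < max_mito:
            kept_rows.append(i)
    kept_genes = []
    for j in range(counts.shape[1]):
        n_cells = sum(1 for i in kept_rows if counts[i, j] > 0)
        if n_cells >= min_cells:
            kept_genes.append(j)
    return kept_rows, kept_genes
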