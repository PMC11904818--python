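"""Marker-gene detection and two-group differential expression.

Marker detection is one-vs-rest per cluster with a Wilcoxon rank-sum
test on normalized expression.  A gene is reported for a cluster only if
it is detected (count > 0) in more than ``min_expr_fraction`` of the
cluster's cells and its average |log2 fold change| exceeds
``min_abs_log2fc`` (defaults 10% and 0.26); fold changes are computed on
de-logged (CPM-scale) means with a pseudocount.

The rank-sum p-value uses the normal approximation with tie correction,
except when both groups have at most :data:`EXACT_MAX` observations, in
which case the exact permutation tail is computed by full enumeration of
all assignments (ties handled via midranks).

Two-group DE on counts uses a negative-binomial Wald test with
method-of-moments dispersion pooled across the two groups; on
normalized expression the Wilcoxon test is used.  The pass flag applies
the raw-p and fold-change thresholds (p < alpha, |log2FC| > 0.26 by
default); Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, DERecord

__all__ = [
    "DEParams",
    "wilcoxon_rank_sum",
    "find_markers",
    "de_between_groups",
    "EXACT_MAX",
]

EXACT_MAX = 8  # exact enumeration when both groups are at most this size


@dataclass
class DEParams:
    min_expr_fraction: float = 0.10
    min_abs_log2fc: float = 0.26
    alpha: float = 0.05
    fc_pseudocount: float = 1.0
    test: str = "wilcoxon"  # "wilcoxon" | "nb_wald"
    mtc: str = "bh"  # "none" | "bh"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_expr_fraction <= 1.0):
            raise ValueError("min_expr_fraction must be in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("wilcoxon", "nb_wald"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.mtc not in ("none", "bh"):
            raise ValueError(f"unknown mtc {self.mtc!r}")


# ----------------------------------------------------------------------
# Wilcoxon rank-sum
# ----------------------------------------------------------------------

def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (midranks for ties).

    p = P(|W - mu| >= |W_obs - mu|) over all C(n1+n2, n1) equally likely
    assignments of the pooled values to group 1, where W is the sum of
    group-1 midranks and mu its permutation mean n1*(N+1)/2.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    w_all = ranks[combos].sum(axis=1)
    dev = np.abs(w_obs - mu)
    count = int((np.abs(w_all - mu) >= dev - 1e-9).sum())
    return count / len(w_all)


def _tie_term(col: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups of one pooled sample."""
    _, counts = np.unique(col, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def _normal_ranksum_p(X: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum p over gene columns.

    ``X`` is the pooled (n1+n2) x genes matrix with group 1 first.
    Tie-corrected variance, no continuity correction.
    """
    n, n_genes = X.shape
    n2 = n - n1
    ranks = stats.rankdata(X, axis=0)
    w = ranks[:n1].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    tie = np.array([_tie_term(X[:, j]) for j in range(n_genes)])
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    p = np.ones(n_genes)
    ok = var > 0
    z = np.zeros(n_genes)
    z[ok] = (w[ok] - mu) / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
    return np.minimum(p, 1.0)


def wilcoxon_rank_sum(x, y, exact_max: int = EXACT_MAX) -> float:
    """Two-sided rank-sum p-value for one gene; exact when both groups <= exact_max."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= exact_max and len(y) <= exact_max:
        return _exact_ranksum_p(x, y)
    pooled = np.concatenate([x, y])[:, None]
    return float(_normal_ranksum_p(pooled, len(x))[0])


def _ranksum_pvalues(x_mat: np.ndarray, y_mat: np.ndarray) -> np.ndarray:
    """Column-wise rank-sum p-values; exact path when both groups are small."""
    n1, n2 = x_mat.shape[0], y_mat.shape[0]
    if n1 <= EXACT_MAX and n2 <= EXACT_MAX:
        return np.array(
            [_exact_ranksum_p(x_mat[:, j], y_mat[:, j]) for j in range(x_mat.shape[1])]
        )
    return _normal_ranksum_p(np.vstack([x_mat, y_mat]), n1)


def _bh(p: np.ndarray, mtc: str) -> np.ndarray:
    if len(p) == 0:
        return p.copy()
    if mtc == "none":
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# Markers
# ----------------------------------------------------------------------

def _dense(values) -> np.ndarray:
    return np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)


def _unlog_means(expr, rows: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Per-gene mean of de-logged (CPM-scale) expression over the given rows."""
    sub = expr[rows]
    if sp.issparse(sub):
        sub = sub.tocsr().copy()
        sub.data = np.power(2.0, sub.data) - pseudocount
        return np.asarray(sub.mean(axis=0)).ravel()
    return (np.power(2.0, np.asarray(sub, dtype=float)) - pseudocount).mean(axis=0)


def find_markers(
    expr,
    labels,
    p: DEParams | None = None,
    gene_ids=None,
) -> list[DERecord]:
    """One-vs-rest marker detection per cluster on normalized (log2-CPM) expression.

    ``expr`` is observations x genes (sparse or dense log2-CPM with
    pseudocount 1, so a positive value marks a detected gene);
    ``labels`` assigns a cluster per observation.  Clusters with fewer
    than 2 observations are skipped with a warning.  Returned records
    carry p (rank-sum), q (BH within cluster) and ``passes_filter``
    meaning p < alpha on top of the fraction/fold-change prefilter.
    """
    if p is None:
        p = DEParams()
    labels = np.asarray(labels)
    if gene_ids is None:
        gene_ids = np.array([f"g{j}" for j in range(expr.shape[1])], dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)
    clusters = sorted(set(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for marker detection")

    records: list[DERecord] = []
    detected = expr > 0
    for cluster in clusters:
        in_c = labels == cluster
        if in_c.sum() < 2:
            warnings.warn(f"cluster {cluster!r} has fewer than 2 observations; skipped")
            continue
        rows_in = np.where(in_c)[0]
        rows_out = np.where(~in_c)[0]
        frac1 = np.asarray(detected[rows_in].sum(axis=0)).ravel() / len(rows_in)
        frac2 = np.asarray(detected[rows_out].sum(axis=0)).ravel() / max(len(rows_out), 1)
        m1 = _unlog_means(expr, rows_in)
        m2 = _unlog_means(expr, rows_out)
        log2fc = np.log2((m1 + p.fc_pseudocount) / (m2 + p.fc_pseudocount))
        candidate = (frac1 > p.min_expr_fraction) & (np.abs(log2fc) > p.min_abs_log2fc)
        idx = np.where(candidate)[0]
        if len(idx) == 0:
            continue
        x = _dense(expr[rows_in][:, idx])
        y = _dense(expr[rows_out][:, idx])
        pvals = _ranksum_pvalues(x, y)
        qvals = _bh(pvals, p.mtc)
        for j, gi in enumerate(idx):
            records.append(
                DERecord(
                    gene_id=str(gene_ids[gi]),
                    group=str(cluster),
                    log2fc=float(log2fc[gi]),
                    expr_fraction_1=float(frac1[gi]),
                    expr_fraction_2=float(frac2[gi]),
                    p_value=float(pvals[j]),
                    q_value=float(qvals[j]),
                    direction="up" if log2fc[gi] > 0 else "down",
                    passes_filter=bool(pvals[j] < p.alpha),
                )
            )
    return records


# ----------------------------------------------------------------------
# Two-group DE
# ----------------------------------------------------------------------

def _nb_wald(
    x_mat: np.ndarray, y_mat: np.ndarray, offset: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """NB Wald test per gene: returns (natural-log ratio, two-sided p).

    Method-of-moments dispersion pooled across the two groups; Wald
    statistic on the log ratio of (offset-shifted) group means with a t
    reference on n1 + n2 - 2 degrees of freedom.
    """
    n1, n2 = x_mat.shape[0], y_mat.shape[0]
    m1 = x_mat.mean(axis=0)
    m2 = y_mat.mean(axis=0)
    s1 = x_mat.var(axis=0, ddof=1)
    s2 = y_mat.var(axis=0, ddof=1)
    num = (n1 - 1) * (s1 - m1) + (n2 - 1) * (s2 - m2)
    den = (n1 - 1) * m1**2 + (n2 - 1) * m2**2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mom = np.where(den > 0, np.maximum(num / np.maximum(den, 1e-300), 0.0), 0.0)
    a1, a2 = m1 + offset, m2 + offset
    # delta method: Var(ln(mbar + c)) ~= Var(mbar) / (m + c)^2 with the NB
    # model variance evaluated at the raw mean (floored for all-zero groups)
    v1 = np.maximum(m1 + alpha_mom * m1**2, offset)
    v2 = np.maximum(m2 + alpha_mom * m2**2, offset)
    se = np.sqrt(v1 / (n1 * a1**2) + v2 / (n2 * a2**2))
    lr = np.log(a1) - np.log(a2)
    tstat = lr / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n1 + n2 - 2)
    return lr, np.minimum(pvals, 1.0)


def de_between_groups(
    data,
    group_labels,
    p: DEParams | None = None,
    gene_ids=None,
    groups: tuple | None = None,
) -> list[DERecord]:
    """Two-group differential expression.

    ``data`` is a :class:`CountMatrix` or a raw matrix (observations x
    genes): counts for ``test='nb_wald'``, log2-CPM for
    ``test='wilcoxon'`` (a CountMatrix is normalized internally for the
    Wilcoxon path).  ``groups=(g1, g2)`` fixes the contrast direction;
    log2fc is group1 over group2.  All-zero genes yield p = 1,
    log2fc = 0 and ``testable=False``.
    """
    if p is None:
        p = DEParams(test="nb_wald")
    group_labels = np.asarray(group_labels)
    uniq = sorted(set(group_labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly 2 groups required, got {uniq}")
    if groups is None:
        groups = (uniq[0], uniq[1])
    g1, g2 = groups
    if sorted((g1, g2)) != uniq:
        raise ValueError("groups argument does not match the labels present")

    if isinstance(data, CountMatrix):
        gene_ids = data.gene_ids
        if p.test == "wilcoxon":
            from .qc_norm import normalize_log_cpm

            values = normalize_log_cpm(data)
        else:
            # library-size normalize counts to the mean library
            libs = data.library_sizes().astype(float)
            if (libs == 0).any():
                libs = np.maximum(libs, 1.0)
            scale = libs.mean() / libs
            values = _dense(data.values) * scale[:, None]
    else:
        values = data
        if gene_ids is None:
            gene_ids = np.array([f"g{j}" for j in range(values.shape[1])], dtype=object)
    gene_ids = np.asarray(gene_ids, dtype=object)

    rows1 = np.where(group_labels == g1)[0]
    rows2 = np.where(group_labels == g2)[0]
    x = _dense(values[rows1])
    y = _dense(values[rows2])
    contrast = f"{g1}_vs_{g2}"

    frac1 = (x > 0).mean(axis=0)
    frac2 = (y > 0).mean(axis=0)
    testable = ~((x.sum(axis=0) == 0) & (y.sum(axis=0) == 0))

    if p.test == "nb_wald":
        lr, pvals = _nb_wald(x, y)
        log2fc = lr / np.log(2.0)
    else:
        m1 = _unlog_means(values, rows1)
        m2 = _unlog_means(values, rows2)
        log2fc = np.log2((m1 + p.fc_pseudocount) / (m2 + p.fc_pseudocount))
        pvals = _ranksum_pvalues(x, y)
    pvals = np.where(testable, pvals, 1.0)
    log2fc = np.where(testable, log2fc, 0.0)
    qvals = _bh(pvals, p.mtc)

    records = []
    for j in range(len(gene_ids)):
        passes = bool(
            testable[j]
            and pvals[j] < p.alpha
            and abs(log2fc[j]) > p.min_abs_log2fc
        )
        records.append(
            DERecord(
                gene_id=str(gene_ids[j]),
                group=contrast,
                log2fc=float(log2fc[j]),
                expr_fraction_1=float(frac1[j]),
                expr_fraction_2=float(frac2[j]),
                p_value=float(pvals[j]),
                q_value=float(qvals[j]),
                direction="up" if log2fc[j] > 0 else "down",
                passes_filter=passes,
                testable=bool(testable[j]),
            )
        )
    return records
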