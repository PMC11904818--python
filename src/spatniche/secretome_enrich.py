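"""Secretory annotation of DEGs, multi-comparison screening and gene-set enrichment.

A DEG is flagged *secreted* when any of its annotated subcellular
locations contains a secreted keyword (case-insensitive substring,
default "Secreted") — i.e. identifier lookup into a provided
UniProt-style location table.  The comparison screen intersects signed
(up/down) DEG sets from several contrasts (e.g. FAPs-high vs FAPs-low
regions, obese vs lean breed within FAPs) into common and unique
partitions with direction bookkeeping.  Over-representation of gene
sets uses the hypergeometric upper tail (R's ``phyper`` semantics) with
Benjamini-Hochberg correction across the tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DERecord, EnrichmentRecord

__all__ = [
    "LocationTable",
    "ComparisonScreen",
    "annotate_secretory",
    "screen_comparisons",
    "hypergeom_enrich",
]


@dataclass
class LocationTable:
    """gene_id -> set of subcellular-location strings."""

    locations: dict
    secreted_keywords: frozenset = frozenset({"Secreted"})

    def __post_init__(self) -> None:
        self.locations = {str(k): set(v) for k, v in self.locations.items()}
        self.secreted_keywords = frozenset(str(k) for k in self.secreted_keywords)

    def is_secreted(self, gene_id: str) -> bool | None:
        """True/False for annotated genes; None when the gene is absent."""
        locs = self.locations.get(gene_id)
        if locs is None:
            return None
        for loc in locs:
            low = loc.lower()
            if any(kw.lower() in low for kw in self.secreted_keywords):
                return True
        return False


def annotate_secretory(records: Sequence[DERecord], table: LocationTable) -> list[DERecord]:
    """Set the ``secreted`` flag on DE records from the location table.

    Genes absent from the table get ``secreted=False`` with
    ``in_location_table=False`` as the distinct missing marker.
    Annotation is idempotent and order independent.
    """
    out = []
    for r in records:
        status = table.is_secreted(r.gene_id)
        out.append(
            DERecord(
                **{
                    **r.__dict__,
                    "secreted": bool(status) if status is not None else False,
                    "in_location_table": status is not None,
                }
            )
        )
    return out


@dataclass
class ComparisonScreen:
    """Result of intersecting signed DEG sets across named comparisons."""

    comparisons: dict  # name -> {"up": set, "down": set}
    common: set = field(default_factory=set)  # genes in every comparison
    common_direction_consistent: set = field(default_factory=set)
    unique: dict = field(default_factory=dict)  # name -> genes only in that comparison
    counts: dict = field(default_factory=dict)

    def partition_of(self, gene: str) -> str | None:
        if gene in self.common:
            return "common"
        for name, genes in self.unique.items():
            if gene in genes:
                return f"unique:{name}"
        return "shared" if any(gene in c["up"] | c["down"] for c in self.comparisons.values()) else None


def screen_comparisons(comparisons: Mapping[str, Mapping[str, set]]) -> ComparisonScreen:
    """Intersect signed DEG sets from >= 2 named comparisons.

    Each comparison maps ``"up"``/``"down"`` to gene sets in that
    comparison's own sign convention.  A gene listed both up and down
    within one comparison is a validation error.  The common set holds
    genes present (either direction) in every comparison; the
    direction-consistent subset keeps those whose direction agrees in
    all of them; unique sets hold genes seen in exactly one comparison.
    """
    if len(comparisons) < 2:
        raise ValueError("need at least 2 comparisons to screen")
    clean: dict[str, dict[str, set]] = {}
    for name, sets in comparisons.items():
        up = set(sets.get("up", set()))
        down = set(sets.get("down", set()))
        both = up & down
        if both:
            raise ValueError(
                f"comparison {name!r}: genes listed both up and down: {sorted(both)[:5]}"
            )
        clean[name] = {"up": up, "down": down}

    alls = {name: c["up"] | c["down"] for name, c in clean.items()}
    common = set.intersection(*alls.values())
    consistent = {
        g
        for g in common
        if len({("up" if g in c["up"] else "down") for c in clean.values()}) == 1
    }
    unique = {
        name: genes - set.union(*(o for n, o in alls.items() if n != name))
        for name, genes in alls.items()
    }
    counts = {
        "common": len(common),
        "common_direction_consistent": len(consistent),
        **{f"n_{name}": len(genes) for name, genes in alls.items()},
        **{f"unique_{name}": len(genes) for name, genes in unique.items()},
    }
    return ComparisonScreen(
        comparisons=clean,
        common=common,
        common_direction_consistent=consistent,
        unique=unique,
        counts=counts,
    )


def hypergeom_enrich(
    query: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    q_threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of each gene set in the query.

    With universe size N, set size K (after intersecting the set with
    the universe), query size n and overlap k, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  Records are BH-corrected across the tested
    sets and sorted by (p, set name).  ``rich_factor`` is k / K.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    if not set(query) <= universe:  # pragma: no cover - defensive
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)

    names, pvals, meta = [], [], []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        # upper tail P(X >= k); k = 0 gives p = 1 exactly
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        names.append(name)
        pvals.append(min(p, 1.0))
        meta.append((K, k))
    if not names:
        return []
    qvals = multipletests(np.array(pvals), method="fdr_bh")[1]
    records = [
        EnrichmentRecord(
            set_name=name,
            universe_size=N,
            set_size=K,
            query_size=n,
            overlap=k,
            p_value=p,
            q_value=float(q),
            rich_factor=k / K,
            significant=bool(q < q_threshold),
        )
        for name, p, q, (K, k) in zip(names, pvals, qvals, meta)
    ]
    records.sort(key=lambda r: (r.p_value, r.set_name))
    return records
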