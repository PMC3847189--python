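"""Hypergeometric over-representation of a gene query in annotated gene sets.

For a query of n genes drawn from a universe of N, a set with K members in
the universe and k in the query gets the upper-tail probability
P(X >= k) under Hypergeometric(N, K, n). Results are filtered on raw p-value
and minimum overlap count — no multiple-testing correction is applied to the
filter, matching common raw-p reporting practice for pathway tables; a
Benjamini-Hochberg FDR column is emitted alongside for context but not used
for filtering.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

P_MAX = 0.05
MIN_COUNT = 3


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int  # overlap of query with the set
    K: int  # set size within the universe
    n: int  # query size
    N: int  # universe size
    p: float
    bh_fdr: float = float("nan")

    def __post_init__(self):
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(f"{self.set_id}: overlap {self.k} outside "
                             f"[0, min({self.K}, {self.n})]")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(query: Iterable[str], universe: Iterable[str],
                     gene_sets: Mapping[str, Iterable[str]],
                     p_max: float = P_MAX, min_count: int = MIN_COUNT,
                     exclusions: Iterable[str] = ()) -> list[EnrichmentResult]:
    """Test every gene set for over-representation of the query.

    Gene sets are intersected with the universe before testing; excluded set
    ids are never tested. Retained results satisfy p < ``p_max`` and overlap
    >= ``min_count`` and are sorted by ascending p (ties by set id).
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("universe and query must be non-empty")
    if not query <= universe:
        raise ValueError(f"{len(query - universe)} query genes outside the universe")
    excluded = set(exclusions)
    N, n = len(universe), len(query)
    results = []
    for set_id, genes in gene_sets.items():
        if set_id in excluded:
            continue
        members = set(genes) & universe
        if not members:
            continue
        k = len(members & query)
        p = hypergeom_pvalue(k, len(members), n, N)
        results.append(EnrichmentResult(set_id, k, len(members), n, N, p))
    if results:
        _, fdrs, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        results = [dataclasses.replace(r, bh_fdr=float(f))
                   for r, f in zip(results, fdrs)]
    kept = [r for r in results if r.p < p_max and r.k >= min_count]
    return sorted(kept, key=lambda r: (r.p, r.set_id))
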