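"""Over-representation analysis of a gene set against a pathway collection.

The statistic is the hypergeometric upper tail P(X >= k) for observing k
query genes inside a pathway of size K, with query size n and universe
size N.  This equals the one-sided Fisher exact p of the corresponding
2x2 table.  Results are filtered at raw p < 0.05 and truncated to the 30
smallest p-values by default; Benjamini-Hochberg adjustment is opt-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSet, NetpharmError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int  # overlap count
    n: int  # query size (inside universe)
    K: int  # pathway size (inside universe)
    N: int  # universe size
    p: float
    p_adj: float | None = None

    @property
    def percentage(self) -> float:
        """Share of the query hit by this pathway, in percent."""
        return 100.0 * self.k / self.n if self.n else 0.0


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts query genes falling in a pathway of size K when n genes are
    drawn without replacement from a universe of N.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"infeasible margins: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy's implementation is
    # log-gamma based and stable for the sizes seen here
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjustment, capped at 1, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    # p * m/m can round below p; the adjusted value must never be smaller
    return np.maximum(out, p).tolist()


def enrich(
    query: GeneSet,
    collection: list[GeneSet],
    universe: GeneSet | int | None = None,
    p_max: float = 0.05,
    top_n: int | None = 30,
    adjust: str = "none",
) -> list[EnrichmentResult]:
    """Test each pathway, filter by p, sort ascending, truncate to top_n.

    The universe defaults to the union of all collection genes.  Query
    genes outside the universe are dropped (shrinking n) and logged.
    Passing an integer universe skips membership restriction and only
    fixes N (pathway sizes are then taken at face value).
    """
    if not collection:
        raise NetpharmError("pathway collection is empty")
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")

    if universe is None:
        members: set[str] = set()
        for gs in collection:
            members |= gs.genes
        universe = GeneSet(label="universe", genes=frozenset(members))

    if isinstance(universe, int):
        N = universe
        query_genes = set(query.genes)
        restrict = None
    else:
        if len(universe) == 0:
            raise NetpharmError("enrichment universe is empty")
        N = len(universe)
        restrict = universe.genes
        query_genes = set(query.genes) & restrict
        n_lost = len(query.genes) - len(query_genes)
        if n_lost:
            logger.warning(
                "%d of %d query genes absent from the universe were dropped",
                n_lost,
                len(query.genes),
            )
    n = len(query_genes)

    results: list[EnrichmentResult] = []
    for gs in collection:
        pathway_genes = gs.genes if restrict is None else gs.genes & restrict
        K = len(pathway_genes)
        if K > N or n > N:
            raise NetpharmError(
                f"pathway {gs.label!r}: sizes exceed universe (K={K}, n={n}, N={N})"
            )
        k = len(query_genes & pathway_genes)
        results.append(
            EnrichmentResult(
                pathway=gs.label, k=k, n=n, K=K, N=N, p=hypergeom_p(k, n, K, N)
            )
        )

    padj = bh_adjust([r.p for r in results])
    results = [
        EnrichmentResult(
            pathway=r.pathway, k=r.k, n=r.n, K=r.K, N=r.N, p=r.p, p_adj=a
        )
        for r, a in zip(results, padj)
    ]

    keyfn = (lambda r: r.p_adj) if adjust == "bh" else (lambda r: r.p)
    kept = [r for r in results if keyfn(r) < p_max]
    kept.sort(key=lambda r: (r.p, r.pathway))
    if top_n is not None:
        kept = kept[:top_n]
    return kept


def bubble_export(results: list[EnrichmentResult], path=None) -> pd.DataFrame:
    """Table with exactly the fields a bubble chart encodes."""
    df = pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "k": r.k,
                "percentage": r.percentage,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in results
        ],
        columns=["pathway", "k", "percentage", "p", "p_adj"],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
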