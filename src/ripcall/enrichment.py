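"""Gene-set over-representation analysis.

Hypergeometric upper-tail test per term with Benjamini-Hochberg FDR
control, over a user-supplied term-to-gene mapping.  For a target list
of n genes drawn from a universe of N genes, a term annotating K
universe genes and containing k target genes is scored

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

and p-values are BH-adjusted within each term category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentTerm", "hypergeom_upper_tail", "bh_fdr", "enrich"]


@dataclass(frozen=True)
class EnrichmentTerm:
    """One tested gene-set term (k of K term genes hit by n of N)."""

    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k: observed successes in the draw; K: successes in the population;
    n: draw size; N: population size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    # sf(k-1) = P(X >= k); scipy computes this stably in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    target_genes: Iterable[str],
    term_map: pd.DataFrame,
    universe: Optional[Iterable[str]] = None,
    *,
    include_zero_overlap: bool = False,
    fdr_scope: str = "category",
) -> pd.DataFrame:
    """Over-representation of each term in the target gene list.

    ``term_map`` needs columns term_id, gene_id and optionally
    term_name, category.  The universe defaults to all genes appearing
    in the mapping; target genes outside it are dropped with a warning.
    FDR is computed within each category (``fdr_scope='global'`` pools
    all terms).  Terms with no target gene are skipped unless
    ``include_zero_overlap``.  Rows are sorted by (category, p_value).
    """
    if fdr_scope not in ("category", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    tm = term_map.copy()
    if "term_name" not in tm.columns:
        tm["term_name"] = tm["term_id"]
    if "category" not in tm.columns:
        tm["category"] = "default"
    universe_set = (set(universe) if universe is not None
                    else set(tm["gene_id"]))
    if not universe_set:
        raise ValueError("empty gene universe")
    targets = set(target_genes)
    dropped = targets - universe_set
    if dropped:
        logger.warning("%d target genes outside the universe dropped",
                       len(dropped))
        targets &= universe_set
    if not targets:
        return pd.DataFrame(
            columns=["term_id", "term_name", "category",
                     "k", "K", "n", "N", "p_value", "fdr"]
        )
    N = len(universe_set)
    n = len(targets)
    rows = []
    grouped = tm[tm["gene_id"].isin(universe_set)].groupby(
        ["category", "term_id"], sort=True
    )
    for (category, term_id), sub in grouped:
        term_genes = set(sub["gene_id"])
        K = len(term_genes)
        k = len(term_genes & targets)
        if k == 0 and not include_zero_overlap:
            continue
        rows.append(
            {"term_id": term_id, "term_name": sub["term_name"].iloc[0],
             "category": category, "k": k, "K": K, "n": n, "N": N,
             "p_value": hypergeom_upper_tail(k, K, n, N)}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["term_id", "term_name", "category",
                     "k", "K", "n", "N", "p_value", "fdr"]
        )
        return df
    if fdr_scope == "category":
        df["fdr"] = df.groupby("category")["p_value"].transform(
            lambda s: bh_fdr(s.to_numpy())
        )
    else:
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return (df.sort_values(["category", "p_value", "term_id"])
            .reset_index(drop=True))
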