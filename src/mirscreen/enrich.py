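"""Hypergeometric over-representation of gene sets within expression clusters.

For a universe of N genes containing K members of a set, and a cluster of
n genes overlapping the set in k, the over-representation p-value is the
upper hypergeometric tail P(X >= k) and the enrichment factor is
EF = (k/n) / (K/N) — the overlap fraction relative to the background
fraction. The tail is computed exactly (log-gamma based survival function,
no normal approximation) so that p-values down to ~1e-300 are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, TargetMap

logger = logging.getLogger("mirscreen")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    N: universe size; K: set members in the universe; n: draws (cluster
    size); k: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_factor(k: int, K: int, n: int, N: int) -> float:
    """EF = (k/n) / (K/N); equals 1 when the overlap matches the background rate."""
    if n <= 0 or K <= 0:
        raise ZeroDivisionError("enrichment factor undefined for empty cluster or set")
    return (k / n) / (K / N)


@dataclass
class EnrichmentResult:
    """One (cluster, set) hypergeometric outcome."""

    cluster_id: str
    set_name: str
    N: int
    K: int
    n: int
    k: int
    EF: float
    pvalue: float
    pval_adj: float = np.nan


def enrich_clusters(
    clusters: dict[str, set[str]],
    sets: GeneSetCollection | TargetMap | dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Test every (cluster, set) pair for over-representation.

    Sets and clusters are intersected with the universe before counting;
    sets disjoint from the universe are skipped with a warning. BH
    adjustment is applied across the whole batch; the raw p-value is kept
    because screening thresholds in this pipeline act on it. Rows are
    sorted by p-value.
    """
    if not universe:
        raise ValueError("empty universe")
    if isinstance(sets, TargetMap):
        set_map = sets.by_mirna()
    elif isinstance(sets, GeneSetCollection):
        set_map = sets.sets
    else:
        set_map = sets
    N = len(universe)
    rows = []
    for set_name in sorted(set_map):
        members = set_map[set_name] & universe
        if not members:
            logger.warning("set %r disjoint from universe; skipped", set_name)
            continue
        K = len(members)
        for cluster_id in sorted(clusters):
            cluster = clusters[cluster_id] & universe
            n = len(cluster)
            if n == 0:
                continue
            k = len(cluster & members)
            rows.append(
                {
                    "cluster": cluster_id,
                    "set": set_name,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "EF": enrichment_factor(k, K, n, N),
                    "pvalue": hypergeom_tail(k, K, n, N),
                }
            )
    df = pd.DataFrame(
        rows, columns=["cluster", "set", "k", "n", "K", "N", "EF", "pvalue"]
    )
    if df.empty:
        return df.assign(pval_adj=pd.Series(dtype=float))
    from .diffexp import bh_adjust

    df["pval_adj"] = bh_adjust(df["pvalue"].to_numpy())
    return df.sort_values(["pvalue", "set", "cluster"], ignore_index=True)
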