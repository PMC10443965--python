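"""Anti-correlation screen nominating candidate regulator miRNAs.

A differentially expressed miRNA is nominated when (1) its predicted
targets are over-represented in a cluster of differentially expressed
genes (hypergeometric tail p below ``p_thresh``) and (2) its own
standardized 6-condition mean expression profile is negatively correlated
(Pearson r below ``r_thresh``) with the mean standardized profile of its
predicted targets inside that cluster. Both organs' condition means enter
one joint correlation. The full (miRNA × cluster) table is emitted,
including failing pairs, for transparency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterResult
from .enrich import enrich_clusters
from .io import TargetMap
from .preprocess import ConditionProfile

logger = logging.getLogger("mirscreen")


@dataclass
class ScreenParams:
    p_thresh: float = 0.01    # enrichment p, strict
    r_thresh: float = -0.4    # Pearson r, strict
    min_targets: int = 5      # floor on targets inside the cluster for a meaningful r


def target_mean_profile(
    cluster_members: set[str],
    mirna_id: str,
    target_map: TargetMap,
    profiles: ConditionProfile,
    min_targets: int = 5,
) -> np.ndarray | None:
    """Mean standardized profile of the miRNA's predicted targets in the cluster.

    Returns None (and logs) when fewer than ``min_targets`` targets with a
    standardized profile fall inside the cluster.
    """
    targets = target_map.targets_of(mirna_id) & cluster_members
    targets &= set(profiles.standardized.index)
    if len(targets) < min_targets:
        logger.debug(
            "%s: %d targets in cluster (< %d); skipped", mirna_id, len(targets), min_targets
        )
        return None
    return profiles.standardized.loc[sorted(targets)].to_numpy().mean(axis=0)


def anticorr(mirna_profile: np.ndarray, target_profile: np.ndarray) -> float:
    """Pearson correlation of the two 6-condition profiles; NaN if either is constant."""
    x = np.asarray(mirna_profile, dtype=float)
    y = np.asarray(target_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def screen_regulators(
    de_mirnas: pd.Index | set[str],
    clusters: ClusterResult,
    target_map: TargetMap,
    mrna_profiles: ConditionProfile,
    mirna_profiles: ConditionProfile,
    universe: set[str],
    params: ScreenParams | None = None,
) -> pd.DataFrame:
    """Joint enrichment + anti-correlation screen over (DE miRNA, cluster) pairs.

    Only differentially expressed miRNAs are screened. Returns a table
    sorted by (pvalue, r) with one row per testable pair and a ``passes``
    flag: passes ⇔ pvalue < p_thresh and r < r_thresh (with at least
    ``min_targets`` targets in the cluster — pairs below the floor or with
    an undefined r are reported with r = NaN and never pass).
    """
    params = params or ScreenParams()
    de_mirnas = sorted(set(de_mirnas) & set(target_map.pairs["mirna_id"].unique()))
    cluster_sets = clusters.cluster_sets()
    sub_map = {
        m: target_map.targets_of(m) for m in de_mirnas
    }
    enr = enrich_clusters(cluster_sets, sub_map, universe)
    rows = []
    for _, e in enr.iterrows():
        mirna = e["set"]
        cid = e["cluster"]
        if mirna not in mirna_profiles.standardized.index:
            continue  # constant or undetected miRNA profile: r undefined
        tprof = target_mean_profile(
            cluster_sets[cid], mirna, target_map, mrna_profiles, params.min_targets
        )
        n_in_cluster = len(
            target_map.targets_of(mirna)
            & cluster_sets[cid]
            & set(mrna_profiles.standardized.index)
        )
        if tprof is None:
            r = float("nan")
        else:
            mprof = mirna_profiles.standardized.loc[mirna].to_numpy()
            r = anticorr(mprof, tprof)
        passes = (
            np.isfinite(r)
            and e["pvalue"] < params.p_thresh
            and r < params.r_thresh
        )
        rows.append(
            {
                "mirna": mirna,
                "cluster": cid,
                "k": e["k"],
                "n": e["n"],
                "K": e["K"],
                "N": e["N"],
                "EF": e["EF"],
                "pvalue": e["pvalue"],
                "pval_adj": e["pval_adj"],
                "r": r,
                "n_targets_in_cluster": n_in_cluster,
                "passes": bool(passes),
            }
        )
    cols = [
        "mirna", "cluster", "k", "n", "K", "N", "EF",
        "pvalue", "pval_adj", "r", "n_targets_in_cluster", "passes",
    ]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return df
    return df.sort_values(["pvalue", "r"], na_position="last", ignore_index=True)


def passing_mirnas(candidates: pd.DataFrame) -> list[str]:
    """Unique miRNAs with at least one passing (cluster) row."""
    if candidates.empty:
        return []
    return sorted(candidates.loc[candidates["passes"], "mirna"].unique())
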