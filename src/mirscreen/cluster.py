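"""Clustering of standardized 6-condition profiles into expression programs.

Differentially expressed features are partitioned — separately for the up-
and down-regulated sets — by k-means over their standardized condition
profiles, with k chosen by maximal mean silhouette over a scanned range.
Two post-passes reproduce the behaviour of homogeneity-driven clusterers
used for this kind of time-course data: features correlating poorly with
their centroid are moved to UNASSIGNED, and clusters that fall below a
minimum size are dissolved. Clusters are then tagged by the shape of their
mean profile (shared vs organ-specific, up/down/transient) with an
absolute-level qualifier from the organs' mean CPM ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .preprocess import ConditionProfile

logger = logging.getLogger("mirscreen")

UNASSIGNED = "UNASSIGNED"


@dataclass
class ClusterParams:
    k_range: tuple[int, int] = (2, 12)
    homogeneity: float = 0.7      # min Pearson r of a member to its centroid
    min_cluster_size: int = 20
    n_restarts: int = 10
    seed: int = 0


@dataclass
class ClusterResult:
    """Assignments of features to clusters plus cluster mean profiles.

    ``assignments`` maps feature -> cluster id (or UNASSIGNED);
    ``cluster_means`` holds each cluster's mean standardized profile;
    ``labels`` maps cluster id -> category tag once ``label_clusters`` ran.
    """

    assignments: pd.Series
    cluster_means: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)

    def members(self, cluster_id: str) -> set[str]:
        return set(self.assignments.index[self.assignments == cluster_id])

    def cluster_sets(self) -> dict[str, set[str]]:
        return {
            cid: self.members(cid)
            for cid in self.cluster_means.index
        }

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_means)


def _row_centroid_correlation(x: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pearson r of each profile row with its assigned centroid."""
    c = centroids[labels]
    xc = x - x.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    num = (xc * cc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (cc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(np.isfinite(r), r, 1.0)  # zero-variance rows trivially homogeneous


def cluster_profiles(
    profiles: ConditionProfile,
    features: set[str] | None = None,
    direction: str = "",
    params: ClusterParams | None = None,
) -> ClusterResult:
    """k-means over standardized profiles with silhouette model selection.

    ``direction`` only prefixes the emitted cluster ids (e.g. "down-1") so
    up- and down-regulated partitions can be merged without collision.
    Deterministic for a fixed ``params.seed``.
    """
    params = params or ClusterParams()
    std = profiles.standardized
    if features is not None:
        feats = [f for f in features if f in std.index]
        std = std.loc[feats]
    prefix = f"{direction}-" if direction else "c"
    if len(std) < params.min_cluster_size:
        logger.warning(
            "only %d features (< min_cluster_size=%d); all left unassigned",
            len(std), params.min_cluster_size,
        )
        return ClusterResult(
            pd.Series(UNASSIGNED, index=std.index, dtype=object),
            pd.DataFrame(columns=std.columns),
        )
    x = std.to_numpy()
    k_lo, k_hi = params.k_range
    k_hi = min(k_hi, len(std) - 1)
    best = None
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=params.n_restarts, random_state=params.seed)
        lab = km.fit_predict(x)
        if len(np.unique(lab)) < 2:
            continue
        score = silhouette_score(x, lab)
        if best is None or score > best[0]:
            best = (score, lab, km.cluster_centers_)
    if best is None:  # degenerate: all profiles identical
        lab = np.zeros(len(std), dtype=int)
        centroids = x[:1].copy()
    else:
        _, lab, centroids = best

    # homogeneity post-pass: poorly-correlated members -> UNASSIGNED
    r = _row_centroid_correlation(x, centroids, lab)
    assigned = r >= params.homogeneity

    # dissolve undersized clusters
    ids = np.unique(lab[assigned])
    for cid in ids:
        if (assigned & (lab == cid)).sum() < params.min_cluster_size:
            assigned &= lab != cid

    kept = sorted(np.unique(lab[assigned]))
    rename = {old: f"{prefix}{i + 1}" for i, old in enumerate(kept)}
    assignments = pd.Series(UNASSIGNED, index=std.index, dtype=object)
    assignments[assigned] = [rename[v] for v in lab[assigned]]
    means = {}
    for old, new in rename.items():
        means[new] = x[assigned & (lab == old)].mean(axis=0)
    cluster_means = pd.DataFrame.from_dict(means, orient="index", columns=std.columns)
    return ClusterResult(assignments, cluster_means)


def _organ_shape(values: np.ndarray, tol: float) -> str:
    """Classify one organ's 3-point profile: up, down, flat or transient.

    "transient" means the middle timepoint is an extremum exceeding both
    endpoints by ``tol``; otherwise the T0->T2 delta decides (monotone rank
    trend, flat when |delta| < tol).
    """
    if len(values) == 3:
        if values[1] > values[0] + tol and values[1] > values[2] + tol:
            return "transient"
        if values[1] < values[0] - tol and values[1] < values[2] - tol:
            return "transient"
    delta = values[-1] - values[0]
    if abs(delta) < tol:
        return "flat"
    return "up" if delta > 0 else "down"


def label_clusters(
    result: ClusterResult,
    profiles: ConditionProfile,
    flatness_tol: float = 0.5,
    level_ratio: float = 2.0,
) -> ClusterResult:
    """Tag each cluster as a shared / organ-specific / transient program.

    Per organ, the standardized mean profile's T0->T2 movement defines a
    trend: monotone rise, monotone fall, or flat (|delta| below
    ``flatness_tol`` standardized units). Same nonzero trend in both organs
    -> "shared-up"/"shared-down"; trend in exactly one organ ->
    "<organ>-specific-<dir>"; a T1 extremum in at least one organ with no
    monotone trend -> "transient". A "high-<organ>" qualifier is added when
    the cluster's mean CPM in one organ exceeds the other by
    ``level_ratio``. Unrecognised shapes get "unlabeled".
    """
    organs = sorted({o for o, _ in profiles.conditions})
    n_tp = len(profiles.conditions) // len(organs)
    labels: dict[str, str] = {}
    for cid in result.cluster_means.index:
        mean = result.cluster_means.loc[cid].to_numpy()
        per_organ = {
            organ: mean[i * n_tp : (i + 1) * n_tp] for i, organ in enumerate(organs)
        }
        shapes = {o: _organ_shape(v, flatness_tol) for o, v in per_organ.items()}

        members = result.members(cid)
        mem_cpm = profiles.mean_cpm.loc[sorted(members & set(profiles.mean_cpm.index))]
        organ_level = [
            mem_cpm.iloc[:, i * n_tp : (i + 1) * n_tp].to_numpy().mean()
            for i in range(len(organs))
        ]
        qualifier = ""
        if min(organ_level) > 0:
            if organ_level[0] / organ_level[1] > level_ratio:
                qualifier = f"-high-{organs[0]}"
            elif organ_level[1] / organ_level[0] > level_ratio:
                qualifier = f"-high-{organs[1]}"

        s = [shapes[o] for o in organs]
        if "transient" in s:
            tag = "transient"
        elif s[0] == s[1] and s[0] in ("up", "down"):
            tag = f"shared-{s[0]}"
        elif "flat" in s and sum(v in ("up", "down") for v in s) == 1:
            organ = organs[0] if s[0] != "flat" else organs[1]
            tag = f"{organ}-specific-{shapes[organ]}"
        else:
            tag = "unlabeled"
        labels[cid] = tag + qualifier
    result.labels = labels
    return result
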