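"""CPM transformation, detection filtering, condition profiles and PCA QC.

The detection rule follows the strict reading of "over X CPM": a feature is
kept iff some single (organ, timepoint) condition has at least
``min_replicates`` samples strictly above ``min_cpm``. Profiles are per-
feature means over replicates within each of the six (organ, timepoint)
conditions; standardization is to mean 0, SD 1 (population SD, divisor n)
across the six log2(condition mean CPM + 1) values, the scale on which
expression profiles are compared before clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("mirscreen")

#: defaults mirroring the published detection rules
MRNA_DETECTION = dict(min_cpm=0.5, min_replicates=3)
MIRNA_DETECTION = dict(min_cpm=1.0, min_replicates=2)


@dataclass
class CPMMatrix:
    """Counts-per-million values with the same shape/design as the source counts."""

    values: pd.DataFrame
    design: list
    feature_kind: str

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class ConditionProfile:
    """Per-feature mean (and standardized) expression over the 6 conditions.

    ``conditions`` is the fixed organ-major ordering
    (A,T0) (A,T1) (A,T2) (B,T0) (B,T1) (B,T2). ``standardized`` contains
    only features with non-zero variance across condition means; the rest
    are listed in ``zero_variance``.
    """

    conditions: list[tuple[str, str]]
    mean_cpm: pd.DataFrame
    standardized: pd.DataFrame
    zero_variance: list[str]

    @property
    def feature_ids(self) -> pd.Index:
        return self.mean_cpm.index


def cpm_transform(counts: CountMatrix) -> CPMMatrix:
    """Scale each sample's counts to counts per million.

    Raises if any sample has a zero library (no reads): CPM is undefined
    there and the sample should be dropped upstream.
    """
    libsizes = counts.counts.sum(axis=0)
    zero = libsizes[libsizes == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    values = counts.counts / libsizes * 1e6
    return CPMMatrix(values, counts.design, counts.feature_kind)


def detection_filter(
    cpm: CPMMatrix, min_cpm: float, min_replicates: int
) -> pd.Index:
    """Features detected in at least one (organ, timepoint) condition.

    A condition "detects" a feature when ≥ ``min_replicates`` of its
    replicates are strictly above ``min_cpm``.
    """
    conds: dict[tuple[str, str], list[str]] = {}
    for d in cpm.design:
        conds.setdefault((d.organ, d.timepoint), []).append(d.sample_id)
    if min_replicates > max(len(s) for s in conds.values()):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds the largest condition "
            f"({max(len(s) for s in conds.values())} replicates)"
        )
    keep = np.zeros(len(cpm.values), dtype=bool)
    for samples in conds.values():
        above = (cpm.values[samples] > min_cpm).sum(axis=1)
        keep |= (above >= min_replicates).to_numpy()
    retained = cpm.values.index[keep]
    if len(retained) == 0:
        logger.warning("detection filter retained no features")
    return retained


def condition_profiles(cpm: CPMMatrix, features=None) -> ConditionProfile:
    """Mean CPM per (organ, timepoint) condition and the standardized profiles.

    Standardization acts on log2(mean CPM + 1) — the scale on which
    expression profiles are conventionally compared and clustered —
    subtracting the per-feature mean of the six condition values and
    dividing by their population SD. Constant (zero-variance) features are
    flagged and excluded from the standardized table.
    """
    values = cpm.values if features is None else cpm.values.loc[list(features)]
    organs = tuple(sorted({d.organ for d in cpm.design}))
    from .io import infer_timepoint_order

    timepoints = infer_timepoint_order(d.timepoint for d in cpm.design)
    conditions = [(o, t) for o in organs for t in timepoints]
    cols = {}
    for organ, tp in conditions:
        samples = [
            d.sample_id for d in cpm.design if d.organ == organ and d.timepoint == tp
        ]
        if not samples:
            raise ValueError(f"no samples for condition ({organ}, {tp})")
        cols[f"{organ}:{tp}"] = values[samples].mean(axis=1)
    mean_cpm = pd.DataFrame(cols)
    arr = np.log2(mean_cpm.to_numpy() + 1.0)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population SD (divisor n)
    zero_var = sd[:, 0] == 0
    std = pd.DataFrame(
        (arr[~zero_var] - mu[~zero_var]) / sd[~zero_var],
        index=mean_cpm.index[~zero_var],
        columns=mean_cpm.columns,
    )
    zv = mean_cpm.index[zero_var].tolist()
    if zv:
        logger.info("%d zero-variance features excluded from standardization", len(zv))
    return ConditionProfile(conditions, mean_cpm, std, zv)


def pca_qc(
    cpm: CPMMatrix, n_top: int = 500, n_components: int = 5
) -> tuple[np.ndarray, pd.DataFrame]:
    """QC PCA on log2(CPM+1) of the most-variable features.

    Returns (variance fractions over all PCs, sample scores for the first
    ``n_components`` PCs). Scores are centered; fractions sum to 1. The
    log-CPM on top-variance features is the annotation-free stand-in for a
    variance-stabilized PCA.
    """
    if cpm.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    log_expr = np.log2(cpm.values + 1.0)
    variances = log_expr.var(axis=1)
    top = variances.sort_values(ascending=False).index[: min(n_top, len(variances))]
    x = log_expr.loc[top].to_numpy().T  # samples × features
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("all samples identical on selected features; PCA undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=cpm.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return fractions, scores
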