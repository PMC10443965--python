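"""Per-organ differential expression of each later timepoint vs the T0 baseline.

A feature is differentially expressed when it passes three criteria
jointly: FDR below a kind-specific alpha (1% for mRNA, 5% for miRNA), an
estimated fold change above a kind-specific minimum (2.5 for mRNA, 1.5 for
miRNA), and direction consistency — every replicate of the later timepoint
falls on the same side of the baseline condition mean.

The test is a plain two-group negative-binomial Wald test: median-of-ratios
size factors, per-feature method-of-moments dispersion (floored), group
means fitted by Newton iteration on the NB score equation with a log link,
and a normal Wald statistic on the log fold change. Dispersion-trend and
fold-change shrinkage, independent filtering and outlier handling are
deliberately out of scope: the downstream calls depend only on
(p, fold change, consistency). ``fit_nb_test`` accepts a ``backend``
callable so an external NB engine can be substituted; the native test is
the reference implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix
from .preprocess import CPMMatrix

logger = logging.getLogger("mirscreen")

_MIN_Q = 1e-8  # floor for fitted group means (normalized scale)


@dataclass(frozen=True)
class DEContrast:
    """Later timepoint vs the first (baseline) timepoint within one organ."""

    organ: str
    timepoint: str  # T1 or T2 equivalent; baseline is always the first timepoint


@dataclass
class DEConfig:
    """Thresholds of the three-criterion differential-expression call."""

    alpha_fdr: float = 0.01
    fc_min: float = 2.5

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fdr < 1:
            raise ValueError("alpha_fdr must lie in (0, 1)")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")

    @classmethod
    def for_kind(cls, feature_kind: str) -> "DEConfig":
        if feature_kind == "miRNA":
            return cls(alpha_fdr=0.05, fc_min=1.5)
        return cls(alpha_fdr=0.01, fc_min=2.5)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over features with all-positive counts."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no feature has all-positive counts; cannot estimate size factors")
    log_geo_mean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo_mean, axis=0)
    return np.exp(ratios.median(axis=0))


def _fit_group_means(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 25
) -> np.ndarray:
    """MLE of the normalized group mean q per feature, fixed dispersion.

    Solves the NB score equation sum_i (y_i - s_i q) / (1 + alpha s_i q) = 0
    by damped Newton on q, vectorized over features. y: features × samples.
    """
    q = y.sum(axis=1) / s.sum()
    q = np.maximum(q, _MIN_Q)
    for _ in range(n_iter):
        mu = s[None, :] * q[:, None]
        denom = 1.0 + alpha[:, None] * mu
        f = ((y - mu) / denom).sum(axis=1)
        fprime = -((s[None, :] * (1.0 + alpha[:, None] * y)) / denom**2).sum(axis=1)
        step = np.where(fprime != 0, f / fprime, 0.0)
        q_new = np.maximum(q - step, _MIN_Q)
        if np.allclose(q_new, q, rtol=1e-10, atol=1e-12):
            q = q_new
            break
        q = q_new
    return q


def moment_dispersion(norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments dispersion from normalized counts.

    Uses the pooled within-group sample variance v and the overall mean m:
    alpha = (v - m) / m**2. Depending only on normalized counts keeps the
    test exactly invariant to rescaling every sample's counts (the Poisson
    term is only approximate under unequal size factors, which is
    negligible at bulk depths). Each feature's estimate is then floored
    at the median estimate over all features (and at 1e-8 absolutely): with
    few replicates the raw moment estimate is extremely noisy and its
    underestimates — not its overestimates — are what inflate the Wald
    test, so a pooled lower bound restores calibration without imposing a
    mean-dispersion trend.
    """
    m = norm.mean(axis=1)
    num = 0.0
    dof = 0
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] >= 2:
            num = num + sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
            dof += sub.shape[1] - 1
    if dof == 0:
        raise ValueError("need >= 2 replicates in at least one group for dispersion")
    v = num / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    pooled = float(np.median(alpha[m > 0])) if np.any(m > 0) else 0.0
    return np.maximum(alpha, max(pooled, 1e-8))


def fit_nb_test(
    counts: CountMatrix,
    contrast: DEContrast,
    backend: Callable[..., pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test of the contrast's timepoint vs baseline.

    Returns a DataFrame indexed by feature with columns log2fc, pvalue,
    base_mean. Features with zero counts in both groups get NaN p-values
    and are excluded from multiple-testing correction downstream.
    """
    baseline_tp = counts.timepoints[0]
    if contrast.timepoint == baseline_tp:
        raise ValueError("contrast timepoint equals the baseline")
    base_samples = counts.condition_samples(contrast.organ, baseline_tp)
    later_samples = counts.condition_samples(contrast.organ, contrast.timepoint)
    if len(base_samples) < 2 or len(later_samples) < 2:
        raise ValueError(
            f"contrast ({contrast.organ}, {contrast.timepoint}) needs >= 2 samples per group"
        )
    if backend is not None:
        return backend(counts, contrast)

    sub = counts.counts[base_samples + later_samples]
    groups = np.array([0] * len(base_samples) + [1] * len(later_samples))
    sf = size_factors(sub).to_numpy()
    y = sub.to_numpy(dtype=float)
    norm = y / sf[None, :]
    alpha = moment_dispersion(norm, groups)

    q0 = _fit_group_means(y[:, groups == 0], sf[groups == 0], alpha)
    q1 = _fit_group_means(y[:, groups == 1], sf[groups == 1], alpha)

    # Fisher information of beta_g = ln q_g: sum_i mu_i / (1 + alpha mu_i)
    def info(q: np.ndarray, s: np.ndarray) -> np.ndarray:
        mu = s[None, :] * q[:, None]
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    i0 = info(q0, sf[groups == 0])
    i1 = info(q1, sf[groups == 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / i0 + 1.0 / i1)
        z = (np.log(q1) - np.log(q0)) / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = (np.log(q1) - np.log(q0)) / np.log(2.0)

    all_zero = y.sum(axis=1) == 0
    pvalue[all_zero] = np.nan
    log2fc[all_zero] = 0.0
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "base_mean": norm.mean(axis=1)},
        index=sub.index,
    )


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaNs are passed through and excluded from the number of tests m.
    Values outside [0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if ((pm < 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(m)
    result[order] = adjusted
    out[mask] = result
    return out


def consistency_filter(cpm: CPMMatrix, contrast: DEContrast) -> pd.Series:
    """Direction consistency of each later-timepoint replicate vs the baseline mean.

    TRUE iff sign(CPM_rep - mean baseline CPM) is identical and nonzero for
    every replicate of the later timepoint. Exact ties (a replicate equal
    to the baseline mean) fail.
    """
    from .io import infer_timepoint_order

    baseline_tp = infer_timepoint_order(d.timepoint for d in cpm.design)[0]
    base = [
        d.sample_id for d in cpm.design
        if d.organ == contrast.organ and d.timepoint == baseline_tp
    ]
    later = [
        d.sample_id for d in cpm.design
        if d.organ == contrast.organ and d.timepoint == contrast.timepoint
    ]
    baseline_mean = cpm.values[base].mean(axis=1)
    diffs = cpm.values[later].sub(baseline_mean, axis=0)
    signs = np.sign(diffs.to_numpy())
    consistent = (np.abs(signs.sum(axis=1)) == signs.shape[1]) & (signs != 0).all(axis=1)
    return pd.Series(consistent, index=cpm.values.index)


@dataclass
class DEResult:
    """Per-contrast statistics plus the per-feature summary calls.

    ``table`` has one row per (feature, contrast) with columns organ,
    timepoint, log2fc, pvalue, fdr, consistent, is_de, direction.
    ``feature_calls`` summarises each feature over all contrasts: whether
    it is DE anywhere, its direction for clustering membership (conflicts
    resolved by the larger |log2fc| and flagged), and for miRNA-style
    calling whether the criteria were met at either later timepoint.
    """

    table: pd.DataFrame
    feature_calls: pd.DataFrame
    config: DEConfig = field(default_factory=DEConfig)

    def de_features(self, direction: str | None = None) -> pd.Index:
        calls = self.feature_calls[self.feature_calls["is_de"]]
        if direction is not None:
            calls = calls[calls["direction"] == direction]
        return calls.index


def call_degs(
    counts: CountMatrix,
    cpm: CPMMatrix,
    config: DEConfig | None = None,
    features: pd.Index | None = None,
    backend: Callable[..., pd.DataFrame] | None = None,
) -> DEResult:
    """Run all four contrasts (2 organs × 2 later timepoints) and call DEGs.

    FDR adjustment is applied per contrast across the tested features.
    A feature's summary direction is "up"/"down" if it is DE with that
    direction in any contrast; conflicting directions across contrasts are
    resolved by the larger |log2fc| and flagged in ``direction_conflict``.
    """
    config = config or DEConfig.for_kind(counts.feature_kind)
    if features is not None:
        counts = counts.subset_features(list(features))
        cpm = CPMMatrix(cpm.values.loc[list(features)], cpm.design, cpm.feature_kind)
    timepoints = counts.timepoints
    lfc_min = np.log2(config.fc_min)
    rows = []
    for organ in counts.organs:
        for tp in timepoints[1:]:
            contrast = DEContrast(organ, tp)
            res = fit_nb_test(counts, contrast, backend=backend)
            res["fdr"] = bh_adjust(res["pvalue"])
            res["consistent"] = consistency_filter(cpm, contrast)
            res["is_de"] = (
                (res["fdr"] < config.alpha_fdr)
                & (res["log2fc"].abs() > lfc_min)
                & res["consistent"]
            ).fillna(False)
            res["direction"] = np.where(
                ~res["is_de"], "none", np.where(res["log2fc"] > 0, "up", "down")
            )
            res.insert(0, "timepoint", tp)
            res.insert(0, "organ", organ)
            rows.append(res.rename_axis("feature_id").reset_index())
    table = pd.concat(rows, ignore_index=True)

    de_rows = table[table["is_de"]]
    direction = {}
    conflict = {}
    best_lfc = {}
    for _, row in de_rows.iterrows():
        fid = row["feature_id"]
        if fid not in direction:
            direction[fid] = row["direction"]
            best_lfc[fid] = abs(row["log2fc"])
            conflict[fid] = False
        else:
            if row["direction"] != direction[fid]:
                conflict[fid] = True
            if abs(row["log2fc"]) > best_lfc[fid]:
                best_lfc[fid] = abs(row["log2fc"])
                direction[fid] = row["direction"]
    n_flagged = sum(conflict.values())
    if n_flagged:
        logger.warning("%d features DE in conflicting directions across contrasts", n_flagged)
    feature_calls = pd.DataFrame(
        {
            "is_de": [fid in direction for fid in counts.feature_ids],
            "direction": [direction.get(fid, "none") for fid in counts.feature_ids],
            "direction_conflict": [conflict.get(fid, False) for fid in counts.feature_ids],
        },
        index=counts.feature_ids,
    )
    return DEResult(table, feature_calls, config)
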