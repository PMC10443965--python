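"""CPM, detection filtering, condition profiles and PCA QC."""

import numpy as np
import pandas as pd
import pytest

from mirscreen import (
    CountMatrix,
    SampleDesign,
    condition_profiles,
    cpm_transform,
    detection_filter,
    pca_qc,
)


def make_matrix(counts: dict, design: list[SampleDesign], kind="mRNA") -> CountMatrix:
    df = pd.DataFrame(counts, index=[d.sample_id for d in design]).T
    return CountMatrix(df, design, kind)


def two_cond_design(n_rep=3):
    design = []
    for tp in ("T0", "T1"):
        for r in range(1, n_rep + 1):
            design.append(SampleDesign(f"A_{tp}_r{r}", "A", tp, r))
    return design


def test_cpm_basic_values():
    design = [SampleDesign("s1", "A", "T0", 1), SampleDesign("s2", "A", "T0", 2)]
    df = pd.DataFrame(
        {"s1": [250000, 250000, 500000], "s2": [1, 0, 1999999]},
        index=["g1", "g2", "g3"],
    )
    cpm = cpm_transform(CountMatrix(df, design))
    assert list(cpm.values["s1"]) == [250000.0, 250000.0, 500000.0]
    assert cpm.values.loc["g1", "s2"] == pytest.approx(0.5)
    assert cpm.values.loc["g2", "s2"] == 0.0
    assert np.allclose(cpm.values.sum(axis=0), 1e6)


def test_cpm_zero_sum_sample_errors():
    design = [SampleDesign("s1", "A", "T0", 1), SampleDesign("empty", "A", "T0", 2)]
    df = pd.DataFrame({"s1": [5], "empty": [0]}, index=["g1"])
    with pytest.raises(ValueError, match="empty"):
        cpm_transform(CountMatrix(df, design))


def test_cpm_scale_invariance(small_dataset):
    cm = small_dataset.mrna
    cpm1 = cpm_transform(cm)
    scaled = CountMatrix(cm.counts * 7, cm.design, cm.feature_kind)
    cpm2 = cpm_transform(scaled)
    pd.testing.assert_frame_equal(cpm1.values, cpm2.values)


def detection_case(cpms_by_condition, min_cpm, min_replicates):
    """Build a one-feature matrix from per-condition CPM triples and filter it."""
    design, col = [], {}
    i = 0
    for tp, values in cpms_by_condition.items():
        for r, v in enumerate(values, start=1):
            sid = f"A_{tp}_r{r}"
            design.append(SampleDesign(sid, "A", tp, r))
            col[sid] = v
            i += 1
    # express CPMs exactly: library 1e6 per sample, counts = CPM
    df = pd.DataFrame({sid: [col[sid], 1_000_000 - col[sid]] for sid in col},
                      index=["target", "filler"])
    cpm = cpm_transform(CountMatrix(df.astype(int), design))
    kept = detection_filter(cpm, min_cpm=min_cpm, min_replicates=min_replicates)
    return "target" in kept


def test_detection_above_threshold_retained():
    # 0.6/0.7/0.55 CPM in one condition clears "over 0.5 CPM in three replicates"
    assert detection_case({"T0": [1, 1, 1], "T1": [0, 0, 0]}, 0.5, 3)


def test_detection_boundary_is_strict():
    # exactly at the threshold everywhere -> dropped ("over" is strict)
    df_cpms = {"T0": [0.5, 0.5, 0.5]}
    design = [SampleDesign(f"A_T0_r{r}", "A", "T0", r) for r in (1, 2, 3)]
    df = pd.DataFrame(
        {d.sample_id: [1, 1_999_999] for d in design}, index=["target", "filler"]
    )
    cpm = cpm_transform(CountMatrix(df, design))
    assert np.allclose(cpm.values.loc["target"], 0.5)
    assert "target" not in detection_filter(cpm, min_cpm=0.5, min_replicates=3)


def test_detection_mirna_two_of_three():
    # above 1 CPM in 2 of 3 replicates of one condition satisfies the miRNA rule
    assert detection_case({"T0": [2, 2, 0]}, 1.0, 2)
    assert not detection_case({"T0": [2, 0, 0]}, 1.0, 2)


def test_detection_monotone_in_both_knobs(small_dataset):
    cpm = cpm_transform(small_dataset.mrna)
    base = set(detection_filter(cpm, 0.5, 2))
    assert set(detection_filter(cpm, 2.0, 2)) <= base
    assert set(detection_filter(cpm, 0.5, 3)) <= base


def test_detection_min_replicates_too_large(small_dataset):
    cpm = cpm_transform(small_dataset.mrna)
    with pytest.raises(ValueError, match="min_replicates"):
        detection_filter(cpm, 0.5, 99)


def full_design(n_rep=2):
    return [
        SampleDesign(f"{o}_{t}_r{r}", o, t, r)
        for o in ("A", "B")
        for t in ("T0", "T1", "T2")
        for r in range(1, n_rep + 1)
    ]


def test_profiles_standardized_rows():
    design = full_design()
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.integers(10, 1000, size=(20, len(design))),
        index=[f"g{i}" for i in range(20)],
        columns=[d.sample_id for d in design],
    )
    prof = condition_profiles(cpm_transform(CountMatrix(df, design)))
    arr = prof.standardized.to_numpy()
    assert np.abs(arr.mean(axis=1)).max() < 1e-8
    assert np.abs(arr.std(axis=1) - 1).max() < 1e-8
    assert prof.conditions == [
        ("A", "T0"), ("A", "T1"), ("A", "T2"),
        ("B", "T0"), ("B", "T1"), ("B", "T2"),
    ]


def test_constant_feature_flagged_zero_variance():
    design = full_design()
    df = pd.DataFrame(
        {d.sample_id: [5, np.random.default_rng(1).integers(1, 100)] for d in design},
        index=["const", "varies"],
    )
    # make the library sizes equal so "const" is constant in CPM too
    df.loc["filler"] = 1000 - df.sum(axis=0)
    cm = CountMatrix(df.astype(int), design)
    prof = condition_profiles(cpm_transform(cm))
    assert "const" in prof.zero_variance
    assert "const" not in prof.standardized.index


def test_profiles_invariant_to_replicate_order(small_dataset):
    cm = small_dataset.mrna
    perm = list(range(len(cm.design)))
    rng = np.random.default_rng(3)
    rng.shuffle(perm)
    design = [cm.design[i] for i in perm]
    shuffled = CountMatrix(cm.counts.iloc[:, perm], design, cm.feature_kind)
    p1 = condition_profiles(cpm_transform(cm))
    p2 = condition_profiles(cpm_transform(shuffled))
    pd.testing.assert_frame_equal(p1.mean_cpm, p2.mean_cpm)


def test_pca_variance_fractions_sum_to_one(small_dataset):
    fracs, scores = pca_qc(cpm_transform(small_dataset.mrna))
    assert fracs.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.allclose(scores.mean(axis=0), 0, atol=1e-6)


def test_pca_identical_samples_error():
    design = [SampleDesign("s1", "A", "T0", 1), SampleDesign("s2", "A", "T0", 2)]
    df = pd.DataFrame({"s1": [10, 20], "s2": [10, 20]}, index=["g1", "g2"])
    with pytest.raises(ValueError, match="identical"):
        pca_qc(cpm_transform(CountMatrix(df, design)))


def test_pca_separates_organs(default_dataset):
    """On the synthetic fixture, PC1 scores separate the two organs."""
    from sklearn.metrics import silhouette_score

    fracs, scores = pca_qc(cpm_transform(default_dataset.mrna))
    organs = [d.organ for d in default_dataset.mrna.design]
    sil = silhouette_score(scores[["PC1"]].to_numpy(), organs)
    assert sil > 0
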