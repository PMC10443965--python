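"""NB Wald test, BH adjustment, consistency filter and DEG calling."""

import numpy as np
import pandas as pd
import pytest

from mirscreen import (
    CountMatrix,
    DEConfig,
    DEContrast,
    SampleDesign,
    bh_adjust,
    call_degs,
    consistency_filter,
    cpm_transform,
    fit_nb_test,
    simulate_dataset,
)

from conftest import small_config


# --------------------------------------------------------------------------
# BH adjustment
# --------------------------------------------------------------------------


def bh_reference(p):
    """Literal O(m^2) step-up definition, independent of the implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        out[idx] = min(1.0, min(candidates))
    return out


def test_bh_hand_computed_example():
    # p(i)*m/i = .04,.04,.04,.04; cumulative min from the largest keeps .04
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_matches_reference_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        m = rng.integers(1, 40)
        p = rng.uniform(size=m)
        assert np.allclose(bh_adjust(p), bh_reference(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.uniform(size=200)
    assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


def test_bh_permutation_equivariance():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=30)
    perm = rng.permutation(30)
    assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


def test_bh_nan_passthrough_excluded_from_m():
    p = np.array([0.01, np.nan, 0.02])
    adj = bh_adjust(p)
    assert np.isnan(adj[1])
    assert np.allclose(adj[[0, 2]], bh_adjust([0.01, 0.02]))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40)
)
def test_bh_properties_hold_for_arbitrary_p_vectors(p):
    """BH output stays in [0,1], never falls below the raw p ranking order,
    and agrees with the literal step-up reference."""
    adj = bh_adjust(p)
    assert ((adj >= 0) & (adj <= 1)).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in the p ordering
    assert np.allclose(adj, bh_reference(p), atol=1e-12)


# --------------------------------------------------------------------------
# consistency filter
# --------------------------------------------------------------------------


def consistency_case(baseline, later):
    design, cols = [], {}
    for i, v in enumerate(baseline, 1):
        sid = f"A_T0_r{i}"
        design.append(SampleDesign(sid, "A", "T0", i))
        cols[sid] = v
    for i, v in enumerate(later, 1):
        sid = f"A_T1_r{i}"
        design.append(SampleDesign(sid, "A", "T1", i))
        cols[sid] = v
    df = pd.DataFrame({s: [c, 1_000_000 - c] for s, c in cols.items()},
                      index=["target", "filler"])
    cpm = cpm_transform(CountMatrix(df.astype(int), design))
    return bool(consistency_filter(cpm, DEContrast("A", "T1"))["target"])


def test_consistency_flipped_replicate_fails():
    assert not consistency_case([10, 10, 10], [25, 30, 2])


def test_consistency_all_same_side_passes():
    assert consistency_case([10, 10, 10], [26, 31, 24])
    assert consistency_case([30, 30, 30], [4, 2, 9])


def test_consistency_exact_tie_fails():
    assert not consistency_case([10, 10, 10], [26, 31, 10])


# --------------------------------------------------------------------------
# NB Wald test
# --------------------------------------------------------------------------


def null_counts(seed=0, n=2000):
    return simulate_dataset(
        small_config(seed=seed, n_genes=n, coupling_strength=0.0,
                     archetypes=(), n_regulators=0)
    ).mrna


def test_equal_means_give_small_lfc_and_large_p():
    """Features whose observed group means coincide get ~zero lfc and large p;
    under pure null draws the p distribution stays roughly uniform."""
    cm = simulate_dataset(
        small_config(seed=11, n_genes=2000, coupling_strength=0.0,
                     archetypes=(), n_regulators=0, libsize_log_sd=0.0)
    ).mrna
    # equal library sizes -> identical counts mean identical normalized means
    counts = cm.counts.copy()
    base = cm.condition_samples("A", "T0")
    later = cm.condition_samples("A", "T1")
    for g in counts.index[:20]:
        counts.loc[g, later] = counts.loc[g, base].to_numpy()
    res = fit_nb_test(CountMatrix(counts, cm.design), DEContrast("A", "T1"))
    planted = res.iloc[:20].dropna()
    assert (planted["log2fc"].abs() < 0.1).all()
    assert (planted["pvalue"] > 0.5).all()
    assert res["pvalue"].dropna().median() > 0.3


def test_scale_invariance_doubling_counts():
    """Doubling every sample's counts leaves results essentially unchanged:
    the only leak is the (tiny at bulk depth) Poisson term of the dispersion
    estimate, which re-weights the group-mean MLE under unequal size factors."""
    cm = null_counts(seed=3, n=400)
    res1 = fit_nb_test(cm, DEContrast("A", "T2"))
    doubled = CountMatrix(cm.counts * 2, cm.design, cm.feature_kind)
    res2 = fit_nb_test(doubled, DEContrast("A", "T2"))
    assert np.abs(res1["log2fc"] - res2["log2fc"]).max() < 0.01
    p1, p2 = res1["pvalue"].dropna(), res2["pvalue"].dropna()
    assert np.abs(p1 - p2).max() < 0.01


def test_group_swap_negates_lfc_preserves_p():
    cm = null_counts(seed=4, n=300)
    res = fit_nb_test(cm, DEContrast("A", "T1"))
    # swap the group labels by exchanging timepoint labels in the design
    swapped_design = [
        SampleDesign(d.sample_id, d.organ,
                     {"T0": "T1", "T1": "T0"}.get(d.timepoint, d.timepoint),
                     d.replicate)
        for d in cm.design
    ]
    res_sw = fit_nb_test(
        CountMatrix(cm.counts, swapped_design, cm.feature_kind), DEContrast("A", "T1")
    )
    assert np.allclose(res["log2fc"], -res_sw["log2fc"], atol=1e-8)
    assert np.allclose(res["pvalue"].dropna(), res_sw["pvalue"].dropna(), atol=1e-9)


def test_all_zero_feature_gets_nan_p():
    cm = null_counts(seed=5, n=200)
    counts = cm.counts.copy()
    counts.iloc[0] = 0
    res = fit_nb_test(CountMatrix(counts, cm.design), DEContrast("A", "T1"))
    assert np.isnan(res["pvalue"].iloc[0])


def test_too_few_replicates_rejected():
    design = [
        SampleDesign("a", "A", "T0", 1),
        SampleDesign("b", "A", "T1", 1),
        SampleDesign("c", "A", "T1", 2),
    ]
    df = pd.DataFrame(
        np.ones((3, 3), dtype=int) * 10, index=list("xyz"),
        columns=["a", "b", "c"],
    )
    with pytest.raises(ValueError, match="2 samples"):
        fit_nb_test(CountMatrix(df, design), DEContrast("A", "T1"))


# --------------------------------------------------------------------------
# DEG calling
# --------------------------------------------------------------------------


def test_fc_threshold_uses_log2_arithmetic():
    """A clean 2-fold change (log2fc = 1.0) fails fc_min=2.5 (needs > 1.32)
    however significant, but passes a 1.9-fold threshold."""
    design = []
    cols = {}
    rng = np.random.default_rng(8)
    for o in ("A", "B"):
        for t in ("T0", "T1", "T2"):
            for r in (1, 2, 3):
                sid = f"{o}_{t}_r{r}"
                design.append(SampleDesign(sid, o, t, r))
                flat = rng.poisson(500, size=60)
                target = 2000 if (o == "A" and t != "T0") else 1000
                cols[sid] = np.concatenate([[target], flat])
    df = pd.DataFrame(cols, index=["doubler"] + [f"f{i}" for i in range(60)])
    cm = CountMatrix(df, design)
    cpm = cpm_transform(cm)
    strict = call_degs(cm, cpm, DEConfig(alpha_fdr=0.01, fc_min=2.5))
    loose = call_degs(cm, cpm, DEConfig(alpha_fdr=0.01, fc_min=1.9))
    assert not strict.feature_calls.loc["doubler", "is_de"]
    assert loose.feature_calls.loc["doubler", "is_de"]
    lfc = loose.table.query("feature_id == 'doubler' and organ == 'A'")["log2fc"]
    assert np.allclose(lfc, 1.0, atol=0.15)


def test_three_criterion_call_on_fixture(default_dataset, default_result):
    """DE calls require all of: FDR, fold change, and consistency."""
    table = default_result.mrna_de.table
    de = table[table["is_de"]]
    assert (de["fdr"] < 0.01).all()
    assert (de["log2fc"].abs() > np.log2(2.5)).all()
    assert de["consistent"].all()
    # and the planted down-regulated genes are overwhelmingly recovered
    truth = default_dataset.truth.gene_archetype
    down = [g for g, a in truth.items() if a == "shared-down"]
    calls = default_result.mrna_de.feature_calls.loc[down]
    assert (calls["direction"] == "down").mean() > 0.9


def test_deg_set_shrinks_as_thresholds_tighten(small_dataset):
    cpm = cpm_transform(small_dataset.mrna)
    loose = call_degs(small_dataset.mrna, cpm, DEConfig(0.05, 1.5))
    tight_fc = call_degs(small_dataset.mrna, cpm, DEConfig(0.05, 3.0))
    tight_a = call_degs(small_dataset.mrna, cpm, DEConfig(0.001, 1.5))
    assert set(tight_fc.de_features()) <= set(loose.de_features())
    assert set(tight_a.de_features()) <= set(loose.de_features())


def test_mirna_called_de_if_either_later_timepoint(default_dataset, default_result):
    """The miRNA rule unions T1 and T2 contrasts: DE at either suffices."""
    calls = default_result.mirna_de.feature_calls
    table = default_result.mirna_de.table
    per_contrast_de = set(table.loc[table["is_de"], "feature_id"])
    assert set(calls.index[calls["is_de"]]) == per_contrast_de
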