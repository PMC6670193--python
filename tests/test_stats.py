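"""CLR transform, association models, q-values, validation, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import coabund as cb
from helpers import cag_pipeline, canonical_ids

pytestmark = pytest.mark.filterwarnings(
    "ignore::statsmodels.tools.sm_exceptions.ConvergenceWarning"
)


def _clr_frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=pd.Index(range(arr.shape[0]), name="cag"),
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def _meta(status, subjects=None, cohort="discovery"):
    n = len(status)
    subjects = subjects or [f"u{i}" for i in range(n)]
    return cb.SampleMetadata(
        pd.DataFrame(
            {"subject": subjects, "status": status, "cohort": cohort},
            index=pd.Index([f"s{j}" for j in range(n)], name="sample"),
        )
    )


# ---------------------------------------------------------------------------
# CLR


def test_clr_uniform_composition_is_zero():
    out = cb.clr_transform(_clr_frame([[0.25]] * 4))
    assert np.allclose(out.to_numpy(), 0.0)


def test_clr_hand_computed_values():
    out = cb.clr_transform(_clr_frame([[0.5], [0.25], [0.25]]))
    expected = np.log([0.5, 0.25, 0.25]) - np.mean(np.log([0.5, 0.25, 0.25]))
    assert np.allclose(out.to_numpy().ravel(), expected)
    assert out.to_numpy().ravel() == pytest.approx([0.462, -0.231, -0.231], abs=1e-3)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_clr_columns_sum_to_zero_with_zeros_replaced(seed):
    rng = np.random.default_rng(seed)
    arr = rng.gamma(0.3, size=(12, 6))
    arr[rng.random(arr.shape) < 0.3] = 0.0
    arr[:, arr.sum(axis=0) == 0] = 1.0
    out = cb.clr_transform(_clr_frame(arr))
    assert np.allclose(out.sum(axis=0), 0.0, atol=1e-9)


def test_clr_rejects_degenerate_input():
    with pytest.raises(cb.ParameterError):
        cb.clr_transform(_clr_frame([[0.0], [0.0]]))  # all-zero sample
    with pytest.raises(cb.ParameterError):
        cb.clr_transform(_clr_frame([[1.0, 2.0]]))  # single feature


# ---------------------------------------------------------------------------
# association models


def test_identical_groups_give_zero_coefficient_p_one():
    clr = _clr_frame(np.tile([[1.0, 1.0, 1.0, 1.0]], (2, 1)))
    res = cb.fit_cag_association(clr, _meta([0, 0, 1, 1]))
    assert res["estimate"].to_numpy() == pytest.approx([0.0, 0.0])
    assert res["p"].to_numpy() == pytest.approx([1.0, 1.0])


def test_single_sample_per_subject_reduces_to_ols():
    rng = np.random.default_rng(0)
    clr = _clr_frame(rng.normal(size=(5, 24)))
    meta = _meta([0, 1] * 12)
    auto = cb.fit_cag_association(clr, meta, model="auto")
    fixed = cb.fit_cag_association(clr, meta, model="fixed")
    assert (auto["model"] == "fixed").all()
    pd.testing.assert_frame_equal(auto, fixed)
    forced = cb.fit_cag_association(clr, meta, model="mixed")
    assert np.allclose(forced["estimate"], fixed["estimate"], atol=1e-6)


def test_sign_convention_positive_means_healthy():
    # feature 0 higher in healthy (status 0) samples -> positive estimate
    healthy_high = np.array([[2.0] * 6 + [0.5] * 6, [0.5] * 6 + [2.0] * 6])
    clr = _clr_frame(healthy_high - healthy_high.mean(axis=0))
    res = cb.fit_cag_association(clr, _meta([0] * 6 + [1] * 6))
    assert res.loc[0, "estimate"] > 0 > res.loc[1, "estimate"]


def test_too_few_samples_per_group_rejected():
    clr = _clr_frame(np.random.default_rng(0).normal(size=(2, 5)))
    with pytest.raises(cb.ParameterError):
        cb.fit_cag_association(clr, _meta([0, 0, 0, 0, 1]))


def test_effect_recovery_within_three_se():
    """Known planted effects are recovered by the CLR model (100 seeds)."""
    hits = total = 0
    for seed in range(100):
        config = cb.SimulationConfig(
            seed=seed, n_cags=10, genes_per_cag=(3, 8), n_samples=200,
            n_subjects=200, effect_cags=2, effect_size=1.0,
        )
        matrix, meta, truth = cb.simulate_cohort(config)
        cat = truth.true_catalog()
        ids = canonical_ids(truth, cat)
        res = cag_pipeline(matrix, meta, cat)
        for tc, sign in truth.effect_sign.items():
            if sign == 0:
                continue
            row = res.loc[ids[tc]]
            total += 1
            hits += abs(row["estimate"] - truth.expected_clr_shift(tc)) <= 3 * row["se"]
    assert hits / total >= 0.95


# ---------------------------------------------------------------------------
# q-values


def test_qvalues_all_ones():
    assert cb.estimate_qvalues(np.ones(50)).tolist() == [1.0] * 50


def test_qvalues_with_pi0_one_equal_bh():
    rng = np.random.default_rng(1)
    p = rng.random(200) ** 2
    q = cb.estimate_qvalues(p, pi0=1.0)
    bh = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(q, bh, atol=1e-12)


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(2)
    p = rng.random(500)
    q = cb.estimate_qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_qvalues_fall_back_to_bh_for_few_pvalues():
    p = np.array([0.01, 0.2, 0.5, 0.9])
    with pytest.warns(UserWarning, match="fewer than 10"):
        q = cb.estimate_qvalues(p)
    assert np.allclose(q, multipletests(p, method="fdr_bh")[1])


def test_qvalues_control_null_discoveries():
    """Uniform p-values: the q <= 0.2 fraction stays small (50 replicates)."""
    rng = np.random.default_rng(3)
    ok = 0
    for _ in range(50):
        p = rng.random(1000)
        frac = (cb.estimate_qvalues(p) <= 0.2).mean()
        ok += frac <= 0.05
    assert ok >= 47  # >= 95% of replicates


def test_qvalue_input_validation():
    with pytest.raises(cb.ParameterError):
        cb.estimate_qvalues([0.5, np.nan])
    with pytest.raises(cb.ParameterError):
        cb.estimate_qvalues([1.2])


# ---------------------------------------------------------------------------
# discovery / validation


def test_discover_threshold_inclusive():
    results = pd.DataFrame({"q": [0.1, 0.2, 0.2000001]}, index=[0, 1, 2])
    assert cb.discover(results) == [0, 1]
    assert cb.discover(pd.DataFrame()) == []


def test_validate_requires_validation_results():
    disc = pd.DataFrame({"estimate": [1.0], "p": [0.01], "q": [0.01]}, index=[0])
    val = pd.DataFrame({"estimate": [], "p": [], "q": []})
    with pytest.raises(cb.ParameterError):
        cb.validate([0], disc, val)


def test_validate_single_cag_opposite_sign():
    disc = pd.DataFrame({"estimate": [1.0], "p": [0.01]}, index=[0])
    val = pd.DataFrame({"estimate": [-2.0], "p": [0.001]}, index=[0])
    with pytest.warns(UserWarning):  # BH fallback on 1 p-value
        report = cb.validate([0], disc, val)
    assert report.validated == [] and report.c1 == 1 and report.c2 == 0


def test_strong_effects_validate_with_matching_signs():
    config = cb.SimulationConfig(
        seed=7, n_cags=50, genes_per_cag=(3, 10), n_samples=60, n_subjects=40,
        effect_cags=10, effect_size=3.0,
    )
    (dm, dmeta), (vm, vmeta), truth = cb.simulate_paired_cohorts(config)
    cat = truth.true_catalog()
    ids = canonical_ids(truth, cat)
    dres = cag_pipeline(dm, dmeta, cat)
    vres = cag_pipeline(vm, vmeta, cat)
    assert (dres["model"] == "mixed").all()  # repeated measures exercised
    discovered = cb.discover(dres)
    report = cb.validate(discovered, dres, vres)
    effect = {ids[tc] for tc, s in truth.effect_sign.items() if s != 0}
    assert effect <= set(discovered)
    assert effect <= set(report.validated)
    for tc, sign in truth.effect_sign.items():
        if sign != 0:
            assert np.sign(dres.loc[ids[tc], "estimate"]) == sign


# ---------------------------------------------------------------------------
# sign-agreement bound


def test_sign_agreement_reference_values():
    b = cb.sign_agreement_pvalue(10, 10)
    assert b.p_exact == pytest.approx(2.0**-10, rel=1e-12)
    even = cb.sign_agreement_pvalue(20, 10)
    assert even.p_normal == pytest.approx(0.5, rel=1e-12)
    assert even.p_exact > 0.5  # includes the C2=C1/2 mass itself
    with pytest.raises(cb.ParameterError):
        cb.sign_agreement_pvalue(10, 11)
    with pytest.raises(cb.ParameterError):
        cb.sign_agreement_pvalue(0, 0)


def test_sign_agreement_exact_matches_enumeration():
    """Log-space tail equals direct binomial summation for C1 <= 30."""
    for c1 in (1, 2, 7, 18, 30):
        for c2 in range(c1 + 1):
            direct = sum(math.comb(c1, k) for k in range(c2, c1 + 1)) / 2.0**c1
            assert cb.sign_agreement_pvalue(c1, c2).p_exact == pytest.approx(
                direct, rel=1e-10
            )


def test_sign_agreement_bound_is_conservative():
    """Type-I error at level alpha stays <= alpha over 500 null replicates."""
    rng = np.random.default_rng(4)
    c1 = 50
    rejections = {0.05: 0, 0.2: 0}
    for _ in range(500):
        c2 = rng.binomial(c1, 0.5)
        p = cb.sign_agreement_pvalue(c1, c2).p_exact
        for alpha in rejections:
            rejections[alpha] += p <= alpha
    for alpha, count in rejections.items():
        assert count / 500 <= alpha


# ---------------------------------------------------------------------------
# representatives, enrichment, sign summary


def test_representative_selection_identity_and_determinism():
    singletons = cb.CAGCatalog.from_members([["gA"], ["gB"], ["gC"]])
    sel = cb.select_representative_genes(singletons, seed=0)
    assert set(sel) == {"gA", "gB", "gC"}
    multi = cb.CAGCatalog.from_members([["g1", "g2", "g3"], ["g4", "g5"]])
    s1 = cb.select_representative_genes(multi, seed=9)
    s2 = cb.select_representative_genes(multi, seed=9)
    pd.testing.assert_series_equal(s1, s2)
    assert all(g in multi.members(c) for c, g in s1.items())


def _brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    return sum(prob(x) for x in support if prob(x) <= p_obs * (1 + 1e-9))


def test_enrichment_fisher_matches_enumeration():
    genes = [f"g{i}" for i in range(20)]
    target = genes[:10]
    # 8 of 10 target genes labelled, 1 of 10 background-only genes labelled
    labelled = target[:8] + [genes[10]]
    ann = cb.AnnotationTable.from_pairs([(g, "K001") for g in labelled])
    out = cb.annotation_enrichment(target, genes, ann, alpha=0.01)
    assert out.loc["K001", ["a", "b", "c", "d"]].tolist() == [8, 2, 1, 9]
    assert out.loc["K001", "p"] == pytest.approx(_brute_force_fisher(8, 2, 1, 9), rel=1e-9)
    # single label: Holm-Sidak decision equals raw p < alpha
    assert out.loc["K001", "significant"] == (out.loc["K001", "p"] < 0.01)


def test_enrichment_equal_frequency_not_significant():
    genes = [f"g{i}" for i in range(40)]
    target = genes[:20]
    labelled = genes[:10] + genes[20:30]  # 50% in both target and rest
    ann = cb.AnnotationTable.from_pairs([(g, "K002") for g in labelled])
    out = cb.annotation_enrichment(target, genes, ann)
    assert out.loc["K002", "odds_ratio"] == pytest.approx(1.0)
    assert not out.loc["K002", "significant"]


def test_enrichment_requires_target_subset():
    with pytest.raises(cb.ParameterError):
        cb.annotation_enrichment(["gX"], ["gA"], cb.AnnotationTable())


def test_sign_summary():
    res = pd.DataFrame({"estimate": [0.5, 1.2, -0.1, 2.0]})
    assert cb.sign_summary(res) == pytest.approx(0.75)
    with pytest.raises(cb.ParameterError):
        cb.sign_summary(pd.DataFrame({"estimate": [np.nan]}))
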