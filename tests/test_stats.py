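"""Two-sample tests, BH, empirical-Bayes shrinkage, and the moderated test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from phosq import (
    Design,
    EBayesHyper,
    QuantTable,
    ValidationError,
    adjust_by_protein,
    bh_adjust,
    fit_ebayes,
    fit_normalization,
    glog_transform,
    moderated_test,
    pathway_group_test,
    protein_fold_changes,
    welch_t,
    wilcoxon_rank_sum,
)
from phosq.simulate import SimConfig, simulate_experiment
from phosq.stats import posterior_variance


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def test_welch_hand_oracle():
    """t, df from the Welch formulas computed by hand for (1,2,3) vs (2,3,4)."""
    r = welch_t([1, 2, 3], [2, 3, 4])
    assert abs(r.statistic - (-1.22474487)) < 1e-7
    assert abs(r.df - 4.0) < 1e-9
    assert abs(r.p - 0.28786413) < 1e-7


def test_welch_identical_samples():
    r = welch_t([1, 2, 3], [1, 2, 3])
    assert r.statistic == 0.0 and r.p == 1.0


def test_welch_scale_invariance():
    x, y = [1.0, 2.0, 5.0], [2.5, 3.0, 4.0, 8.0]
    a = welch_t(x, y)
    b = welch_t([10 * v for v in x], [10 * v for v in y])
    assert abs(a.statistic - b.statistic) < 1e-12
    assert abs(a.df - b.df) < 1e-12
    assert abs(a.p - b.p) < 1e-12


def test_welch_degenerate_errors():
    with pytest.raises(ValidationError):
        welch_t([1.0], [1, 2, 3])
    with pytest.raises(ValidationError):
        welch_t([2, 2, 2], [3, 3, 3])  # zero variance, different means


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def test_wilcoxon_exact_enumeration_oracle():
    """(1,2) vs (3,4): all C(4,2)=6 assignments, extreme split => p = 2/6."""
    r = wilcoxon_rank_sum([1, 2], [3, 4])
    assert r.exact
    assert abs(r.p - 1.0 / 3.0) < 1e-12
    assert r.statistic == 3.0  # rank-sum of x = 1 + 2


def test_wilcoxon_identical_multisets_p_one():
    r = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert r.p == 1.0


def test_wilcoxon_exact_vs_approx_agree_at_n50():
    rng = np.random.default_rng(101)
    x = rng.normal(0, 1, 50)
    y = rng.normal(0.3, 1, 50)
    pe = wilcoxon_rank_sum(x, y, mode="exact").p
    pa = wilcoxon_rank_sum(x, y, mode="approx").p
    assert abs(pe - pa) < 0.02


def test_wilcoxon_exact_refuses_ties():
    with pytest.raises(ValidationError):
        wilcoxon_rank_sum([1, 1], [2, 3], mode="exact")


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def _bh_brute(p, alpha):
    """Step-up: reject H_(1..k) for the largest k with p_(k) <= k*alpha/m."""
    p = np.sort(np.asarray(p, float))
    m = len(p)
    ks = [k for k in range(1, m + 1) if p[k - 1] <= k * alpha / m]
    return max(ks) if ks else 0


def test_bh_hand_oracle():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_single_and_bounds():
    assert bh_adjust([0.37])[0] == 0.37
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


def test_bh_permutation_invariance():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=9)
    q = bh_adjust(p)
    perm = rng.permutation(9)
    np.testing.assert_allclose(np.sort(bh_adjust(p[perm])), np.sort(q), atol=1e-12)


def _rejected_at(p, i, alpha):
    """Is hypothesis i rejected by the BH step-up procedure at level alpha?"""
    k = _bh_brute(p, alpha)
    return k > 0 and p[i] <= np.sort(p)[k - 1]


def test_bh_q_is_smallest_rejecting_alpha():
    """q_i equals the smallest alpha at which step-up rejects hypothesis i."""
    rng = np.random.default_rng(7)
    p = rng.uniform(size=8)
    for size in range(1, 9):
        for subset in itertools.combinations(range(8), size):
            sub = p[list(subset)]
            m = len(sub)
            q = bh_adjust(sub)
            # candidate alphas where the rejection set can change
            cands = sorted({pv * m / k for pv in sub for k in range(1, m + 1)} | {1.0})
            for i, qi in enumerate(q):
                brute = next(a for a in cands if _rejected_at(sub, i, a + 1e-12))
                assert abs(qi - brute) < 1e-9


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_properties(p):
    q = bh_adjust(p)
    assert ((q >= np.asarray(p) - 1e-12) | np.isclose(q, p)).all()
    assert (q <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()  # step-up monotone


# ---------------------------------------------------------------------------
# empirical Bayes
# ---------------------------------------------------------------------------

def test_ebayes_equal_variances_give_infinite_prior_df():
    h = fit_ebayes(np.full(100, 0.3), 4.0)
    assert np.isinf(h.d0)


def test_ebayes_parameter_recovery():
    """Scaled-chi-square draws (s0^2=0.04, d0=4, n=5000) recovered."""
    rng = np.random.default_rng(11)
    s2 = 0.04 * rng.chisquare(4, 5000) / 4.0
    h = fit_ebayes(s2, np.inf)
    assert 3.0 <= h.d0 <= 5.0
    assert abs(h.s0_sq - 0.04) / 0.04 < 0.15


def test_ebayes_scale_equivariance():
    rng = np.random.default_rng(13)
    s2 = 0.1 * rng.chisquare(6, 2000) / 6.0
    h1 = fit_ebayes(s2, np.inf)
    h2 = fit_ebayes(2 * s2, np.inf)
    assert abs(h2.d0 - h1.d0) < 1e-9
    assert abs(h2.s0_sq - 2 * h1.s0_sq) < 1e-9


def test_ebayes_needs_enough_variances():
    with pytest.raises(ValidationError):
        fit_ebayes(np.full(10, 0.1), 4.0)


# ---------------------------------------------------------------------------
# moderated test
# ---------------------------------------------------------------------------

def _glog_table_and_design(seed=21, n_proteins=150):
    _, phospho, _, design, _, _ = simulate_experiment(SimConfig(n_proteins=n_proteins, seed=seed))
    return glog_transform(phospho, fit_normalization(phospho)), design


def test_moderated_limits_match_plain_statistics():
    table, design = _glog_table_and_design()
    dep = design.channels("phospho", "deprived")
    fed = design.channels("phospho", "fed")

    # d0 = inf: t equals fc / (s0 * sqrt(1/n1 + 1/n2))
    s0 = 0.02
    res = moderated_test(table, design, EBayesHyper(np.inf, s0))
    complete = table.values.dropna()
    fc = complete[dep].mean(axis=1) - complete[fed].mean(axis=1)
    expect = fc / np.sqrt(s0 * (1 / 3 + 1 / 3))
    got = res.set_index("site_id").loc[complete.index, "t_mod"]
    np.testing.assert_allclose(got, expect, rtol=1e-9)

    # d0 = 0: t equals the pooled-variance two-sample t
    res0 = moderated_test(table, design, EBayesHyper(0.0, 1.0)).set_index("site_id")
    row = complete.iloc[0]
    t_pooled = sps.ttest_ind(row[dep], row[fed], equal_var=True).statistic
    assert abs(res0.loc[complete.index[0], "t_mod"] - t_pooled) < 1e-9


def test_moderated_matches_straight_line_formula_on_random_sites():
    """Posterior-variance formula recomputed independently for 50 sites."""
    table, design = _glog_table_and_design(seed=33)
    res = moderated_test(table, design).set_index("site_id")
    hyper = res.attrs["ebayes"]
    dep = design.channels("phospho", "deprived")
    fed = design.channels("phospho", "fed")
    rng = np.random.default_rng(0)
    tested = res[res["p"].notna()]
    for sid in rng.choice(tested.index, 50, replace=False):
        x = table.values.loc[sid, dep].dropna().to_numpy()
        y = table.values.loc[sid, fed].dropna().to_numpy()
        d = len(x) + len(y) - 2
        s2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / d
        if np.isinf(hyper.d0):  # shrinkage limit: all weight on the prior
            s2_post = hyper.s0_sq
        else:
            s2_post = (hyper.d0 * hyper.s0_sq + d * s2) / (hyper.d0 + d)
        t_expect = (x.mean() - y.mean()) / np.sqrt(s2_post * (1 / len(x) + 1 / len(y)))
        assert abs(res.loc[sid, "t_mod"] - t_expect) < 1e-9


def test_moderated_insufficient_replication_flagged():
    table, design = _glog_table_and_design(seed=5)
    vals = table.values.copy()
    dep = design.channels("phospho", "deprived")
    vals.loc[vals.index[0], dep[:2]] = np.nan  # only 1 deprived value left
    res = moderated_test(QuantTable(vals, "glog"), design).set_index("site_id")
    row = res.loc[vals.index[0]]
    assert row["reason"] == "insufficient_replication"
    assert np.isnan(row["p"]) and np.isnan(row["t_mod"])


def test_moderated_requires_glog_scale():
    _, phospho, _, design, _, _ = simulate_experiment(SimConfig(n_proteins=50, seed=2))
    with pytest.raises(ValidationError):
        moderated_test(phospho, design)


def test_q_never_below_p():
    table, design = _glog_table_and_design(seed=41)
    res = moderated_test(table, design)
    ok = res["p"].notna()
    assert (res.loc[ok, "q"] >= res.loc[ok, "p"] - 1e-12).all()


# ---------------------------------------------------------------------------
# protein adjustment
# ---------------------------------------------------------------------------

def test_adjustment_arithmetic():
    res = pd.DataFrame({
        "site_id": ["P1_S1", "P2_S2", "P3_S3"],
        "log2fc_raw": [1.0, 2.0, 0.7],
        "protein_log2fc": np.nan, "log2fc_adj": np.nan, "adjusted_flag": False,
        "p": [0.1, 0.2, 0.3],
    })
    mapping = {"P1_S1": "P1", "P2_S2": "P2", "P3_S3": "P3"}
    pfc = pd.Series({"P1": 1.0, "P2": 0.5})  # P3 not quantified in flow-through
    out = adjust_by_protein(res, mapping, pfc).set_index("site_id")
    assert out.loc["P1_S1", "log2fc_adj"] == 0.0
    assert out.loc["P2_S2", "log2fc_adj"] == 1.5
    assert out.loc["P3_S3", "log2fc_adj"] == 0.7
    assert not out.loc["P3_S3", "adjusted_flag"]
    assert out.loc["P1_S1", "adjusted_flag"]


def test_adjustment_centers_protein_driven_sites():
    """Sites with protein-only change end up centred at 0 after adjustment."""
    sites, phospho, ft, design, _, truth = simulate_experiment(
        SimConfig(n_proteins=667, seed=9)
    )
    g = glog_transform(phospho, fit_normalization(phospho))
    gft = glog_transform(ft, fit_normalization(ft))
    res = moderated_test(g, design)
    mapping = pd.Series({s.site_id: s.protein_id for s in sites})
    res = adjust_by_protein(res, mapping, protein_fold_changes(gft, design))
    se = truth.site_effects
    protein_only = se[(se["true_log2_effect"] == 0) & (se["total_log2_effect"] != 0)].index
    sub = res.set_index("site_id").reindex(protein_only).dropna(subset=["log2fc_raw"])
    sub = sub[sub["adjusted_flag"]]
    assert len(sub) >= 20
    assert sub["log2fc_adj"].abs().mean() < sub["log2fc_raw"].abs().mean()
    assert abs(sub["log2fc_adj"].mean()) < 0.1


# ---------------------------------------------------------------------------
# pathway group test
# ---------------------------------------------------------------------------

def test_pathway_degenerate_partition_errors():
    fc = pd.Series([0.1, -0.2, 0.3], index=["a", "b", "c"])
    with pytest.raises(ValidationError):
        pathway_group_test(fc, {"a", "b", "c"})
    with pytest.raises(ValidationError):
        pathway_group_test(fc, set())


def test_pathway_planted_recovery():
    """80 member sites of 2000 shifted by -0.8 detected (negative, p<0.01)."""
    rng = np.random.default_rng(13)
    fc = pd.Series(rng.normal(0, 0.15, 2000),
                   index=[f"s{i}" for i in range(2000)])
    members = {f"s{i}" for i in range(80)}
    fc.loc[sorted(members)] += -0.8
    r = pathway_group_test(fc, members)
    assert r.p < 0.01
    assert r.shift < 0


def test_pathway_null_calibration_over_seeds():
    """Random memberships under the null reject at ~5%."""
    rejections = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(10_000 + seed)
        fc = pd.Series(rng.normal(0, 0.15, 400), index=[f"s{i}" for i in range(400)])
        members = set(rng.choice(fc.index, 40, replace=False))
        if pathway_group_test(fc, members).p < 0.05:
            rejections += 1
    assert 0.02 <= rejections / n_seeds <= 0.09


def test_welch_wilcoxon_rejection_concordance():
    """At n=50 and |shift|=1 the two tests nearly always agree on rejection."""
    rng = np.random.default_rng(55)
    agree = 0
    n_rep = 100
    for _ in range(n_rep):
        shift = rng.choice([0.0, 1.0])
        x = rng.normal(0, 1, 50)
        y = rng.normal(shift, 1, 50)
        rw = welch_t(x, y).p < 0.05
        ru = wilcoxon_rank_sum(x, y).p < 0.05
        agree += int(rw == ru)
    assert agree / n_rep >= 0.95


def test_posterior_variance_limits():
    s2 = np.array([0.1, 0.4])
    d = np.array([4.0, 4.0])
    np.testing.assert_allclose(posterior_variance(s2, d, EBayesHyper(np.inf, 0.2)), [0.2, 0.2])
    np.testing.assert_allclose(posterior_variance(s2, d, EBayesHyper(0.0, 9.9)), s2)
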