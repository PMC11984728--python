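import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from cardiopcct import (CohortSpec, assumption_gate, benjamini_hochberg,
                        cohens_d, generate_cohort, run_factorial_anova,
                        run_gamma_glm, run_kruskal_dunn,
                        stratified_mannwhitney)
from cardiopcct.stats import _mannwhitney


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSpec(seed=123))


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------


def test_bh_hand_computed_case():
    adj = benjamini_hochberg([0.01, 0.02, 0.03])
    # step-up: 0.03*3/3 = 0.03; 0.02*3/2 = 0.03; 0.01*3/1 = 0.03
    assert np.allclose(adj, [0.03, 0.03, 0.03])


def test_bh_matches_statsmodels(rng):
    for _ in range(20):
        p = rng.random(rng.integers(1, 30))
        want = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(p), want)


def test_bh_properties(rng):
    p = rng.random(50)
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in the raw order
    assert benjamini_hochberg([]).size == 0
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        benjamini_hochberg([0.5, 1.5])


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def test_kruskal_h_matches_rank_formula():
    groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
    n = 9
    rank_sums = [6.0, 15.0, 24.0]  # ranks 1..9 in order
    H_hand = 12.0 / (n * (n + 1)) * sum(r ** 2 / 3 for r in rank_sums) - 3 * (n + 1)
    table = pd.DataFrame({
        "x": np.concatenate(groups),
        "g": np.repeat(["a", "b", "c"], 3),
    })
    res = run_kruskal_dunn(table, "x", "g")
    assert res["H"] == pytest.approx(H_hand)
    assert res["H"] == pytest.approx(sps.kruskal(*groups).statistic)


def test_kruskal_dunn_posthoc_pairs():
    rng = np.random.default_rng(0)
    table = pd.DataFrame({
        "x": np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 1, 15),
                             rng.normal(4, 1, 15)]),
        "g": np.repeat(["a", "b", "c"], 15),
    })
    res = run_kruskal_dunn(table, "x", "g")
    assert res["p"] < 0.05
    pairs = res["pairs"].set_index(["a", "b"])
    assert len(pairs) == 3
    # the separated group differs from both others; a-b does not
    assert pairs.loc[("a", "c"), "p_fdr"] < 0.05
    assert pairs.loc[("b", "c"), "p_fdr"] < 0.05
    assert pairs.loc[("a", "b"), "p_fdr"] > 0.05


def test_kruskal_skips_tiny_levels():
    table = pd.DataFrame({"x": [1.0, 2, 3, 4, 9], "g": ["a", "a", "b", "b", "c"]})
    with pytest.warns(UserWarning, match="< 2 observations"):
        run_kruskal_dunn(table, "x", "g")
    with pytest.raises(ValueError, match=">= 2 usable levels"):
        run_kruskal_dunn(pd.DataFrame({"x": [1.0, 2], "g": ["a", "a"]}), "x", "g")


def test_exact_mannwhitney_matches_enumeration(rng):
    # for n <= 6 per group the exact two-sided p equals full enumeration
    for _ in range(5):
        a = rng.normal(size=rng.integers(3, 7))
        b = rng.normal(size=rng.integers(3, 7))
        u_obs, p_obs = _mannwhitney(a, b)
        pooled = np.concatenate([a, b])
        na = len(a)
        u_all = []
        for idx in itertools.combinations(range(len(pooled)), na):
            sel = np.zeros(len(pooled), bool)
            sel[list(idx)] = True
            u = sps.mannwhitneyu(pooled[sel], pooled[~sel],
                                 alternative="two-sided").statistic
            u_all.append(u)
        u_all = np.asarray(u_all)
        mean_u = na * (len(b)) / 2.0
        p_enum = np.mean(np.abs(u_all - mean_u) >= np.abs(u_obs - mean_u) - 1e-12)
        assert p_obs == pytest.approx(p_enum, abs=1e-12)


def test_mannwhitney_uses_asymptotic_with_ties():
    a = np.array([1.0, 1.0, 2.0, 3.0])
    b = np.array([1.0, 2.0, 2.0, 4.0])
    _, p = _mannwhitney(a, b)
    want = sps.mannwhitneyu(a, b, alternative="two-sided",
                            method="asymptotic").pvalue
    assert p == pytest.approx(want)


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------


def test_cohens_d_hand_value():
    a = np.array([2.0, 4.0, 6.0])  # mean 3+1, var 4
    b = np.array([1.0, 3.0, 5.0])  # mean 3, var 4
    assert cohens_d(a, b) == pytest.approx(0.5)
    assert cohens_d(a, a) == 0.0
    with pytest.raises(ValueError, match="n >= 2"):
        cohens_d([1.0], b)
    with pytest.raises(ValueError, match="zero pooled SD"):
        cohens_d([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# Assumption gate
# ---------------------------------------------------------------------------


def test_assumption_gate_routes(rng):
    base = {
        "genotype": np.repeat(["apoe2", "apoe3", "apoe4"], 40),
        "sex": np.tile(np.repeat(["male", "female"], 20), 3),
        "exercise": np.tile(np.repeat(["yes", "no"], 10), 6),
    }
    normal = pd.DataFrame({**base, "m": rng.normal(10, 1, 120)})
    rep = assumption_gate(normal, "m")
    assert rep.route == "ANOVA" and rep.normal and rep.homogeneous

    skewed = pd.DataFrame({**base, "m": rng.gamma(1.2, 2.0, 120)})
    rep = assumption_gate(skewed, "m")
    assert not rep.normal
    assert rep.route in ("GLM_gamma_log", "KRUSKAL")

    hetero = normal.copy()
    hetero.loc[hetero.genotype == "apoe4", "m"] = rng.normal(10, 8, 40)
    rep = assumption_gate(hetero, "m")
    assert not rep.homogeneous

    with pytest.raises(KeyError, match="missing"):
        assumption_gate(normal, "nope")
    with pytest.raises(ValueError, match=">= 3 observations"):
        assumption_gate(normal.head(11), "m")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


def test_anova_type1_eta_squared_decomposes(rng):
    # balanced design: every genotype x exercise x sex x hn cell has n = 5
    cells = [(g, e, s, h)
             for g in ("apoe2", "apoe3", "apoe4")
             for e in ("yes", "no") for s in ("male", "female") for h in (0, 1)]
    rows = [{"genotype": g, "exercise": e, "sex": s, "hn": h,
             "EF": float(rng.normal(50, 5))}
            for g, e, s, h in cells for _ in range(5)]
    balanced = pd.DataFrame(rows)
    out = run_factorial_anova(balanced, "EF", ss_type=1)
    # Type I sums of squares partition the total exactly
    total = out["eta_squared"].sum() + out.attrs["ss_residual"] / out.attrs["ss_total"]
    assert total == pytest.approx(1.0, abs=1e-10)
    assert set(out.columns) == {"term", "F", "p", "p_fdr", "eta_squared",
                                "size_class"}
    assert "genotype:exercise" in set(out["term"])
    assert np.all((out["p_fdr"] >= out["p"] - 1e-15))


def test_anova_detects_planted_exercise_effect(cohort):
    # the published group means encode a real exercise effect on SV
    out = run_factorial_anova(cohort, "SV").set_index("term")
    assert out.loc["exercise", "p"] < 0.05


def test_gamma_glm_output_and_positivity(cohort):
    out = run_gamma_glm(cohort, "EF")
    assert {"term", "coef", "multiplicative_effect", "p"} <= set(out.columns)
    row = out[out["term"].str.contains("exercise")].iloc[0]
    assert row["multiplicative_effect"] == pytest.approx(np.exp(row["coef"]))
    bad = cohort.copy()
    bad.loc[bad.index[0], "EF"] = -1.0
    with pytest.raises(ValueError, match="check units"):
        run_gamma_glm(bad, "EF")


def test_stratified_mannwhitney_structure(cohort):
    out = stratified_mannwhitney(cohort, metrics=("EF", "CI"))
    # 2 sexes + 3 genotypes strata x 2 metrics = 10 rows, one BH family
    assert len(out) == 10
    assert set(out["stratum"]) == {"sex=male", "sex=female", "genotype=apoe2",
                                   "genotype=apoe3", "genotype=apoe4"}
    assert np.allclose(out["p_fdr"],
                       benjamini_hochberg(out["p"].to_numpy()))
    assert out["cohens_d"].notna().all()


def test_stratified_skips_missing_arm(cohort):
    crippled = cohort[~((cohort.sex == "male") & (cohort.exercise == "no"))]
    with pytest.warns(UserWarning, match="lacks one exercise arm"):
        out = stratified_mannwhitney(crippled, metrics=("EF",))
    assert "sex=male" not in set(out["stratum"])
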