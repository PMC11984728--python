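"""Multi-factor statistics for the cardiac-metric cohort.

The cascade mirrors standard practice for this design:

1.  Per metric, Shapiro-Wilk normality (on the metric's marginal
    distribution) and median-centred Levene homogeneity across the
    genotype x sex x exercise cells, both at alpha = 0.05, route the metric:
    normal & homogeneous -> full-factorial ANOVA; non-normal & homogeneous
    -> Gamma GLM with log link; non-normal & heteroscedastic ->
    Kruskal-Wallis with Dunn's post hoc.
2.  ANOVA: ``metric ~ genotype * exercise * sex * hn`` with per-term F,
    eta-squared effect sizes (SS_term / SS_total; 0.01/0.06/0.14 = small/
    medium/large) and Benjamini-Hochberg FDR across the model's terms.
3.  Stratified exercise comparisons (within sex, within genotype) use the
    Mann-Whitney U test -- exact for small groups, tie-corrected normal
    approximation otherwise -- with one BH family across all stratified
    tests, reported with Cohen's D.

Standard tests come from scipy/statsmodels; the BH step-up adjustment and
Dunn's z-tests are written out explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AssumptionReport",
    "assumption_gate",
    "run_factorial_anova",
    "run_gamma_glm",
    "run_kruskal_dunn",
    "stratified_mannwhitney",
    "benjamini_hochberg",
    "cohens_d",
    "EFFECT_SIZE_THRESHOLDS",
]

ALPHA = 0.05
EFFECT_SIZE_THRESHOLDS = {"small": 0.01, "medium": 0.06, "large": 0.14}

FACTORS = ("genotype", "exercise", "sex", "hn")


@dataclass
class AssumptionReport:
    metric: str
    shapiro_p: float
    levene_p: float
    normal: bool
    homogeneous: bool
    route: str  # ANOVA | GLM_gamma_log | KRUSKAL


def _group_values(table: pd.DataFrame, metric: str,
                  by=("genotype", "sex", "exercise")):
    return [g[metric].to_numpy() for _, g in table.groupby(list(by)) if len(g) > 0]


def assumption_gate(table: pd.DataFrame, metric: str,
                    alpha: float = ALPHA) -> AssumptionReport:
    """Shapiro-Wilk + Levene gating that routes a metric to its analysis.

    Normality is tested on the metric's marginal distribution (not model
    residuals -- a deliberate, literal convention); homogeneity uses the
    median-centred (robust) Levene variant across the 12 genotype x sex x
    exercise cells.  Routing: both pass -> ANOVA; only normality fails ->
    Gamma log-link GLM; both fail -> Kruskal-Wallis.  The non-normal route
    is also taken when homogeneity alone fails (conservative fallback).
    """
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} missing from cohort table")
    values = table[metric].to_numpy(dtype=float)
    groups = _group_values(table, metric)
    if any(len(g) < 3 for g in groups):
        raise ValueError("need >= 3 observations per tested group")
    shapiro_p = float(sps.shapiro(values).pvalue)
    levene_p = float(sps.levene(*groups, center="median").pvalue)
    normal = shapiro_p >= alpha
    homogeneous = levene_p >= alpha
    if normal and homogeneous:
        route = "ANOVA"
    elif not normal and homogeneous:
        route = "GLM_gamma_log"
    else:
        route = "KRUSKAL"
    return AssumptionReport(metric=metric, shapiro_p=shapiro_p, levene_p=levene_p,
                            normal=normal, homogeneous=homogeneous, route=route)


# ---------------------------------------------------------------------------
# Core procedures
# ---------------------------------------------------------------------------


def _full_factorial_formula(metric: str) -> str:
    return (f"{metric} ~ C(genotype) * C(exercise) * C(sex) * C(hn)")


def _clean_term(term: str) -> str:
    return (term.replace("C(", "").replace(")", "")
            .replace(":", ":").strip())


def run_factorial_anova(table: pd.DataFrame, metric: str,
                        ss_type: int = 2) -> pd.DataFrame:
    """Full-factorial ANOVA of genotype x exercise x sex x HN.

    Returns one row per model term with F, raw p, BH-adjusted p (family =
    this metric's terms), eta-squared (SS_term / SS_total, where SS_total is
    the centred total sum of squares) and its size class.  Inestimable terms
    (empty cells) are dropped with a warning.  ``ss_type`` selects the
    sums-of-squares convention (Type II default; Type I decomposes SS_total
    exactly).
    """
    model = smf.ols(_full_factorial_formula(metric), data=table).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singular-term warnings handled below
        tab = anova_lm(model, typ=ss_type)
    tab = tab.rename(columns={"sum_sq": "ss", "PR(>F)": "p"})
    resid_ss = float(tab.loc["Residual", "ss"])
    y = table[metric].to_numpy(dtype=float)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    terms = tab.drop(index="Residual")
    bad = terms.index[~np.isfinite(terms["F"])]
    if len(bad):
        warnings.warn(f"dropping inestimable term(s) {list(bad)}")
        terms = terms.drop(index=bad)
    eta2 = terms["ss"].to_numpy() / ss_total
    out = pd.DataFrame({
        "term": [_clean_term(t) for t in terms.index],
        "F": terms["F"].to_numpy(),
        "p": terms["p"].to_numpy(),
        "p_fdr": benjamini_hochberg(terms["p"].to_numpy()),
        "eta_squared": eta2,
        "size_class": [_size_class(e) for e in eta2],
    })
    out.attrs["ss_residual"] = resid_ss
    out.attrs["ss_total"] = ss_total
    out.attrs["ss_type"] = ss_type
    return out


def _size_class(eta2: float) -> str:
    if eta2 >= EFFECT_SIZE_THRESHOLDS["large"]:
        return "large"
    if eta2 >= EFFECT_SIZE_THRESHOLDS["medium"]:
        return "medium"
    return "small"


def run_gamma_glm(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Gamma GLM with log link on a strictly positive, skewed metric.

    Full factorial in the four factors; Wald z-tests per coefficient;
    ``exp(coef)`` reported as the multiplicative effect on the metric's mean.
    """
    y = table[metric].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError(
            f"{metric} has non-positive values; a Gamma log-link model needs "
            "strictly positive responses (check units)")
    model = smf.glm(_full_factorial_formula(metric), data=table,
                    family=sm.families.Gamma(link=sm.families.links.Log())).fit()
    out = pd.DataFrame({
        "term": [_clean_term(t) for t in model.params.index],
        "coef": model.params.to_numpy(),
        "multiplicative_effect": np.exp(model.params.to_numpy()),
        "p": model.pvalues.to_numpy(),
    })
    return out


def run_kruskal_dunn(table: pd.DataFrame, metric: str, factor: str,
                     alpha: float = ALPHA) -> dict:
    """Kruskal-Wallis across the factor's levels; Dunn's post hoc if significant.

    Dunn's pairwise z statistics use rank sums with the tie correction, BH
    adjusted within the family of pairs.  Levels with < 2 observations are
    skipped with a warning.
    """
    groups = {lvl: g[metric].to_numpy(dtype=float)
              for lvl, g in table.groupby(factor)}
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    for k in set(groups) - set(usable):
        warnings.warn(f"level {k!r} has < 2 observations; skipped in post hoc")
    if len(usable) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 usable levels")
    H, p = sps.kruskal(*usable.values())
    result = {"H": float(H), "p": float(p), "factor": factor, "metric": metric,
              "pairs": pd.DataFrame(columns=["a", "b", "z", "p", "p_fdr"])}
    if p >= alpha:
        return result

    # Dunn's z tests on the joint ranking
    all_vals = np.concatenate(list(usable.values()))
    ranks = sps.rankdata(all_vals)
    n_total = len(all_vals)
    mean_ranks, sizes = {}, {}
    start = 0
    for k, v in usable.items():
        mean_ranks[k] = ranks[start:start + len(v)].mean()
        sizes[k] = len(v)
        start += len(v)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    rows = []
    for a, b in combinations(usable, 2):
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"a": a, "b": b, "z": float(z),
                     "p": float(2.0 * sps.norm.sf(abs(z)))})
    pairs = pd.DataFrame(rows)
    pairs["p_fdr"] = benjamini_hochberg(pairs["p"].to_numpy())
    result["pairs"] = pairs
    return result


# ---------------------------------------------------------------------------
# Stratified comparisons
# ---------------------------------------------------------------------------


def _mannwhitney(a: np.ndarray, b: np.ndarray, exact_max_n: int = 8):
    """Two-sided U test: exact for small tie-free groups, else tie-corrected normal."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= exact_max_n and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def stratified_mannwhitney(table: pd.DataFrame,
                           metrics=("EF", "CI", "RVEF"),
                           strata: tuple = ("sex", "genotype"),
                           include_cells: bool = False) -> pd.DataFrame:
    """Exercised-vs-non-exercised comparisons within each stratum.

    Strata are the levels of each factor in ``strata`` (and, optionally, the
    sex x genotype cells).  All (metric, stratum) p-values form one BH
    family.  Cohen's D (pooled-SD) accompanies every comparison; strata
    missing one exercise arm are skipped with a warning.
    """
    jobs = []
    for factor in strata:
        for lvl in sorted(table[factor].astype(str).unique()):
            jobs.append((f"{factor}={lvl}", table[table[factor].astype(str) == lvl]))
    if include_cells:
        for (s, g), sub in table.groupby(["sex", "genotype"]):
            jobs.append((f"sex={s},genotype={g}", sub))

    rows = []
    for stratum, sub in jobs:
        a = sub[sub["exercise"].astype(str) == "yes"]
        b = sub[sub["exercise"].astype(str) == "no"]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"stratum {stratum} lacks one exercise arm; skipped")
            continue
        for metric in metrics:
            x, y = a[metric].to_numpy(float), b[metric].to_numpy(float)
            u, p = _mannwhitney(x, y)
            rows.append({"stratum": stratum, "metric": metric, "U": u, "p": p,
                         "cohens_d": cohens_d(x, y)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = benjamini_hochberg(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up FDR adjustment: order-preserving, monotone, >= raw p."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def cohens_d(a, b) -> float:
    """Standardised mean difference with the pooled (n_a + n_b - 2) SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d undefined")
    return float((a.mean() - b.mean()) / pooled)
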