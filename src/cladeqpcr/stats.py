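"""Study-design statistics: depth ANOVA + Tukey letters, paired tests, GLM.

Three contrasts mirror the two study arms:

* survey — one-way ANOVA of relative expression across the three depth
  classes per gene x clade, Tukey HSD post hoc with a compact letter
  display, and a Kolmogorov-Smirnov normality check;
* exposure — paired t-tests of treatment vs control delta-Cp (reported as
  the mean per-pair fold ratio) and a 3-way factorial general linear model
  of the fold-change response with factors Treatment, Strain, Time and all
  interactions (two-level factors, so each term has 1 df);
* nonparametric — paired Wilcoxon signed-rank for cell-count style data.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .config import InsufficientDataError, ValidationError, logger

__all__ = [
    "DepthContrastResult",
    "PairedTestResult",
    "WilcoxonResult",
    "depth_anova",
    "paired_ratio_test",
    "exposure_glm",
    "paired_wilcoxon",
    "tukey_letters",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# --------------------------------------------------------------------------
# depth contrasts (survey arm)
# --------------------------------------------------------------------------
@dataclass
class DepthContrastResult:
    gene: str
    clade: str
    group_means: Mapping[str, float]
    group_n: Mapping[str, int]
    anova_f: float
    anova_p: float
    ks_p: float                  # normality of pooled standardized residuals
    letters: Mapping[str, str]   # compact letter display per group
    degenerate: bool = False     # zero within-group variance everywhere


def tukey_letters(
    groups: Sequence[str],
    means: Mapping[str, float],
    nonsig_pairs: set[frozenset],
) -> dict[str, str]:
    """Compact letter display from pairwise non-significance decisions.

    Maximal cliques of the 'not significantly different' graph each get one
    letter; cliques are lettered in order of their lowest group mean
    (deterministic tie-break toward lower mean, then group name).  Any two
    groups sharing a letter are pairwise non-significant and conversely.
    Brute-force subset enumeration — fine for the handful of groups a
    depth or treatment design has.
    """
    groups = sorted(groups, key=lambda g: (means[g], g))

    def is_clique(sub):
        return all(frozenset(p) in nonsig_pairs
                   for p in itertools.combinations(sub, 2))

    cliques = []
    for size in range(len(groups), 0, -1):
        for sub in itertools.combinations(groups, size):
            if is_clique(sub) and not any(set(sub) <= set(c) for c in cliques):
                cliques.append(sub)
    cliques.sort(key=lambda c: (min(means[g] for g in c), c))
    letters = {g: "" for g in groups}
    for symbol, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += symbol
    return letters


def depth_anova(
    quant: pd.DataFrame,
    response: str = "rel_expr",
    group_col: str = "depth_class",
    by: Sequence[str] = ("gene", "clade"),
    alpha: float = 0.05,
    min_group_n: int = 3,
) -> list[DepthContrastResult]:
    """One-way ANOVA + Tukey HSD letters per gene x clade across depths.

    ``quant`` is long-form with one row per sample carrying the response,
    the grouping column and the ``by`` columns.  Units with fewer than two
    groups of ``min_group_n`` records are skipped with a log notice.
    Constant (zero-variance) units are returned flagged ``degenerate``
    with a single shared letter.
    """
    results = []
    for keys, sub in quant.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        sub = sub.dropna(subset=[response])
        counts = sub.groupby(group_col)[response].count()
        ok_groups = counts[counts >= min_group_n].index.tolist()
        if len(ok_groups) < 2:
            logger.info("depth_anova: skipping %s (need >=2 groups of >=%d)",
                        keys, min_group_n)
            continue
        sub = sub[sub[group_col].isin(ok_groups)]
        arrays = [sub.loc[sub[group_col] == g, response].to_numpy()
                  for g in ok_groups]
        means = {g: float(a.mean()) for g, a in zip(ok_groups, arrays)}
        ns = {g: int(a.size) for g, a in zip(ok_groups, arrays)}

        pooled_sd = np.sqrt(np.mean([a.var(ddof=1) for a in arrays]))
        if pooled_sd == 0:
            logger.info("depth_anova: %s degenerate (zero variance)", keys)
            results.append(DepthContrastResult(
                gene=str(keys[0]), clade=str(keys[-1]) if len(keys) > 1 else "",
                group_means=means, group_n=ns,
                anova_f=float("nan"), anova_p=float("nan"),
                ks_p=float("nan"),
                letters={g: "a" for g in ok_groups}, degenerate=True,
            ))
            continue

        f_stat, p = ss.f_oneway(*arrays)
        resid = np.concatenate([(a - a.mean()) for a in arrays]) / pooled_sd
        ks_p = float(ss.kstest(resid, "norm").pvalue)

        tukey = pairwise_tukeyhsd(
            sub[response].to_numpy(), sub[group_col].to_numpy(), alpha=alpha
        )
        nonsig = set()
        res = tukey.summary().data[1:]
        for row in res:
            g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
            if not reject:
                nonsig.add(frozenset((g1, g2)))
        letters = tukey_letters(ok_groups, means, nonsig)
        results.append(DepthContrastResult(
            gene=str(keys[0]), clade=str(keys[-1]) if len(keys) > 1 else "",
            group_means=means, group_n=ns,
            anova_f=float(f_stat), anova_p=float(p), ks_p=ks_p,
            letters=letters,
        ))
    return results


def depth_anova_frame(results: Sequence[DepthContrastResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for g in sorted(r.group_means):
            rows.append({
                "gene": r.gene, "clade": r.clade, "depth_class": g,
                "n": r.group_n[g], "mean": r.group_means[g],
                "anova_F": r.anova_f, "anova_p": r.anova_p,
                "ks_p": r.ks_p, "letters": r.letters[g],
                "degenerate": r.degenerate,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# paired treatment/control tests (exposure arm)
# --------------------------------------------------------------------------
@dataclass
class PairedTestResult:
    label: str
    n: int
    mean_ratio: float   # mean of per-pair 2^(dCp_T - dCp_C)
    sd_ratio: float
    t_statistic: float
    df: int             # n - 1
    p_value: float


def paired_ratio_test(
    dcp_treatment: Sequence[float],
    dcp_control: Sequence[float],
    label: str = "",
) -> PairedTestResult:
    """Paired t-test on delta-Cp, summarized as a fold ratio.

    The per-pair fold is 2^(dCp_T - dCp_C); the test itself is the paired
    t-test of treatment vs control delta-Cp (equivalently, a one-sample
    test of the log2 fold against zero), df = n - 1.
    """
    t_arr = np.asarray(dcp_treatment, dtype=float)
    c_arr = np.asarray(dcp_control, dtype=float)
    if t_arr.shape != c_arr.shape:
        raise ValidationError("unpaired records: lengths differ")
    mask = ~(np.isnan(t_arr) | np.isnan(c_arr))
    t_arr, c_arr = t_arr[mask], c_arr[mask]
    n = int(t_arr.size)
    if n < 2:
        raise InsufficientDataError("need >= 2 complete pairs")
    folds = 2.0 ** (t_arr - c_arr)
    diffs = t_arr - c_arr
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs[0], 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = ss.ttest_rel(t_arr, c_arr)
    return PairedTestResult(
        label=label, n=n,
        mean_ratio=float(folds.mean()), sd_ratio=float(folds.std(ddof=1)),
        t_statistic=float(t_stat), df=n - 1, p_value=float(p),
    )


# --------------------------------------------------------------------------
# factorial GLM (exposure arm)
# --------------------------------------------------------------------------
def exposure_glm(
    data: pd.DataFrame,
    response: str = "fold",
    factors: Sequence[str] = ("treatment", "strain", "time"),
    log2_response: bool = False,
) -> pd.DataFrame:
    """Full-factorial ANOVA of the fold-change response.

    Fits an OLS with all main effects and interactions of the categorical
    ``factors`` and returns the type-II ANOVA table (term, df, F, p,
    stars).  On a balanced design type II equals type I/III and the table
    is invariant to factor ordering; the convention is recorded in
    ``DataFrame.attrs['sum_of_squares']``.  ``log2_response`` switches to
    the variance-stabilized log2 fold.  Empty design cells raise, naming
    the cell.
    """
    for f in factors:
        if f not in data.columns:
            raise ValidationError(f"missing factor column {f!r}")
    if response not in data.columns:
        raise ValidationError(f"missing response column {response!r}")
    levels = [sorted(data[f].unique()) for f in factors]
    counts = data.groupby(list(factors), sort=True)[response].count()
    for cell in itertools.product(*levels):
        if cell not in counts.index or counts[cell] == 0:
            raise ValidationError(f"empty design cell {dict(zip(factors, cell))}")

    df = data.copy()
    df["_y"] = np.log2(df[response]) if log2_response else df[response]
    terms = []
    if float(np.var(df["_y"])) == 0.0:
        # constant response: no variance to partition
        for order in range(1, len(factors) + 1):
            for combo in itertools.combinations(factors, order):
                terms.append({"term": " x ".join(combo),
                              "df": int(np.prod([len(set(df[f])) - 1
                                                 for f in combo])),
                              "F": 0.0, "p": 1.0, "stars": ""})
        out = pd.DataFrame(terms)
        out.attrs["sum_of_squares"] = "type II"
        return out

    rhs = " * ".join(f"C({f})" for f in factors)
    fit = smf.ols(f"_y ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        clean = (name.replace("C(", "").replace(")", "")
                 .replace(":", " x "))
        p = float(row["PR(>F)"])
        terms.append({"term": clean, "df": int(row["df"]),
                      "F": float(row["F"]), "p": p,
                      "stars": significance_stars(p)})
    out = pd.DataFrame(terms)
    out.attrs["sum_of_squares"] = "type II"
    return out


# --------------------------------------------------------------------------
# nonparametric paired test
# --------------------------------------------------------------------------
@dataclass
class WilcoxonResult:
    label: str
    n: int
    statistic: float
    p_value: float


def paired_wilcoxon(
    x: Sequence[float], y: Sequence[float], label: str = ""
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test (e.g. treatment/control cell counts).

    Identical pairs (all differences zero) return p = 1 by convention.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("unpaired records: lengths differ")
    n = int(a.size)
    if n < 2:
        raise InsufficientDataError("need >= 2 pairs")
    d = a - b
    if np.all(d == 0):
        return WilcoxonResult(label, n, 0.0, 1.0)
    stat, p = ss.wilcoxon(a, b)
    return WilcoxonResult(label, n, float(stat), float(p))
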