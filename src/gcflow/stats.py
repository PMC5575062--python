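"""Standard-score correlation statistics and group comparisons.

The correlation workflow mirrors the reference analysis: paired
per-growth-cone measurements are standard-score normalized (so both
axes are in units of standard deviation, σ), Pearson's r is computed,
and a least-squares line is fitted — on z-scored data the fitted slope
equals r and the intercept is 0, which is the identity the analysis
exploits when reporting "Line equation" and "Pearson r" together.
Linearity is assessed by a nested-model F-test (quadratic vs linear);
when the deviation from linearity is significant a second-order
polynomial fit is reported instead, itself checked for deviation from
the model (cubic vs quadratic).

Group comparisons use the two-tailed Student's t-test for two groups
and one-way ANOVA with Dunnett (vs control) or Tukey (all pairs) post
hoc adjustment otherwise, reporting means ± SEM (sd/sqrt(n), sample sd
with n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm


@dataclass
class ZScoredPair:
    x_z: np.ndarray
    y_z: np.ndarray
    n: int
    x_mean: float
    x_sd: float
    y_mean: float
    y_sd: float


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    ci95: str = "95% confidence band from the OLS slope/intercept covariance"


@dataclass
class PolyFitResult:
    coefficients: tuple                   # (c0, c1, c2) for c0 + c1 x + c2 x^2
    r_squared: float
    lack_of_linearity_p: float
    deviation_from_model_p: float         # cubic-vs-quadratic F-test, expected n.s.
    n: int = 0


@dataclass
class GroupComparison:
    groups: dict                          # label -> {mean, sem, sd, n}
    test: str
    comparisons: list = field(default_factory=list)  # {pair, diff, p_raw, p_adj}
    statistic: float = float("nan")
    p_value: float = float("nan")         # omnibus p (t or ANOVA F)


def _as_array(v, name):
    a = np.asarray(v, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return a


def zscore_pair(x, y) -> ZScoredPair:
    """Standard-score each variable: (v - mean) / sd, sample sd (n-1)."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    out = {}
    for name, v in (("x", x), ("y", y)):
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"variable {name!r} has zero variance")
        out[name] = ((v - v.mean()) / sd, float(v.mean()), float(sd))
    return ZScoredPair(x_z=out["x"][0], y_z=out["y"][0], n=len(x),
                       x_mean=out["x"][1], x_sd=out["x"][2],
                       y_mean=out["y"][1], y_sd=out["y"][2])


def pearson_fit(x, y=None) -> CorrelationResult:
    """Pearson r with two-sided p (t, n-2 df) and the least-squares line.

    Accepts either two raw arrays or a ZScoredPair; on z-scored input
    slope == r and intercept == 0 up to floating-point roundoff.
    """
    if isinstance(x, ZScoredPair):
        xv, yv = x.x_z, x.y_z
    else:
        xv, yv = _as_array(x, "x"), _as_array(y, "y")
    if len(xv) < 3:
        raise ValueError("need n >= 3")
    if xv.std(ddof=1) == 0 or yv.std(ddof=1) == 0:
        raise ValueError("degenerate variance")
    r, p = sps.pearsonr(xv, yv)
    X = sm.add_constant(xv)
    ols = sm.OLS(yv, X).fit()
    return CorrelationResult(r=float(r), p_value=float(p),
                             slope=float(ols.params[1]), intercept=float(ols.params[0]),
                             n=len(xv), slope_se=float(ols.bse[1]),
                             intercept_se=float(ols.bse[0]))


def _nested_f(rss_small, df_small, rss_big, df_big):
    num = (rss_small - rss_big) / (df_small - df_big)
    den = rss_big / df_big
    if den <= 0:
        return np.inf, 0.0
    f = num / den
    return f, float(sps.f.sf(f, df_small - df_big, df_big))


def fit_with_linearity_gate(x, y, alpha: float = 0.05):
    """Linear fit unless the deviation from linearity is significant.

    Fits the straight line and tests linearity by the quadratic-vs-linear
    nested-model F-test at ``alpha``; if significant, escalates to the
    second-order polynomial and reports its R² plus a quadratic-vs-cubic
    deviation-from-model check (expected non-significant).
    """
    xv, yv = _as_array(x, "x"), _as_array(y, "y")
    n = len(xv)
    if n < 5:
        raise ValueError("need n >= 5 for the quadratic degrees of freedom")
    fits = {}
    for deg in (1, 2, 3):
        cols = np.column_stack([xv ** k for k in range(deg + 1)])
        res = sm.OLS(yv, cols).fit()
        fits[deg] = res
    _, p_lin = _nested_f(fits[1].ssr, n - 2, fits[2].ssr, n - 3)
    if p_lin >= alpha:
        out = pearson_fit(xv, yv)
        return out
    _, p_dev = _nested_f(fits[2].ssr, n - 3, fits[3].ssr, n - 4)
    return PolyFitResult(coefficients=tuple(float(c) for c in fits[2].params),
                         r_squared=float(fits[2].rsquared),
                         lack_of_linearity_p=p_lin,
                         deviation_from_model_p=p_dev, n=n)


def _summaries(samples: dict) -> dict:
    out = {}
    for label, v in samples.items():
        a = _as_array(v, str(label))
        if len(a) < 2:
            raise ValueError(f"group {label!r} needs n >= 2")
        out[label] = {"mean": float(a.mean()), "sd": float(a.std(ddof=1)),
                      "sem": float(a.std(ddof=1) / np.sqrt(len(a))), "n": len(a)}
    return out


def compare_groups(samples: dict, design: str = "auto",
                   control: str | None = None) -> GroupComparison:
    """Compare group means the way the source analysis does.

    Parameters
    ----------
    samples : dict of label -> 1-D array
    design : {"auto", "t_test", "one_way_anova_dunnett", "one_way_anova_tukey"}
        "auto" picks the t-test for two groups and Dunnett (if a control
        is named) or Tukey otherwise. With exactly two groups every
        design reduces to the two-tailed Student's t-test.
    control : label of the reference group, required for Dunnett.
    """
    labels = list(samples.keys())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    groups = _summaries(samples)
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}

    if design == "auto":
        if len(labels) == 2:
            design = "t_test"
        elif control is not None:
            design = "one_way_anova_dunnett"
        else:
            design = "one_way_anova_tukey"

    if len(labels) == 2:
        a, b = (arrays[k] for k in labels)
        t, p = sps.ttest_ind(a, b)
        comp = [{"pair": (labels[0], labels[1]),
                 "diff": groups[labels[0]]["mean"] - groups[labels[1]]["mean"],
                 "p_raw": float(p), "p_adj": float(p)}]
        return GroupComparison(groups=groups, test="t_test", comparisons=comp,
                               statistic=float(t), p_value=float(p))

    f, p_omni = sps.f_oneway(*arrays.values())

    # raw per-comparison p from the pooled-variance t (same error model the
    # post hoc procedures use), so adjusted p >= raw p holds by construction
    all_vals = list(arrays.values())
    n_total = sum(len(a) for a in all_vals)
    df_pool = n_total - len(all_vals)
    s2_pool = sum((len(a) - 1) * np.var(a, ddof=1) for a in all_vals) / df_pool

    def raw_p(u, v):
        se = np.sqrt(s2_pool * (1 / len(u) + 1 / len(v)))
        tstat = (u.mean() - v.mean()) / se
        return float(2 * sps.t.sf(abs(tstat), df_pool))

    if design == "one_way_anova_dunnett":
        if control is None or control not in arrays:
            raise ValueError("Dunnett post hoc requires a control group label")
        others = [k for k in labels if k != control]
        res = sps.dunnett(*[arrays[k] for k in others], control=arrays[control])
        comps = []
        for k, p_adj in zip(others, res.pvalue):
            comps.append({"pair": (k, control),
                          "diff": groups[k]["mean"] - groups[control]["mean"],
                          "p_raw": raw_p(arrays[k], arrays[control]),
                          "p_adj": float(p_adj)})
        test = "one_way_anova_dunnett"
    elif design == "one_way_anova_tukey":
        res = sps.tukey_hsd(*arrays.values())
        comps = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                comps.append({"pair": (labels[i], labels[j]),
                              "diff": groups[labels[i]]["mean"] - groups[labels[j]]["mean"],
                              "p_raw": raw_p(arrays[labels[i]], arrays[labels[j]]),
                              "p_adj": float(res.pvalue[i, j])})
        test = "one_way_anova_tukey"
    else:
        raise ValueError(f"unknown design {design!r} for {len(labels)} groups")
    return GroupComparison(groups=groups, test=test, comparisons=comps,
                           statistic=float(f), p_value=float(p_omni))


def two_way_anova_tukey(df, value: str, factor_a: str, factor_b: str) -> GroupComparison:
    """Two-way ANOVA with interaction plus Tukey all-pairs on the cells.

    ``df`` is a long-format table; the omnibus statistic/p reported are
    those of factor_a's main effect, and the cell-wise Tukey adjusted
    p-values cover every (factor_a, factor_b) combination.
    """
    import pandas as pd
    from statsmodels.formula.api import ols as smf_ols

    d = pd.DataFrame({"value": df[value], "fa": df[factor_a], "fb": df[factor_b]})
    model = smf_ols("value ~ C(fa) * C(fb)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    cells = {f"{a}|{b}": g["value"].to_numpy()
             for (a, b), g in d.groupby(["fa", "fb"]) if len(g) >= 2}
    out = compare_groups(cells, design="one_way_anova_tukey")
    out.test = "two_way_anova_tukey"
    out.statistic = float(table.loc["C(fa)", "F"])
    out.p_value = float(table.loc["C(fa)", "PR(>F)"])
    return out
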