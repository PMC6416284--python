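"""Plant-response statistics: two-factor ANOVA, Tukey HSD, simple OLS.

Dry matter and colonization are analysed as a source x inoculum factorial
(the greenhouse design), with Tukey's studentized-range test on the eight
cell means and ordinary least squares for dose-response trends such as
colonization vs %P2O5.  Normality (Shapiro-Wilk) is reported, never enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data import ValidationError

__all__ = [
    "AnovaTable",
    "TukeyTable",
    "LinearFit",
    "anova_two_factor",
    "tukey_hsd",
    "linear_fit",
    "normality_check",
]


@dataclass
class AnovaTable:
    table: pd.DataFrame  # rows: factor_a, factor_b, interaction, Residual

    @property
    def ss_total(self) -> float:
        return float(self.table["SS"].sum())

    def summary(self) -> str:
        return "Two-factor ANOVA\n" + self.table.to_string(
            float_format=lambda v: f"{v:.4g}"
        )


@dataclass
class TukeyTable:
    table: pd.DataFrame  # per pair: group1, group2, meandiff, q, p_adj, significant
    alpha: float
    mse: float
    df_resid: int

    def letters(self) -> dict[str, str]:
        """Compact letter display: groups sharing a letter do not differ."""
        groups = sorted(set(self.table["group1"]) | set(self.table["group2"]))
        differ = {
            frozenset((r.group1, r.group2))
            for r in self.table.itertuples()
            if r.significant
        }
        letters: dict[str, str] = {g: "" for g in groups}
        sets: list[set[str]] = []
        for g in groups:
            placed = False
            for s in sets:
                if all(frozenset((g, other)) not in differ for other in s):
                    s.add(g)
                    placed = True
            if not placed:
                sets.append({g})
        for idx, s in enumerate(sets):
            ch = chr(ord("a") + idx)
            for g in s:
                letters[g] += ch
        return letters

    def summary(self) -> str:
        head = f"Tukey HSD (alpha={self.alpha}, MSE={self.mse:.4g}, df={self.df_resid})"
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v:.4g}")


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    rse: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        return (
            f"OLS fit: y = {self.intercept:.6g} + {self.slope:.6g} x "
            f"(R2={self.r_squared:.4f}, p={self.p_value:.3g}, RSE={self.rse:.4g}, n={self.n})"
        )


def anova_two_factor(values, factor_a, factor_b) -> AnovaTable:
    """Two-factor ANOVA with interaction.

    Balanced layouts use the classical sequential decomposition; unbalanced
    layouts fall back to Type II sums of squares.  Degenerate designs (an
    empty cell) are rejected.
    """
    y = np.asarray(values, dtype=float)
    df = pd.DataFrame({"y": y, "a": np.asarray(factor_a), "b": np.asarray(factor_b)})
    cells = df.groupby(["a", "b"], observed=True).size()
    n_a, n_b = df["a"].nunique(), df["b"].nunique()
    if n_a < 2 or n_b < 2:
        raise ValidationError("each factor needs at least 2 levels")
    if len(cells) < n_a * n_b:
        raise ValidationError("empty cell in the two-factor design")
    balanced = cells.nunique() == 1

    model = smf.ols("y ~ C(a) + C(b) + C(a):C(b)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1 if balanced else 2)
    anova = anova.rename(
        index={
            "C(a)": "factor_a",
            "C(b)": "factor_b",
            "C(a):C(b)": "interaction",
        }
    )
    out = pd.DataFrame(
        {
            "df": anova["df"].astype(int),
            "SS": anova["sum_sq"],
            "MS": anova["sum_sq"] / anova["df"],
            "F": anova.get("F"),
            "p": anova.get("PR(>F)"),
        }
    )
    # zero-variance layouts: define F = 0, p = 1 rather than 0/0
    ss_res = out.loc["Residual", "SS"]
    for row in out.index:
        if row == "Residual":
            continue
        if np.isclose(out.loc[row, "SS"], 0.0, atol=1e-12) and np.isclose(ss_res, 0.0, atol=1e-12):
            out.loc[row, ["F", "p"]] = [0.0, 1.0]
    out.loc["Residual", ["F", "p"]] = [np.nan, np.nan]
    return AnovaTable(out)


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyTable:
    """All pairwise comparisons via the studentized range distribution.

    Uses the pooled one-way MSE with its residual degrees of freedom; the
    Tukey-Kramer standard error handles unequal group sizes.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    names = sorted(pd.unique(g).tolist())
    if len(names) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = {name: int((g == name).sum()) for name in names}
    if min(sizes.values()) < 2:
        raise ValidationError("every group needs at least 2 observations")
    means = {name: float(y[g == name].mean()) for name in names}
    n = len(y)
    k = len(names)
    ss_res = sum(((y[g == name] - means[name]) ** 2).sum() for name in names)
    df_resid = n - k
    mse = ss_res / df_resid

    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            diff = means[g2] - means[g1]
            if mse > 0:
                se = np.sqrt(mse / 2.0 * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_resid))
            else:
                q, p_adj = 0.0, 1.0
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "meandiff": diff,
                    "q": q,
                    "p_adj": min(p_adj, 1.0),
                    "significant": p_adj < alpha,
                }
            )
    return TukeyTable(pd.DataFrame(rows), alpha, mse, df_resid)


def linear_fit(x, y) -> LinearFit:
    """Ordinary least squares y = intercept + slope * x.

    Slope p-value from the t distribution with n - 2 df; RSE is
    sqrt(SS_res / (n - 2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    rse = float(np.sqrt((resid**2).sum() / (len(x) - 2)))
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        rse=rse,
        n=len(x),
    )


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value (reported, never enforced)."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)
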