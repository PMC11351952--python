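"""Univariate statistics layer for the two-factor (genotype × diet) design.

Normality screening by Shapiro–Wilk, genotype × diet two-way ANOVA with
Type II sums of squares, Tukey's studentized-range post-hoc, and the two
t-test variants used on normalized data (two-sample, and one-sample against
100%).  Standard distributions and fits come from scipy/statsmodels; the
wrappers enforce the design's validity rules (balanced-enough cells, minimum
group sizes, non-degenerate variances) and return plain result records.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "shapiro_wilk",
    "two_way_anova",
    "tukey_hsd",
    "one_sample_t",
    "two_sample_t",
    "percent_of_group_mean",
]


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    ss: float  # Type II sum of squares


@dataclass
class AnovaResult:
    genotype: AnovaEffect
    diet: AnovaEffect
    interaction: AnovaEffect
    residual_df: int

    def as_frame(self) -> pd.DataFrame:
        rows = {
            "genotype": self.genotype,
            "diet": self.diet,
            "interaction": self.interaction,
        }
        return pd.DataFrame(
            {k: {"F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p} for k, e in rows.items()}
        ).T


@dataclass
class TukeyResult:
    table: pd.DataFrame  # columns: group_a, group_b, diff, q, p_adj


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p (Royston's approximation, 3 ≤ n ≤ 2000)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 2000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 2000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def two_way_anova(values, genotype, diet) -> AnovaResult:
    """Genotype × diet ANOVA with Type II sums of squares.

    Type II matches classical balanced ANOVA exactly and stays sensible for
    the mildly unbalanced cells (6–8 animals) typical of these designs.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": np.asarray(genotype).astype(str),
            "diet": np.asarray(diet).astype(str),
        }
    )
    if df["genotype"].nunique() < 2 or df["diet"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    counts = df.groupby(["genotype", "diet"]).size()
    n_cells = df["genotype"].nunique() * df["diet"].nunique()
    if len(counts) < n_cells:
        raise ValueError("empty genotype x diet cell")
    fit = smf.ols("value ~ C(genotype) * C(diet)", data=df).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    tab = sm.stats.anova_lm(fit, typ=2)
    resid_df = int(tab.loc["Residual", "df"])

    def eff(row: str) -> AnovaEffect:
        return AnovaEffect(
            F=float(tab.loc[row, "F"]),
            df_num=int(tab.loc[row, "df"]),
            df_den=resid_df,
            p=float(tab.loc[row, "PR(>F)"]),
            ss=float(tab.loc[row, "sum_sq"]),
        )

    return AnovaResult(
        genotype=eff("C(genotype)"),
        diet=eff("C(diet)"),
        interaction=eff("C(genotype):C(diet)"),
        residual_df=resid_df,
    )


def tukey_hsd(values, groups) -> TukeyResult:
    """Tukey(-Kramer) all-pairs comparison via the studentized range.

    q = |mean_i − mean_j| / sqrt(MSE/2 · (1/n_i + 1/n_j)); adjusted p from
    the studentized range distribution with k groups and N − k error df.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups).astype(str)
    labels = list(dict.fromkeys(g.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by = {lab: x[g == lab] for lab in labels}
    for lab, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {lab!r} has n < 2")
    k = len(labels)
    n_total = x.size
    df_err = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / df_err
    if mse <= 0:
        raise ValueError("zero within-group variance")
    rows = []
    for a, b in combinations(labels, 2):
        va, vb = by[a], by[b]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / va.size + 1.0 / vb.size))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_err))
        rows.append({"group_a": a, "group_b": b, "diff": diff, "q": float(q), "p_adj": min(max(p, 0.0), 1.0)})
    return TukeyResult(table=pd.DataFrame(rows))


def one_sample_t(values, mu: float = 100.0) -> tuple[float, float]:
    """Two-sided one-sample Student t against ``mu`` (default 100%)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("zero variance")
    t, p = sps.ttest_1samp(x, mu)
    return float(t), float(p)


def two_sample_t(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t (pooled-variance Student by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def percent_of_group_mean(values, values_ref) -> np.ndarray:
    """Express each value as percent of a reference group's mean.

    Used for diet-normalized readouts: Western-diet samples are expressed as
    percent of their own genotype's control-diet mean, then tested against
    100 with :func:`one_sample_t`.
    """
    ref_mean = float(np.mean(np.asarray(values_ref, dtype=float)))
    if ref_mean == 0:
        raise ValueError("reference group mean is zero")
    return 100.0 * np.asarray(values, dtype=float) / ref_mean
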