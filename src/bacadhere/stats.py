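"""First-principles statistics for the adhesion-count comparisons.

Two procedures are used on the adhesion counts: a two-tailed independent
two-sample t-test (pooled-variance Student form by default, Welch
optional), and a balanced two-way ANOVA with treatment and morphology as
crossed factors plus their interaction.  Both are implemented directly
from the sums-of-squares algebra; only the reference distributions (t, F)
come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, UnbalancedDesignError

__all__ = ["TTestResult", "ttest_ind", "anova_two_way"]


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float


def ttest_ind(a, b, pooled: bool = True) -> TTestResult:
    """Two-tailed independent two-sample t-test.

    ``pooled=True`` gives the classical Student test (equal-variance,
    df = n1 + n2 - 2); ``pooled=False`` the Welch form with
    Satterthwaite degrees of freedom.  Degenerate inputs with zero
    variance in both groups yield p = 1 for equal means and the p -> 0
    limit (t = +-inf) for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("non-finite values in input")
    n1, n2 = a.size, b.size
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        if se > 0:
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        else:
            df = n1 + n2 - 2
    if se == 0:
        if m1 == m2:
            return TTestResult(0.0, float(df), 1.0)
        return TTestResult(float(np.sign(m1 - m2) * np.inf), float(df), 0.0)
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def anova_two_way(table: pd.DataFrame, treatment: str = "treatment",
                  morphology: str = "morphology", value: str = "count") -> pd.DataFrame:
    """Balanced two-way ANOVA with interaction.

    Expects a tidy table with one row per observation and a fully crossed,
    balanced layout (equal n >= 2 in every factor cell); unbalanced input
    is refused rather than silently picking a sums-of-squares type.  For
    balanced data the sequential decomposition is order-free:

        SS_A  = b n sum_i (ybar_i.. - ybar...)^2
        SS_B  = a n sum_j (ybar_.j. - ybar...)^2
        SS_AB = n sum_ij (ybar_ij. - ybar_i.. - ybar_.j. + ybar...)^2
        SS_res = sum (y - ybar_ij.)^2

    Returns a DataFrame indexed by effect with columns ``sum_sq``, ``df``,
    ``mean_sq``, ``F``, ``p``.  When the residual mean square is zero
    (constant data) F and p are NaN.
    """
    for col in (treatment, morphology, value):
        if col not in table.columns:
            raise ParameterError(f"missing column {col!r}")
    y = table[value].to_numpy(dtype=float)
    A = table[treatment].to_numpy()
    B = table[morphology].to_numpy()
    a_levels = np.unique(A)
    b_levels = np.unique(B)
    cell_sizes = {
        (ai, bj): int(np.sum((A == ai) & (B == bj)))
        for ai in a_levels for bj in b_levels
    }
    sizes = set(cell_sizes.values())
    if len(sizes) != 1 or min(sizes) < 2:
        raise UnbalancedDesignError(
            "balanced factorial layout required (equal cell n >= 2); "
            f"got cell sizes {sorted(sizes)}"
        )
    n = sizes.pop()
    a, b = len(a_levels), len(b_levels)
    grand = y.mean()
    mean_A = {ai: y[A == ai].mean() for ai in a_levels}
    mean_B = {bj: y[B == bj].mean() for bj in b_levels}
    mean_AB = {
        (ai, bj): y[(A == ai) & (B == bj)].mean()
        for ai in a_levels for bj in b_levels
    }
    ss_A = b * n * sum((mean_A[ai] - grand) ** 2 for ai in a_levels)
    ss_B = a * n * sum((mean_B[bj] - grand) ** 2 for bj in b_levels)
    ss_AB = n * sum(
        (mean_AB[ai, bj] - mean_A[ai] - mean_B[bj] + grand) ** 2
        for ai in a_levels for bj in b_levels
    )
    ss_res = sum(
        ((y[(A == ai) & (B == bj)] - mean_AB[ai, bj]) ** 2).sum()
        for ai in a_levels for bj in b_levels
    )
    df_A, df_B = a - 1, b - 1
    df_AB = df_A * df_B
    df_res = a * b * (n - 1)
    rows = {}
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    for name, ss, df in (
        (treatment, ss_A, df_A),
        (morphology, ss_B, df_B),
        (f"{treatment}:{morphology}", ss_AB, df_AB),
        ("residual", ss_res, df_res),
    ):
        ms = ss / df if df > 0 else np.nan
        if name == "residual" or df == 0 or not np.isfinite(ms_res) or ms_res == 0:
            F = p = np.nan
        else:
            F = ms / ms_res
            p = float(sps.f.sf(F, df, df_res))
        rows[name] = {"sum_sq": ss, "df": df, "mean_sq": ms, "F": F, "p": p}
    return pd.DataFrame(rows).T[["sum_sq", "df", "mean_sq", "F", "p"]]
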