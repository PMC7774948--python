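"""Statistical stage: distribution comparison, skew correction, the
condition x group ANOVA with effect sizes, and Tukey HSD post-hoc tests.

The design is within-subject for vision condition (optimal vs degraded) and
between-subject for degradation group (lower vs higher). Two ANOVA modes
are exposed:

* ``paper_df`` (default) — a two-way fixed-effects ANOVA on the session-
  level values, giving df = (1, N_sessions - 4), i.e. (1, 38) for a
  21-participant cohort. This reproduces the degrees-of-freedom structure
  of published analyses that treat the 42 sessions as independent cells.
* ``mixed`` — the statistically conventional mixed ANOVA with the
  within-subject error term computed from participant x condition cells
  (delegated to pingouin).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int


@dataclass
class TransformRecord:
    """Box-Cox transform provenance: exponent, shift, skew before/after."""

    lmbda: float
    shift: float
    skew_before: float
    skew_after: float
    applied: bool
    note: str = ""


@dataclass
class AnovaResult:
    """Per-effect F tests for the condition x group design."""

    table: pd.DataFrame  # effect, F, df_num, df_den, p, eta_sq
    mode: str

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


# ---------------------------------------------------------------------------

def kde_1d(
    samples: np.ndarray,
    grid: Optional[np.ndarray] = None,
    bandwidth: Optional[float] = None,
) -> tuple:
    """Gaussian kernel density estimate on a stated grid.

    Bandwidth follows Silverman's rule unless a factor is given. Returns
    (grid, density). Raises for zero-variance input, where a fixed
    bandwidth would be needed instead.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples for a KDE")
    if np.std(samples) == 0:
        raise ValueError(
            "zero-variance input: Silverman's rule degenerates; "
            "supply a fixed bandwidth"
        )
    kde = sps.gaussian_kde(samples, bw_method=bandwidth or "silverman")
    if grid is None:
        lo, hi = samples.min(), samples.max()
        pad = 4 * kde.factor * np.std(samples)
        grid = np.linspace(lo - pad, hi + pad, 512)
    return grid, kde(grid)


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum distance between the two empirical CDFs; the null is
    that both samples come from the same continuous distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def boxcox_if_skewed(values: np.ndarray, alpha: float = 0.05) -> tuple:
    """Box-Cox correct a sample if a Shapiro-Wilk pre-test rejects normality.

    Non-positive samples are shifted to positivity first. Returns
    (values, TransformRecord or None); the input is passed through
    untouched when the normality gate does not trigger.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        return values, TransformRecord(
            np.nan, 0.0, 0.0, 0.0, applied=False, note="constant input left unchanged"
        )
    _, p_norm = sps.shapiro(values)
    if p_norm >= alpha:
        return values, None
    shift = 0.0
    if values.min() <= 0:
        shift = -values.min() + 1e-6 * max(1.0, np.ptp(values))
    skew_before = float(sps.skew(values))
    transformed, lmbda = sps.boxcox(values + shift)
    return transformed, TransformRecord(
        float(lmbda), shift, skew_before, float(sps.skew(transformed)), applied=True
    )


# ---------------------------------------------------------------------------
# ANOVA

_REQUIRED_COLS = ("participant", "condition", "group", "value")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    cells = table.groupby(["condition", "group"]).size()
    conditions = table["condition"].unique()
    groups = table["group"].unique()
    absent = [
        (c, g)
        for c in conditions
        for g in groups
        if (c, g) not in cells.index
    ]
    if absent:
        raise ValueError(f"empty condition x group cells: {absent}")


def anova_condition_group(table: pd.DataFrame, mode: str = "paper_df") -> AnovaResult:
    """Two-way ANOVA of one value per session on condition and group.

    ``table`` needs columns participant, condition, group, value (one row
    per session). eta squared is SS_effect / SS_total in both modes.
    """
    _check_table(table)
    if mode == "paper_df":
        return _anova_fixed(table)
    if mode == "mixed":
        return _anova_mixed(table)
    raise ValueError(f"unknown mode {mode!r}; expected 'paper_df' or 'mixed'")


def _anova_fixed(table: pd.DataFrame) -> AnovaResult:
    """Fixed-effects two-way ANOVA on session values (df_den = N - 4).

    Computed directly from cell means (type II sums of squares, which for
    the proportional condition x group layout coincide with types I/III and
    are additive with the interaction and error terms).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={"value": "y"}).copy()
    model = smf.ols("y ~ C(condition) * C(group)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    effects = {
        "condition": "C(condition)",
        "group": "C(group)",
        "condition:group": "C(condition):C(group)",
    }
    df_den = float(aov.loc["Residual", "df"])
    rows = []
    for name, key in effects.items():
        rows.append(
            {
                "effect": name,
                "F": float(aov.loc[key, "F"]),
                "df_num": float(aov.loc[key, "df"]),
                "df_den": df_den,
                "p": float(aov.loc[key, "PR(>F)"]),
                "eta_sq": float(aov.loc[key, "sum_sq"]) / ss_total,
                "ss": float(aov.loc[key, "sum_sq"]),
            }
        )
    rows.append(
        {
            "effect": "residual",
            "F": np.nan,
            "df_num": df_den,
            "df_den": np.nan,
            "p": np.nan,
            "eta_sq": float(aov.loc["Residual", "sum_sq"]) / ss_total,
            "ss": float(aov.loc["Residual", "sum_sq"]),
        }
    )
    return AnovaResult(pd.DataFrame(rows), mode="paper_df")


def _anova_mixed(table: pd.DataFrame) -> AnovaResult:
    """Mixed ANOVA: condition within subjects, group between subjects."""
    import pingouin as pg

    aov = pg.mixed_anova(
        data=table,
        dv="value",
        within="condition",
        subject="participant",
        between="group",
    )
    name_map = {"group": "group", "condition": "condition", "Interaction": "condition:group"}
    rows = []
    for _, r in aov.iterrows():
        rows.append(
            {
                "effect": name_map.get(r["Source"], r["Source"]),
                "F": float(r["F"]),
                "df_num": float(r["DF1"]),
                "df_den": float(r["DF2"]),
                "p": float(r["p_unc"] if "p_unc" in r else r["p-unc"]),
                "eta_sq": float(r["np2"]),  # partial eta squared in mixed mode
                "ss": np.nan,
            }
        )
    return AnovaResult(pd.DataFrame(rows), mode="mixed")


@lru_cache(maxsize=None)
def _studentized_range_crit(k: int, df: int, alpha: float) -> float:
    from scipy.stats import studentized_range

    return float(studentized_range.ppf(1 - alpha, k, df))


def tukey_hsd(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons across the condition x group cells.

    Cells with fewer than 2 observations are excluded (recorded in the
    output's ``attrs["excluded_cells"]``). Returns the studentized-range
    (Tukey-Kramer for unequal n) pairwise table with columns group1,
    group2, meandiff, p-adj, lower, upper, reject. The critical value is
    cached per (k, df, alpha), which keeps repeated calls cheap.
    """
    from itertools import combinations

    from scipy.stats import studentized_range

    _check_table(table)
    df = table.copy()
    df["cell"] = df["condition"].astype(str) + "/" + df["group"].astype(str)
    sizes = df.groupby("cell").size()
    small = sizes[sizes < 2].index.tolist()
    df = df[~df["cell"].isin(small)]
    cells = sorted(df["cell"].unique())
    k = len(cells)
    if k < 2:
        raise ValueError("need at least 2 cells with n >= 2 for Tukey HSD")
    groups = {c: df.loc[df["cell"] == c, "value"].to_numpy(dtype=float) for c in cells}
    ns = {c: g.size for c, g in groups.items()}
    means = {c: g.mean() for c, g in groups.items()}
    df_err = sum(ns.values()) - k
    mse = sum(((g - means[c]) ** 2).sum() for c, g in groups.items()) / df_err
    q_crit = _studentized_range_crit(k, df_err, alpha)
    rows = []
    for c1, c2 in combinations(cells, 2):
        diff = means[c2] - means[c1]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[c1] + 1.0 / ns[c2]))
        q = abs(diff) / se if se > 0 else np.inf
        p_adj = float(studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
        half_width = q_crit * se
        rows.append(
            {
                "group1": c1,
                "group2": c2,
                "meandiff": diff,
                "p-adj": p_adj,
                "lower": diff - half_width,
                "upper": diff + half_width,
                "reject": bool(p_adj < alpha),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded_cells"] = small
    return out
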