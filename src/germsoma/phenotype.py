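"""Survival and categorical phenotype statistics for worm assays.

Kaplan-Meier estimation and the log-rank test run through lifelines;
percent lifespan extension, the summary-statistics two-way ANOVA
(unweighted-means reconstruction from mean/SEM/n cells), Holm-Sidak
adjustment, the Pearson chi-squared test on high/medium/low score tables,
COPAS GFP/TOF normalisation and kinetic slopes are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class SurvivalCohort:
    """Per-animal survival records.

    ``data`` columns: ``time_days`` (> 0), ``event`` (True = death
    observed, False = censored), and one or more grouping columns
    (``group`` by default).
    """

    data: pd.DataFrame
    group_col: str = "group"

    def __post_init__(self) -> None:
        for col in ("time_days", "event"):
            if col not in self.data.columns:
                raise ValueError(f"missing column {col!r}")
        if (self.data["time_days"] <= 0).any():
            raise ValueError("times must be positive")
        if self.group_col not in self.data.columns:
            raise ValueError(f"missing grouping column {self.group_col!r}")

    @classmethod
    def from_csv(cls, path, group_col: str = "group") -> "SurvivalCohort":
        return cls(pd.read_csv(path), group_col=group_col)

    def group(self, label) -> pd.DataFrame:
        sub = self.data[self.data[self.group_col] == label]
        if sub.empty:
            raise ValueError(f"group {label!r} is empty")
        return sub

    def groups(self) -> list:
        return list(self.data[self.group_col].unique())


def km_estimate(cohort: SurvivalCohort, group) -> pd.DataFrame:
    """Product-limit survival estimate for one group.

    Returns a DataFrame indexed by event time with column ``S`` (the KM
    step function, right-continuous, S(0) = 1); censored animals leave the
    risk set without contributing a death.
    """
    sub = cohort.group(group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_days"], event_observed=sub["event"].astype(bool))
    out = kmf.survival_function_
    out.columns = ["S"]
    out.index.name = "time_days"
    return out


def median_survival(cohort: SurvivalCohort, group) -> float:
    sub = cohort.group(group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_days"], event_observed=sub["event"].astype(bool))
    return float(kmf.median_survival_time_)


def logrank_pair(cohort: SurvivalCohort, group_a, group_b) -> tuple[float, float]:
    """Unweighted log-rank test between two groups: (chi2 on 1 df, p)."""
    a, b = cohort.group(group_a), cohort.group(group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("no death events in either group")
    res = _ll_logrank(
        a["time_days"],
        b["time_days"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def percent_extension(mean_treatment: float, mean_control: float) -> float:
    """Percent lifespan (or survival) extension, to 2 decimals."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    if mean_treatment <= 0:
        raise ValueError("treatment mean must be positive")
    return round(100.0 * (mean_treatment / mean_control - 1.0), 2)


@dataclass
class SummaryCell:
    """One table cell: mean lifespan (days), its SEM, and the n behind it."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def variance(self) -> float:
        """Within-cell sample variance recovered from the SEM."""
        return self.sem**2 * self.n


@dataclass
class Anova2Result:
    """Two-way ANOVA decomposition with interaction."""

    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_interaction: float
    p_interaction: float
    df_a: int
    df_b: int
    df_interaction: int
    df_error: int
    ms_error: float

    def summary(self) -> str:
        rows = [
            ("factor A", self.f_a, self.df_a, self.p_a),
            ("factor B", self.f_b, self.df_b, self.p_b),
            ("A x B", self.f_interaction, self.df_interaction, self.p_interaction),
        ]
        lines = ["Two-way ANOVA (unweighted means from summary cells)"]
        for name, f, df, p in rows:
            lines.append(f"  {name:9s} F({df}, {self.df_error}) = {f:.4g}, p = {p:.4g}")
        return "\n".join(lines)


def anova2_from_summary(cells: list[list[SummaryCell]]) -> Anova2Result:
    """Two-way factorial ANOVA reconstructed from mean/SEM/n cells.

    ``cells[i][j]`` is the cell for level i of factor A and level j of
    factor B.  The error mean square pools the within-cell variances
    (SEM^2 * n) over their Sum(n_ij - 1) degrees of freedom; factor and
    interaction sums of squares use unweighted cell means with the
    harmonic mean of the cell sizes, which reproduces the raw-data ANOVA
    exactly when the design is balanced.
    """
    a = len(cells)
    b = len(cells[0])
    if a < 2 or b < 2 or any(len(row) != b for row in cells):
        raise ValueError("need a full a x b grid with a, b >= 2")
    means = np.array([[c.mean for c in row] for row in cells], dtype=float)
    ns = np.array([[c.n for c in row] for row in cells], dtype=float)
    variances = np.array([[c.variance for c in row] for row in cells], dtype=float)

    df_error = int((ns - 1).sum())
    ms_error = float(((ns - 1) * variances).sum() / df_error)

    n_h = a * b / (1.0 / ns).sum()  # harmonic mean cell size
    grand = means.mean()
    row_means = means.mean(axis=1)
    col_means = means.mean(axis=0)
    ss_a = b * n_h * ((row_means - grand) ** 2).sum()
    ss_b = a * n_h * ((col_means - grand) ** 2).sum()
    resid = means - row_means[:, None] - col_means[None, :] + grand
    ss_int = n_h * (resid**2).sum()

    df_a, df_b, df_int = a - 1, b - 1, (a - 1) * (b - 1)

    def _f_p(ss: float, df: int) -> tuple[float, float]:
        if ms_error == 0:
            f = np.inf if ss > 0 else 0.0
        else:
            f = (ss / df) / ms_error
        p = float(stats.f.sf(f, df, df_error)) if np.isfinite(f) else 0.0
        return float(f), p

    f_a, p_a = _f_p(ss_a, df_a)
    f_b, p_b = _f_p(ss_b, df_b)
    f_i, p_i = _f_p(ss_int, df_int)
    return Anova2Result(f_a, p_a, f_b, p_b, f_i, p_i, df_a, df_b, df_int, df_error, ms_error)


def anova2_from_raw(values: pd.DataFrame) -> Anova2Result:
    """Two-way ANOVA from per-animal records (columns: value, a, b).

    Collapses each cell to mean/SEM/n and delegates to the summary-cell
    path; on balanced designs this equals the classical raw-data ANOVA.
    """
    levels_a = sorted(values["a"].unique())
    levels_b = sorted(values["b"].unique())
    cells = []
    for la in levels_a:
        row = []
        for lb in levels_b:
            v = values.loc[(values["a"] == la) & (values["b"] == lb), "value"]
            if len(v) < 2:
                raise ValueError(f"cell ({la}, {lb}) has fewer than 2 observations")
            row.append(SummaryCell(float(v.mean()), float(v.sem()), int(len(v))))
        cells.append(row)
    return anova2_from_summary(cells)


def holm_sidak_adjust(pvals) -> np.ndarray:
    """Step-down Sidak multiple-comparison adjustment."""
    p = np.asarray(pvals, dtype=float)
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm-sidak")[1]


def chi2_score_test(table: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Two-sided Pearson chi-squared test on a groups x categories table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least two groups and two categories")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def copas_normalize(gfp, tof):
    """Per-animal GFP fluorescence normalised to body size (GFP/TOF)."""
    gfp_a = np.asarray(gfp, dtype=float)
    tof_a = np.asarray(tof, dtype=float)
    if (tof_a <= 0).any():
        raise ValueError("TOF values must be positive")
    ratio = gfp_a / tof_a
    return ratio if ratio.ndim else float(ratio)


def kinetic_slope(times, fluorescence) -> float:
    """OLS slope of a kinetic fluorescence trace (activity readout)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.ptp(t) == 0:
        raise ValueError("time vector is constant")
    return float(np.polyfit(t, y, 1)[0])
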