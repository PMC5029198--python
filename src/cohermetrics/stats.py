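"""Hierarchical regression, effect sizes, pooled t-tests and correlations.

The central analysis is a two-step ordinary-least-squares hierarchical
regression on coherence thresholds: gender and non-verbal IQ enter as
control variables at step 1, and either the continuous reading composite
(whole-sample mode) or a good/dyslexia group code (between-group mode)
enters at step 2.  The step-2 increment is judged by the R-squared change

    F_change = (delta_R2 / df1) / ((1 - R2_full) / df2),   df1 = 1,
    df2 = n - k_full - 1,

and its local effect size by Cohen's f-squared,

    f2 = delta_R2 / (1 - R2_full),

with 0.02 / 0.15 / 0.35 the conventional small / medium / large anchors.
Group psychometric differences use the pooled-variance two-sample t-test
(df = n1 + n2 - 2), and cross-task structure uses Pearson correlations of
z-scored thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "HierarchicalModelResult",
    "GroupComparison",
    "CorrelationReport",
    "hierarchical_fit",
    "cohens_f2_local",
    "pooled_t",
    "task_correlations",
]

#: condition number above which a design is flagged as collinear
_COND_LIMIT = 1e10


@dataclass
class CoefficientRecord:
    """One predictor's raw (B), standard-error and standardized (beta) slope."""

    name: str
    B: float
    SE_B: float
    beta: float
    t: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class HierarchicalModelResult:
    """Two-step hierarchical OLS output."""

    n: int
    r2_step1: float
    r2_full: float
    delta_r2: float
    f_change: float
    df_change: tuple[int, int]
    p_change: float
    step1_coefficients: list[CoefficientRecord] = field(default_factory=list)
    coefficients: list[CoefficientRecord] = field(default_factory=list)
    f2_local: float = np.nan

    def coefficient(self, name: str) -> CoefficientRecord:
        for rec in self.coefficients:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def report(self) -> dict:
        def block(recs):
            return [{"name": r.name, "B": r.B, "SE_B": r.SE_B, "beta": r.beta,
                     "t": r.t, "p": r.p} for r in recs]
        return {"n": self.n, "r2_step1": self.r2_step1, "r2_full": self.r2_full,
                "delta_r2": self.delta_r2, "f_change": self.f_change,
                "df_change": list(self.df_change), "p_change": self.p_change,
                "f2_local": self.f2_local, "step1": block(self.step1_coefficients),
                "step2": block(self.coefficients)}


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    res = model.fit()
    cond = np.linalg.cond(model.exog)
    if cond > _COND_LIMIT:
        raise ValueError(f"collinear design (condition number {cond:.3g})")
    return res


def _records(res, X: pd.DataFrame, y: np.ndarray) -> list[CoefficientRecord]:
    sd_y = y.std(ddof=1)
    ci = res.conf_int()
    recs = []
    for name in X.columns:
        sd_x = X[name].std(ddof=1)
        recs.append(CoefficientRecord(
            name=name, B=float(res.params[name]), SE_B=float(res.bse[name]),
            beta=float(res.params[name] * sd_x / sd_y),
            t=float(res.tvalues[name]), p=float(res.pvalues[name]),
            ci_low=float(ci.loc[name, 0]), ci_high=float(ci.loc[name, 1])))
    return recs


def hierarchical_fit(data: pd.DataFrame, y: str, controls: list[str],
                     predictor: str) -> HierarchicalModelResult:
    """Two-step hierarchical OLS: ``controls`` at step 1, + ``predictor`` at step 2.

    Gender should be coded 0/1 (female = 1 by this package's convention)
    and group codes Good = 0, Dyslexia = 1, so a positive B on the step-2
    group term means higher thresholds in the dyslexia group.
    """
    cols = [y, *controls, predictor]
    frame = data[cols].astype(float).dropna()
    n = len(frame)
    if n <= len(controls) + 2:
        raise ValueError("too few observations for the full model")
    yv = frame[y].to_numpy()

    res1 = _fit_ols(yv, frame[controls])
    res2 = _fit_ols(yv, frame[[*controls, predictor]])
    r2_1, r2_2 = float(res1.rsquared), float(res2.rsquared)
    delta = r2_2 - r2_1
    df1, df2 = 1, n - (len(controls) + 1) - 1
    if r2_2 >= 1.0:
        f_change, p_change = np.inf, 0.0
    else:
        f_change = (delta / df1) / ((1.0 - r2_2) / df2)
        p_change = float(scipy.stats.f.sf(f_change, df1, df2))
    f2 = cohens_f2_local(max(delta, 0.0), r2_2) if r2_2 < 1.0 else np.inf
    return HierarchicalModelResult(
        n=n, r2_step1=r2_1, r2_full=r2_2, delta_r2=delta,
        f_change=float(f_change), df_change=(df1, df2), p_change=p_change,
        step1_coefficients=_records(res1, frame[controls], yv),
        coefficients=_records(res2, frame[[*controls, predictor]], yv),
        f2_local=float(f2))


def cohens_f2_local(delta_r2: float, r2_full: float) -> float:
    """Local Cohen's f-squared for one predictor: delta_R2 / (1 - R2_full)."""
    if not 0.0 <= delta_r2 <= r2_full:
        raise ValueError("need 0 <= delta_r2 <= r2_full")
    if r2_full >= 1.0:
        raise ValueError("effect size undefined for a saturated model (R2 = 1)")
    return delta_r2 / (1.0 - r2_full)


@dataclass
class GroupComparison:
    """Two-sample t-test computed from group summary statistics."""

    t: float
    df: float
    p: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    n_per_group: tuple[int, int]
    kind: str = "pooled"


def pooled_t(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
             welch: bool = False) -> GroupComparison:
    """Two-sample t from summary statistics (pooled variance by default).

    The pooled test has df = n1 + n2 - 2; ``welch=True`` switches to the
    unequal-variance test with Welch-Satterthwaite df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            t, df = 0.0, float(n1 + n2 - 2)
            return GroupComparison(t, df, 1.0, (mean1, mean2), (sd1, sd2), (n1, n2))
        raise ValueError("zero variance in both groups with unequal means: "
                         "t statistic is infinite")
    if welch:
        se1, se2 = sd1 ** 2 / n1, sd2 ** 2 / n2
        se = np.sqrt(se1 + se2)
        df = (se1 + se2) ** 2 / (se1 ** 2 / (n1 - 1) + se2 ** 2 / (n2 - 1))
        kind = "welch"
    else:
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        kind = "pooled"
    t = (mean1 - mean2) / se
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df))
    return GroupComparison(float(t), float(df), p, (mean1, mean2), (sd1, sd2),
                           (n1, n2), kind)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations of z-scored threshold columns."""

    columns: list[str]
    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    n: int

    def report(self) -> dict:
        return {"columns": self.columns, "n": self.n,
                "r": self.r_matrix.round(10).to_dict(),
                "p": self.p_matrix.round(10).to_dict()}


def task_correlations(data: pd.DataFrame, columns: list[str] | None = None,
                      ) -> CorrelationReport:
    """All pairwise Pearson r (with two-sided p) between threshold columns.

    Columns are z-transformed first; this leaves r unchanged but matches
    the reporting convention for cross-task scatterplots.
    """
    from .composite import z_transform

    cols = list(columns) if columns is not None else list(data.columns)
    frame = data[cols].astype(float).dropna()
    n = len(frame)
    if n < 4:
        raise ValueError("need at least four observations")
    if np.any(frame.std(ddof=1) == 0.0):
        raise ValueError("constant column: correlation undefined")
    z = z_transform(frame)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            rr, pp = scipy.stats.pearsonr(z[a], z[b])
            r.loc[a, b] = r.loc[b, a] = float(rr)
            p.loc[a, b] = p.loc[b, a] = float(pp)
    return CorrelationReport(cols, r, p, n)
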