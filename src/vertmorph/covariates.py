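"""Covariate-importance analysis for the morphometry metrics.

Three routine analyses quantify how much of the metric variability is
explained by vertebral level versus subject covariates:

- :func:`anova_metric` — least-squares ANOVA of one metric on vertebral
  level (always included, dummy-coded) plus optional covariates, with
  partial (Type II) F statistics per term and the R² of the full fit
  versus a level-only refit.  The comparison of the two R² values is the
  point: when level dominates, dropping every covariate barely moves R².
- :func:`metric_correlations` — Pearson correlation matrix of the six
  metrics.  VBHR and EPA are near-perfectly (negatively) correlated by
  construction: both measure endplate convergence.
- :func:`pca_metrics` — PCA on the 6×6 correlation matrix (correlation,
  not covariance, because the metrics mix unitless ratios with angles in
  degrees); eigenvalues sum to 6.

p values are reported but never used for gating, and no multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import dmatrix

from .errors import RankDeficiencyError, VertmorphError
from .metrics import METRIC_COLUMNS

__all__ = ["AnovaResult", "PcaResult", "anova_metric", "metric_correlations", "pca_metrics"]

_CATEGORICAL = {"sex", "race", "origin", "level", "region"}


@dataclass
class AnovaResult:
    """Per-term partial F tests plus full vs level-only R² for one metric."""

    metric: str
    terms: pd.DataFrame  # columns: term, df, F, p
    r2_full: float
    r2_level_only: float


@dataclass
class PcaResult:
    """Correlation-matrix PCA of the six metrics."""

    eigenvalues: np.ndarray  # descending
    cumulative_variance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = float(np.sum(self.eigenvalues))
        self.cumulative_variance = np.cumsum(self.eigenvalues) / total


def _term_expr(name: str) -> str:
    return f"C({name})" if name in _CATEGORICAL else name


def anova_metric(metrics: pd.DataFrame, metric: str,
                 covariates: list[str] | tuple[str, ...] = ()) -> AnovaResult:
    """ANOVA of ``metric`` on vertebral level plus ``covariates``.

    Level is always included as a categorical factor; ``sex``, ``race``
    and ``origin`` are dummy-coded, other covariates enter as numeric.
    Partial (Type II) F statistics are reported per term.

    Raises
    ------
    RankDeficiencyError
        Naming the first term whose columns are collinear with the
        preceding design.
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    terms = ["level", *covariates]
    data = metrics.dropna(subset=[metric, *covariates])

    # locate rank deficiency term by term so the error can name the culprit
    design = np.ones((len(data), 1))
    for t in terms:
        block = np.asarray(dmatrix(f"0 + {_term_expr(t)}", data))
        cand = np.hstack([design, block])
        gained = np.linalg.matrix_rank(cand) - np.linalg.matrix_rank(design)
        expected = np.linalg.matrix_rank(block) - (1 if t in _CATEGORICAL else 0)
        if gained < expected:
            raise RankDeficiencyError(f"term {t!r} is collinear with the rest of the design")
        design = cand
    if design.shape[0] <= design.shape[1]:
        raise VertmorphError("no residual degrees of freedom for the ANOVA")

    rhs = " + ".join(_term_expr(t) for t in terms)
    fit = smf.ols(f"{metric} ~ {rhs}", data=data).fit()
    table = sm.stats.anova_lm(fit, typ=2).reset_index().rename(columns={
        "index": "term", "F": "F", "PR(>F)": "p"})
    table = table[table["term"] != "Residual"][["term", "df", "F", "p"]]
    fit_level = smf.ols(f"{metric} ~ C(level)", data=data).fit()
    return AnovaResult(metric=metric, terms=table.reset_index(drop=True),
                       r2_full=float(fit.rsquared), r2_level_only=float(fit_level.rsquared))


def metric_correlations(metrics: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the six metrics.

    Constant metrics yield NaN rows/columns (flagged, not an error);
    the diagonal is forced to 1 where defined.
    """
    if len(metrics) < 3:
        raise VertmorphError("need at least 3 rows for correlations")
    corr = metrics[list(METRIC_COLUMNS)].corr(method="pearson")
    return corr


def pca_metrics(metrics: pd.DataFrame) -> PcaResult:
    """Eigendecomposition of the 6×6 metric correlation matrix."""
    if len(metrics) < len(METRIC_COLUMNS) + 1:
        raise VertmorphError("need more rows than metrics for PCA")
    x = metrics[list(METRIC_COLUMNS)].to_numpy(dtype=float)
    if np.any(np.std(x, axis=0) == 0.0):
        constant = [m for m, s in zip(METRIC_COLUMNS, np.std(x, axis=0)) if s == 0.0]
        raise VertmorphError(f"constant metric column(s): {', '.join(constant)}")
    corr = np.corrcoef(x, rowvar=False)
    eigenvalues = np.linalg.eigvalsh(corr)[::-1]
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    return PcaResult(eigenvalues=eigenvalues)
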