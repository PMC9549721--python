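"""Vertebra-specific Z-scores, abnormality flags, and level classification.

The central object is :class:`VertebralZScorer`, a scikit-learn style
transformer: ``fit`` builds the trimmed normative reference (and the
adjacent-level norms) from a metrics table; ``transform`` standardizes a
metrics table into vertebra-specific Z-scores

    Z = (x − μ) / σ

with μ and σ the (region, level, metric)-specific mean and SD of the
trimmed reference.  A metric is flagged abnormal when |Z| > ``z_cut``
(default 2) and a vertebra is "normal" when all six metrics are within
the cut.  Because the trimmed SDs are smaller than the untrimmed SDs
used to identify outliers, re-scoring the reference population itself
flags more than the trimmed-away fraction — this is intentional: the
trimmed SDs are the more sensitive yardstick.

:class:`LevelThresholdClassifier` selects a single metric threshold that
best separates one vertebral level (e.g. S1) from the rest, reporting the
misclassification-minimal threshold and the area under the full ROC
curve.  The Youden-optimal alternative is not implemented; with near-equal
class prevalences the two selections coincide in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.metrics import roc_auc_score

from .errors import MissingReferenceError, VertmorphError
from .metrics import METRIC_COLUMNS
from .reference import adjacent_differences, build_reference, trim_outliers

__all__ = [
    "VertebralZScorer",
    "LevelThresholdClassifier",
    "ThresholdResult",
    "zscore",
    "summarize_subjects",
    "fraction_normal",
    "classify_level_threshold",
]

_Z_COLS = tuple(f"z_{m}" for m in METRIC_COLUMNS)
_FLAG_COLS = tuple(f"abnormal_{m}" for m in METRIC_COLUMNS)


class VertebralZScorer(BaseEstimator, TransformerMixin):
    """Standardize vertebral morphometry into vertebra-specific Z-scores.

    Parameters
    ----------
    trim_k : float, default 2.0
        SD multiplier for the single-pass outlier trim when building the
        reference.  ``inf`` disables trimming.
    z_cut : float, default 2.0
        |Z| threshold for the per-metric abnormality flags.

    Attributes
    ----------
    reference_ : DataFrame
        Per (region, level, metric) reference statistics after trimming.
    trim_report_ : DataFrame
        Before/after counts and moments of the trim.
    adjacent_diffs_ : DataFrame
        Adjacent-level difference norms (caudal − cranial) on trimmed data.

    Examples
    --------
    >>> scorer = VertebralZScorer().fit(metrics_table)   # doctest: +SKIP
    >>> z = scorer.transform(metrics_table)              # doctest: +SKIP
    """

    def __init__(self, trim_k: float = 2.0, z_cut: float = 2.0):
        self.trim_k = trim_k
        self.z_cut = z_cut

    def fit(self, X: pd.DataFrame, y=None) -> "VertebralZScorer":
        """Build the trimmed reference tables from a metrics table ``X``."""
        self._validate_table(X)
        trimmed, report = trim_outliers(X, k=self.trim_k)
        self.reference_ = build_reference(trimmed)
        self.trim_report_ = report
        self.adjacent_diffs_ = adjacent_differences(trimmed)
        self.n_features_in_ = len(METRIC_COLUMNS)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Z-score a metrics table against the fitted reference.

        Returns a frame with ``subject_id, region, level``, the six
        ``z_*`` columns, six boolean ``abnormal_*`` flags,
        ``vertebra_normal`` and ``unscorable`` (True where a reference SD
        is zero, in which case the z columns are NaN and no flags are
        raised).

        Raises
        ------
        MissingReferenceError
            If a (region, level) stratum present in ``X`` has no
            reference entry.
        """
        if not hasattr(self, "reference_"):
            raise VertmorphError("VertebralZScorer is not fitted")
        self._validate_table(X)
        return zscore(X, self.reference_, z_cut=self.z_cut)

    @staticmethod
    def _validate_table(X: pd.DataFrame) -> None:
        missing = [c for c in ("region", "level", *METRIC_COLUMNS) if c not in X.columns]
        if missing:
            raise VertmorphError(f"metrics table lacks column(s): {', '.join(missing)}")


def zscore(metrics: pd.DataFrame, reference: pd.DataFrame, z_cut: float = 2.0,
           ) -> pd.DataFrame:
    """Standardize a metrics table against a reference table (see class docs)."""
    ref = reference.set_index(["region", "level", "metric"])
    out = metrics[[c for c in ("subject_id", "region", "level") if c in metrics.columns]].copy()
    strata = metrics.groupby(["region", "level"], sort=False).groups
    for m in METRIC_COLUMNS:
        out[f"z_{m}"] = np.nan
    out["unscorable"] = False
    for (region, level), idx in strata.items():
        for m in METRIC_COLUMNS:
            try:
                entry = ref.loc[(region, level, m)]
            except KeyError:
                raise MissingReferenceError(
                    f"no reference entry for stratum ({region}, {level}, {m})") from None
            sd = float(entry["sd"])
            if sd == 0.0:
                out.loc[idx, "unscorable"] = True
                continue
            out.loc[idx, f"z_{m}"] = (metrics.loc[idx, m] - float(entry["mean"])) / sd
    for m in METRIC_COLUMNS:
        z = out[f"z_{m}"]
        out[f"abnormal_{m}"] = z.abs().gt(z_cut).fillna(False)
    out["vertebra_normal"] = (~out[list(_FLAG_COLS)].any(axis=1)) & ~out["unscorable"]
    return out


def summarize_subjects(zrecords: pd.DataFrame) -> pd.DataFrame:
    """Per-subject count of abnormal (level, metric) pairs across the region."""
    flags = zrecords[list(_FLAG_COLS)].sum(axis=1)
    summary = (pd.DataFrame({"subject_id": zrecords["subject_id"],
                             "abnormality_sum": flags})
               .groupby("subject_id", sort=True)["abnormality_sum"].sum().reset_index())
    summary["abnormality_sum"] = summary["abnormality_sum"].astype(int)
    return summary


def fraction_normal(zrecords: pd.DataFrame) -> float:
    """Fraction of scorable vertebrae with all six |Z| ≤ z_cut."""
    scorable = zrecords[~zrecords["unscorable"]]
    if len(scorable) == 0:
        return float("nan")
    return float(scorable["vertebra_normal"].mean())


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a single-metric level-separation threshold search."""

    metric: str
    threshold: float
    misclassified: int
    auc: float


class LevelThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier separating one vertebral level by a single metric.

    ``fit`` takes the metric values ``X`` (shape (n,) or (n, 1)) and
    boolean labels ``y`` (True = positive level, e.g. S1) and selects the
    threshold minimizing total misclassifications, predicting positive
    where ``value > threshold``.  Candidate thresholds are the midpoints
    between consecutive sorted distinct values plus ±inf; ties are broken
    toward the lowest threshold.

    Attributes
    ----------
    threshold_ : float
    misclassified_ : int
    auc_ : float
        Trapezoid-rule area under the full ROC curve.
    """

    def __init__(self):
        pass

    def fit(self, X, y) -> "LevelThresholdClassifier":
        values = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=bool).reshape(-1)
        if values.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if y.all() or not y.any():
            raise VertmorphError("threshold search needs both classes present")
        distinct = np.unique(values)
        candidates = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0,
                                     [np.inf]))
        pos, neg = np.sort(values[y]), np.sort(values[~y])
        # predict positive iff value > t:  errors = (#pos ≤ t) + (#neg > t)
        fn = np.searchsorted(pos, candidates, side="right")
        fp = len(neg) - np.searchsorted(neg, candidates, side="right")
        errors = fn + fp
        best = int(np.argmin(errors))  # argmin takes the first = lowest threshold
        self.threshold_ = float(candidates[best])
        self.misclassified_ = int(errors[best])
        self.auc_ = float(roc_auc_score(y, values))
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        values = np.asarray(X, dtype=float).reshape(-1)
        return values > self.threshold_

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float).reshape(-1) - self.threshold_


def classify_level_threshold(metrics: pd.DataFrame, positive_level: str,
                             metric: str = "fbdr") -> ThresholdResult:
    """Find the metric threshold separating ``positive_level`` from the others.

    Operates on one region at a time (filter the table first if it spans
    regions whose level names collide).
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    y = (metrics["level"] == positive_level).to_numpy()
    clf = LevelThresholdClassifier().fit(metrics[metric].to_numpy(dtype=float), y)
    return ThresholdResult(metric=metric, threshold=clf.threshold_,
                           misclassified=clf.misclassified_, auc=clf.auc_)
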