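"""Trimmed normative reference tables and adjacent-level difference norms.

The normative pipeline is deliberately simple and mirrors common practice
for constructing morphometric reference data from a large population
sample:

1. Within each (region, level) stratum, compute the untrimmed mean and
   sample SD of each of the six metrics, and *trim* — drop a vertebra if
   any of its six metrics lies more than ``k`` SDs from the stratum mean
   (default k = 2).  Trimming is a single pass; it is not iterated to
   convergence.
2. Tabulate descriptive statistics (n, mean, SD, CV, skewness, kurtosis)
   of the trimmed data per (region, level, metric).  These means and SDs
   are the μ and σ of the downstream Z-score standardization.
3. Tabulate, per subject and per adjacent level pair, the caudal − cranial
   difference of each metric among trimming survivors, giving normal
   ranges (mean ± 1.96 SD) for adjacent-level comparisons.

SDs use the n−1 (sample) denominator.  Skewness and kurtosis are the
moment (biased) definitions, with kurtosis reported non-excess so a
Gaussian has kurtosis 3.  Strata are pooled over sex/age/race: covariates
contribute little to metric variability compared with vertebral level.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import REGION_LEVELS, adjacent_pairs
from .metrics import METRIC_COLUMNS

__all__ = [
    "trim_outliers",
    "build_reference",
    "adjacent_differences",
    "normal_range",
]

logger = logging.getLogger(__name__)

_STRATUM = ["region", "level"]


def _level_sorter(region: str):
    order = {lv: i for i, lv in enumerate(REGION_LEVELS[region])}
    return order


def trim_outliers(metrics: pd.DataFrame, k: float = 2.0,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass k-SD trimming per (region, level) stratum.

    A vertebra is dropped when *any* of its six metrics is more than
    ``k`` sample SDs from its stratum's untrimmed mean.  A metric with
    zero SD in a stratum imposes no exclusions.  ``k = inf`` is the
    identity.

    Returns the trimmed table and a trim report with one row per
    (region, level, metric) holding before/after counts and moments.
    """
    if k <= 0:
        raise ValueError("trim multiplier k must be positive")
    keep_all = pd.Series(True, index=metrics.index)
    report_rows = []
    for (region, level), grp in metrics.groupby(_STRATUM, sort=False):
        keep = pd.Series(True, index=grp.index)
        stats_before = {}
        for m in METRIC_COLUMNS:
            x = grp[m].to_numpy(dtype=float)
            mean = float(np.mean(x))
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            stats_before[m] = (mean, sd, _skew(x), _kurt(x))
            if sd == 0.0:
                logger.info("stratum (%s, %s): metric %s has zero SD; no exclusions",
                            region, level, m)
                continue
            if math.isfinite(k):
                keep &= (grp[m] - mean).abs() <= k * sd
        kept = grp[keep]
        keep_all[grp.index[~keep]] = False
        for m in METRIC_COLUMNS:
            mean_b, sd_b, sk_b, ku_b = stats_before[m]
            xk = kept[m].to_numpy(dtype=float)
            report_rows.append({
                "region": region, "level": level, "metric": m,
                "n_before": len(grp), "n_after": len(kept),
                "mean_before": mean_b, "sd_before": sd_b,
                "skewness_before": sk_b, "kurtosis_before": ku_b,
                "skewness_after": _skew(xk), "kurtosis_after": _kurt(xk),
            })
    trimmed = metrics[keep_all]  # original row order preserved
    return trimmed, pd.DataFrame(report_rows)


def _skew(x: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0.0:
        return 0.0
    return float(stats.skew(x, bias=True))


def _kurt(x: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0.0:
        return 0.0
    return float(stats.kurtosis(x, fisher=False, bias=True))


def build_reference(trimmed: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per (region, level, metric) from a trimmed table.

    Columns: ``region, level, metric, n, mean, sd, cv, skewness, kurtosis,
    degenerate``.  ``degenerate`` marks strata whose SD is zero, where
    skewness/kurtosis are reported as 0 by convention.  Strata with fewer
    than 2 vertebrae are omitted with a warning.
    """
    rows = []
    for (region, level), grp in trimmed.groupby(_STRATUM, sort=False):
        if len(grp) < 2:
            logger.warning("stratum (%s, %s) has n=%d < 2; omitted from reference",
                           region, level, len(grp))
            continue
        for m in METRIC_COLUMNS:
            x = grp[m].to_numpy(dtype=float)
            mean = float(np.mean(x))
            sd = float(np.std(x, ddof=1))
            degenerate = sd == 0.0
            rows.append({
                "region": region, "level": level, "metric": m, "n": len(x),
                "mean": mean, "sd": sd,
                "cv": sd / mean if mean != 0.0 else np.nan,
                "skewness": _skew(x), "kurtosis": _kurt(x),
                "degenerate": degenerate,
            })
    ref = pd.DataFrame(rows, columns=["region", "level", "metric", "n", "mean",
                                      "sd", "cv", "skewness", "kurtosis", "degenerate"])
    return ref


def normal_range(mean_diff: float, sd_diff: float, z: float = 1.96) -> tuple[float, float]:
    """Normal range mean ± z·SD for an adjacent-level metric difference."""
    half = z * sd_diff
    return (mean_diff - half, mean_diff + half)


def adjacent_differences(trimmed: pd.DataFrame) -> pd.DataFrame:
    """Per-subject caudal − cranial metric differences for adjacent level pairs.

    Differences are computed only among vertebrae that survived trimming
    and only for subjects contributing both levels of a pair.  Pairs with
    fewer than 2 subjects are omitted.

    Columns: ``region, cranial, caudal, metric, n, mean_diff, sd_diff,
    lo95, hi95`` where the 95% limits are mean ± 1.96 SD.
    """
    rows = []
    for region, grp in trimmed.groupby("region", sort=False):
        for cranial, caudal in adjacent_pairs(region):
            upper = grp[grp["level"] == cranial].set_index("subject_id")
            lower = grp[grp["level"] == caudal].set_index("subject_id")
            common = upper.index.intersection(lower.index)
            if len(common) < 2:
                continue
            for m in METRIC_COLUMNS:
                diff = (lower.loc[common, m] - upper.loc[common, m]).to_numpy(dtype=float)
                mean_d = float(np.mean(diff))
                sd_d = float(np.std(diff, ddof=1))
                lo, hi = normal_range(mean_d, sd_d)
                rows.append({"region": region, "cranial": cranial, "caudal": caudal,
                             "metric": m, "n": len(diff), "mean_diff": mean_d,
                             "sd_diff": sd_d, "lo95": lo, "hi95": hi})
    return pd.DataFrame(rows, columns=["region", "cranial", "caudal", "metric", "n",
                                       "mean_diff", "sd_diff", "lo95", "hi95"])
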