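"""Z-score standardization, subject summaries, and threshold classification."""

import numpy as np
import pandas as pd
import pytest

from vertmorph import (LevelThresholdClassifier, MissingReferenceError,
                       VertebralZScorer, VertmorphError, classify_level_threshold,
                       fraction_normal, summarize_subjects, zscore)
from vertmorph.metrics import METRIC_COLUMNS


def _ref_entry(region="lumbar", level="L1", mean=1.0, sd=0.042):
    return [{"region": region, "level": level, "metric": m, "n": 100,
             "mean": mean, "sd": sd, "cv": sd / mean, "skewness": 0.0,
             "kurtosis": 3.0, "degenerate": sd == 0}
            for m in METRIC_COLUMNS]


def _metrics_row(region="lumbar", level="L1", value=1.0, subject="S1"):
    row = {"subject_id": subject, "region": region, "level": level}
    row.update({m: value for m in METRIC_COLUMNS})
    return row


class TestZscore:
    def test_at_the_mean_z_is_zero(self):
        ref = pd.DataFrame(_ref_entry())
        table = pd.DataFrame([_metrics_row(value=1.0)])
        z = zscore(table, ref)
        assert z["z_vbhr"].iloc[0] == 0.0
        assert z["vertebra_normal"].iloc[0]

    def test_printed_reference_arithmetic(self):
        """x = 0.85 against mu = 1, sigma = 0.042 gives Z = -3.5714."""
        ref = pd.DataFrame(_ref_entry(mean=1.0, sd=0.042))
        table = pd.DataFrame([_metrics_row(value=0.85)])
        z = zscore(table, ref)
        assert z["z_vbhr"].iloc[0] == pytest.approx(-0.15 / 0.042, abs=1e-9)
        assert z["z_vbhr"].iloc[0] == pytest.approx(-3.5714, abs=1e-4)

    def test_missing_stratum_names_it(self):
        ref = pd.DataFrame(_ref_entry(level="L1"))
        table = pd.DataFrame([_metrics_row(level="L2")])
        with pytest.raises(MissingReferenceError, match="L2"):
            zscore(table, ref)

    def test_zero_sd_marks_unscorable(self):
        ref = pd.DataFrame(_ref_entry(sd=0.0))
        table = pd.DataFrame([_metrics_row(value=1.3)])
        z = zscore(table, ref)
        assert z["unscorable"].iloc[0]
        assert not z["vertebra_normal"].iloc[0]
        assert not z[[f"abnormal_{m}" for m in METRIC_COLUMNS]].iloc[0].any()

    def test_self_scored_population_has_unit_moments(self, gaussian_metrics):
        """Scoring a sample against its own moments gives mean 0, SD 1 exactly."""
        from vertmorph import build_reference

        table = gaussian_metrics(500)
        ref = build_reference(table)
        z = zscore(table, ref)
        for m in METRIC_COLUMNS:
            assert z[f"z_{m}"].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[f"z_{m}"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zcut_three_flags_subset_of_zcut_two(self, gaussian_metrics):
        from vertmorph import build_reference

        table = gaussian_metrics(500)
        ref = build_reference(table)
        loose = zscore(table, ref, z_cut=3.0)
        tight = zscore(table, ref, z_cut=2.0)
        for m in METRIC_COLUMNS:
            assert not (loose[f"abnormal_{m}"] & ~tight[f"abnormal_{m}"]).any()


class TestVertebralZScorer:
    def test_fit_transform_pipeline(self, lumbar_metrics):
        scorer = VertebralZScorer(trim_k=2.0, z_cut=2.0).fit(lumbar_metrics)
        assert {"region", "level", "metric", "mean", "sd"} <= set(scorer.reference_.columns)
        z = scorer.transform(lumbar_metrics)
        assert len(z) == len(lumbar_metrics)
        # trimmed SDs are tighter than the trim itself, so < 75.6% are fully normal
        assert fraction_normal(z) < 0.9545 ** 6

    def test_sklearn_get_set_params(self):
        scorer = VertebralZScorer()
        assert scorer.get_params() == {"trim_k": 2.0, "z_cut": 2.0}
        scorer.set_params(z_cut=3.0)
        assert scorer.z_cut == 3.0

    def test_transform_before_fit_raises(self, lumbar_metrics):
        with pytest.raises(VertmorphError):
            VertebralZScorer().transform(lumbar_metrics)

    def test_contamination_lowers_fraction_normal(self):
        """Against a fixed normative reference, more fracture contamination
        means fewer fully normal vertebrae."""
        from vertmorph import compute_dataset_metrics, default_cohort_spec, generate_cohort

        clean_spec = default_cohort_spec(n_subjects=300, contamination_rate=0.0, seed=7)
        clean_ds, _ = generate_cohort(clean_spec)
        clean_table, _ = compute_dataset_metrics(clean_ds)
        scorer = VertebralZScorer().fit(clean_table)

        fractions = []
        for rate in (0.0, 0.10, 0.25):
            spec = default_cohort_spec(n_subjects=150, contamination_rate=rate, seed=8)
            ds, _ = generate_cohort(spec)
            table, _ = compute_dataset_metrics(ds)
            fractions.append(fraction_normal(scorer.transform(table)))
        assert fractions[0] > fractions[1] > fractions[2]


class TestSummaries:
    def test_counts_abnormal_level_metric_pairs(self):
        ref = pd.DataFrame(_ref_entry(level="L1") + _ref_entry(level="L2"))
        rows = [_metrics_row(level="L1", value=1.0, subject="A"),
                _metrics_row(level="L2", value=1.0, subject="A"),
                _metrics_row(level="L1", value=1.0 + 3 * 0.042, subject="B")]
        z = zscore(pd.DataFrame(rows), ref)
        summary = summarize_subjects(z).set_index("subject_id")
        assert summary.loc["A", "abnormality_sum"] == 0
        # subject B deviates by 3 SD on every metric of one level
        assert summary.loc["B", "abnormality_sum"] == 6

    def test_gaussian_fraction_normal(self, gaussian_metrics):
        from vertmorph import build_reference

        table = gaussian_metrics(20_000)
        ref = build_reference(table)
        z = zscore(table, ref)
        assert fraction_normal(z) == pytest.approx(0.9545 ** 6, abs=0.01)


def _brute_force_threshold(values, y):
    """O(n^2) exhaustive search over midpoint candidates, lowest-threshold ties."""
    distinct = np.unique(values)
    candidates = [-np.inf] + [(a + b) / 2 for a, b in zip(distinct, distinct[1:])] + [np.inf]
    best_t, best_err = None, None
    for t in candidates:
        pred = values > t
        err = int(np.sum(pred != y))
        if best_err is None or err < best_err:
            best_t, best_err = t, err
    return best_t, best_err


class TestThresholdClassifier:
    def test_worked_example(self):
        values = np.array([1.10, 1.08, 1.00, 1.02, 1.06])
        y = np.array([True, True, False, False, False])
        clf = LevelThresholdClassifier().fit(values, y)
        assert clf.threshold_ == pytest.approx(1.07)
        assert clf.misclassified_ == 0
        assert clf.auc_ == 1.0
        assert list(clf.predict([1.0, 1.09])) == [False, True]

    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        neg = rng.uniform(0, 1, 50)
        pos = rng.uniform(2, 3, 50)
        clf = LevelThresholdClassifier().fit(np.concatenate([neg, pos]),
                                             np.repeat([False, True], 50))
        assert clf.auc_ == 1.0
        assert clf.misclassified_ == 0

    def test_identical_distributions_auc_near_half(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 4000)
        y = np.repeat([False, True], 2000)
        clf = LevelThresholdClassifier().fit(values, y)
        assert clf.auc_ == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(VertmorphError):
            LevelThresholdClassifier().fit([1.0, 2.0], [True, True])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 200)
            values = np.round(rng.normal(1.0, 0.05, n), 3)
            y = rng.random(n) < 0.3
            if y.all() or not y.any():
                continue
            clf = LevelThresholdClassifier().fit(values, y)
            bf_t, bf_err = _brute_force_threshold(values, y)
            assert clf.misclassified_ == bf_err
            assert clf.threshold_ == pytest.approx(bf_t)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        values = rng.normal(1.0, 0.1, 300)
        y = rng.random(300) < 0.4
        a1 = LevelThresholdClassifier().fit(values, y).auc_
        a2 = LevelThresholdClassifier().fit(np.exp(3 * values), y).auc_
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_classify_s1_from_cohort(self, lumbar_metrics):
        result = classify_level_threshold(lumbar_metrics, "S1", metric="fbdr")
        assert result.auc > 0.9
        assert result.threshold > 1.0
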