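"""Quadrilateral construction and synthetic cohort generation."""

import numpy as np
import pandas as pd
import pytest

from vertmorph import (ContaminationSpec, InfeasibleParameterError, LevelShapeSpec,
                       SyntheticCohortSpec, build_quadrilateral, compute_dataset_metrics,
                       compute_metrics, default_cohort_spec, generate_cohort)
from vertmorph.metrics import METRIC_COLUMNS


class TestBuildQuadrilateral:
    def test_neutral_parameters_give_unit_square_shape(self):
        lm = build_quadrilateral(1.0, 1.0, 1.0, 90.0)
        six = compute_metrics(lm)
        for name, expected in [("vbhr", 1), ("epwr", 1), ("fbdr", 1), ("hwr", 1),
                               ("epa_deg", 0), ("psa_deg", 90)]:
            assert six.as_dict()[name] == pytest.approx(expected, abs=1e-9)

    def test_round_trip_single(self):
        lm = build_quadrilateral(0.8, 1.0, 1.0, 90.0)
        six = compute_metrics(lm)
        assert six.vbhr == pytest.approx(0.8, abs=1e-9)
        assert six.psa_deg == pytest.approx(90.0, abs=1e-9)

    def test_round_trip_random_sweep(self):
        """1000 random parameter draws rebuild and re-measure to 1e-9."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            vbhr = rng.uniform(0.8, 1.3)
            epwr = rng.uniform(0.85, 1.15)
            hwr = rng.uniform(0.6, 1.1)
            psa = rng.uniform(82.0, 98.0)
            six = compute_metrics(build_quadrilateral(vbhr, epwr, hwr, psa))
            assert six.vbhr == pytest.approx(vbhr, abs=1e-9)
            assert six.epwr == pytest.approx(epwr, abs=1e-9)
            assert six.hwr == pytest.approx(hwr, abs=1e-9)
            assert six.psa_deg == pytest.approx(psa, abs=1e-9)

    def test_infeasible_parameters_raise(self):
        # anterior height far too short for any inclination within +/-30 degrees
        with pytest.raises(InfeasibleParameterError):
            build_quadrilateral(0.05, 1.0, 1.0, 90.0)
        with pytest.raises(InfeasibleParameterError):
            build_quadrilateral(-1.0, 1.0, 1.0, 90.0)


class TestSpecs:
    def test_contamination_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ContaminationSpec(weights={"none": 0.5, "crush": 0.2})

    def test_unknown_contamination_type_rejected(self):
        with pytest.raises(ValueError):
            ContaminationSpec(weights={"none": 0.5, "explosion": 0.5})

    def test_levels_must_match_region(self):
        shape = LevelShapeSpec(vbhr=(1, 0.04), epwr=(1, 0.03),
                               hwr=(0.9, 0.04), psa=(90, 1))
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_subjects=5, region="cervical",
                                level_shapes={"L1": shape})


class TestGenerateCohort:
    def test_zero_sd_no_contamination_hits_means_exactly(self):
        shape = LevelShapeSpec(vbhr=(1.05, 0.0), epwr=(0.98, 0.0),
                               hwr=(0.85, 0.0), psa=(92.0, 0.0))
        spec = SyntheticCohortSpec(n_subjects=5, region="lumbar",
                                   level_shapes={"L1": shape}, seed=3)
        ds, truth = generate_cohort(spec)
        table, _ = compute_dataset_metrics(ds)
        np.testing.assert_allclose(table["vbhr"], 1.05, atol=1e-9)
        np.testing.assert_allclose(table["epwr"], 0.98, atol=1e-9)
        np.testing.assert_allclose(table["hwr"], 0.85, atol=1e-9)
        np.testing.assert_allclose(table["psa_deg"], 92.0, atol=1e-9)

    def test_seed_determinism(self):
        spec = default_cohort_spec(n_subjects=20, seed=11)
        ds1, truth1 = generate_cohort(spec)
        ds2, truth2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(ds1.to_frame(), ds2.to_frame())
        pd.testing.assert_frame_equal(truth1, truth2)
        ds3, _ = generate_cohort(default_cohort_spec(n_subjects=20, seed=12))
        assert not ds1.to_frame()[["x", "y"]].equals(ds3.to_frame()[["x", "y"]])

    def test_transforms_leave_metrics_at_truth(self, lumbar_cohort, lumbar_metrics):
        """Similarity transforms (incl. mirrors) never move the six metrics."""
        _, _, truth = lumbar_cohort
        merged = lumbar_metrics.merge(truth, on=["subject_id", "region", "level"])
        for m in METRIC_COLUMNS:
            np.testing.assert_allclose(merged[m], merged[f"true_{m}"],
                                       rtol=0, atol=1e-9)

    def test_contamination_rate_recovered(self):
        spec = default_cohort_spec(n_subjects=400, contamination_rate=0.10, seed=5)
        _, truth = generate_cohort(spec)
        frac = (truth["contamination"] != "none").mean()
        n = len(truth)
        # binomial 3-SE band around 0.10
        assert abs(frac - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n)
        kinds = truth.loc[truth["contamination"] != "none", "contamination"].unique()
        assert set(kinds) == {"anterior_wedge", "posterior_wedge", "crush",
                              "epwr_anomaly"}

    def test_vbhr_moments_recover_generator(self):
        """Sample VBHR mean/SD of a clean cohort match mu=1, sigma=0.042."""
        spec = default_cohort_spec(n_subjects=1000, contamination_rate=0.0, seed=2)
        spec = SyntheticCohortSpec(n_subjects=1000, region="lumbar",
                                   level_shapes={"L1": spec.level_shapes["L1"]},
                                   contamination=spec.contamination, seed=2)
        ds, _ = generate_cohort(spec)
        table, _ = compute_dataset_metrics(ds)
        n = len(table)
        assert abs(table["vbhr"].mean() - 1.0) < 3 * 0.042 / np.sqrt(n)
        assert table["vbhr"].std() == pytest.approx(0.042, rel=0.1)

    def test_injected_anterior_wedge_is_detected(self):
        """A 0.8 height-factor wedge lands at vbhr z <= -2 in >= 95% of cases."""
        from vertmorph import VertebralZScorer

        spec = default_cohort_spec(n_subjects=600, contamination_rate=0.0, seed=9)
        ds, _ = generate_cohort(spec)
        table, _ = compute_dataset_metrics(ds)
        scorer = VertebralZScorer().fit(table)

        wedge_spec = SyntheticCohortSpec(
            n_subjects=200, region="lumbar", level_shapes=spec.level_shapes,
            contamination=ContaminationSpec(
                weights={"anterior_wedge": 1.0}, wedge_severity=(0.8, 0.8)),
            seed=10)
        wds, wtruth = generate_cohort(wedge_spec)
        wtable, _ = compute_dataset_metrics(wds)
        z = scorer.transform(wtable)
        assert (z["z_vbhr"] <= -2).mean() >= 0.95
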