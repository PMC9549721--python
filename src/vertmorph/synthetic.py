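"""Synthetic landmark cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in real populations:

- per-level Gaussian "shape cores" for the four free shape parameters of
  a vertebral quadrilateral — (vbhr, epwr, hwr, psa).  After removing
  similarity (position, orientation, scale) a quadrilateral has exactly
  four shape degrees of freedom, so these four parameters determine the
  shape and the remaining two metrics (epa, fbdr) are emergent.  This
  gives an internal consistency oracle: rebuild → re-measure must round
  trip.
- heavy-tailed contamination by fracture-like deformities (anterior
  wedge, posterior wedge, crush, endplate-width anomaly), applied
  geometrically to the corner points so the severity factor scales the
  named height/width exactly and the other metrics respond the way a
  real deformity would (a wedge tilts the superior endplate, so it moves
  PSA and EPA as well as VBHR);
- arbitrary similarity transforms of the coordinates (magnification,
  rotation, translation, occasional mirror), under which all six metrics
  are invariant;
- subject covariates with NHANES-like marginals (ages 25–74, a
  white/black/other race mix near 87/11/2, BMI from height and weight).

Defaults are neutral rectangles (vbhr = 1, epwr = 1, psa = 90°; hwr 0.9
lumbar, 0.75 cervical) with a VBHR SD of 0.042, except L5 (vbhr 1.124,
matching a caudal−cranial L4→L5 VBHR difference of 0.124) and the
anterior-tall S1 (vbhr 1.15 with psa 100°: the sacral superior endplate
is inclined, which is what expresses the extra anterior height on the
superior side and makes S1's forward/backward diagonal ratio exceed the
lumbar range).  These stand in for population tables and are
configuration, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleParameterError
from .landmarks import (REGION_LEVELS, CornerLandmarks, StudyDataset,
                        VertebraLabel, VertebraRecord)
from .metrics import compute_metrics

__all__ = [
    "LevelShapeSpec",
    "ContaminationSpec",
    "SyntheticCohortSpec",
    "default_cohort_spec",
    "build_quadrilateral",
    "generate_cohort",
]

SHAPE_PARAMS = ("vbhr", "epwr", "hwr", "psa")
CONTAMINATION_TYPES = ("none", "anterior_wedge", "posterior_wedge", "crush", "epwr_anomaly")

_MAX_INCLINATION_DEG = 30.0
_TRUNCATION_SD = 4.0
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class LevelShapeSpec:
    """Mean and SD of the four free shape parameters for one level."""

    vbhr: tuple[float, float]
    epwr: tuple[float, float]
    hwr: tuple[float, float]
    psa: tuple[float, float]  # degrees

    def __post_init__(self) -> None:
        for name in SHAPE_PARAMS:
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")
            if name != "psa" and mean <= 0:
                raise ValueError(f"{name} mean must be > 0")
        if not 0 < self.psa[0] < 180:
            raise ValueError("psa mean must be in (0, 180) degrees")


@dataclass(frozen=True)
class ContaminationSpec:
    """Mixture of fracture-like deformities applied to the corner points.

    ``weights`` maps each contamination type to its probability (must sum
    to 1).  Severities are multiplicative height/width factors drawn
    uniformly from the stated ranges and applied geometrically:

    - anterior wedge: AS moves toward AI so the anterior height scales
      by the factor (the superior endplate tilts — VBHR, EPA and PSA
      all respond);
    - posterior wedge: PS moves toward PI, scaling the posterior height;
    - crush: both superior corners move down, scaling both heights;
    - endplate-width anomaly: AS slides along the superior endplate so
      the superior width scales by the factor (or its reciprocal,
      equally likely).
    """

    weights: dict[str, float] = field(default_factory=lambda: {"none": 1.0})
    wedge_severity: tuple[float, float] = (0.70, 0.85)
    crush_severity: tuple[float, float] = (0.70, 0.85)
    epwr_severity: tuple[float, float] = (1.15, 1.30)

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CONTAMINATION_TYPES)
        if unknown:
            raise ValueError(f"unknown contamination type(s): {sorted(unknown)}")
        w = np.array([self.weights.get(t, 0.0) for t in CONTAMINATION_TYPES])
        if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("contamination weights must be >= 0 and sum to 1")

    def probabilities(self) -> np.ndarray:
        return np.array([self.weights.get(t, 0.0) for t in CONTAMINATION_TYPES])


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full generative recipe for one synthetic cohort (bit-exact under seed)."""

    n_subjects: int
    region: str
    level_shapes: dict[str, LevelShapeSpec]
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)
    scale_range: tuple[float, float] = (0.5, 2.0)
    rotation_range_deg: tuple[float, float] = (-10.0, 10.0)
    translation_range: tuple[float, float] = (-50.0, 50.0)
    flip_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.region not in REGION_LEVELS:
            raise ValueError(f"unknown region {self.region!r}")
        missing = set(self.level_shapes) - set(REGION_LEVELS[self.region])
        if missing:
            raise ValueError(f"levels {sorted(missing)} not in region {self.region!r}")


_DEFAULT_SD = {"vbhr": 0.042, "epwr": 0.03, "hwr": 0.045, "psa": 1.0}


def default_cohort_spec(region: str = "lumbar", n_subjects: int = 500,
                        contamination_rate: float = 0.05, seed: int = 0,
                        ) -> SyntheticCohortSpec:
    """Cohort spec with the package's default level shapes and contamination.

    ``contamination_rate`` is split equally between anterior wedge,
    posterior wedge, crush and endplate-width anomaly.
    """
    shapes: dict[str, LevelShapeSpec] = {}
    hwr_mean = 0.9 if region == "lumbar" else 0.75
    for level in REGION_LEVELS[region]:
        vbhr_mean, psa_mean = 1.0, 90.0
        if level == "L5":
            vbhr_mean = 1.124  # neutral L4 plus the target L4→L5 shift of 0.124
        elif level == "S1":
            # anterior-tall with an inclined superior (sacral) endplate, so the
            # extra anterior height sits superiorly and FBDR rises above the
            # lumbar range
            vbhr_mean, psa_mean = 1.15, 100.0
        shapes[level] = LevelShapeSpec(
            vbhr=(vbhr_mean, _DEFAULT_SD["vbhr"]),
            epwr=(1.0, _DEFAULT_SD["epwr"]),
            hwr=(hwr_mean, _DEFAULT_SD["hwr"]),
            psa=(psa_mean, _DEFAULT_SD["psa"]),
        )
    if not 0 <= contamination_rate < 1:
        raise ValueError("contamination_rate must be in [0, 1)")
    each = contamination_rate / 4.0
    contamination = ContaminationSpec(weights={
        "none": 1.0 - contamination_rate, "anterior_wedge": each,
        "posterior_wedge": each, "crush": each, "epwr_anomaly": each})
    return SyntheticCohortSpec(n_subjects=n_subjects, region=region,
                               level_shapes=shapes, contamination=contamination,
                               seed=seed)


def build_quadrilateral(vbhr: float, epwr: float, hwr: float, psa_deg: float,
                        ) -> CornerLandmarks:
    """Construct corner landmarks realizing the four free shape parameters.

    The quadrilateral is built in a canonical pose — posterior wall
    vertical from PI = (0, 0) to PS = (0, Hp), anterior toward +x — with
    the inferior endplate inclination solved by 1-D root finding so the
    anterior height comes out exactly.  Re-measuring the result
    reproduces (vbhr, epwr, hwr, psa) to ~1e−12.

    Raises
    ------
    InfeasibleParameterError
        When no inferior endplate inclination in (−30°, 30°) produces
        the requested anterior height.
    """
    if min(vbhr, epwr, hwr) <= 0:
        raise InfeasibleParameterError("vbhr, epwr and hwr must be positive")
    if not 0 < psa_deg < 180:
        raise InfeasibleParameterError("psa must be in (0, 180) degrees")
    wi = 1.0
    ws = epwr
    mean_width = (wi + ws) / 2.0
    mean_height = hwr * mean_width
    hp = 2.0 * mean_height / (1.0 + vbhr)
    ha = vbhr * hp

    pi_pt = np.array([0.0, 0.0])
    ps_pt = np.array([0.0, hp])
    beta_s = math.radians(psa_deg - 90.0)  # superior endplate inclination
    as_pt = ps_pt + ws * np.array([math.cos(beta_s), math.sin(beta_s)])

    def height_error(beta_i: float) -> float:
        ai = pi_pt + wi * np.array([math.cos(beta_i), math.sin(beta_i)])
        return float(np.linalg.norm(as_pt - ai)) - ha

    lo, hi = math.radians(-_MAX_INCLINATION_DEG), math.radians(_MAX_INCLINATION_DEG)
    f_lo, f_hi = height_error(lo), height_error(hi)
    if f_lo == 0.0:
        beta_i = lo
    elif f_hi == 0.0:
        beta_i = hi
    elif f_lo * f_hi > 0:
        raise InfeasibleParameterError(
            f"no inferior endplate inclination in ±{_MAX_INCLINATION_DEG}° yields "
            f"vbhr={vbhr:.4g} with epwr={epwr:.4g}, hwr={hwr:.4g}, psa={psa_deg:.4g}°")
    else:
        beta_i = brentq(height_error, lo, hi, xtol=1e-14, rtol=8.9e-16)
    ai_pt = pi_pt + wi * np.array([math.cos(beta_i), math.sin(beta_i)])
    return CornerLandmarks(tuple(as_pt), tuple(ps_pt), tuple(ai_pt), tuple(pi_pt))


def _draw_params(rng: np.random.Generator, shape: LevelShapeSpec) -> dict[str, float]:
    """One truncated-Gaussian draw of the four shape parameters (±4 SD)."""
    out = {}
    for name in SHAPE_PARAMS:
        mean, sd = getattr(shape, name)
        if sd == 0.0:
            out[name] = mean
            continue
        while True:
            value = rng.normal(mean, sd)
            if abs(value - mean) <= _TRUNCATION_SD * sd:
                out[name] = value
                break
    return out


def _contaminate(rng: np.random.Generator, lm: CornerLandmarks,
                 spec: ContaminationSpec) -> tuple[CornerLandmarks, str, float]:
    """Apply one deformity from the mixture to a built quadrilateral."""
    kind = CONTAMINATION_TYPES[rng.choice(len(CONTAMINATION_TYPES),
                                          p=spec.probabilities())]
    if kind == "none":
        return lm, kind, 1.0
    as_pt, ps_pt = np.array(lm.as_pt), np.array(lm.ps_pt)
    ai_pt, pi_pt = np.array(lm.ai_pt), np.array(lm.pi_pt)
    if kind == "anterior_wedge":
        severity = rng.uniform(*spec.wedge_severity)
        as_pt = ai_pt + severity * (as_pt - ai_pt)
    elif kind == "posterior_wedge":
        severity = rng.uniform(*spec.wedge_severity)
        ps_pt = pi_pt + severity * (ps_pt - pi_pt)
    elif kind == "crush":
        severity = rng.uniform(*spec.crush_severity)
        as_pt = ai_pt + severity * (as_pt - ai_pt)
        ps_pt = pi_pt + severity * (ps_pt - pi_pt)
    else:  # epwr_anomaly
        severity = rng.uniform(*spec.epwr_severity)
        if rng.random() < 0.5:
            severity = 1.0 / severity
        as_pt = ps_pt + severity * (as_pt - ps_pt)
    return CornerLandmarks(tuple(as_pt), tuple(ps_pt), tuple(ai_pt), tuple(pi_pt)), \
        kind, severity


def _draw_covariates(rng: np.random.Generator) -> dict:
    sex = "male" if rng.random() < 0.5 else "female"
    age = float(rng.uniform(25.0, 74.0))
    race = ["white", "black", "other"][int(rng.choice(3, p=[0.869, 0.112, 0.019]))]
    origin = ["european", "afro_american", "other"][
        int(rng.choice(3, p=[0.741, 0.108, 0.151]))]
    height = float(rng.normal(1.75 if sex == "male" else 1.62, 0.07))  # m
    bmi = float(rng.normal(25.7, 4.5))
    weight = bmi * height**2
    return {"sex": sex, "race": race, "origin": origin, "age": age,
            "height": height, "weight": weight, "bmi": bmi}


def generate_cohort(spec: SyntheticCohortSpec):
    """Generate a landmark cohort plus a ground-truth sidecar table.

    Returns
    -------
    dataset : StudyDataset
        One vertebra per (subject, level in ``spec.level_shapes``) with a
        random similarity transform applied and covariates attached.
    truth : pandas.DataFrame
        ``subject_id, region, level, contamination, severity`` plus the
        six pre-transform metric values (``true_vbhr`` … ``true_psa_deg``).
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    levels = [lv for lv in REGION_LEVELS[spec.region] if lv in spec.level_shapes]
    records, truth_rows = [], []
    for i in range(spec.n_subjects):
        subject_id = f"S{i + 1:05d}"
        cov = _draw_covariates(rng)
        for level in levels:
            shape = spec.level_shapes[level]
            lm = None
            for _ in range(_MAX_REDRAWS):
                params = _draw_params(rng, shape)
                try:
                    core = build_quadrilateral(params["vbhr"], params["epwr"],
                                               params["hwr"], params["psa"])
                except InfeasibleParameterError:
                    continue
                lm, kind, severity = _contaminate(rng, core, spec.contamination)
                break
            if lm is None:
                raise InfeasibleParameterError(
                    f"could not realize a feasible shape for level {level} "
                    f"after {_MAX_REDRAWS} redraws")
            true_metrics = compute_metrics(lm)
            transformed = lm.transformed(
                scale=float(rng.uniform(*spec.scale_range)),
                rotation_deg=float(rng.uniform(*spec.rotation_range_deg)),
                translation=(float(rng.uniform(*spec.translation_range)),
                             float(rng.uniform(*spec.translation_range))),
                flip_x=bool(rng.random() < spec.flip_probability))
            records.append(VertebraRecord(
                subject_id=subject_id, label=VertebraLabel(spec.region, level),
                landmarks=transformed, **cov))
            truth_rows.append({
                "subject_id": subject_id, "region": spec.region, "level": level,
                "contamination": kind, "severity": severity,
                **{f"true_{k}": v for k, v in true_metrics.as_dict().items()}})
    dataset = StudyDataset(records=records, source=f"synthetic(seed={spec.seed})",
                           convention="y_up", unit="arbitrary")
    truth = pd.DataFrame(truth_rows, columns=[
        "subject_id", "region", "level", "contamination", "severity",
        "true_vbhr", "true_epwr", "true_fbdr", "true_hwr",
        "true_epa_deg", "true_psa_deg"])
    return dataset, truth
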