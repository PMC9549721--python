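"""The six vertebral body morphometry metrics.

Given the four corner landmarks of a vertebral body the module computes:

- **VBHR** — anterior/posterior vertebral body height ratio; < 1 indicates
  anterior wedging.
- **EPWR** — superior/inferior endplate width ratio.
- **FBDR** — forward/backward diagonal ratio.  The forward diagonal runs
  AS↔PI and the backward diagonal PS↔AI, so an anterior-tall trapezoid
  (such as S1) has FBDR > 1; the opposite pairing is available through
  ``fbdr_orientation="reverse"`` for sensitivity checks.
- **HWR** — mean height over mean width, with the means taken over the
  anterior/posterior heights and the superior/inferior endplate widths.
- **EPA** — signed angle (degrees) between the superior and inferior
  endplate lines, positive when the endplates converge anteriorly
  (anterior wedging).
- **PSA** — unsigned interior angle (degrees) at the postero-superior
  corner between the superior endplate (ray PS→AS) and the posterior
  wall (ray PS→PI); 90° for a rectangle, > 90° for a posterior wedge.

All six are ratios or angles and are therefore invariant under
translation, rotation and uniform scaling — in particular under
radiographic magnification.  The anterior direction is re-derived from
the corner *labels*, so a mirrored radiograph whose labels still track
the anatomy yields identical metrics (including the EPA sign).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import DomainError
from .landmarks import COVARIATE_COLUMNS, CornerLandmarks, StudyDataset

__all__ = ["MorphometrySix", "METRIC_COLUMNS", "compute_metrics", "compute_dataset_metrics"]

logger = logging.getLogger(__name__)

#: Metric column names used in every tabular interface, in canonical order.
METRIC_COLUMNS = ("vbhr", "epwr", "fbdr", "hwr", "epa_deg", "psa_deg")

_DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class MorphometrySix:
    """The six metric values for one vertebra (ratios unitless, angles in degrees)."""

    vbhr: float
    epwr: float
    fbdr: float
    hwr: float
    epa_deg: float
    psa_deg: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _cross(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def compute_metrics(lm: CornerLandmarks, fbdr_orientation: str = "forward") -> MorphometrySix:
    """Compute the six morphometry metrics from one set of corner landmarks.

    Raises
    ------
    DomainError
        If any height, width or diagonal is numerically degenerate
        (zero relative to the vertebra size).
    """
    if fbdr_orientation not in ("forward", "reverse"):
        raise ValueError(f"fbdr_orientation must be 'forward' or 'reverse', got {fbdr_orientation!r}")
    a_s, p_s, a_i, p_i = (np.asarray(p, dtype=float) for p in
                          (lm.as_pt, lm.ps_pt, lm.ai_pt, lm.pi_pt))

    ha = float(np.linalg.norm(a_s - a_i))
    hp = float(np.linalg.norm(p_s - p_i))
    ws = float(np.linalg.norm(a_s - p_s))
    wi = float(np.linalg.norm(a_i - p_i))
    d_fwd = float(np.linalg.norm(a_s - p_i))
    d_bwd = float(np.linalg.norm(p_s - a_i))

    scale = max(ha, hp, ws, wi)
    for name, value in (("anterior height", ha), ("posterior height", hp),
                        ("superior width", ws), ("inferior width", wi),
                        ("forward diagonal", d_fwd), ("backward diagonal", d_bwd)):
        if value <= _DEGENERACY_RTOL * scale:
            raise DomainError(f"degenerate landmarks: {name} is zero")

    vbhr = ha / hp
    epwr = ws / wi
    fbdr = d_fwd / d_bwd if fbdr_orientation == "forward" else d_bwd / d_fwd
    hwr = ((ha + hp) / 2.0) / ((ws + wi) / 2.0)

    # Endplate directions taken posterior→anterior, so the sign convention
    # follows the anatomy, not the coordinate frame handedness.
    sup = a_s - p_s
    inf = a_i - p_i
    anterior = (a_s + a_i) / 2.0 - (p_s + p_i) / 2.0
    superior = (a_s + p_s) / 2.0 - (a_i + p_i) / 2.0
    omega = 1.0 if _cross(anterior, superior) >= 0.0 else -1.0
    epa = omega * math.degrees(math.atan2(_cross(sup, inf), float(np.dot(sup, inf))))

    v1 = a_s - p_s  # ray PS→AS
    v2 = p_i - p_s  # ray PS→PI
    psa = math.degrees(math.atan2(abs(_cross(v1, v2)), float(np.dot(v1, v2))))

    return MorphometrySix(vbhr=vbhr, epwr=epwr, fbdr=fbdr, hwr=hwr,
                          epa_deg=epa, psa_deg=psa)


def compute_dataset_metrics(ds: StudyDataset, fbdr_orientation: str = "forward",
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the metrics table for a whole dataset.

    Returns
    -------
    metrics : DataFrame
        One row per vertebra: ``subject_id, region, level``, the six metric
        columns, then any covariates.
    rejects : DataFrame
        One row per geometrically degenerate vertebra with the failure
        reason; these are excluded from ``metrics``.
    """
    rows, rejects = [], []
    for rec in ds:
        base = {"subject_id": rec.subject_id, "region": rec.label.region,
                "level": rec.label.level}
        try:
            six = compute_metrics(rec.landmarks, fbdr_orientation=fbdr_orientation)
        except DomainError as exc:
            rejects.append({**base, "reason": str(exc)})
            continue
        rows.append({**base, **six.as_dict(), **rec.covariates()})
    cols = ["subject_id", "region", "level", *METRIC_COLUMNS, *COVARIATE_COLUMNS]
    metrics = pd.DataFrame(rows, columns=cols)
    rejects_df = pd.DataFrame(rejects, columns=["subject_id", "region", "level", "reason"])
    if len(rejects_df):
        logger.warning("excluded %d degenerate vertebra(e)", len(rejects_df))
    return metrics, rejects_df
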