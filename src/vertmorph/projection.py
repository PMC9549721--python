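"""Radiographic projection-error simulation for out-of-plane vertebrae.

A vertebral body is modeled as a prism: its midsagittal quadrilateral
swept laterally by ±d (half-depth).  A lateral radiograph is modeled as a
central projection from a point source onto a flat detector:

- detector plane at z = 0 (z is the lateral/beam axis),
- point source at z = SID (source-to-detector distance),
- prism centroid at z = OID (object-to-detector distance),

so a point at depth z projects with per-point magnification
SID / (SID − z).  ``sid = inf`` gives the parallel-beam limit
(magnification 1 everywhere).

Out-of-plane pose is an axial rotation about the superior (y) axis
followed by a tilt about the anterior (x) axis, both about the prism
centroid.  The landmarking convention is then re-derived exactly as on a
real radiograph: each corner landmark is the *midpoint of the left and
right projected images* of that corner ("bisecting the shadows").  With
zero pose the left/right images of every corner share one depth, so the
midshadow landmarks are a uniform magnification of the true shape and
every metric is exact; with pose the six metrics acquire errors that grow
with the out-of-plane angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .landmarks import CornerLandmarks
from .metrics import METRIC_COLUMNS, compute_metrics

__all__ = [
    "Box3D",
    "BeamGeometry",
    "project_box",
    "midshadow_landmarks",
    "projection_error_sweep",
]

_CORNER_ORDER = ("AS", "PS", "AI", "PI")


@dataclass(frozen=True)
class Box3D:
    """A prismatic vertebral body: midsagittal section swept laterally by ±d."""

    section: CornerLandmarks
    half_depth: float

    def __post_init__(self) -> None:
        if self.half_depth <= 0:
            raise GeometryError("half_depth must be > 0")

    def corners(self) -> dict[str, np.ndarray]:
        """Left/right 3D corners, keyed by corner name → (2, 3) array.

        Row 0 is the left (z = +d) corner, row 1 the right (z = −d);
        x, y are the midsagittal coordinates.
        """
        out = {}
        for name, (x, y) in zip(_CORNER_ORDER,
                                (self.section.as_pt, self.section.ps_pt,
                                 self.section.ai_pt, self.section.pi_pt)):
            out[name] = np.array([[x, y, self.half_depth],
                                  [x, y, -self.half_depth]], dtype=float)
        return out


@dataclass(frozen=True)
class BeamGeometry:
    """Point-source beam geometry and out-of-plane pose.

    Parameters
    ----------
    sid : float
        Source-to-detector distance (``inf`` = parallel beam).
    oid : float
        Object-centroid-to-detector distance.
    rotation_deg : float
        Axial rotation about the superior (y) axis, applied first.
    tilt_deg : float
        Tilt about the anterior (x) axis, applied second.
    """

    sid: float
    oid: float = 0.0
    rotation_deg: float = 0.0
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sid > self.oid >= 0):
            raise GeometryError("require SID > OID >= 0")
        if abs(self.rotation_deg) >= 45 or abs(self.tilt_deg) >= 45:
            raise GeometryError("|rotation| and |tilt| must be < 45 degrees")


def _pose_matrix(rotation_deg: float, tilt_deg: float) -> np.ndarray:
    ry = math.radians(rotation_deg)
    rx = math.radians(tilt_deg)
    rot_y = np.array([[math.cos(ry), 0.0, math.sin(ry)],
                      [0.0, 1.0, 0.0],
                      [-math.sin(ry), 0.0, math.cos(ry)]])
    rot_x = np.array([[1.0, 0.0, 0.0],
                      [0.0, math.cos(rx), -math.sin(rx)],
                      [0.0, math.sin(rx), math.cos(rx)]])
    return rot_x @ rot_y


def project_box(box: Box3D, geom: BeamGeometry) -> dict[str, np.ndarray]:
    """Project the rotated prism corners onto the detector plane.

    Returns, per corner name, a (2, 2) array of the left/right projected
    images in detector coordinates (x anterior, y superior).

    Raises
    ------
    GeometryError
        If any corner reaches the source plane (z >= SID).
    """
    corners = box.corners()
    all_pts = np.vstack(list(corners.values()))  # (8, 3)
    center = all_pts.mean(axis=0)
    pose = _pose_matrix(geom.rotation_deg, geom.tilt_deg)

    out = {}
    for name, pair in corners.items():
        rotated = (pair - center) @ pose.T + center
        depth = geom.oid + rotated[:, 2]  # z relative to the detector plane
        if math.isinf(geom.sid):
            mag = np.ones(2)
        else:
            if np.any(depth >= geom.sid):
                raise GeometryError(f"corner {name} at or beyond the source plane")
            mag = geom.sid / (geom.sid - depth)
        out[name] = rotated[:, :2] * mag[:, None]
    return out


def midshadow_landmarks(projected: dict[str, np.ndarray]) -> CornerLandmarks:
    """Corner landmarks as midpoints of the left/right projected images."""
    mids = {name: tuple(np.asarray(pair, dtype=float).mean(axis=0))
            for name, pair in projected.items()}
    return CornerLandmarks(mids["AS"], mids["PS"], mids["AI"], mids["PI"],
                           validate=False)


def projection_error_sweep(lm: CornerLandmarks, half_depth: float,
                           rotations_deg, tilts_deg,
                           sid: float = 1000.0, oid: float = 100.0) -> pd.DataFrame:
    """Metric errors over a grid of out-of-plane poses.

    For every (rotation, tilt) pair the prism is projected, midshadow
    landmarks are re-derived, and the error per metric is
    metric(midshadow) − metric(true midsagittal shape).

    Returns a tidy frame: ``rotation_deg, tilt_deg, metric, error``.
    """
    box = Box3D(section=lm, half_depth=half_depth)
    true_values = compute_metrics(lm).as_dict()
    rows = []
    for rot in np.atleast_1d(rotations_deg):
        for tilt in np.atleast_1d(tilts_deg):
            geom = BeamGeometry(sid=sid, oid=oid, rotation_deg=float(rot),
                                tilt_deg=float(tilt))
            apparent = compute_metrics(midshadow_landmarks(project_box(box, geom)))
            for m in METRIC_COLUMNS:
                rows.append({"rotation_deg": float(rot), "tilt_deg": float(tilt),
                             "metric": m,
                             "error": apparent.as_dict()[m] - true_values[m]})
    return pd.DataFrame(rows, columns=["rotation_deg", "tilt_deg", "metric", "error"])
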