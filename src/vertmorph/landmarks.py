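"""Vertebral corner-landmark data model and CSV I/O.

A vertebral body on a lateral spine radiograph is reduced to its four
corner landmarks: antero-superior (AS), postero-superior (PS),
antero-inferior (AI) and postero-inferior (PI), each a 2D point in the
midsagittal plane.  Internally the package always works in a Cartesian
convention with x increasing anteriorly and y increasing superiorly;
image-style y-down coordinates are supported only through the ingest flag
of :func:`read_landmarks`.  Units are opaque (pixels or mm) — every
downstream metric is a ratio or an angle, so no unit conversion exists
anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import DomainError, FormatError, IntegrityError, ParseError

__all__ = [
    "CornerLandmarks",
    "VertebraLabel",
    "VertebraRecord",
    "StudyDataset",
    "CERVICAL_LEVELS",
    "LUMBAR_LEVELS",
    "REGION_LEVELS",
    "adjacent_pairs",
    "read_landmarks",
    "write_landmarks",
]

CORNERS = ("AS", "PS", "AI", "PI")

CERVICAL_LEVELS = ("C2", "C3", "C4", "C5", "C6", "C7")
LUMBAR_LEVELS = ("L1", "L2", "L3", "L4", "L5", "S1")
REGION_LEVELS = {"cervical": CERVICAL_LEVELS, "lumbar": LUMBAR_LEVELS}

COVARIATE_COLUMNS = ("sex", "race", "origin", "age", "height", "weight", "bmi")
_CATEGORICAL_COVARIATES = ("sex", "race", "origin")


def adjacent_pairs(region: str) -> list[tuple[str, str]]:
    """Cranial→caudal adjacent level pairs for a region, e.g. ``("L4", "L5")``."""
    levels = REGION_LEVELS[region]
    return [(levels[i], levels[i + 1]) for i in range(len(levels) - 1)]


Point = tuple[float, float]


@dataclass(frozen=True)
class CornerLandmarks:
    """Four labeled corner points of one vertebral body (y-up, x-anterior).

    Parameters
    ----------
    as_pt, ps_pt, ai_pt, pi_pt
        Antero-superior, postero-superior, antero-inferior and
        postero-inferior corners as ``(x, y)`` pairs in one arbitrary
        length unit.
    validate
        When True (default) the constructor rejects non-finite points,
        coincident corners, zero heights/widths and self-intersecting
        quadrilaterals.
    """

    as_pt: Point
    ps_pt: Point
    ai_pt: Point
    pi_pt: Point
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        pts = tuple((float(p[0]), float(p[1])) for p in
                    (self.as_pt, self.ps_pt, self.ai_pt, self.pi_pt))
        object.__setattr__(self, "as_pt", pts[0])
        object.__setattr__(self, "ps_pt", pts[1])
        object.__setattr__(self, "ai_pt", pts[2])
        object.__setattr__(self, "pi_pt", pts[3])
        if validate:
            self._check()

    def _check(self) -> None:
        pts = self.points()
        if not np.all(np.isfinite(pts)):
            raise DomainError("landmark coordinates must be finite")
        names = ("AS", "PS", "AI", "PI")
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(pts[i], pts[j], atol=0.0, rtol=0.0):
                    raise DomainError(f"coincident landmarks {names[i]} and {names[j]}")
        for name, value in (("anterior height", self.anterior_height),
                            ("posterior height", self.posterior_height),
                            ("superior width", self.superior_width),
                            ("inferior width", self.inferior_width)):
            if value <= 0.0:
                raise DomainError(f"{name} must be > 0")
        # AS→PS→PI→AI in either orientation; simplicity and nonzero area via shapely
        poly = Polygon([self.as_pt, self.ps_pt, self.pi_pt, self.ai_pt])
        if not poly.is_valid or poly.area <= 0.0:
            raise DomainError("corner quadrilateral is self-intersecting or has zero area")

    def points(self) -> np.ndarray:
        """Corners as a (4, 2) array in the fixed order AS, PS, AI, PI."""
        return np.array([self.as_pt, self.ps_pt, self.ai_pt, self.pi_pt], dtype=float)

    @classmethod
    def from_points(cls, pts: np.ndarray, validate: bool = True) -> "CornerLandmarks":
        """Inverse of :meth:`points`."""
        pts = np.asarray(pts, dtype=float)
        return cls(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]), tuple(pts[3]),
                   validate=validate)

    # geometric primitives shared by the metric definitions
    @property
    def anterior_height(self) -> float:
        return math.dist(self.as_pt, self.ai_pt)

    @property
    def posterior_height(self) -> float:
        return math.dist(self.ps_pt, self.pi_pt)

    @property
    def superior_width(self) -> float:
        return math.dist(self.as_pt, self.ps_pt)

    @property
    def inferior_width(self) -> float:
        return math.dist(self.ai_pt, self.pi_pt)

    def transformed(self, *, scale: float = 1.0, rotation_deg: float = 0.0,
                    translation: Point = (0.0, 0.0), flip_x: bool = False,
                    validate: bool = True) -> "CornerLandmarks":
        """Apply a similarity transform (optionally with a mirror about x=0).

        The corner labels stay attached to the anatomy, so a mirrored
        vertebra keeps its anterior corners labeled anterior.
        """
        pts = self.points()
        if flip_x:
            pts = pts * np.array([-1.0, 1.0])
        th = math.radians(rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        pts = scale * pts @ rot.T + np.asarray(translation, dtype=float)
        return CornerLandmarks.from_points(pts, validate=validate)


@dataclass(frozen=True)
class VertebraLabel:
    """Spinal region plus level, e.g. lumbar L4 or cervical C5."""

    region: str
    level: str

    def __post_init__(self) -> None:
        if self.region not in REGION_LEVELS:
            raise DomainError(f"unknown region {self.region!r}")
        if self.level not in REGION_LEVELS[self.region]:
            raise DomainError(f"level {self.level!r} not in region {self.region!r}")

    @property
    def order(self) -> int:
        """Cranial→caudal index within the region (C2=0 … C7=5; L1=0 … S1=5)."""
        return REGION_LEVELS[self.region].index(self.level)


@dataclass
class VertebraRecord:
    """One vertebra of one subject: label, landmarks, optional covariates."""

    subject_id: str
    label: VertebraLabel
    landmarks: CornerLandmarks
    sex: str | None = None
    race: str | None = None
    origin: str | None = None
    age: float | None = None
    height: float | None = None
    weight: float | None = None
    bmi: float | None = None

    def covariates(self) -> dict:
        return {k: getattr(self, k) for k in COVARIATE_COLUMNS}


@dataclass
class StudyDataset:
    """An ordered collection of vertebra records sharing one coordinate convention."""

    records: list[VertebraRecord] = field(default_factory=list)
    source: str = "unknown"
    convention: str = "y_up"
    unit: str = "arbitrary"
    n_dropped_incomplete: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VertebraRecord]:
        return iter(self.records)

    def counts(self) -> pd.Series:
        """Number of vertebrae per (region, level)."""
        idx = [(r.label.region, r.label.level) for r in self.records]
        if not idx:
            return pd.Series(dtype=int)
        return pd.Series(1, index=pd.MultiIndex.from_tuples(idx, names=["region", "level"])
                         ).groupby(level=[0, 1]).sum()

    def provenance(self) -> dict:
        return {"source": self.source, "convention": self.convention, "unit": self.unit}

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per corner (the on-disk layout)."""
        rows = []
        for rec in self.records:
            corner_pts = dict(zip(CORNERS, (rec.landmarks.as_pt, rec.landmarks.ps_pt,
                                            rec.landmarks.ai_pt, rec.landmarks.pi_pt)))
            for corner in CORNERS:
                x, y = corner_pts[corner]
                row = {"subject_id": rec.subject_id, "region": rec.label.region,
                       "level": rec.label.level, "corner": corner, "x": x, "y": y}
                row.update(rec.covariates())
                rows.append(row)
        cols = ["subject_id", "region", "level", "corner", "x", "y", *COVARIATE_COLUMNS]
        return pd.DataFrame(rows, columns=cols)


_REQUIRED_COLUMNS = ("subject_id", "region", "level", "corner", "x", "y")


def read_landmarks(path, convention: str = "y_up") -> StudyDataset:
    """Read a landmark CSV into a :class:`StudyDataset`.

    The file must carry the columns ``subject_id, region, level, corner, x, y``
    (plus optional covariate columns); each vertebra is assembled from its
    four corner rows, keyed by the ``corner`` label, never by row order.
    Vertebrae with fewer than four corners are dropped and counted in
    ``n_dropped_incomplete``.  With ``convention="y_down"`` the y axis is
    negated on ingest so the in-memory convention is always y-up.
    """
    if convention not in ("y_up", "y_down"):
        raise FormatError(f"unknown coordinate convention {convention!r}")
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ParseError(
                f"non-numeric value {df.loc[row, col]!r} in column {col!r} at data row {row}")
        df[col] = coerced

    dup = df.duplicated(subset=["subject_id", "level", "corner"], keep=False)
    if dup.any():
        key = df.loc[dup.idxmax(), ["subject_id", "level", "corner"]].tolist()
        raise IntegrityError(f"duplicate corner row for (subject, level, corner) = {tuple(key)}")

    if convention == "y_down":
        df["y"] = -df["y"]

    records: list[VertebraRecord] = []
    n_dropped = 0
    for (subject, region, level), grp in df.groupby(
            ["subject_id", "region", "level"], sort=False):
        have = set(grp["corner"])
        if not set(CORNERS) <= have:
            n_dropped += 1
            continue
        pts = {r.corner: (float(r.x), float(r.y)) for r in grp.itertuples()}
        # geometric degeneracy is handled (and reported) at metric computation,
        # so ingest does not validate shapes, only structure
        lm = CornerLandmarks(pts["AS"], pts["PS"], pts["AI"], pts["PI"], validate=False)
        first = grp.iloc[0]
        cov = {}
        for name in COVARIATE_COLUMNS:
            if name in grp.columns and pd.notna(first[name]):
                cov[name] = (str(first[name]) if name in _CATEGORICAL_COVARIATES
                             else float(first[name]))
        records.append(VertebraRecord(subject_id=str(subject),
                                      label=VertebraLabel(str(region), str(level)),
                                      landmarks=lm, **cov))
    return StudyDataset(records=records, source=str(path), convention="y_up",
                        n_dropped_incomplete=n_dropped)


def write_landmarks(dataset: StudyDataset, path) -> None:
    """Write a dataset back to the landmark CSV layout (y-up, '#' provenance header)."""
    df = dataset.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in dataset.provenance().items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
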