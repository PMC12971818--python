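"""Anatomical coordinate frames and rotation axes from knee landmarks.

The femoral frame follows the CT convention used for TT-TG work: the X-axis
runs along the best-fit cylinder through both femoral condyles (flexion axis,
oriented medial-to-lateral), the Z-axis is the component of the line to the
femoral head centre orthogonal to X (oriented proximally), and Y completes a
right-handed triad (anterior for a right knee).  Two rotation axes derive
from this anatomy:

* FAR — femoral axial rotation axis: the fitted condylar cylinder axis,
  a surrogate for the surgical transepicondylar axis, about which knee
  flexion is simulated.
* TAR — tibial axial rotation axis: the anatomical tibial long axis through
  the proximal (1/3) and distal (2/3) shaft midpoints, about which
  screw-home internal/external rotation is simulated.

Landmark roster (all points in mm):

=======  =====================================================
FHC      femoral head centre
FMCP     most posterior point, medial femoral condyle
FLCP     most posterior point, lateral femoral condyle
TGCP     trochlear groove centre point
TTP      tibial tuberosity point
TAPP     proximal tibial shaft midpoint (1/3 down the shaft)
TADP     distal tibial shaft midpoint (2/3 down the shaft)
=======  =====================================================
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import (
    AxisLine,
    CylinderFit,
    DegenerateGeometryError,
    GeometryError,
    closest_point_on_line,
    fit_cylinder,
    unit,
)

__all__ = [
    "LANDMARK_NAMES",
    "FEMORAL_LANDMARKS",
    "TIBIAL_LANDMARKS",
    "LandmarkSet",
    "FemoralFrame",
    "build_femoral_frame",
    "far_axis",
    "tar_axis",
    "shaft_midpoints",
    "canonicalize_side",
    "read_landmarks",
    "write_landmarks_csv",
    "condyle_points_from_mesh",
]

LANDMARK_NAMES = ("FHC", "FMCP", "FLCP", "TGCP", "TTP", "TAPP", "TADP")
FEMORAL_LANDMARKS = ("FHC", "FMCP", "FLCP", "TGCP")
TIBIAL_LANDMARKS = ("TTP", "TAPP", "TADP")


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical landmarks plus condylar surface samples for one knee."""

    specimen_id: str
    side: str  # "left" | "right"
    FHC: np.ndarray
    FMCP: np.ndarray
    FLCP: np.ndarray
    TGCP: np.ndarray
    TTP: np.ndarray
    TAPP: np.ndarray
    TADP: np.ndarray
    condyle_points: np.ndarray | None = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise GeometryError(f"landmark {name} must be a finite 3-vector")
            object.__setattr__(self, name, p)
        if np.allclose(self.FMCP, self.FLCP):
            raise DegenerateGeometryError("FMCP and FLCP coincide")
        if np.allclose(self.TAPP, self.TADP):
            raise DegenerateGeometryError("TAPP and TADP coincide")
        if self.condyle_points is not None:
            cp = np.asarray(self.condyle_points, dtype=float)
            if cp.ndim != 2 or cp.shape[1] != 3:
                raise GeometryError("condyle_points must be an (n, 3) array")
            object.__setattr__(self, "condyle_points", cp)

    def landmarks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in LANDMARK_NAMES}


@dataclass(frozen=True)
class FemoralFrame:
    """Right-handed orthonormal femoral coordinate system (axes are unit vectors)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        x, y, z = self.x_axis, self.y_axis, self.z_axis
        for v in (x, y, z):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise GeometryError("frame axes must be unit vectors")
        if max(abs(x @ y), abs(y @ z), abs(x @ z)) > 1e-9:
            raise GeometryError("frame axes must be pairwise orthogonal")
        if np.linalg.norm(np.cross(x, y) - z) > 1e-9:
            raise GeometryError("frame must be right-handed (x cross y = z)")


def build_femoral_frame(lm: LandmarkSet, fit: CylinderFit | None = None) -> FemoralFrame:
    """Construct the femoral frame from a landmark set.

    ``x_axis`` is the condylar cylinder axis oriented medial-to-lateral
    (positive dot product with FLCP - FMCP); the frame origin is the point on
    that axis closest to the FMCP/FLCP midpoint; ``z_axis`` is the unit
    component of FHC - origin orthogonal to ``x_axis`` (proximal); ``y_axis``
    completes the right-handed triad.

    An already-computed cylinder ``fit`` may be passed to avoid refitting.
    """
    if fit is None:
        if lm.condyle_points is None or len(lm.condyle_points) == 0:
            raise DegenerateGeometryError(
                f"specimen {lm.specimen_id}: condyle_points required to build the frame"
            )
        fit = fit_cylinder(lm.condyle_points, reference_direction=lm.FLCP - lm.FMCP)
    x = fit.axis.direction.copy()
    if x @ (lm.FLCP - lm.FMCP) < 0:
        x = -x
    axis = AxisLine(fit.axis.origin, x)
    origin = closest_point_on_line(0.5 * (lm.FMCP + lm.FLCP), axis)
    v = lm.FHC - origin
    v_perp = v - (v @ x) * x
    if np.linalg.norm(v_perp) < 1e-9:
        raise DegenerateGeometryError(
            f"specimen {lm.specimen_id}: FHC lies on the condylar axis; Z undefined"
        )
    z = unit(v_perp)
    y = np.cross(z, x)
    return FemoralFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def far_axis(frame: FemoralFrame, fit: CylinderFit) -> AxisLine:
    """Femoral axial rotation (flexion) axis: the fitted condylar cylinder axis,
    oriented like the frame's medial-to-lateral X-axis."""
    d = fit.axis.direction
    if d @ frame.x_axis < 0:
        d = -d
    if np.linalg.norm(np.cross(d, frame.x_axis)) > 1e-6:
        raise GeometryError("cylinder fit and frame disagree on the condylar axis")
    return AxisLine(fit.axis.origin, frame.x_axis)


def tar_axis(lm: LandmarkSet) -> AxisLine:
    """Tibial axial rotation axis through TAPP, oriented distally (towards TADP)."""
    return AxisLine(lm.TAPP, unit(lm.TADP - lm.TAPP))


def shaft_midpoints(shaft_proximal, shaft_distal) -> tuple[np.ndarray, np.ndarray]:
    """TAPP/TADP at 1/3 and 2/3 of the way from the proximal to the distal
    tibial shaft endpoint."""
    a = np.asarray(shaft_proximal, dtype=float)
    b = np.asarray(shaft_distal, dtype=float)
    if np.allclose(a, b):
        raise DegenerateGeometryError("shaft endpoints coincide")
    return a + (b - a) / 3.0, a + 2.0 * (b - a) / 3.0


def _reflect(points: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    rel = np.atleast_2d(points) - origin
    out = np.atleast_2d(points) - 2.0 * np.outer(rel @ normal, normal)
    return out[0] if np.asarray(points).ndim == 1 else out


def canonicalize_side(lm: LandmarkSet) -> LandmarkSet:
    """Map a left knee into right-knee convention by mirroring across its
    sagittal plane (the plane through the frame origin normal to the condylar
    axis); right knees are returned unchanged.

    After canonicalization one sign convention for "internal rotation" holds
    across the whole cohort.  Mirroring is an involution and, because TT-TG
    is a projection difference, it leaves the measured TT-TG of the specimen
    unchanged.
    """
    if lm.side == "right":
        return lm
    frame = build_femoral_frame(lm)
    o, nrm = frame.origin, frame.x_axis
    mirrored = {name: _reflect(getattr(lm, name), o, nrm) for name in LANDMARK_NAMES}
    cp = None
    if lm.condyle_points is not None:
        cp = _reflect(lm.condyle_points, o, nrm)
    return LandmarkSet(
        specimen_id=lm.specimen_id, side="right", condyle_points=cp, **mirrored
    )


# ---------------------------------------------------------------------------
# Landmark file I/O
# ---------------------------------------------------------------------------

def read_landmarks(path, specimen_id: str | None = None, side: str = "right",
                   condyle_points=None) -> LandmarkSet:
    """Read a landmark file: CSV with header ``name,x,y,z`` or a JSON mapping
    ``{"FHC": [x, y, z], ...}`` (mm).  All seven landmarks must be present."""
    path = Path(path)
    named: dict[str, np.ndarray] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for name, xyz in data.items():
            named[name] = np.asarray(xyz, dtype=float)
    else:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                named[row["name"]] = np.array(
                    [float(row["x"]), float(row["y"]), float(row["z"])]
                )
    missing = [n for n in LANDMARK_NAMES if n not in named]
    if missing:
        raise ValueError(f"landmark file {path} is missing {missing}")
    return LandmarkSet(
        specimen_id=specimen_id or path.stem,
        side=side,
        condyle_points=condyle_points,
        **{n: named[n] for n in LANDMARK_NAMES},
    )


def write_landmarks_csv(lm: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x", "y", "z"])
        for name in LANDMARK_NAMES:
            p = getattr(lm, name)
            w.writerow([name, f"{p[0]:.9g}", f"{p[1]:.9g}", f"{p[2]:.9g}"])


def condyle_points_from_mesh(mesh_path, bounds=None, n: int = 200, seed: int = 0) -> np.ndarray:
    """Sample condylar surface points from a PLY/STL bone mesh.

    ``bounds`` is an optional ``(min_xyz, max_xyz)`` axis-aligned box (mm)
    restricting sampling to the condylar region; faces whose centroid falls
    outside are discarded before area-weighted surface sampling.
    """
    import trimesh

    mesh = trimesh.load_mesh(str(mesh_path))
    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        centers = mesh.triangles_center
        keep = np.all((centers >= lo) & (centers <= hi), axis=1)
        if not np.any(keep):
            raise DegenerateGeometryError("no mesh faces inside the condylar bounds")
        mesh = mesh.submesh([np.nonzero(keep)[0]], append=True)
    samples, _ = trimesh.sample.sample_surface(mesh, n, seed=seed)
    return np.asarray(samples, dtype=float)
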