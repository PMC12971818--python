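"""Geometry kernel: points, axis lines, rigid rotations, projections, cylinder fits.

All lengths are millimetres; angles cross the API boundary in degrees and are
converted to radians exactly once, here.  Points are plain ``(3,)`` float64
numpy arrays (see :func:`point`), which keeps the kernel interoperable with
the rest of the scientific stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GeometryError",
    "DegenerateGeometryError",
    "ConvergenceError",
    "point",
    "unit",
    "AxisLine",
    "RigidTransform",
    "CylinderFit",
    "rotation_about_axis",
    "apply_transform",
    "project_scalar",
    "point_line_distance",
    "closest_point_on_line",
    "fit_cylinder",
]

_UNIT_TOL = 1e-6  # direction vectors must be unit within this before normalising
_ORTHO_TOL = 1e-9  # rotation matrices must be orthonormal within this


class GeometryError(ValueError):
    """Base class for geometric precondition failures."""


class DegenerateGeometryError(GeometryError):
    """Input geometry does not determine the requested object."""


class ConvergenceError(GeometryError):
    """An iterative fit failed to converge within its iteration cap."""

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual


def point(x: float, y: float, z: float) -> np.ndarray:
    """Build a 3D point (mm) as a float64 array, rejecting non-finite input."""
    p = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(p)):
        raise GeometryError(f"non-finite point coordinates: {p}")
    return p


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"expected (n, 3) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError("non-finite point coordinates")
    return arr


def unit(v) -> np.ndarray:
    """Normalise ``v`` to unit length; error on (near-)zero vectors."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalise a zero-length vector")
    return v / n


@dataclass(frozen=True)
class AxisLine:
    """An infinite oriented line: unit ``direction`` through ``origin`` (mm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > _UNIT_TOL:
            raise GeometryError(
                f"axis direction must be unit length (|d| = {n:.3g}); normalise explicitly"
            )
        object.__setattr__(self, "direction", d / n)
        if not (np.all(np.isfinite(self.origin)) and np.all(np.isfinite(self.direction))):
            raise GeometryError("non-finite axis")

    @classmethod
    def through(cls, a, b) -> "AxisLine":
        """Axis through ``a`` oriented towards ``b``."""
        a = np.asarray(a, dtype=float)
        return cls(a, unit(np.asarray(b, dtype=float) - a))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rigid transform needs a 3x3 rotation and 3-vector translation")
        if np.abs(R @ R.T - np.eye(3)).max() > _ORTHO_TOL:
            raise GeometryError("rotation matrix is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise GeometryError("rotation matrix determinant is not +1 within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Apply to one point or an (n, 3) stack, preserving the input shape."""
        arr = np.asarray(points, dtype=float)
        single = arr.ndim == 1
        out = _as_points(arr) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the map ``p -> self(inner(p))``."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))


@dataclass(frozen=True)
class CylinderFit:
    """Least-squares circular cylinder: axis line, radius and RMS orthogonal residual."""

    axis: AxisLine
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError(f"cylinder radius must be positive, got {self.radius}")
        if self.rms_residual < 0:
            raise GeometryError("rms residual must be non-negative")


def rotation_about_axis(axis: AxisLine, angle_deg: float) -> RigidTransform:
    """Right-handed rotation by ``angle_deg`` about an arbitrary axis line.

    Implements the Rodrigues form ``R = cos t I + sin t [u]x + (1 - cos t) u u^T``
    and shifts it so the axis line is pointwise fixed:
    ``p -> origin + R (p - origin)``.
    """
    u = axis.direction
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux = np.array([[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]])
    R = c * np.eye(3) + s * ux + (1.0 - c) * np.outer(u, u)
    return RigidTransform(R, axis.origin - R @ axis.origin)


def apply_transform(t: RigidTransform, p) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(p)


def project_scalar(p, axis: AxisLine) -> float:
    """Signed coordinate of the orthogonal projection of ``p`` onto ``axis`` (mm)."""
    return float((np.asarray(p, dtype=float) - axis.origin) @ axis.direction)


def closest_point_on_line(p, axis: AxisLine) -> np.ndarray:
    return axis.origin + project_scalar(p, axis) * axis.direction


def point_line_distance(points, axis: AxisLine) -> np.ndarray | float:
    """Orthogonal distance(s) from point(s) to an axis line (mm)."""
    arr = np.asarray(points, dtype=float)
    single = arr.ndim == 1
    d = _line_distances(_as_points(arr), axis.origin, axis.direction)
    return float(d[0]) if single else d


def _line_distances(pts: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = pts - origin
    along = rel @ direction
    perp = rel - along[:, None] * direction
    return np.linalg.norm(perp, axis=1)


def _orthobasis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``u`` to an orthonormal basis."""
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(u, helper))
    e2 = np.cross(u, e1)
    return e1, e2


def _fit_from_direction(pts: np.ndarray, u0: np.ndarray, centroid: np.ndarray):
    """Run the LM least-squares cylinder fit starting from axis direction ``u0``.

    The axis is parameterised as a perturbation of ``u0`` (two tangent
    coefficients) plus a 2D origin offset in the plane normal to ``u0``
    through the centroid — 4 axis dof, with the radius as a fifth parameter.
    The tangent-plane parameterisation has no polar singularity at the
    starting direction, which is where the solution lives.
    """
    e1, e2 = _orthobasis(u0)
    d0 = _line_distances(pts, centroid, u0)
    x0 = np.array([0.0, 0.0, 0.0, 0.0, float(np.mean(d0))])

    def _parts(x):
        a, b, p, q, r = x
        v = u0 + a * e1 + b * e2
        nv = np.linalg.norm(v)
        u = v / nv
        origin = centroid + p * e1 + q * e2
        rel = pts - origin
        along = rel @ u
        perp = rel - along[:, None] * u
        d = np.linalg.norm(perp, axis=1)
        return u, nv, rel, along, perp, d, r

    def residuals(x):
        d, r = _parts(x)[5:]
        return d - r

    def jacobian(x):
        u, nv, rel, along, perp, d, r = _parts(x)
        safe = np.where(d > 1e-12, d, 1e-12)
        J = np.empty((pts.shape[0], 5))
        # d(d_i)/d(direction tangent coeffs): project e through (I - u u^T)/|v|
        for col, e in ((0, e1), (1, e2)):
            J[:, col] = -(along * (perp @ e)) / (safe * nv)
        # d(d_i)/d(origin offsets)
        J[:, 2] = -(perp @ e1) / safe
        J[:, 3] = -(perp @ e2) / safe
        J[:, 4] = -1.0
        return J

    sol = least_squares(
        residuals, x0, jac=jacobian, method="lm",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=200 * 6,
    )
    a, b, p, q, r = sol.x
    direction = unit(u0 + a * e1 + b * e2)
    origin = centroid + p * e1 + q * e2
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return origin, direction, float(r), rms, sol


def fit_cylinder(
    points,
    initial_axis: AxisLine | None = None,
    reference_direction=None,
) -> CylinderFit:
    """Orthogonal-distance least-squares circular cylinder through a point cloud.

    Minimises ``sum_i (d_i - r)^2`` where ``d_i`` is the orthogonal distance of
    point ``i`` to the axis line, over the 4 axis degrees of freedom and the
    radius.  Deterministic: without ``initial_axis`` the fit is started from
    each principal axis of the cloud's covariance and the lowest-residual
    solution is kept (partial-arc clouds can make the principal directions
    ambiguous, so a single start is not reliable).

    Parameters
    ----------
    points : (n, 3) array-like
        Surface samples, n >= 8, not collinear.
    initial_axis : AxisLine, optional
        Start the local optimisation from this axis only.
    reference_direction : array-like, optional
        The fitted axis direction is flipped, if needed, to have positive dot
        product with this vector; the fit itself is sign-ambiguous.  Without a
        reference the direction's largest-magnitude component is made positive.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 8:
        raise DegenerateGeometryError(f"cylinder fit needs at least 8 points, got {n}")
    centroid = pts.mean(axis=0)
    svals = np.linalg.svd(pts - centroid, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateGeometryError("points are collinear; cylinder is undetermined")

    if initial_axis is not None:
        starts = [initial_axis.direction]
    else:
        _, _, vt = np.linalg.svd(pts - centroid)
        starts = [vt[0], vt[1], vt[2]]

    best = None
    for u0 in starts:
        origin, direction, r, rms, sol = _fit_from_direction(pts, unit(u0), centroid)
        if r <= 0 or not np.isfinite(rms):
            continue
        if best is None or rms < best[3]:
            best = (origin, direction, r, rms, sol)
    if best is None:
        raise ConvergenceError("cylinder fit failed from every starting direction")
    origin, direction, r, rms, sol = best
    if not sol.success:
        raise ConvergenceError(
            f"cylinder fit did not converge: {sol.message}", last_residual=rms
        )

    if reference_direction is not None:
        if direction @ np.asarray(reference_direction, dtype=float) < 0:
            direction = -direction
    elif direction[np.argmax(np.abs(direction))] < 0:
        direction = -direction
    # pin the reported origin to the point on the axis closest to the centroid
    axis = AxisLine(closest_point_on_line(centroid, AxisLine(origin, direction)), direction)
    return CylinderFit(axis=axis, radius=r, rms_residual=rms, n_points=n)
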