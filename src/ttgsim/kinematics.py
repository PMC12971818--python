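"""Flexion × screw-home rotation pose grid and the rigid-body simulation.

Knee flexion is simulated as rotation of the tibia about the femoral axial
rotation axis (FAR, the condylar cylinder axis); tibial internal rotation —
the screw-home component — as rotation about the tibial axial rotation axis
(TAR, the anatomical tibial long axis).  Both angles are non-negative degrees;
their anatomical sense (flexion posterior, internal rotation medial) is
resolved internally for right-canonical specimens.

Two composition conventions are available:

``extension_fixed`` (default)
    Internal rotation is applied about the TAR axis as located in the
    extended acquisition pose, *after* flexion.  The tuberosity's anterior
    lever arm relative to that fixed axis shrinks as the tibia flexes away
    from it, so |ΔTT-TG| for a given rotation attenuates with flexion.

``body_fixed``
    Internal rotation is applied about the tibia's own (flexed) long axis;
    equivalently, rotation about the extended-pose TAR *before* flexion.
    Under this convention ΔTT-TG is flexion-invariant whenever the posterior
    condylar axis is parallel to FAR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .frames import LandmarkSet, build_femoral_frame, canonicalize_side, far_axis, tar_axis
from .geometry import AxisLine, GeometryError, RigidTransform, fit_cylinder, rotation_about_axis
from .ttg import TTTGMatrix, measure_ttg

__all__ = [
    "CONVENTIONS",
    "KneePose",
    "PoseGrid",
    "default_grid",
    "make_grid",
    "pose_transform",
    "simulate_specimen",
    "simulate_cohort",
]

CONVENTIONS = ("extension_fixed", "body_fixed")

DEFAULT_FLEXIONS = (0.0, 10.0, 20.0, 30.0)
DEFAULT_ROTATIONS = (0.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True, order=True)
class KneePose:
    """One simulated pose: flexion and internal tibial rotation, degrees >= 0."""

    flexion: float
    internal_rotation: float

    def __post_init__(self):
        object.__setattr__(self, "flexion", float(self.flexion))
        object.__setattr__(self, "internal_rotation", float(self.internal_rotation))
        if self.flexion < 0 or self.internal_rotation < 0:
            raise ValueError(f"pose angles must be non-negative, got {self}")

    @property
    def key(self) -> tuple[float, float]:
        return (self.flexion, self.internal_rotation)


@dataclass(frozen=True)
class PoseGrid:
    """Ordered, duplicate-free pose list containing the (0, 0) baseline."""

    poses: tuple[KneePose, ...]

    def __post_init__(self):
        poses = tuple(self.poses)
        object.__setattr__(self, "poses", poses)
        if len(set(poses)) != len(poses):
            raise ValueError("pose grid contains duplicate poses")
        if KneePose(0.0, 0.0) not in poses:
            raise ValueError("pose grid must contain the (0, 0) baseline")

    def __iter__(self):
        return iter(self.poses)

    def __len__(self):
        return len(self.poses)


def make_grid(flexions: Iterable[float] = DEFAULT_FLEXIONS,
              rotations: Iterable[float] = DEFAULT_ROTATIONS) -> PoseGrid:
    """Grid of every (flexion, rotation) combination, except that rotated
    poses at 0° flexion are excluded: in the extended knee the screw-home
    rotation is taken up by the acquisition position itself, so only the
    baseline cell exists there (the cohort tables show "–" in that row)."""
    poses = [KneePose(0.0, 0.0)]
    for f in flexions:
        for r in rotations:
            p = KneePose(f, r)
            if p.flexion == 0.0 and p.internal_rotation > 0.0:
                continue
            if p not in poses:
                poses.append(p)
    return PoseGrid(tuple(poses))


def default_grid() -> PoseGrid:
    """The study grid: baseline plus {10, 20, 30}° flexion × {0, 5, 10, 15, 20}°
    internal rotation — 16 poses."""
    return make_grid()


def pose_transform(pose: KneePose, far: AxisLine, tar: AxisLine,
                   convention: str = "extension_fixed") -> RigidTransform:
    """Rigid transform taking extended-pose tibial points to the given pose.

    Both axes must be given in the extended acquisition configuration, for a
    right-canonical specimen: FAR oriented medial-to-lateral, TAR oriented
    distally.  With those orientations, flexion (tibia swings posteriorly) is
    rotation by ``-flexion`` about FAR, and internal rotation (tuberosity
    moves medially) is rotation by ``-internal_rotation`` about TAR.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    flex = rotation_about_axis(far, -pose.flexion)
    rot = rotation_about_axis(tar, -pose.internal_rotation)
    if convention == "extension_fixed":
        return rot.compose(flex)  # flex first, then rotate about the fixed TAR
    return flex.compose(rot)  # rotate about TAR first == body-fixed TAR after flexion


def simulate_specimen(lm: LandmarkSet, grid: PoseGrid | None = None,
                      convention: str = "extension_fixed") -> TTTGMatrix:
    """Measure TT-TG at every pose of the grid for one specimen.

    The specimen is first canonicalized to right-knee convention; the femoral
    frame and both rotation axes are then built once, in the extended pose.
    At each pose only the tibial landmarks move — the femoral landmarks
    (FHC, FMCP, FLCP, TGCP) are never transformed — and TT-TG is measured on
    the posed tuberosity against the fixed femoral geometry.
    """
    grid = grid or default_grid()
    try:
        lm = canonicalize_side(lm)
        fit = fit_cylinder(lm.condyle_points, reference_direction=lm.FLCP - lm.FMCP)
        frame = build_femoral_frame(lm, fit=fit)
        far = far_axis(frame, fit)
        tar = tar_axis(lm)
    except GeometryError as err:
        raise type(err)(f"specimen {lm.specimen_id}: {err}") from err
    values: dict[tuple[float, float], float] = {}
    for pose in grid:
        t = pose_transform(pose, far, tar, convention=convention)
        ttp = t.apply(lm.TTP)
        values[pose.key] = measure_ttg(lm.FMCP, lm.FLCP, lm.TGCP, ttp)
    return TTTGMatrix(specimen_id=lm.specimen_id, values=values)


def simulate_cohort(specimens: Iterable[LandmarkSet], grid: PoseGrid | None = None,
                    convention: str = "extension_fixed"):
    """Simulate every specimen; returns the long-format cohort DataFrame
    (``specimen_id, flexion_deg, rotation_deg, tttg_mm``)."""
    from .ttg import cohort_long

    grid = grid or default_grid()
    return cohort_long(simulate_specimen(lm, grid, convention=convention) for lm in specimens)
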