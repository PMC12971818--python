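"""Parametric synthetic knee specimens with geometric ground truth.

Each specimen is built in a canonical right-knee coordinate system — x
medial-to-lateral, y anterior, z proximal, with the condylar (flexion) axis
along x through the origin — and then optionally mirrored to a left knee and
placed at a random rigid pose, as a segmented CT specimen would be.

The construction is landmark-first:

* condylar surface points sampled on a posterior arc of a cylinder of drawn
  radius about the x-axis (plus isotropic surface noise);
* FMCP/FLCP at the posterior extremes of the two condyles (plus landmark
  noise, which tilts the posterior condylar axis slightly off the cylinder
  axis — the realistic source of a small flexion effect on TT-TG);
* TGCP anterior between the condyles, FHC proximal on the femoral shaft;
* a vertical tibial shaft below the knee centre, with TAPP/TADP at 1/3 and
  2/3 of its length;
* TTP at a drawn anterior and distal offset from the knee centre, with its
  lateral offset solved in closed form from a drawn baseline TT-TG target —
  so the cohort baseline distribution is calibrated exactly, not tuned.

Every draw is recorded in a :class:`GroundTruth` so that recovery oracles
(cylinder axis, offsets, analytic per-pose TT-TG) can be checked against the
pipeline.  Cohorts use one seed with per-specimen substreams: extending a
cohort never perturbs earlier specimens.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from .frames import LandmarkSet, shaft_midpoints
from .geometry import AxisLine, unit

__all__ = [
    "SyntheticKneeParams",
    "GroundTruth",
    "sample_specimen",
    "sample_cohort",
    "analytic_tttg",
    "zero_noise",
    "export_condyle_mesh",
]


@dataclass(frozen=True)
class SyntheticKneeParams:
    """Population parameters for the synthetic cohort (lengths in mm, angles
    in degrees).

    The defaults define the study conditions: a cohort of 56 knees whose
    baseline TT-TG is drawn from N(14.1, 4.0²), condylar cylinders of radius
    ~22 mm, and a tuberosity ~35 mm anterior and ~25 mm distal to the knee
    centre — the lever-arm geometry that reproduces the reported per-pose
    ΔTT-TG pattern under the extension-fixed rotation convention.
    """

    n_specimens: int = 56
    # femoral condyle cylinder
    condyle_radius_mean: float = 22.0
    condyle_radius_sd: float = 2.0
    intercondylar_halfwidth: float = 25.0
    condyle_arc: float = 140.0
    n_surface_points: int = 200
    surface_noise_sd: float = 0.1
    # posterior condylar landmarks
    posterior_landmark_halfwidth: float = 30.0
    posterior_landmark_noise_sd: float = 0.5
    # femur / tibia long geometry
    fhc_offset: float = 400.0
    fhc_medial_offset: float = 40.0
    shaft_top_offset: float = 20.0
    shaft_length: float = 300.0
    # tuberosity placement
    tt_anterior_offset_mean: float = 35.0
    tt_anterior_offset_sd: float = 3.5
    tt_distal_offset_mean: float = 25.0
    tt_distal_offset_sd: float = 3.5
    # trochlear groove placement
    tgcp_medial_offset: float = 2.5
    tgcp_anterior_offset: float = 25.0
    # baseline TT-TG calibration target
    baseline_ttg_target_mean: float = 14.1
    baseline_ttg_target_sd: float = 4.0
    # cohort structure
    side_probability: float = 0.5  # probability a specimen is right-sided
    randomize_pose: bool = True
    pose_translation_range: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 2:
            raise ValueError("n_specimens must be at least 2")
        for name in ("condyle_radius_sd", "surface_noise_sd", "posterior_landmark_noise_sd",
                     "tt_anterior_offset_sd", "tt_distal_offset_sd", "baseline_ttg_target_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("condyle_radius_mean", "intercondylar_halfwidth", "condyle_arc",
                     "fhc_offset", "shaft_length", "tt_anterior_offset_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.side_probability <= 1.0:
            raise ValueError("side_probability must be in [0, 1]")
        if self.n_surface_points < 8:
            raise ValueError("n_surface_points must be at least 8")

    @property
    def tt_lateral_offset_mean(self) -> float:
        """Mean lateral offset of TTP from the tibial axis implied by the
        baseline calibration (closed form, see :func:`sample_specimen`)."""
        return self.baseline_ttg_target_mean - self.tgcp_medial_offset

    @property
    def tt_lateral_offset_sd(self) -> float:
        return self.baseline_ttg_target_sd


def zero_noise(params: SyntheticKneeParams | None = None, **overrides) -> SyntheticKneeParams:
    """A copy of ``params`` with every noise/spread source set to zero —
    specimens become analytically exact and cohorts degenerate-deterministic."""
    base = params or SyntheticKneeParams()
    zeroed = dict(
        condyle_radius_sd=0.0,
        surface_noise_sd=0.0,
        posterior_landmark_noise_sd=0.0,
        tt_anterior_offset_sd=0.0,
        tt_distal_offset_sd=0.0,
        baseline_ttg_target_sd=0.0,
    )
    zeroed.update(overrides)
    return dataclasses.replace(base, **zeroed)


@dataclass(frozen=True)
class GroundTruth:
    """Per-specimen generative truth, recorded in canonical right-knee space."""

    specimen_id: str
    side: str
    radius: float
    condyle_axis: AxisLine  # canonical flexion axis (x through origin)
    tar: AxisLine  # canonical tibial long axis, oriented distally
    landmarks: dict[str, np.ndarray]  # canonical right-convention landmarks
    tt_anterior_offset: float
    tt_distal_offset: float
    tt_lateral_offset: float
    baseline_ttg: float
    world_rotation: np.ndarray  # applied after any mirroring
    world_translation: np.ndarray
    mirrored: bool


def _sample_condyle_points(params: SyntheticKneeParams, radius: float,
                           rng: np.random.Generator) -> np.ndarray:
    hw = params.intercondylar_halfwidth
    x = rng.uniform(-hw, hw, params.n_surface_points)
    half_arc = np.deg2rad(params.condyle_arc) / 2.0
    psi = rng.uniform(-half_arc, half_arc, params.n_surface_points)
    # arc centred on the posterior direction (-y), sweeping proximal/distal
    pts = np.column_stack([x, -radius * np.cos(psi), radius * np.sin(psi)])
    if params.surface_noise_sd > 0:
        pts = pts + rng.normal(0.0, params.surface_noise_sd, pts.shape)
    return pts


def sample_specimen(params: SyntheticKneeParams, rng: np.random.Generator,
                    specimen_id: str = "synthetic-000") -> tuple[LandmarkSet, GroundTruth]:
    """Draw one specimen; returns its landmark set (world coordinates) and
    the generative ground truth (canonical coordinates + world transform)."""
    radius = float(rng.normal(params.condyle_radius_mean, params.condyle_radius_sd))
    if radius <= 0:
        raise ValueError("drawn condyle radius is non-positive; reduce condyle_radius_sd")
    condyle_points = _sample_condyle_points(params, radius, rng)

    phw = params.posterior_landmark_halfwidth
    noise = (lambda: rng.normal(0.0, params.posterior_landmark_noise_sd, 3)) \
        if params.posterior_landmark_noise_sd > 0 else (lambda: np.zeros(3))
    FMCP = np.array([-phw, -radius, 0.0]) + noise()
    FLCP = np.array([phw, -radius, 0.0]) + noise()
    TGCP = np.array([-params.tgcp_medial_offset, params.tgcp_anterior_offset, 0.0])
    FHC = np.array([-params.fhc_medial_offset, 0.0, params.fhc_offset])

    shaft_prox = np.array([0.0, 0.0, -params.shaft_top_offset])
    shaft_dist = shaft_prox + np.array([0.0, 0.0, -params.shaft_length])
    TAPP, TADP = shaft_midpoints(shaft_prox, shaft_dist)

    w_ant = float(rng.normal(params.tt_anterior_offset_mean, params.tt_anterior_offset_sd))
    d_tt = float(rng.normal(params.tt_distal_offset_mean, params.tt_distal_offset_sd))
    baseline = float(rng.normal(params.baseline_ttg_target_mean, params.baseline_ttg_target_sd))
    # closed-form calibration: TT-TG(baseline) = lateral + tgcp_medial_offset
    lateral = baseline - params.tgcp_medial_offset
    TTP = np.array([lateral, w_ant, -d_tt])

    canonical = {"FHC": FHC, "FMCP": FMCP, "FLCP": FLCP, "TGCP": TGCP,
                 "TTP": TTP, "TAPP": TAPP, "TADP": TADP}
    side = "right" if rng.random() < params.side_probability else "left"

    world_points = {k: v.copy() for k, v in canonical.items()}
    world_condyles = condyle_points.copy()
    mirrored = side == "left"
    if mirrored:
        for v in world_points.values():
            v[0] = -v[0]
        world_condyles[:, 0] = -world_condyles[:, 0]

    if params.randomize_pose:
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-params.pose_translation_range, params.pose_translation_range, 3)
    else:
        R, t = np.eye(3), np.zeros(3)
    world_points = {k: R @ v + t for k, v in world_points.items()}
    world_condyles = world_condyles @ R.T + t

    lm = LandmarkSet(specimen_id=specimen_id, side=side,
                     condyle_points=world_condyles, **world_points)
    gt = GroundTruth(
        specimen_id=specimen_id,
        side=side,
        radius=radius,
        condyle_axis=AxisLine(np.zeros(3), np.array([1.0, 0.0, 0.0])),
        tar=AxisLine(TAPP, unit(TADP - TAPP)),
        landmarks=canonical,
        tt_anterior_offset=w_ant,
        tt_distal_offset=d_tt,
        tt_lateral_offset=lateral,
        baseline_ttg=baseline,
        world_rotation=R,
        world_translation=t,
        mirrored=mirrored,
    )
    return lm, gt


def specimen_streams(params: SyntheticKneeParams) -> Iterator[np.random.Generator]:
    """Independent per-specimen random substreams derived from the cohort seed."""
    for child in np.random.SeedSequence(params.seed).spawn(params.n_specimens):
        yield np.random.default_rng(child)


def sample_cohort(params: SyntheticKneeParams | None = None) -> list[tuple[LandmarkSet, GroundTruth]]:
    """Draw the full cohort: ``n_specimens`` independent specimens from one
    seeded stream with per-specimen substreams."""
    params = params or SyntheticKneeParams()
    out = []
    for i, rng in enumerate(specimen_streams(params)):
        out.append(sample_specimen(params, rng, specimen_id=f"synthetic-{i:03d}"))
    return out


def analytic_tttg(gt: GroundTruth, flexion: float, internal_rotation: float,
                  convention: str = "extension_fixed") -> float:
    """Closed-form TT-TG at a pose, from generative ground truth alone.

    Works entirely in canonical right-knee space with the *true* condylar
    axis (never the fitted one) and scipy's rotation machinery, so it is an
    independent oracle for the full landmark->frame->pose->measurement
    pipeline.  TT-TG is invariant under the specimen's mirroring and world
    pose, so no world transform enters.
    """
    lms = gt.landmarks
    a = unit(lms["FLCP"] - lms["FMCP"])

    def rotate_about(line: AxisLine, angle_deg: float, p: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * line.direction).as_matrix()
        return line.origin + R @ (p - line.origin)

    far = gt.condyle_axis
    ttp = lms["TTP"]
    if convention == "extension_fixed":
        ttp = rotate_about(far, -flexion, ttp)
        ttp = rotate_about(gt.tar, -internal_rotation, ttp)
    elif convention == "body_fixed":
        ttp = rotate_about(gt.tar, -internal_rotation, ttp)
        ttp = rotate_about(far, -flexion, ttp)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float((ttp - lms["TGCP"]) @ a)


def export_condyle_mesh(gt: GroundTruth, path, sections: int = 64) -> None:
    """Write the specimen's condylar cylinder as a surface mesh (PLY/STL by
    extension), in the same world pose as its emitted landmarks; intended for
    round-trip testing of mesh-based condyle sampling."""
    import trimesh

    halfwidth = 40.0  # generous: covers the sampled intercondylar span
    mesh = trimesh.creation.cylinder(radius=gt.radius, height=2 * halfwidth,
                                     sections=sections)
    # drop the flat end caps: only the lateral surface is condylar
    mesh.update_faces(np.abs(mesh.face_normals[:, 2]) < 0.5)
    # trimesh builds the cylinder along +z; canonical condylar axis is +x
    align = np.eye(4)
    align[:3, :3] = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    mesh.apply_transform(align)
    if gt.mirrored:
        mirror = np.eye(4)
        mirror[0, 0] = -1.0
        mesh.apply_transform(mirror)
    world = np.eye(4)
    world[:3, :3] = gt.world_rotation
    world[:3, 3] = gt.world_translation
    mesh.apply_transform(world)
    mesh.export(str(path))
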