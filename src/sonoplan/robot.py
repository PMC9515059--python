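"""Transducer pose, capsule-chain robot proxy, and projection-based beam blocking.

The ultrasound robot is modeled as a minimal capsule chain that exhibits the
one property the setup optimization exploits: elbow self-motion. Given a base
position and a transducer pose, the wrist point is fixed by the probe geometry
and the elbow lies on a circle (the self-motion manifold) parameterized by the
LIFT angle, so the arm can move during treatment without moving the probe.
Upper arm and forearm are 460 mm each (920 mm wrist reach), the probe link is
120 mm, and the matrix-probe body is a 16 mm-radius capsule (24x26 mm
footprint).

Blocking is capsule-versus-cone clearance: a candidate beam is blocked when
some capsule comes closer to the beam axis than the capsule radius plus the
collimator cone radius at the closest point plus a 20 mm motion margin. With
several LIFT angles, a beam counts as blocked only if every resulting arm
configuration blocks it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beams import SOURCE_RADIUS_MM, CandidateBeamSet

UPPER_ARM_MM = 460.0
FOREARM_MM = 460.0
PROBE_LINK_MM = 120.0
WRIST_REACH_MM = UPPER_ARM_MM + FOREARM_MM    # 920
WRIST_MIN_MM = 150.0
LINK_RADIUS_MM = 60.0
PROBE_RADIUS_MM = 16.0
BLOCKING_MARGIN_MM = 20.0
DEFAULT_LIFT_TRIPLET = tuple(np.deg2rad([-30.0, 0.0, 30.0]))


class SetupInfeasibleError(RuntimeError):
    """No solvable arm configuration exists for the requested setup."""


@dataclass
class TransducerPose:
    position: np.ndarray       # skin point (probe face)
    axial_axis: np.ndarray     # unit vector toward the PTV centroid
    roll: np.ndarray           # unit vector, mounting direction, perpendicular to axis
    roll_fallback: bool = False


@dataclass
class BasePositionBox:
    """Axis-aligned box of allowed robot base positions."""

    name: str
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, float)
        self.hi = np.asarray(self.hi, float)

    def contains(self, p: np.ndarray) -> bool:
        return bool(np.all(p >= self.lo - 1e-9) and np.all(p <= self.hi + 1e-9))

    def clip(self, p: np.ndarray) -> np.ndarray:
        return np.clip(p, self.lo, self.hi)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lo, self.hi)


def default_base_boxes(body_semiaxes=(160.0, 105.0, 120.0), center=(0.0, 0.0, 0.0)):
    """Base-position boxes beside the patient and between the legs."""
    cx, cy, cz = center
    ax, ay, az = body_semiaxes
    side_dx, dy, dz = 250.0, 300.0, 300.0
    return [
        BasePositionBox(
            "left", (cx + ax + 80.0, cy - dy / 2, cz - dz / 2),
            (cx + ax + 80.0 + side_dx, cy + dy / 2, cz + dz / 2),
        ),
        BasePositionBox(
            "right", (cx - ax - 80.0 - side_dx, cy - dy / 2, cz - dz / 2),
            (cx - ax - 80.0, cy + dy / 2, cz + dz / 2),
        ),
        BasePositionBox(
            "legs", (cx - 150.0, cy - dy / 2, cz - az - 100.0 - 350.0),
            (cx + 150.0, cy + dy / 2, cz - az - 100.0),
        ),
    ]


@dataclass
class RobotSetup:
    base_position: np.ndarray
    box_name: str
    viewport_index: int
    lift_angles: tuple

    def __post_init__(self) -> None:
        self.base_position = np.asarray(self.base_position, float)
        self.lift_angles = tuple(float(a) for a in np.atleast_1d(self.lift_angles))


@dataclass
class CapsuleSet:
    """Capsules (a, b, radius) approximating arm links and the probe body."""

    endpoints_a: np.ndarray   # (k, 3)
    endpoints_b: np.ndarray   # (k, 3)
    radii: np.ndarray         # (k,)

    def __len__(self) -> int:
        return len(self.radii)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "CapsuleSet":
        return CapsuleSet(self.endpoints_a @ R.T + t, self.endpoints_b @ R.T + t, self.radii)


def transducer_pose_from_viewport(
    skin_point: np.ndarray, centroid: np.ndarray, base_position: np.ndarray
) -> TransducerPose:
    """Pose rule: axial axis at the target centroid, mounting toward the base.

    The roll vector is the projection of (base - position) onto the plane
    normal to the axial axis; if the base is collinear with the axis, the
    patient-superior direction (projected) is used and flagged.
    """
    skin_point = np.asarray(skin_point, float)
    centroid = np.asarray(centroid, float)
    base_position = np.asarray(base_position, float)
    axis = centroid - skin_point
    axis = axis / np.linalg.norm(axis)
    raw = base_position - skin_point
    roll = raw - (raw @ axis) * axis
    fallback = False
    if np.linalg.norm(roll) < 1e-9:
        fallback = True
        up = np.array([0.0, 0.0, 1.0])
        roll = up - (up @ axis) * axis
        if np.linalg.norm(roll) < 1e-9:
            roll = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    roll = roll / np.linalg.norm(roll)
    return TransducerPose(skin_point, axis, roll, fallback)


def solve_configuration(
    base: np.ndarray, pose: TransducerPose, lift: float
) -> CapsuleSet | None:
    """Realize the capsule chain base→elbow→wrist→probe for one LIFT angle.

    The wrist sits one probe link outside the skin along the axial axis. The
    chain is solvable iff the base-to-wrist distance lies in [150, 920] mm;
    the elbow then lies on the self-motion circle of radius
    sqrt(460^2 - (d/2)^2) in the plane bisecting base and wrist, at angle
    ``lift`` measured from the (projected) superior direction. Returns None
    when unsolvable (a value, not an error).
    """
    base = np.asarray(base, float)
    wrist = pose.position - PROBE_LINK_MM * pose.axial_axis
    bw = wrist - base
    d = float(np.linalg.norm(bw))
    if d > WRIST_REACH_MM + 1e-9 or d < WRIST_MIN_MM - 1e-9:
        return None
    u = bw / d
    r2 = UPPER_ARM_MM**2 - (d / 2.0) ** 2
    r = float(np.sqrt(max(r2, 0.0)))
    up = np.array([0.0, 0.0, 1.0])
    v1 = up - (up @ u) * u
    if np.linalg.norm(v1) < 1e-9:
        v1 = np.array([1.0, 0.0, 0.0]) - u[0] * u
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    elbow = base + 0.5 * bw + r * (np.cos(lift) * v1 + np.sin(lift) * v2)
    a = np.stack([base, elbow, wrist])
    b = np.stack([elbow, wrist, pose.position])
    radii = np.array([LINK_RADIUS_MM, LINK_RADIUS_MM, PROBE_RADIUS_MM])
    return CapsuleSet(a, b, radii)


def _segment_segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min distance between segment batches [p1,q1] and [p2,q2] (broadcast),
    plus the closest parameter on the second segment (the beam axis)."""
    eps = 1e-12
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = (d1 * d1).sum(-1)
    e = (d2 * d2).sum(-1)
    f = (d2 * r).sum(-1)
    c = (d1 * r).sum(-1)
    b = (d1 * d2).sum(-1)
    a_safe = np.where(a > eps, a, 1.0)
    e_safe = np.where(e > eps, e, 1.0)
    denom = a * e - b * b
    # general case: closest parameters on both infinite lines, then clamp and
    # re-project; parallel lines (denom ~ 0) start from s = 0
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0, 1), 0.0)
    t = np.clip((b * s + f) / e_safe, 0.0, 1.0)
    s = np.clip((b * t - c) / a_safe, 0.0, 1.0)
    # degenerate segments: point-vs-segment projections
    s = np.where(a > eps, s, 0.0)
    t = np.where(e > eps, np.where(a > eps, t, np.clip(f / e_safe, 0, 1)), 0.0)
    s = np.where((a > eps) & ~(e > eps), np.clip(-c / a_safe, 0, 1), s)
    c1 = p1 + s[..., None] * d1
    c2 = p2 + t[..., None] * d2
    return np.linalg.norm(c1 - c2, axis=-1), t


def blocked_mask(
    beams: CandidateBeamSet,
    capsules: CapsuleSet,
    margin: float = BLOCKING_MARGIN_MM,
) -> np.ndarray:
    """Vectorized blocking flags for every beam against one capsule set."""
    B, K = len(beams), len(capsules)
    p1 = np.broadcast_to(capsules.endpoints_a[None], (B, K, 3))
    q1 = np.broadcast_to(capsules.endpoints_b[None], (B, K, 3))
    p2 = np.broadcast_to(beams.sources[:, None], (B, K, 3))
    q2 = np.broadcast_to(beams.targets[:, None], (B, K, 3))
    dist, t = _segment_segment_distance(p1, q1, p2, q2)
    axis_len = np.linalg.norm(beams.targets - beams.sources, axis=1)[:, None]
    cone_r = (beams.diameters[:, None] / 2.0) * (t * axis_len) / SOURCE_RADIUS_MM
    return np.any(dist < capsules.radii[None] + cone_r + margin, axis=1)


def beam_blocked(beam, capsules: CapsuleSet, margin: float = BLOCKING_MARGIN_MM) -> bool:
    """Blocking decision for a single beam (clearance against every capsule)."""
    bs = CandidateBeamSet(beam.source[None], beam.target[None], np.array([beam.diameter]))
    return bool(blocked_mask(bs, capsules, margin)[0])


def blocked_set(
    beams: CandidateBeamSet,
    setup: RobotSetup,
    viewport_points: np.ndarray,
    centroid: np.ndarray,
    margin: float = BLOCKING_MARGIN_MM,
) -> np.ndarray:
    """Indices of beams blocked by *all* solvable LIFT configurations.

    Unsolvable LIFT angles are skipped; if no configuration is solvable the
    setup is infeasible and an error is raised.
    """
    skin = np.asarray(viewport_points)[setup.viewport_index]
    pose = transducer_pose_from_viewport(skin, centroid, setup.base_position)
    blocked = None
    solvable = 0
    for lift in setup.lift_angles:
        caps = solve_configuration(setup.base_position, pose, lift)
        if caps is None:
            continue
        solvable += 1
        m = blocked_mask(beams, caps, margin)
        blocked = m if blocked is None else (blocked & m)
    if solvable == 0:
        raise SetupInfeasibleError("no solvable arm configuration for any LIFT angle")
    return np.nonzero(blocked)[0]
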