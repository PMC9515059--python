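"""Capsule-chain kinematics and projection-based beam blocking."""

import numpy as np
import pytest

from sonoplan.beams import Beam, CandidateBeamSet
from sonoplan.robot import (
    PROBE_LINK_MM,
    WRIST_MIN_MM,
    WRIST_REACH_MM,
    CapsuleSet,
    RobotSetup,
    SetupInfeasibleError,
    beam_blocked,
    blocked_mask,
    blocked_set,
    default_base_boxes,
    solve_configuration,
    transducer_pose_from_viewport,
)


def rand_pose(rng):
    skin = rng.normal(scale=80, size=3)
    centroid = skin + rng.normal(scale=60, size=3) + 1.0
    base = rng.normal(scale=300, size=3)
    return skin, centroid, base


class TestTransducerPose:
    @pytest.mark.parametrize("seed", range(10))
    def test_roll_orthogonal_to_axis(self, seed):
        rng = np.random.default_rng(seed)
        skin, centroid, base = rand_pose(rng)
        pose = transducer_pose_from_viewport(skin, centroid, base)
        assert abs(pose.roll @ pose.axial_axis) < 1e-9
        assert np.linalg.norm(pose.axial_axis) == pytest.approx(1.0)

    def test_roll_points_toward_lateral_base(self):
        pose = transducer_pose_from_viewport((0, -70, 0), (0, 0, 0), (300, -70, 0))
        assert pose.roll @ np.array([1.0, 0.0, 0.0]) > 0

    def test_opposite_bases_give_antiparallel_rolls(self):
        p1 = transducer_pose_from_viewport((0, -70, 0), (0, 0, 0), (300, -70, 20))
        p2 = transducer_pose_from_viewport((0, -70, 0), (0, 0, 0), (-300, -70, -20))
        assert p1.roll @ p2.roll == pytest.approx(-1.0, abs=1e-9)

    def test_collinear_base_falls_back_flagged(self):
        pose = transducer_pose_from_viewport((0, -70, 0), (0, 0, 0), (0, -500, 0))
        assert pose.roll_fallback
        assert abs(pose.roll @ pose.axial_axis) < 1e-9

    def test_axis_points_at_centroid(self):
        pose = transducer_pose_from_viewport((10, -70, 5), (0, 0, 0), (300, 0, 0))
        to_centroid = -np.array([10.0, -70.0, 5.0])
        to_centroid /= np.linalg.norm(to_centroid)
        assert pose.axial_axis @ to_centroid > 0.999


class TestSolveConfiguration:
    def pose_at(self, skin, centroid=(0.0, 0.0, 0.0), base=(300.0, 0.0, 0.0)):
        return transducer_pose_from_viewport(np.asarray(skin, float), np.asarray(centroid, float), np.asarray(base, float))

    def test_reach_boundary_unique_chain(self):
        pose = self.pose_at((0, -70, 0))
        wrist = pose.position - PROBE_LINK_MM * pose.axial_axis
        base = wrist + np.array([WRIST_REACH_MM, 0.0, 0.0])
        c1 = solve_configuration(base, pose, 0.0)
        c2 = solve_configuration(base, pose, 2.0)
        assert c1 is not None and c2 is not None
        # elbow circle radius 0: elbow identical for any LIFT angle
        assert np.allclose(c1.endpoints_a[1], c2.endpoints_a[1], atol=1e-6)

    def test_beyond_reach_infeasible(self):
        pose = self.pose_at((0, -70, 0))
        wrist = pose.position - PROBE_LINK_MM * pose.axial_axis
        base = wrist + np.array([WRIST_REACH_MM + 1.0, 0.0, 0.0])
        assert solve_configuration(base, pose, 0.0) is None

    def test_below_min_reach_infeasible(self):
        pose = self.pose_at((0, -70, 0))
        wrist = pose.position - PROBE_LINK_MM * pose.axial_axis
        base = wrist + np.array([WRIST_MIN_MM - 5.0, 0.0, 0.0])
        assert solve_configuration(base, pose, 0.0) is None

    def test_lift_periodicity(self):
        pose = self.pose_at((0, -70, 0))
        base = np.array([400.0, -200.0, 100.0])
        c1 = solve_configuration(base, pose, 0.7)
        c2 = solve_configuration(base, pose, 0.7 + 2 * np.pi)
        assert np.allclose(c1.endpoints_a, c2.endpoints_a, atol=1e-9)

    def test_chain_connects_base_to_probe(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            skin, centroid, _ = rand_pose(rng)
            pose = transducer_pose_from_viewport(skin, centroid, (400, 0, 0))
            base = rng.uniform(-400, 400, 3)
            caps = solve_configuration(base, pose, rng.uniform(-np.pi, np.pi))
            if caps is None:
                continue
            assert np.allclose(caps.endpoints_a[0], base)
            assert np.allclose(caps.endpoints_b[-1], pose.position, atol=1.0)
            # consecutive capsules share endpoints
            assert np.allclose(caps.endpoints_b[0], caps.endpoints_a[1])
            assert np.allclose(caps.endpoints_b[1], caps.endpoints_a[2])


def one_beam(source, target, diameter=20.0):
    return CandidateBeamSet(np.atleast_2d(source), np.atleast_2d(target), np.array([diameter]))


class TestBeamBlocked:
    def test_far_capsule_clear(self):
        caps = CapsuleSet(np.array([[500.0, 500, 0]]), np.array([[500.0, 500, 300]]), np.array([60.0]))
        beams = one_beam([0, -800, 0], [0, 0, 0])
        assert not blocked_mask(beams, caps)[0]

    def test_crossing_capsule_blocks(self):
        caps = CapsuleSet(np.array([[-100.0, -400, 0]]), np.array([[100.0, -400, 0]]), np.array([30.0]))
        beams = one_beam([0, -800, 0], [0, 0, 0])
        assert blocked_mask(beams, caps)[0]

    def test_margin_monotonicity(self):
        rng = np.random.default_rng(5)
        caps = CapsuleSet(rng.normal(scale=200, size=(3, 3)), rng.normal(scale=200, size=(3, 3)), np.array([40.0, 40.0, 16.0]))
        beams = CandidateBeamSet(
            rng.normal(scale=400, size=(200, 3)), rng.normal(scale=100, size=(200, 3)),
            np.full(200, 20.0),
        )
        b_small = blocked_mask(beams, caps, margin=10.0)
        b_large = blocked_mask(beams, caps, margin=40.0)
        assert np.all(b_large[b_small])  # blocked(10) subset of blocked(40)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(scale=500, size=3)
        caps = CapsuleSet(rng.normal(scale=200, size=(2, 3)), rng.normal(scale=200, size=(2, 3)), np.array([30.0, 16.0]))
        src = rng.normal(scale=400, size=(50, 3))
        tgt = rng.normal(scale=80, size=(50, 3))
        beams = CandidateBeamSet(src, tgt, np.full(50, 30.0))
        beams_t = CandidateBeamSet(src @ q.T + t, tgt @ q.T + t, np.full(50, 30.0))
        assert np.array_equal(blocked_mask(beams, caps), blocked_mask(beams_t, caps.transformed(q, t)))

    def test_single_beam_wrapper(self):
        caps = CapsuleSet(np.array([[-100.0, -400, 0]]), np.array([[100.0, -400, 0]]), np.array([30.0]))
        assert beam_blocked(Beam([0, -800, 0], [0, 0, 0], 20.0), caps)


class TestBlockedSet:
    def setup_scene(self, rng, n_beams=60):
        centroid = np.zeros(3)
        viewports = np.array([[0.0, -70.0, 0.0], [30.0, -65.0, 10.0]])
        beams = CandidateBeamSet(
            rng.normal(scale=50, size=(n_beams, 3)) + np.array([0, -800, 200]),
            rng.normal(scale=20, size=(n_beams, 3)),
            rng.choice([10.0, 20.0, 40.0], size=n_beams),
        )
        return centroid, viewports, beams

    def test_single_lift_reduces_to_plain_blocking(self):
        rng = np.random.default_rng(2)
        centroid, viewports, beams = self.setup_scene(rng)
        setup = RobotSetup(np.array([350.0, -100.0, 0.0]), "left", 0, (0.3,))
        blocked = blocked_set(beams, setup, viewports, centroid)
        pose = transducer_pose_from_viewport(viewports[0], centroid, setup.base_position)
        caps = solve_configuration(setup.base_position, pose, 0.3)
        expected = np.nonzero(blocked_mask(beams, caps))[0]
        assert np.array_equal(blocked, expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_three_lifts_subset_of_shared_single_lift(self, seed):
        rng = np.random.default_rng(100 + seed)
        centroid, viewports, beams = self.setup_scene(rng)
        base = np.array([rng.uniform(250, 450), rng.uniform(-150, 150), rng.uniform(-100, 100)])
        lifts = (-0.5, 0.3, 1.1)
        try:
            b3 = blocked_set(beams, RobotSetup(base, "left", 0, lifts), viewports, centroid)
            b1 = blocked_set(beams, RobotSetup(base, "left", 0, (0.3,)), viewports, centroid)
        except SetupInfeasibleError:
            return
        assert set(b3) <= set(b1)

    def test_no_solvable_configuration_raises(self):
        rng = np.random.default_rng(4)
        centroid, viewports, beams = self.setup_scene(rng)
        setup = RobotSetup(np.array([5000.0, 0.0, 0.0]), "left", 0, (0.0,))
        with pytest.raises(SetupInfeasibleError):
            blocked_set(beams, setup, viewports, centroid)

    def test_beam_blocked_under_one_lift_only_is_not_blocked(self):
        """A beam blocked in some but not all arm configurations stays usable."""
        rng = np.random.default_rng(7)
        centroid, viewports, beams = self.setup_scene(rng, n_beams=200)
        base = np.array([350.0, -100.0, 0.0])
        lifts = (-1.2, 0.0, 1.2)
        per_lift = []
        pose = transducer_pose_from_viewport(viewports[0], centroid, base)
        for lift in lifts:
            caps = solve_configuration(base, pose, lift)
            assert caps is not None
            per_lift.append(set(np.nonzero(blocked_mask(beams, caps))[0]))
        combined = set(blocked_set(beams, RobotSetup(base, "left", 0, lifts), viewports, centroid))
        assert combined == per_lift[0] & per_lift[1] & per_lift[2]
        partial = (per_lift[0] | per_lift[1] | per_lift[2]) - combined
        assert partial.isdisjoint(combined)


def test_default_base_boxes_disjoint_from_torso():
    boxes = default_base_boxes()
    for box in boxes:
        assert box.name in ("left", "right", "legs")
        assert np.all(box.hi >= box.lo)
    # lateral boxes flank the body laterally
    assert boxes[0].lo[0] > 160.0
    assert boxes[1].hi[0] < -160.0


from hypothesis import given, settings
from hypothesis import strategies as st

from sonoplan.robot import _segment_segment_distance

coord = st.floats(-500, 500, allow_nan=False)
point = st.tuples(coord, coord, coord)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(p1=point, q1=point, p2=point, q2=point)
def test_segment_distance_symmetric_and_tight(p1, q1, p2, q2):
    a = [np.array(x, float) for x in (p1, q1, p2, q2)]
    d12, _ = _segment_segment_distance(a[0], a[1], a[2], a[3])
    d21, _ = _segment_segment_distance(a[2], a[3], a[0], a[1])
    assert d12 == pytest.approx(d21, abs=1e-6)
    # never larger than any sampled point-pair distance (upper bound check)
    t = np.linspace(0, 1, 9)
    s1 = a[0] + t[:, None] * (a[1] - a[0])
    s2 = a[2] + t[:, None] * (a[3] - a[2])
    sampled = np.linalg.norm(s1[:, None, :] - s2[None, :, :], axis=-1).min()
    assert d12 <= sampled + 1e-6
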