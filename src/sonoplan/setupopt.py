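"""Simulated-annealing search for the ultrasound-robot setup, and the
workflow compositions that couple it to candidate generation and planning.

The annealer minimizes one of four blocking objectives over the state
(robot base position, viewport, LIFT angle):

  BR  — number of blocked randomly sampled candidate beams,
  BRW — total plan MU of blocked beams (weights from a no-robot plan),
  BC  — number of blocked CNN-generated beams,
  BCW — total predicted weight of blocked CNN-generated beams.

Cooling is geometric: temperature starts at 10 and halves every 100
iterations over 1000 iterations; worsening moves are accepted with
probability exp(-delta/theta), and the search restarts from five random
initial states, keeping the best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beams import CandidateBeamSet, compute_dose_matrix, sample_candidate_beams
from .phantom import PTV, CtVolume, StructureSet, VoxelGrid
from .planning import PlanConstraints, TreatmentPlan, optimize_coverage, optimize_mu
from .robot import (
    DEFAULT_LIFT_TRIPLET,
    BasePositionBox,
    RobotSetup,
    SetupInfeasibleError,
    blocked_set,
    default_base_boxes,
)
from .viewports import ViewportMap

OBJECTIVE_KINDS = ("BR", "BRW", "BC", "BCW")


@dataclass
class ObjectiveSpec:
    """Blocking objective: which beams, and what each blocked beam costs."""

    kind: str
    beam_set: CandidateBeamSet
    weights: np.ndarray | None = None   # implicit 1 for BR/BC

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"objective kind must be one of {OBJECTIVE_KINDS}")
        if self.weights is None:
            if self.kind in ("BRW", "BCW"):
                if self.beam_set.weights is None:
                    raise ValueError(f"{self.kind} requires per-beam weights")
                self.weights = np.asarray(self.beam_set.weights, float)
            else:
                self.weights = np.ones(len(self.beam_set))
        else:
            self.weights = np.asarray(self.weights, float)
        if len(self.weights) != len(self.beam_set):
            raise ValueError("weights length must match beam count")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")


@dataclass
class AnnealSchedule:
    theta0: float = 10.0
    halve_every: int = 100
    iterations: int = 1000
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.theta0, self.halve_every, self.iterations, self.restarts) <= 0:
            raise ValueError("schedule parameters must be positive")

    def temperature(self, iteration: int) -> float:
        return self.theta0 * 0.5 ** (iteration // self.halve_every)


@dataclass
class AnnealTrace:
    rows: list = field(default_factory=list)  # (iteration, theta, objective, accepted, best)

    def append(self, iteration, theta, objective, accepted, best) -> None:
        self.rows.append((iteration, theta, objective, accepted, best))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["iteration", "theta", "objective", "accepted", "best"]
        )


def anneal(problem, schedule: AnnealSchedule, rng: np.random.Generator):
    """One Metropolis run; returns (best_state, best_objective, trace).

    ``problem`` provides initial(rng), neighbor(state, theta, rng) and
    objective(state) (lower is better; +inf marks infeasible states).
    """
    state = problem.initial(rng)
    obj = problem.objective(state)
    best_state, best_obj = state, obj
    trace = AnnealTrace()
    for it in range(schedule.iterations):
        theta = schedule.temperature(it)
        cand = problem.neighbor(state, theta, rng)
        cand_obj = problem.objective(cand)
        delta = cand_obj - obj
        accept = delta <= 0 or (np.isfinite(cand_obj) and rng.random() < np.exp(-delta / theta))
        if accept:
            state, obj = cand, cand_obj
            if obj < best_obj:
                best_state, best_obj = state, obj
        trace.append(it, theta, obj, bool(accept), best_obj)
    return best_state, best_obj, trace


def anneal_restarts(problem, schedule: AnnealSchedule):
    """Best of ``schedule.restarts`` independent runs (seeded from schedule.seed)."""
    best = None
    traces = []
    for r in range(schedule.restarts):
        rng = np.random.default_rng(np.random.SeedSequence((schedule.seed, r)))
        state, obj, trace = anneal(problem, schedule, rng)
        traces.append(trace)
        if best is None or obj < best[1]:
            best = (state, obj)
    return best[0], best[1], traces


@dataclass
class RobotSetupProblem:
    """SA search space: base position in one of the allowed boxes, feasible
    viewport index, and a base LIFT angle (k_lift=3 adds ±30° companions)."""

    spec: ObjectiveSpec
    viewport_map: ViewportMap
    centroid: np.ndarray
    boxes: list[BasePositionBox] = None
    k_lift: int = 1
    lift_offsets: tuple = DEFAULT_LIFT_TRIPLET
    base_sigma: float = 30.0
    lift_sigma: float = np.deg2rad(15.0)
    viewport_hop: float = 25.0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.boxes is None:
            self.boxes = default_base_boxes()
        self.centroid = np.asarray(self.centroid, float)
        self._feasible = self.viewport_map.feasible_indices
        if len(self._feasible) == 0:
            raise SetupInfeasibleError("viewport map has no feasible viewport")
        self._points = np.array([v.skin_point for v in self.viewport_map.viewports])
        if self.k_lift not in (1, 3):
            raise ValueError("k_lift must be 1 or 3")

    def _lift_angles(self, base_lift: float) -> tuple:
        if self.k_lift == 1:
            return (base_lift,)
        return tuple(base_lift + o for o in self.lift_offsets)

    def make_setup(self, box_i: int, base: np.ndarray, vp: int, lift: float) -> RobotSetup:
        return RobotSetup(base, self.boxes[box_i].name, int(vp), self._lift_angles(lift))

    def objective(self, state) -> float:
        box_i, base, vp, lift = state
        try:
            idx = blocked_set(
                self.spec.beam_set, self.make_setup(box_i, base, vp, lift),
                self._points, self.centroid,
            )
        except SetupInfeasibleError:
            return np.inf
        return float(self.spec.weights[idx].sum())

    def initial(self, rng: np.random.Generator):
        for _ in range(self.max_retries):
            box_i = int(rng.integers(len(self.boxes)))
            state = (
                box_i,
                self.boxes[box_i].sample(rng),
                int(rng.choice(self._feasible)),
                float(rng.uniform(-np.pi, np.pi)),
            )
            if np.isfinite(self.objective(state)):
                return state
        raise SetupInfeasibleError("could not construct a feasible initial state")

    def neighbor(self, state, theta: float, rng: np.random.Generator):
        """One of four equally likely moves: base jitter (sigma 30 mm, clipped),
        base box switch, viewport hop (within 25 mm, or uniform with prob 0.1),
        LIFT jitter (sigma 15 deg). Resamples until feasible, at most 50 tries,
        falling back to the input state."""
        for _ in range(self.max_retries):
            box_i, base, vp, lift = state
            move = int(rng.integers(4))
            if move == 0:
                base = self.boxes[box_i].clip(base + rng.normal(0.0, self.base_sigma, 3))
            elif move == 1:
                box_i = int(rng.integers(len(self.boxes)))
                base = self.boxes[box_i].sample(rng)
            elif move == 2:
                if rng.random() < 0.1:
                    vp = int(rng.choice(self._feasible))
                else:
                    d = np.linalg.norm(self._points[self._feasible] - self._points[vp], axis=1)
                    near = self._feasible[d <= self.viewport_hop]
                    vp = int(rng.choice(near)) if len(near) else int(rng.choice(self._feasible))
            else:
                lift = float(lift + rng.normal(0.0, self.lift_sigma))
            cand = (box_i, base, vp, lift)
            if np.isfinite(self.objective(cand)):
                return cand
        return state


def optimize_setup(
    spec: ObjectiveSpec,
    viewport_map: ViewportMap,
    centroid: np.ndarray,
    schedule: AnnealSchedule | None = None,
    k_lift: int = 1,
    boxes: list[BasePositionBox] | None = None,
):
    """Best-of-restarts SA; returns (RobotSetup, objective value, traces)."""
    schedule = schedule or AnnealSchedule()
    problem = RobotSetupProblem(spec, viewport_map, centroid, boxes=boxes, k_lift=k_lift)
    state, obj, traces = anneal_restarts(problem, schedule)
    return problem.make_setup(*state), obj, traces


@dataclass
class WorkflowResult:
    plan_coverage: TreatmentPlan
    plan_mu: TreatmentPlan
    setup: RobotSetup | None
    objective_value: float | None
    n_blocked: int
    candidates: CandidateBeamSet


def run_workflow(
    ct: CtVolume,
    structures: StructureSet,
    grid: VoxelGrid,
    variant: str,
    constraints: PlanConstraints | None = None,
    scorer=None,
    n_beams: int = 6000,
    objective_kind: str = "BRW",
    schedule: AnnealSchedule | None = None,
    k_lift: int = 1,
    seed: int = 0,
    viewports: ViewportMap | None = None,
    boxes: list[BasePositionBox] | None = None,
    candidates: CandidateBeamSet | None = None,
    d0: float | None = None,
) -> WorkflowResult:
    """Compose candidate generation (A), setup search (B/B*), planning (C).

    variant:
      "no-robot"   — plain two-stage planning, no blocking;
      "B"          — SA under ``objective_kind`` on the candidate set, blocked
                     beams removed, then planning;
      "Bstar"      — SA scored on the plan-weighted (or CNN-weighted) subset,
                     the found pose applied to the full original set;
      CNN variants — pass a ``scorer``; candidates come from rejection
                     sampling (workflow A) and BC/BCW weights are predictions.
    """
    if constraints is None:
        constraints = PlanConstraints()
    rng_seed = np.random.SeedSequence((seed, 0)).generate_state(1)[0] % (2**31)

    if candidates is None:
        if objective_kind in ("BC", "BCW") or (scorer is not None and variant != "no-robot"):
            from .beamnet.sampling import sample_cnn_beams

            candidates = sample_cnn_beams(scorer, ct, structures, grid, n_beams, rng_seed)
        else:
            candidates = sample_candidate_beams(grid, n_beams, rng_seed)

    D = compute_dose_matrix(ct, grid, candidates, structures=structures, d0=d0)
    p1 = optimize_coverage(D, constraints)
    p2 = optimize_mu(D, constraints, p1)
    if variant == "no-robot":
        return WorkflowResult(p1, p2, None, None, 0, candidates)

    if viewports is None:
        from .viewports import viewport_map as _vmap

        viewports = _vmap(ct, structures.centroid(PTV))
    centroid = grid.ptv_centroid

    if objective_kind == "BRW":
        weights = p1.weights
    elif objective_kind == "BCW":
        weights = candidates.weights
    else:
        weights = None

    if variant == "Bstar" and weights is not None:
        keep = np.nonzero(weights > 0)[0]
        spec = ObjectiveSpec(objective_kind, candidates.subset(keep), weights[keep])
    else:
        spec = ObjectiveSpec(objective_kind, candidates, weights)

    sched = schedule or AnnealSchedule(seed=seed)
    setup, obj, _ = optimize_setup(spec, viewports, centroid, sched, k_lift, boxes)

    points = np.array([v.skin_point for v in viewports.viewports])
    blocked = blocked_set(candidates, setup, points, centroid)
    survivors = np.setdiff1d(np.arange(len(candidates)), blocked)
    D_surv = compute_dose_matrix(ct, grid, candidates.subset(survivors), structures=structures, d0=D.d0)
    q1 = optimize_coverage(D_surv, constraints)
    q2 = optimize_mu(D_surv, constraints, q1)
    return WorkflowResult(q1, q2, setup, obj, int(len(blocked)), candidates)
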