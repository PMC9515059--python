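"""Two-stage linear-programming treatment planning.

Stage 1 maximizes PTV coverage through its linear surrogate — the total
underdosage sum_i max(0, D_rx - d_i) over PTV voxels — under hard maximum-dose
constraints on PTV, organs at risk and the two shell bands, per-beam and total
MU caps. Stage 2 then minimizes total MU while fixing per-voxel lower bounds
at the stage-1 dose, yielding a Pareto step that can only reduce MU without
reducing coverage. Coverage itself (a counting quantity) is never inside the
LP; it is evaluated afterwards on the same planning grid used for
optimization, so no resampling separates optimization from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .beams import DoseMatrix
from .phantom import BLADDER, PTV, RECTUM, SHELL3, SHELL9

DOSE_TOL = 1e-9  # Gy; threshold tolerance for coverage counting


class PlanInfeasibleError(RuntimeError):
    """Raised when the LP has no feasible point; names the suspected bound."""


@dataclass
class PlanConstraints:
    prescribed_dose: float = 36.25
    ptv_max: float = 40.25
    oar_max: float = 36.0
    shell3_max: float = 36.25
    shell9_max: float = 21.75
    beam_mu_max: float = 300.0
    total_mu_max: float = 40000.0

    def __post_init__(self) -> None:
        if self.prescribed_dose > self.ptv_max:
            raise ValueError("prescribed dose must not exceed the PTV maximum")
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TreatmentPlan:
    weights: np.ndarray          # MU per candidate beam
    dose: np.ndarray             # Gy per planning voxel (full stacked grid)
    coverage: float              # fraction of PTV voxels at/above prescription
    total_mu: float
    objective_underdose: float   # Gy-sum of PTV underdosage
    stage: str                   # "coverage" | "mu"
    constraints: PlanConstraints
    solver_status: str = "optimal"

    def to_json(self, path) -> None:
        payload = {
            "stage": self.stage,
            "coverage": self.coverage,
            "total_mu": self.total_mu,
            "objective_underdose": self.objective_underdose,
            "constraints": asdict(self.constraints),
            "weights_mu": self.weights.tolist(),
            "solver": {"backend": "scipy-highs", "status": self.solver_status},
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)


def coverage(dose_ptv: np.ndarray, prescribed: float) -> float:
    """Fraction of PTV voxels receiving at least the prescription (1e-9 Gy tol)."""
    dose_ptv = np.asarray(dose_ptv)
    if dose_ptv.size == 0:
        raise ValueError("empty PTV")
    return float(np.count_nonzero(dose_ptv >= prescribed - DOSE_TOL) / dose_ptv.size)


def _hard_rows(D: DoseMatrix, c: PlanConstraints):
    """Sparse rows and right-hand sides of all hard maximum-dose constraints."""
    blocks, rhs = [], []
    for label, bound in (
        (PTV, c.ptv_max),
        (BLADDER, c.oar_max),
        (RECTUM, c.oar_max),
        (SHELL3, c.shell3_max),
        (SHELL9, c.shell9_max),
    ):
        sl = D.region_slices.get(label)
        if sl is None or sl.stop == sl.start:
            continue
        blocks.append(D.coefficients[sl])
        rhs.append(np.full(sl.stop - sl.start, bound))
    if not blocks:
        return None, None
    return sparse.vstack(blocks, format="csr"), np.concatenate(rhs)


def _solve(c_vec, A_ub, b_ub, bounds, method="highs-ds"):
    res = linprog(c_vec, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method=method)
    return res


def optimize_coverage(D: DoseMatrix, c: PlanConstraints) -> TreatmentPlan:
    """Stage 1: minimize total PTV underdosage under hard max-dose and MU caps.

    Variables are beam weights w (0..300 MU each, sum <= 40000) and per-PTV-voxel
    underdose slacks u >= 0 with u_i >= D_rx - d_i. Solved with HiGHS dual
    simplex (deterministic options recorded on the plan).
    """
    ptv_sl = D.region_slices.get(PTV)
    if ptv_sl is None or ptv_sl.stop == ptv_sl.start:
        raise ValueError("dose matrix has no PTV rows")
    B = D.n_beams
    P = ptv_sl.stop - ptv_sl.start
    D_ptv = D.coefficients[ptv_sl]

    # rows: [-D_ptv | -I] x <= -D_rx  (underdose definition)
    under = sparse.hstack([-D_ptv, -sparse.identity(P, format="csr")], format="csr")
    b_under = np.full(P, -c.prescribed_dose)

    hard, b_hard = _hard_rows(D, c)
    A_rows = [under]
    b_rows = [b_under]
    if hard is not None:
        A_rows.append(sparse.hstack([hard, sparse.csr_matrix((hard.shape[0], P))], format="csr"))
        b_rows.append(b_hard)
    mu_row = sparse.hstack(
        [sparse.csr_matrix(np.ones((1, B))), sparse.csr_matrix((1, P))], format="csr"
    )
    A_rows.append(mu_row)
    b_rows.append(np.array([c.total_mu_max]))

    A_ub = sparse.vstack(A_rows, format="csr")
    b_ub = np.concatenate(b_rows)
    cost = np.concatenate([np.zeros(B), np.ones(P)])
    bounds = [(0.0, c.beam_mu_max)] * B + [(0.0, None)] * P

    res = _solve(cost, A_ub, b_ub, bounds)
    if res.status != 0:
        raise PlanInfeasibleError(
            f"stage-1 LP failed (status {res.status}): {res.message}; "
            "suspect the shell/OAR maximum-dose bounds"
        )
    w = np.clip(res.x[:B], 0.0, c.beam_mu_max)
    dose = D.coefficients @ w
    return TreatmentPlan(
        weights=w,
        dose=dose,
        coverage=coverage(dose[ptv_sl], c.prescribed_dose),
        total_mu=float(w.sum()),
        objective_underdose=float(res.fun),
        stage="coverage",
        constraints=c,
    )


def optimize_mu(D: DoseMatrix, c: PlanConstraints, p1: TreatmentPlan) -> TreatmentPlan:
    """Stage 2: minimize total MU with PTV doses bounded below by the stage-1 dose.

    Keeps every stage-1 hard constraint; by construction coverage cannot drop
    and total MU cannot rise. On numerical infeasibility of the exact lower
    bounds, retries once with a 1e-9 Gy relaxation before raising.
    """
    ptv_sl = D.region_slices[PTV]
    B = D.n_beams
    D_ptv = D.coefficients[ptv_sl]
    # clip at the PTV cap: stage-1 doses may overshoot it by solver tolerance,
    # and a lower bound above a hard upper bound is vacuously infeasible
    d1 = np.minimum(np.asarray(p1.dose[ptv_sl]), c.ptv_max)

    hard, b_hard = _hard_rows(D, c)
    mu_row = sparse.csr_matrix(np.ones((1, B)))
    cost = np.ones(B)
    bounds = [(0.0, c.beam_mu_max)] * B

    for relax in (0.0, DOSE_TOL, 1e-6):
        A_rows = [-D_ptv]
        b_rows = [-(d1 - relax)]
        if hard is not None:
            A_rows.append(hard)
            b_rows.append(b_hard)
        A_rows.append(mu_row)
        b_rows.append(np.array([c.total_mu_max]))
        res = _solve(cost, sparse.vstack(A_rows, format="csr"), np.concatenate(b_rows), bounds)
        if res.status == 0:
            break
    else:
        raise PlanInfeasibleError("stage-2 LP infeasible even after relaxing dose lower bounds")

    w = np.clip(res.x, 0.0, c.beam_mu_max)
    dose = D.coefficients @ w
    cov2 = coverage(dose[ptv_sl], c.prescribed_dose)
    return TreatmentPlan(
        weights=w,
        dose=dose,
        coverage=cov2,
        total_mu=float(w.sum()),
        objective_underdose=float(np.maximum(c.prescribed_dose - dose[ptv_sl], 0.0).sum()),
        stage="mu",
        constraints=c,
    )


@dataclass
class ShellCalibration:
    shell3_max: float
    shell9_max: float
    scale: float
    coverage: float
    trace: list = field(default_factory=list)  # (scale, coverage) pairs tested
    warning: str | None = None


def calibrate_shell_dose(
    D: DoseMatrix,
    constraints: PlanConstraints | None = None,
    target_coverage: float = 0.95,
    tolerance_pp: float = 0.25,
    max_iterations: int = 12,
    inner_outer_ratio: float = 0.6,
) -> ShellCalibration:
    """Tune the shell maximum doses so stage-1 PTV coverage reaches ~95%.

    A single scale factor s sets (shell3, shell9) = s * (D_rx, 0.6 * D_rx) and is
    bisected (at most ``max_iterations`` LP re-solves including bracketing)
    for the smallest tested s whose coverage >= the target, stopping early
    once coverage lands within ``tolerance_pp`` above it. If even unconstrained
    shells cannot reach the target, the unconstrained bounds are returned with
    a warning instead of an error.
    """
    c = constraints or PlanConstraints()
    base3 = c.prescribed_dose
    base9 = inner_outer_ratio * c.prescribed_dose
    trace: list[tuple[float, float]] = []

    def cov_at(s: float) -> float:
        ci = PlanConstraints(
            prescribed_dose=c.prescribed_dose,
            ptv_max=c.ptv_max,
            oar_max=c.oar_max,
            shell3_max=s * base3,
            shell9_max=s * base9,
            beam_mu_max=c.beam_mu_max,
            total_mu_max=c.total_mu_max,
        )
        cov = optimize_coverage(D, ci).coverage
        trace.append((s, cov))
        return cov

    no_shells = all(
        D.region_slices.get(lbl) is None or D.region_slices[lbl].stop == D.region_slices[lbl].start
        for lbl in (SHELL3, SHELL9)
    )
    if no_shells:
        cov = cov_at(1.0)
        return ShellCalibration(base3, base9, 1.0, cov, trace, "no shell voxels; base bounds kept")

    budget = max_iterations
    s_hi, cov_hi = 1.0, cov_at(1.0)
    budget -= 1
    s_lo = None
    if cov_hi >= target_coverage:
        s = 0.5
        while budget > 0:
            cov = cov_at(s)
            budget -= 1
            if cov >= target_coverage:
                s_hi, cov_hi = s, cov
                s /= 2.0
            else:
                s_lo = s
                break
        if s_lo is None:  # target met even at the tightest scale tried
            return ShellCalibration(s_hi * base3, s_hi * base9, s_hi, cov_hi, trace)
    else:
        s = 2.0
        found = False
        while budget > 0:
            cov = cov_at(s)
            budget -= 1
            if cov >= target_coverage:
                s_lo, s_hi, cov_hi = s / 2.0, s, cov
                found = True
                break
            s *= 2.0
            if s > 64.0:
                break
        if not found:
            ceff = PlanConstraints(
                prescribed_dose=c.prescribed_dose, ptv_max=c.ptv_max, oar_max=c.oar_max,
                shell3_max=1e6, shell9_max=1e6,
                beam_mu_max=c.beam_mu_max, total_mu_max=c.total_mu_max,
            )
            cov = optimize_coverage(D, ceff).coverage
            return ShellCalibration(
                1e6, 1e6, np.inf, cov, trace,
                "target coverage unreachable even with unconstrained shells",
            )

    while budget > 0 and cov_hi > target_coverage + tolerance_pp / 100.0:
        mid = 0.5 * (s_lo + s_hi)
        cov = cov_at(mid)
        budget -= 1
        if cov >= target_coverage:
            s_hi, cov_hi = mid, cov
        else:
            s_lo = mid
    return ShellCalibration(s_hi * base3, s_hi * base9, s_hi, cov_hi, trace)
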