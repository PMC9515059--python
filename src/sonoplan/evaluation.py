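"""Cohort-style evaluation harness and statistics utilities.

Runs each workflow variant on each phantom several times with distinct
derived seeds (candidate-beam sampling is the dominant source of randomness)
and collects coverage, MU, blocking counts and objective values into a tidy
report. Seeds derive from the master seed through a counter-based
SeedSequence spawn key (phantom, variant, repeat), so any single row can be
re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import PTV
from .setupopt import run_workflow


def child_seed(master: int, *key: int) -> int:
    """Deterministic per-row seed below 2**31."""
    return int(np.random.SeedSequence((master, *key)).generate_state(1)[0] % (2**31))


@dataclass
class VariantSpec:
    """One evaluation arm: a name plus run_workflow keyword arguments."""

    name: str
    variant: str = "no-robot"           # no-robot | B | Bstar
    kwargs: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    table: pd.DataFrame
    config_hash: str

    def aggregates(self) -> pd.DataFrame:
        return (
            self.table.groupby("variant")[["coverage", "total_mu", "n_blocked"]]
            .agg(["mean", "std"])
        )

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            f.write(f"# config_hash={self.config_hash}\n")
            self.table.to_csv(f, index=False, float_format="%.10g")


def evaluate_cohort(
    phantoms: list,
    variants: list[VariantSpec],
    repeats: int = 10,
    seed: int = 0,
    **common_kwargs,
) -> EvaluationReport:
    """Run every (phantom, variant, repeat) cell; failures are recorded per row.

    ``phantoms`` is a list of (ct, structures, grid) triples; extra keyword
    arguments are passed to every ``run_workflow`` call.
    """
    if not phantoms or not variants:
        raise ValueError("need at least one phantom and one variant")
    rows = []
    for pi, (ct, structures, grid) in enumerate(phantoms):
        for vi, vs in enumerate(variants):
            for r in range(repeats):
                s = child_seed(seed, pi, vi, r)
                row = {
                    "phantom": pi,
                    "variant": vs.name,
                    "repeat": r,
                    "seed": s,
                    "ptv_volume_cm3": structures.volume_cm3(PTV),
                }
                try:
                    res = run_workflow(
                        ct, structures, grid, vs.variant, seed=s,
                        **{**common_kwargs, **vs.kwargs},
                    )
                    row.update(
                        coverage=res.plan_mu.coverage,
                        total_mu=res.plan_mu.total_mu,
                        total_mu_stage1=res.plan_coverage.total_mu,
                        objective_underdose=res.plan_coverage.objective_underdose,
                        setup_objective=res.objective_value,
                        n_blocked=res.n_blocked,
                        error="",
                    )
                except Exception as exc:  # noqa: BLE001 — recorded, run continues
                    row.update(
                        coverage=np.nan, total_mu=np.nan, total_mu_stage1=np.nan,
                        objective_underdose=np.nan, setup_objective=np.nan,
                        n_blocked=-1, error=f"{type(exc).__name__}: {exc}",
                    )
                rows.append(row)
    cfg = json.dumps(
        {"repeats": repeats, "seed": seed, "variants": [(v.name, v.variant, sorted(v.kwargs)) for v in variants],
         "common": sorted(common_kwargs)},
        sort_keys=True,
    )
    return EvaluationReport(pd.DataFrame(rows), hashlib.sha256(cfg.encode()).hexdigest()[:16])


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value (off-the-shelf utility).

    Degenerate all-tied samples return p = 1.0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.unique(np.concatenate([x, y])).size == 1:
        import warnings

        warnings.warn("rank-sum test on all-tied samples; returning p = 1", stacklevel=2)
        return 1.0
    return float(stats.ranksums(x, y).pvalue)


def mu_improvement_vs_ptv_size(report: pd.DataFrame | EvaluationReport,
                               better: str = "cnn", baseline: str = "random"):
    """Spearman correlation between PTV volume and mean MU improvement.

    ``report`` rows must carry variants named ``better`` and ``baseline``;
    improvement per phantom = mean MU(baseline) - mean MU(better). Returns
    (r_s, p) or (None, reason) when undefined (e.g. all improvements zero).
    """
    df = report.table if isinstance(report, EvaluationReport) else report
    per = df.groupby(["phantom", "variant"]).agg(
        mu=("total_mu", "mean"), vol=("ptv_volume_cm3", "first")
    ).reset_index()
    wide = per.pivot(index="phantom", columns="variant", values="mu")
    vols = per.groupby("phantom")["vol"].first()
    if better not in wide or baseline not in wide:
        raise ValueError(f"report lacks variants {better!r}/{baseline!r}")
    improvement = wide[baseline] - wide[better]
    ok = improvement.notna() & vols.notna()
    if ok.sum() < 3:
        return None, "fewer than 3 phantoms with complete plans"
    if np.allclose(improvement[ok], improvement[ok].iloc[0]):
        return None, "improvements constant; correlation undefined"
    r, p = stats.spearmanr(vols[ok], improvement[ok])
    return float(r), float(p)
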