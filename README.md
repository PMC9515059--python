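# sonoplan

Treatment-plan and robot-setup optimization for ultrasound-guided robotic
radiotherapy of the prostate.

Continuous intra-fraction tracking with a robot-held 3-D ultrasound probe is
an attractive alternative to X-ray based tracking, but the probe and its
arm are radio-opaque: wherever they stand, treatment beams are blocked. The
planning problem therefore couples three searches — which candidate beams to
offer the optimizer, where to put the ultrasound robot, and how to weight the
surviving beams. `sonoplan` implements that whole stack on synthetic pelvic
CT phantoms:

- **Phantoms** — parametric pelvic anatomy (ellipsoidal prostate PTV, bladder,
  rectum, pelvic bone, bowel gas) rasterized to CT-like gray values on the
  offset-1000 scale, with 3 mm / 9 mm shell bands around the target and a
  3 × 3 × 3 mm planning grid.
- **Dose model** — an exponential pencil-cone kernel per IRIS collimator
  (10–40 mm) with inverse-square falloff, central-axis water-equivalent depth
  and a collimator penumbra; linear in beam activation time (MU).
- **Two-stage linear programming** — stage 1 maximizes PTV coverage through
  its linear surrogate, min Σᵢ max(0, D_rx − dᵢ) over PTV voxels, under hard
  maximum-dose constraints (PTV 40.25 Gy, organs at risk 36 Gy, calibrated
  shell bounds), per-beam (300 MU) and total (40 000 MU) caps; stage 2
  minimizes total MU with the stage-1 dose as per-voxel lower bound, so
  coverage can only be preserved and MU can only fall. Shell bounds are
  auto-calibrated per case so the no-robot coverage sits at 95 %.
- **Viewports** — skin points from which the probe can image the target:
  the ray to the PTV centroid must cross no bone (max gray > 1300), no gas
  (min gray < 400) and at most 120 mm of tissue.
- **Robot & blocking** — a capsule-chain arm with an analytic elbow
  self-motion circle (the LIFT angle); a candidate beam is blocked when a
  capsule comes within its radius + cone radius + 20 mm motion margin of the
  beam axis, and with several LIFT angles only beams blocked in *every*
  configuration count.
- **CNN beam scorer** — a compact convolutional regressor over 7-channel
  projection features (beam aperture + min/max radiological-depth images of
  PTV, rectum, bladder), trained with a coverage-weighted piecewise squared
  loss on solved plans, then used for rejection sampling of candidate beams
  with acceptance probability p = w_p / 300.
- **Setup annealing** — simulated annealing over base position, viewport and
  LIFT angle(s) under the four blocking objectives BR / BRW / BC / BCW
  (counts or blocked weight, on random or CNN-generated beams), Θ₀ = 10
  halved every 100 of 1000 iterations, best of 5 restarts.

## Worked example

```python
import sonoplan
from sonoplan.beams import sample_candidate_beams, compute_dose_matrix
from sonoplan.planning import PlanConstraints, calibrate_shell_dose, \
    optimize_coverage, optimize_mu

ct, structures, grid = sonoplan.default_phantom(seed=3, scale="desk")
beams = sample_candidate_beams(grid, 500, seed=11)
D = compute_dose_matrix(ct, grid, beams, structures=structures)

cal = calibrate_shell_dose(D)                    # tune shells to 95% coverage
c = PlanConstraints(shell3_max=cal.shell3_max, shell9_max=cal.shell9_max)
p1 = optimize_coverage(D, c)
p2 = optimize_mu(D, c, p1)
print(f"shell scale {cal.scale:.2f}, coverage {p1.coverage:.4f}, "
      f"MU {p1.total_mu:.0f} -> {p2.total_mu:.0f}, "
      f"weighted beams {(p1.weights > 1e-6).sum()}")
```

Output on this seed:

```
shell scale 1.41, coverage 0.9512, MU 1828 -> 1828, weighted beams 198
```

Read: with shell maxima at 1.41 × their base values, the stage-1 plan covers
95.12 % of PTV voxels at the 36.25 Gy prescription using 198 of the 500
candidates; the MU stage finds no further reduction here because the
coverage optimum already pins the dose from below.

The command-line interface mirrors the library:

```bash
sonoplan phantom --out case/ --seed 3
sonoplan sample-beams --phantom-dir case/ --out beams.csv --n 500
sonoplan dose-matrix --phantom-dir case/ --beams-csv beams.csv --out dose.h5
sonoplan plan --dose-h5 dose.h5 --out plan.json --calibrate-shells
sonoplan viewports --phantom-dir case/ --out viewports.csv
sonoplan optimize-setup --phantom-dir case/ --beams-csv beams.csv \
    --out setup.json --objective brw --lift 3
```

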