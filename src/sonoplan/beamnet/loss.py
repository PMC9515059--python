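"""Coverage-weighted piecewise regression loss for beam weights.

Squared error scaled by plan coverage relative to the desired coverage:

    l = (w_p - w_g)^2 * c_des / c_p   if w_g = 0
    l = (w_p - w_g)^2 * c_p / c_des   if w_g > 0

A weighted beam from a high-coverage plan is a more trustworthy positive
label (its loss factor grows with c_p); an unweighted beam from a
low-coverage plan is a more trustworthy negative label (its factor grows as
c_p falls). The formula is genuinely discontinuous across the w_g = 0
boundary; no continuity is claimed or enforced.
"""

from __future__ import annotations

import numpy as np

DESIRED_COVERAGE = 0.95


def _factor(w_g: np.ndarray, c_p: np.ndarray, c_des: float) -> np.ndarray:
    c_p = np.asarray(c_p, dtype=float)
    if np.any(c_p <= 0):
        raise ValueError("plan coverage c_p must be positive")
    return np.where(np.asarray(w_g) == 0, c_des / c_p, c_p / c_des)


def loss(w_p, w_g, c_p, c_des: float = DESIRED_COVERAGE):
    """Piecewise coverage-weighted squared error (elementwise)."""
    w_p = np.asarray(w_p, dtype=float)
    w_g = np.asarray(w_g, dtype=float)
    out = (w_p - w_g) ** 2 * _factor(w_g, c_p, c_des)
    return float(out) if out.ndim == 0 else out


def loss_gradient(w_p, w_g, c_p, c_des: float = DESIRED_COVERAGE):
    """d(loss)/d(w_p), used by the trainer's backward pass."""
    w_p = np.asarray(w_p, dtype=float)
    w_g = np.asarray(w_g, dtype=float)
    return 2.0 * (w_p - w_g) * _factor(w_g, c_p, c_des)
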