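"""CNN-guided candidate beam generation by rejection sampling.

Random beams are drawn from the same node-shell sampler used for the random
heuristic; each is accepted with probability p = w_p / 300, where w_p is the
scorer's (clamped) predicted weight. Drawing continues until the requested
number of beams has been accepted, so the resulting set is enriched in beams
the scorer deems useful while remaining stochastic.
"""

from __future__ import annotations

import numpy as np

from ..beams import CandidateBeamSet, sample_candidate_beams
from ..phantom import CtVolume, StructureSet, VoxelGrid
from .features import compute_features_batch, label_volume
from .nnet import BeamScorer

STALL_DRAWS = 100_000
STALL_RATE = 1e-4


class SamplingStallError(RuntimeError):
    """Acceptance rate collapsed; the scorer rejects essentially every beam."""


def sample_cnn_beams(
    scorer: BeamScorer,
    ct: CtVolume,
    structures: StructureSet,
    grid: VoxelGrid,
    n: int,
    seed: int | np.random.Generator = 0,
    chunk: int = 256,
    stall_draws: int = STALL_DRAWS,
    stall_rate: float = STALL_RATE,
) -> CandidateBeamSet:
    """Sample n CNN-accepted candidate beams (provenance "cnn").

    Predicted weights of the accepted beams are recorded on the returned set.
    Raises :class:`SamplingStallError` once the empirical acceptance rate over
    ``stall_draws`` draws falls below ``stall_rate``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fcfg = dict(scorer.feature_config)
    labels = label_volume(structures)

    kept_src, kept_tgt, kept_diam, kept_w = [], [], [], []
    accepted = 0
    drawn = 0
    while accepted < n:
        batch = sample_candidate_beams(grid, chunk, rng)
        feats = compute_features_batch(ct, structures, batch, labels=labels, **fcfg)
        w_p = scorer.predict(feats)
        u = rng.random(chunk)
        take = u < w_p / BeamScorer.W_MAX
        drawn += chunk
        if take.any():
            kept_src.append(batch.sources[take])
            kept_tgt.append(batch.targets[take])
            kept_diam.append(batch.diameters[take])
            kept_w.append(w_p[take])
            accepted += int(take.sum())
        if drawn >= stall_draws and accepted / drawn < stall_rate:
            raise SamplingStallError(
                f"acceptance rate {accepted / drawn:.2e} below {stall_rate:.0e} "
                f"after {drawn} draws"
            )
    src = np.concatenate(kept_src)[:n]
    tgt = np.concatenate(kept_tgt)[:n]
    diam = np.concatenate(kept_diam)[:n]
    w = np.concatenate(kept_w)[:n]
    out = CandidateBeamSet(src, tgt, diam, weights=w, provenance="cnn")
    out.acceptance_rate = accepted / drawn
    return out
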