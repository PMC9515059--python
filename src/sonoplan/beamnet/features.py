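"""Seven-channel projection features for candidate beams.

Each beam is summarized on the plane through the PTV centroid perpendicular
to the source→centroid line: one binary aperture image (the collimator cone's
section at the plane) and min/max radiological-depth projections of PTV,
rectum and bladder. Depths are water-equivalent millimetres measured from the
beam source, so the images carry both source-distance and tissue information;
pixels whose ray misses a structure hold the sentinel 0. Rays are marched
with nearest-neighbor volume sampling at a configurable step.

Channel order: [aperture, PTV min, PTV max, rectum min, rectum max,
bladder min, bladder max]. The in-plane up direction is the patient-superior
axis projected onto the plane. Default raster: 150x150 px at 1 mm; the
training pipeline uses a coarser raster (same field of view) for speed.
"""

from __future__ import annotations

import numpy as np

from ..beams import SOURCE_RADIUS_MM, CandidateBeamSet
from ..phantom import BLADDER, PTV, RECTUM, CtVolume, StructureSet

STRUCTURE_CODES = {PTV: 1, RECTUM: 2, BLADDER: 3}
N_CHANNELS = 7

try:  # optional JIT fast path; the NumPy march below is the reference
    import numba

    @numba.njit(cache=True)
    def _march_rays_jit(labels, density, src_i, dirs_i, tmin, h, n, out_min, out_max):
        nrays = dirs_i.shape[0]
        nx, ny, nz = labels.shape
        for r in range(nrays):
            cum = 0.0
            hr = h[r]
            for k in range(n):
                t = tmin[r] + (k + 0.5) * hr
                ix = int(np.floor(src_i[0] + t * dirs_i[r, 0] + 0.5))
                iy = int(np.floor(src_i[1] + t * dirs_i[r, 1] + 0.5))
                iz = int(np.floor(src_i[2] + t * dirs_i[r, 2] + 0.5))
                if ix < 0: ix = 0
                elif ix >= nx: ix = nx - 1
                if iy < 0: iy = 0
                elif iy >= ny: iy = ny - 1
                if iz < 0: iz = 0
                elif iz >= nz: iz = nz - 1
                rho = density[ix, iy, iz]
                depth = cum + 0.5 * rho * hr
                cum += rho * hr
                lab = labels[ix, iy, iz]
                if lab > 0:
                    s = lab - 1
                    if depth < out_min[s, r]:
                        out_min[s, r] = depth
                    if depth > out_max[s, r]:
                        out_max[s, r] = depth

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def label_volume(structures: StructureSet) -> np.ndarray:
    """uint8 volume with PTV=1, rectum=2, bladder=3 (background 0)."""
    lab = np.zeros(structures.mask(PTV).shape, dtype=np.uint8)
    for name, code in STRUCTURE_CODES.items():
        if name in structures.masks:
            lab[structures.mask(name)] = code
    return lab


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    up = np.array([0.0, 0.0, 1.0])
    e_up = up - (up @ normal) * normal
    if np.linalg.norm(e_up) < 1e-9:
        e_up = np.array([0.0, 1.0, 0.0]) - normal[1] * normal
    e_up /= np.linalg.norm(e_up)
    e_right = np.cross(normal, e_up)
    return e_up, e_right


def _volume_t_range(ct: CtVolume, source: np.ndarray, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Entry/exit ray parameters (mm from source) against the volume's AABB."""
    lo = ct.origin - 0.5 * ct.spacing
    hi = ct.origin + (np.asarray(ct.shape) - 0.5) * ct.spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - source) / dirs
        t2 = (hi - source) / dirs
    tmin = np.nanmax(np.where(np.isfinite(t1) & np.isfinite(t2), np.minimum(t1, t2), -np.inf), axis=1)
    tmax = np.nanmin(np.where(np.isfinite(t1) & np.isfinite(t2), np.maximum(t1, t2), np.inf), axis=1)
    tmin = np.maximum(tmin, 0.0)
    return tmin, tmax


def compute_features(
    ct: CtVolume,
    structures: StructureSet,
    beam,
    centroid: np.ndarray | None = None,
    shape: tuple[int, int] = (150, 150),
    pixel_mm: float = 1.0,
    step: float = 2.0,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Feature tensor (7, H, W) for one beam. See the module docstring."""
    if centroid is None:
        centroid = structures.centroid(PTV)
    return compute_features_batch(
        ct, structures,
        CandidateBeamSet(beam.source[None], beam.target[None], np.array([beam.diameter])),
        centroid, shape, pixel_mm, step, labels,
    )[0]


def compute_features_batch(
    ct: CtVolume,
    structures: StructureSet,
    beams: CandidateBeamSet,
    centroid: np.ndarray | None = None,
    shape: tuple[int, int] = (150, 150),
    pixel_mm: float = 1.0,
    step: float = 2.0,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Feature tensors (B, 7, H, W) for a whole candidate set.

    The label volume and density grid are shared across beams; within a beam
    all H*W rays are marched together.
    """
    if centroid is None:
        centroid = structures.centroid(PTV)
    centroid = np.asarray(centroid, float)
    if labels is None:
        labels = label_volume(structures)
    H, W = shape
    ys = (np.arange(H) - (H - 1) / 2.0) * pixel_mm
    xs = (np.arange(W) - (W - 1) / 2.0) * pixel_mm
    YY, XX = np.meshgrid(ys, xs, indexing="ij")

    density = (np.maximum(ct.values.astype(np.float64), 0.0) / 1000.0)
    out = np.zeros((len(beams), N_CHANNELS, H, W), dtype=np.float32)
    vol_shape = np.asarray(labels.shape)
    use_jit = _HAVE_NUMBA

    for bi in range(len(beams)):
        source = beams.sources[bi]
        target = beams.targets[bi]
        normal = centroid - source
        dist_plane = np.linalg.norm(normal)
        if dist_plane < 1e-6:
            raise ValueError("beam source coincides with the PTV centroid (degenerate plane)")
        normal = normal / dist_plane
        e_up, e_right = _plane_basis(normal)
        q = centroid + YY[..., None] * e_up + XX[..., None] * e_right  # (H, W, 3)
        q = q.reshape(-1, 3)

        # aperture: pixel inside the collimator cone at the plane
        axis = target - source
        axis = axis / np.linalg.norm(axis)
        rel = q - source
        proj = rel @ axis
        lat2 = np.maximum((rel * rel).sum(1) - proj**2, 0.0)
        cone_r = (beams.diameters[bi] / 2.0) * np.linalg.norm(rel, axis=1) / SOURCE_RADIUS_MM
        out[bi, 0] = ((proj > 0) & (lat2 <= cone_r**2)).reshape(H, W)

        # march all rays through the volume's AABB, in index space with nearest
        # sampling; the phantom's air margin makes border voxels label-0/air
        dirs = rel / np.linalg.norm(rel, axis=1, keepdims=True)
        tmin, tmax = _volume_t_range(ct, source, dirs)
        span = np.maximum(tmax - tmin, 0.0)
        n = max(int(np.ceil(span.max() / step)), 1)
        h = span / n  # per-ray step
        src_i = (source - ct.origin) / ct.spacing
        dirs_i = dirs / ct.spacing

        if use_jit:
            dmin = np.full((3, len(dirs)), np.inf)
            dmax = np.full((3, len(dirs)), -np.inf)
            _march_rays_jit(labels, density, src_i, dirs_i, tmin, h, n, dmin, dmax)
        else:
            t = tmin[:, None] + (np.arange(n)[None, :] + 0.5) * h[:, None]
            idx_f = np.empty((3, t.size))
            for ax in range(3):
                idx_f[ax] = (src_i[ax] + t * dirs_i[:, ax, None]).ravel()
            idx_n = np.clip(np.floor(idx_f + 0.5).astype(np.intp), 0, (vol_shape - 1)[:, None])
            lab = labels[idx_n[0], idx_n[1], idx_n[2]].reshape(-1, n)
            rho = density[idx_n[0], idx_n[1], idx_n[2]].reshape(-1, n)
            # radiological depth from the source at each sample (midpoint cumsum)
            depth = (np.cumsum(rho, axis=1) - 0.5 * rho) * h[:, None]
            dmin = np.empty((3, len(dirs)))
            dmax = np.empty((3, len(dirs)))
            for code in (1, 2, 3):
                hit = lab == code
                dmin[code - 1] = np.where(hit, depth, np.inf).min(axis=1)
                dmax[code - 1] = np.where(hit, depth, -np.inf).max(axis=1)

        for code in (1, 2, 3):
            ch = 2 * code - 1  # 1, 3, 5
            any_hit = np.isfinite(dmin[code - 1])
            out[bi, ch] = np.where(any_hit, dmin[code - 1], 0.0).reshape(H, W)
            out[bi, ch + 1] = np.where(any_hit, dmax[code - 1], 0.0).reshape(H, W)
    return out
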