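"""Candidate beams, radiological depth ray tracing, and the dose-per-MU matrix.

The dose model is a deliberately minimal, physically shaped linear kernel:
an exponential pencil-cone with inverse-square falloff and a hard lateral
cutoff at the collimator cone. It preserves the linear-programming structure
(dose is linear in beam activation time) while staying pluggable, so a more
sophisticated kernel can be substituted without touching the planners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .phantom import BLADDER, BODY, PTV, RECTUM, SHELL3, SHELL9, CtVolume, StructureSet, VoxelGrid

COLLIMATOR_DIAMETERS_MM = (10.0, 15.0, 20.0, 30.0, 40.0)
SOURCE_RADIUS_MM = 800.0          # source-axis distance of the node shell
MU_ATTENUATION_PER_MM = 0.005     # effective linear attenuation of the kernel
PRESCRIBED_DOSE_GY = 36.25
BEAM_MU_MAX = 300.0

REGION_ORDER = (PTV, BLADDER, RECTUM, SHELL3, SHELL9)


@dataclass
class Beam:
    source: np.ndarray
    target: np.ndarray
    diameter: float
    id: int = 0

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if np.allclose(self.source, self.target):
            raise ValueError("beam source and target coincide")
        if float(self.diameter) not in COLLIMATOR_DIAMETERS_MM:
            raise ValueError(f"collimator diameter {self.diameter} not in {COLLIMATOR_DIAMETERS_MM}")

    @property
    def direction(self) -> np.ndarray:
        d = self.target - self.source
        return d / np.linalg.norm(d)


@dataclass
class CandidateBeamSet:
    """Structure-of-arrays container for candidate beams.

    weights, when present, are MU in [0, 300]; provenance records whether the
    set came from random sampling, CNN rejection sampling, or a solved plan.
    """

    sources: np.ndarray
    targets: np.ndarray
    diameters: np.ndarray
    ids: np.ndarray = None
    weights: np.ndarray | None = None
    provenance: str = "random"

    def __post_init__(self) -> None:
        self.sources = np.atleast_2d(np.asarray(self.sources, dtype=float))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.ids is None:
            self.ids = np.arange(len(self.diameters))
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size and (self.weights.min() < -1e-9 or self.weights.max() > BEAM_MU_MAX + 1e-9):
                raise ValueError("beam weights must lie in [0, 300] MU")

    def __len__(self) -> int:
        return int(len(self.diameters))

    def __getitem__(self, i: int) -> Beam:
        return Beam(self.sources[i], self.targets[i], float(self.diameters[i]), int(self.ids[i]))

    def subset(self, index) -> "CandidateBeamSet":
        index = np.asarray(index)
        return CandidateBeamSet(
            self.sources[index],
            self.targets[index],
            self.diameters[index],
            self.ids[index],
            None if self.weights is None else self.weights[index],
            self.provenance,
        )

    def with_weights(self, weights: np.ndarray, provenance: str | None = None) -> "CandidateBeamSet":
        return CandidateBeamSet(
            self.sources, self.targets, self.diameters, self.ids,
            np.asarray(weights, float), provenance or self.provenance,
        )

    @property
    def directions(self) -> np.ndarray:
        d = self.targets - self.sources
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "sx": self.sources[:, 0], "sy": self.sources[:, 1], "sz": self.sources[:, 2],
                "tx": self.targets[:, 0], "ty": self.targets[:, 1], "tz": self.targets[:, 2],
                "diameter_mm": self.diameters,
            }
        )
        if self.weights is not None:
            df["weight_mu"] = self.weights
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, provenance: str = "random") -> "CandidateBeamSet":
        df = pd.read_csv(path)
        return CandidateBeamSet(
            df[["sx", "sy", "sz"]].to_numpy(),
            df[["tx", "ty", "tz"]].to_numpy(),
            df["diameter_mm"].to_numpy(),
            df["id"].to_numpy(),
            df["weight_mu"].to_numpy() if "weight_mu" in df else None,
            provenance,
        )


def _cap_directions(rng: np.random.Generator, n: int, axis: np.ndarray, half_angle_deg: float) -> np.ndarray:
    """Uniform unit vectors on the spherical cap of given half-angle about axis."""
    cos_min = np.cos(np.deg2rad(half_angle_deg))
    cos_t = rng.uniform(cos_min, 1.0, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    local = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return local @ np.stack([e1, e2, axis])


# Node-shell geometry: sources sit on a 800 mm spherical cap about the target
# centroid, oriented anterior-superior so the inferior/table hemisphere is
# excluded (vendor node sets are proprietary; this is the documented stand-in).
CAP_AXIS = np.array([0.0, -1.0, 0.6]) / np.linalg.norm([0.0, -1.0, 0.6])
CAP_HALF_ANGLE_DEG = 80.0


def sample_candidate_beams(
    grid: VoxelGrid,
    n: int = 6000,
    seed: int | np.random.Generator = 0,
    radius: float = SOURCE_RADIUS_MM,
    cap_axis: np.ndarray = CAP_AXIS,
    cap_half_angle_deg: float = CAP_HALF_ANGLE_DEG,
) -> CandidateBeamSet:
    """Sample n candidate beams: cap-uniform sources, PTV-uniform targets,
    collimator diameter uniform over {10, 15, 20, 30, 40} mm."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ptv = grid.points(PTV)
    if len(ptv) == 0:
        raise ValueError("empty PTV")
    centroid = ptv.mean(axis=0)
    dirs = _cap_directions(rng, n, np.asarray(cap_axis, float), cap_half_angle_deg)
    sources = centroid + radius * dirs
    targets = ptv[rng.integers(0, len(ptv), size=n)]
    diameters = rng.choice(COLLIMATOR_DIAMETERS_MM, size=n)
    return CandidateBeamSet(sources.reshape(n, 3), targets.reshape(n, 3), diameters)


def _density_at(ct: CtVolume, points: np.ndarray) -> np.ndarray:
    """Relative density rho = max(gray/1000, 0), trilinear, air outside."""
    return np.maximum(ct.sample(points), 0.0) / 1000.0


def radiological_depth(ct: CtVolume, a: np.ndarray, b: np.ndarray, step: float = 1.0) -> float:
    """Water-equivalent path length along [a, b] (midpoint rule, 1 mm steps)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    length = float(np.linalg.norm(b - a))
    if length == 0.0:
        raise ValueError("a and b coincide")
    n = max(int(np.ceil(length / step)), 1)
    h = length / n
    t = (np.arange(n) + 0.5) * h / length
    pts = a + t[:, None] * (b - a)
    return float(_density_at(ct, pts).sum() * h)


def radiological_depth_batch(
    ct: CtVolume, a: np.ndarray, b: np.ndarray, step: float = 1.0, max_samples: int = 4_000_000
) -> np.ndarray:
    """Vectorized water-equivalent path lengths for many segments at once.

    Each internal chunk shares a step count derived from its longest segment,
    so every segment is integrated with midpoint sampling at step <= ``step``.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    lengths = np.linalg.norm(b - a, axis=1)
    out = np.zeros(len(a))
    if not lengths.size:
        return out
    n_max = max(int(np.ceil(lengths.max() / step)), 1)
    chunk = max(max_samples // n_max, 1)
    for lo in range(0, len(a), chunk):
        sl = slice(lo, lo + chunk)
        seg_len = lengths[sl]
        n = max(int(np.ceil(seg_len.max() / step)), 1)
        t = (np.arange(n) + 0.5) / n
        pts = a[sl, None, :] + t[None, :, None] * (b[sl] - a[sl])[:, None, :]
        rho = _density_at(ct, pts.reshape(-1, 3)).reshape(len(seg_len), n)
        out[sl] = rho.sum(axis=1) * seg_len / n
    return out


def body_entry_points(
    ct: CtVolume, body_mask: np.ndarray, sources: np.ndarray, targets: np.ndarray, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """First body intersection of each source→target ray (1 mm march).

    Returns (entry_points, hit_flags); rays that miss the body entirely get
    hit=False and entry=target (their dose columns are zero anyway).
    """
    sources = np.atleast_2d(sources)
    targets = np.atleast_2d(targets)
    lengths = np.linalg.norm(targets - sources, axis=1)
    n = max(int(np.ceil(lengths.max() / step)), 2)
    t = np.arange(n + 1) / n
    pts = sources[:, None, :] + t[None, :, None] * (targets - sources)[:, None, :]
    idx = np.round((pts.reshape(-1, 3) - ct.origin) / ct.spacing).astype(int)
    shape = np.asarray(body_mask.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    inside = np.zeros(len(idx), dtype=bool)
    inside[ok] = body_mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    inside = inside.reshape(len(sources), n + 1)
    hit = inside.any(axis=1)
    first = np.argmax(inside, axis=1)
    entry = sources + (first / n)[:, None] * (targets - sources)
    entry[~hit] = targets[~hit]
    return entry, hit


@dataclass
class DoseMatrix:
    """Sparse voxel x beam matrix of dose per MU (Gy/MU), with region row blocks."""

    coefficients: sparse.csr_matrix
    region_slices: dict[str, slice]
    points: np.ndarray
    d0: float

    def rows(self, label: str) -> sparse.csr_matrix:
        return self.coefficients[self.region_slices[label]]

    @property
    def n_beams(self) -> int:
        return self.coefficients.shape[1]

    def save_hdf5(self, path) -> None:
        import h5py

        coo = self.coefficients.tocoo()
        with h5py.File(path, "w") as f:
            f.create_dataset("row", data=coo.row)
            f.create_dataset("col", data=coo.col)
            f.create_dataset("value", data=coo.data)
            f.attrs["shape"] = self.coefficients.shape
            f.attrs["d0"] = self.d0
            f.create_dataset("points", data=self.points)
            for label, sl in self.region_slices.items():
                f.attrs[f"slice_{label}"] = (sl.start, sl.stop)

    @staticmethod
    def load_hdf5(path) -> "DoseMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            mat = sparse.csr_matrix(
                (f["value"][:], (f["row"][:], f["col"][:])), shape=tuple(f.attrs["shape"])
            )
            slices = {
                k[len("slice_"):]: slice(int(v[0]), int(v[1]))
                for k, v in f.attrs.items()
                if k.startswith("slice_")
            }
            return DoseMatrix(mat, slices, f["points"][:], float(f.attrs["d0"]))


def calibrate_d0(
    ct: CtVolume,
    grid: VoxelGrid,
    body_mask: np.ndarray,
    mu_max: float = BEAM_MU_MAX,
    prescribed: float = PRESCRIBED_DOSE_GY,
) -> float:
    """Reference dose rate D0 (Gy/MU at the body entry point, 800 mm from source).

    Chosen so a single 40 mm beam along the nominal anterior-superior axis can
    deliver the prescription to the PTV centroid at exactly the per-beam MU cap:
    D0 * exp(-mu * depth(entry→centroid)) = prescribed / mu_max.
    """
    centroid = grid.ptv_centroid
    source = centroid + SOURCE_RADIUS_MM * CAP_AXIS
    entry, hit = body_entry_points(ct, body_mask, source[None], centroid[None])
    depth = radiological_depth(ct, entry[0], centroid) if hit[0] else 0.0
    return float(prescribed / mu_max / np.exp(-MU_ATTENUATION_PER_MM * depth))


def axis_cumulative_depth(
    ct: CtVolume, source: np.ndarray, direction: np.ndarray,
    t_start: float, t_stop: float, step: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative water-equivalent depth along a ray, sampled from t_start to
    t_stop (mm from the source). Returns (t_samples, depth_at_t)."""
    span = max(t_stop - t_start, step)
    n = max(int(np.ceil(span / step)), 1)
    h = span / n
    t_mid = t_start + (np.arange(n) + 0.5) * h
    pts = source + t_mid[:, None] * direction
    rho = _density_at(ct, pts)
    depth = (np.cumsum(rho) - 0.5 * rho) * h  # depth at each midpoint
    return t_mid, depth


PENUMBRA_CORE_FRACTION = 0.5   # flat profile out to this fraction of the cone radius
PENUMBRA_RIM_FACTOR = 0.15     # relative dose at the geometric cone edge


def lateral_profile(
    lateral_fraction: np.ndarray,
    core: float = PENUMBRA_CORE_FRACTION,
    rim: float = PENUMBRA_RIM_FACTOR,
) -> np.ndarray:
    """In-cone lateral dose profile: 1 in the core, feathering linearly to
    ``rim`` at the geometric edge (r = cone radius); zero outside the cone."""
    f = np.asarray(lateral_fraction, dtype=float)
    out = np.where(f <= core, 1.0, 1.0 - (1.0 - rim) * (f - core) / (1.0 - core))
    return np.where(f > 1.0, 0.0, out)


def compute_dose_matrix(
    ct: CtVolume,
    grid: VoxelGrid,
    beams: CandidateBeamSet,
    structures: StructureSet | None = None,
    body_mask: np.ndarray | None = None,
    d0: float | None = None,
    step: float = 1.0,
    core: float = PENUMBRA_CORE_FRACTION,
    rim: float = PENUMBRA_RIM_FACTOR,
) -> DoseMatrix:
    """Dose per MU for every (planning voxel, candidate beam) pair.

    Pencil-cone kernel: a voxel center p gets zero outside the collimator cone
    (lateral distance > (diam/2) * |p-s| / 800); inside,
    D0 * profile(lat/r) * exp(-mu * r_rad) * (800 / |p-s|)^2, where r_rad is
    the central-axis water-equivalent depth from the body entry point to p's
    axial projection (the standard pencil-beam approximation: one axis march
    per beam, linear interpolation at the voxel projections) and ``profile``
    is the collimator penumbra of :func:`lateral_profile`. Beams missing the
    body produce zero columns.
    """
    if len(beams) == 0:
        raise ValueError("empty beam set")
    if body_mask is None:
        if structures is not None and BODY in structures.masks:
            body_mask = structures.mask(BODY)
        else:
            body_mask = ndimage.binary_fill_holes(ct.values >= 500.0)
    if d0 is None:
        d0 = calibrate_d0(ct, grid, body_mask)

    points, slices = grid.stacked(REGION_ORDER)
    entries, hits = body_entry_points(ct, body_mask, beams.sources, beams.targets, step)

    rows_all, cols_all, vals_all = [], [], []
    dirs = beams.directions
    for j in range(len(beams)):
        if not hits[j]:
            continue
        s = beams.sources[j]
        rel = points - s
        proj = rel @ dirs[j]
        dist2 = (rel * rel).sum(axis=1)
        dist = np.sqrt(dist2)
        lateral = np.sqrt(np.maximum(dist2 - proj**2, 0.0))
        cone_r = (beams.diameters[j] / 2.0) * dist / SOURCE_RADIUS_MM
        in_cone = (proj > 0) & (lateral <= cone_r)
        vox = np.nonzero(in_cone)[0]
        if vox.size == 0:
            continue
        t_entry = float(np.linalg.norm(entries[j] - s))
        t_mid, cum = axis_cumulative_depth(ct, s, dirs[j], t_entry, float(proj[vox].max()), step)
        depth = np.interp(proj[vox], t_mid, cum, left=0.0)
        dose = (
            d0
            * lateral_profile(lateral[vox] / cone_r[vox], core, rim)
            * np.exp(-MU_ATTENUATION_PER_MM * depth)
            * (SOURCE_RADIUS_MM / dist[vox]) ** 2
        )
        rows_all.append(vox)
        cols_all.append(np.full(vox.size, j))
        vals_all.append(dose)

    if rows_all:
        mat = sparse.csr_matrix(
            (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(len(points), len(beams)),
        )
    else:
        mat = sparse.csr_matrix((len(points), len(beams)))
    return DoseMatrix(mat, slices, points, float(d0))
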