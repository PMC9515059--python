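"""Synthetic pelvic CT phantoms: gray-value volumes, structure masks, shells, voxel grids.

Gray values follow the offset-1000 scanner convention throughout the package:
air ≈ 0, water ≈ 1000, soft tissue ≈ 1050, bone > 1300, bowel gas < 400.

Coordinates are mm in a right-handed patient system (x left, y posterior,
z superior). Arrays are indexed (ix, iy, iz); ``origin`` is the world position
of the *center* of voxel (0, 0, 0); a voxel is the closed cell around its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# gray-value convention (offset-1000): thresholds used across the package
AIR_GRAY = 0.0
BODY_THRESHOLD = 500.0   # gray >= 500 counts as body on the skin boundary
GAS_THRESHOLD = 400.0    # gray < 400 blocks ultrasound (gas)
BONE_THRESHOLD = 1300.0  # gray > 1300 blocks ultrasound (dense)

PTV = "PTV"
BLADDER = "BLADDER"
RECTUM = "RECTUM"
BODY = "BODY"
SHELL3 = "SHELL3"
SHELL9 = "SHELL9"

OAR_LABELS = (BLADDER, RECTUM)


class InvalidSpecError(ValueError):
    """Raised when a phantom spec rasterizes to overlapping mandatory organs."""


@dataclass
class CtVolume:
    """A 3-D gray-value grid on the offset-1000 scale.

    values : float32 array, shape (nx, ny, nz)
    spacing : mm per axis, all > 0
    origin : world coordinate (mm) of the center of voxel (0, 0, 0)
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CT values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel index of world points (mm); center of voxel i maps to i."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.atleast_2d(idx) * self.spacing + self.origin

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
        grids = np.meshgrid(
            *(self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)),
            indexing="ij",
        )
        return np.stack(grids, axis=-1)

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolated gray values at world points; outside the grid is air (0)."""
        idx = self.world_to_index(points).T
        return ndimage.map_coordinates(
            self.values.astype(float), idx, order=order, mode="constant", cval=AIR_GRAY
        )


@dataclass
class StructureSet:
    """Boolean masks per region label on the same lattice as the CT volume."""

    masks: dict[str, np.ndarray]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    def mask(self, label: str) -> np.ndarray:
        return self.masks[label]

    def centroid(self, label: str) -> np.ndarray:
        """World-coordinate centroid of a region's voxel centers."""
        idx = np.argwhere(self.masks[label])
        if idx.size == 0:
            raise ValueError(f"region {label} is empty")
        return idx.mean(axis=0) * self.spacing + self.origin

    def volume_cm3(self, label: str) -> float:
        return float(self.masks[label].sum() * np.prod(self.spacing) / 1000.0)


@dataclass
class VoxelGrid:
    """Per-region voxel-center coordinates (mm) at planning resolution.

    Region lists are pairwise disjoint: a lattice cell belongs to the region
    covering its center, with tie-break priority PTV > OAR > SHELL.
    """

    regions: dict[str, np.ndarray]
    resolution: float

    def points(self, label: str) -> np.ndarray:
        return self.regions.get(label, np.empty((0, 3)))

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def ptv_centroid(self) -> np.ndarray:
        pts = self.points(PTV)
        if len(pts) == 0:
            raise ValueError("empty PTV")
        return pts.mean(axis=0)

    def stacked(self, order: tuple[str, ...] = (PTV, BLADDER, RECTUM, SHELL3, SHELL9)):
        """All region points stacked, with slices giving each region's row block."""
        blocks, slices, start = [], {}, 0
        for label in order:
            pts = self.points(label)
            blocks.append(pts)
            slices[label] = slice(start, start + len(pts))
            start += len(pts)
        stacked = np.vstack(blocks) if blocks else np.empty((0, 3))
        return stacked, slices


@dataclass
class Ellipsoid:
    center: np.ndarray
    semiaxes: np.ndarray

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = (np.atleast_2d(pts) - np.asarray(self.center)) / np.asarray(self.semiaxes)
        return (d * d).sum(axis=-1) <= 1.0


@dataclass
class PhantomSpec:
    """Parametric description of a pelvic phantom.

    Organ geometry is ellipsoidal; bone elements are boxes or capsules, gas
    pockets are spheres. ``PhantomSpec.random`` draws anatomically plausible
    parameter ranges (PTV volume 25–120 cm³ by default).
    """

    body_semiaxes: tuple = (160.0, 105.0, 120.0)
    body_center: tuple = (0.0, 0.0, 0.0)
    ptv_center: tuple = (0.0, 15.0, -20.0)
    ptv_semiaxes: tuple = (22.0, 18.0, 20.0)
    bladder_center: tuple = (0.0, -30.0, 25.0)
    bladder_semiaxes: tuple = (32.0, 28.0, 28.0)
    rectum_center: tuple = (0.0, 52.0, -10.0)
    rectum_semiaxes: tuple = (14.0, 14.0, 45.0)
    bone_elements: list = field(default_factory=list)   # dicts, see _rasterize_bone
    gas_pockets: list = field(default_factory=list)     # dicts: center, radius, gray
    tissue_gray: float = 1050.0
    bone_gray: float = 1700.0
    gas_gray: float = 100.0
    spacing: tuple = (3.0, 3.0, 3.0)
    seed: int = 0

    @staticmethod
    def random(
        seed: int,
        ptv_volume_range_cm3: tuple | None = None,
        n_gas: int = 2,
        with_bone: bool = True,
        spacing: tuple = (3.0, 3.0, 3.0),
        scale: str = "clinical",
    ) -> "PhantomSpec":
        """Draw a random but anatomically structured phantom spec.

        scale="clinical" draws full pelvis dimensions with PTV volumes spanning
        25-120 cm3. scale="desk" draws a compact pelvis (small-PTV end of the
        clinical range, smaller bladder/rectum) sized for fast repeated
        planning in tests and demonstrations; the geometry layout is identical.
        """
        if scale not in ("clinical", "desk"):
            raise ValueError("scale must be 'clinical' or 'desk'")
        desk = scale == "desk"
        if ptv_volume_range_cm3 is None:
            ptv_volume_range_cm3 = (25.0, 45.0) if desk else (25.0, 120.0)
        rng = np.random.default_rng(seed)
        vol = rng.uniform(*ptv_volume_range_cm3) * 1000.0  # mm^3
        # semiaxes with mild anisotropy around the equivalent-sphere radius
        r0 = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        ani = rng.uniform(0.85, 1.18, size=3)
        ani *= (r0 / (np.prod(ani) ** (1.0 / 3.0)) / r0)
        semi = r0 * ani
        ptv_center = np.array([rng.uniform(-8, 8), rng.uniform(8, 22), rng.uniform(-28, -12)])
        if desk:
            body = np.array([rng.uniform(135, 145), rng.uniform(90, 100), rng.uniform(100, 110)])
            bladder_semi = rng.uniform(18, 24, size=3)
            rectum_semi = (rng.uniform(10, 13), rng.uniform(10, 13), rng.uniform(32, 40))
        else:
            body = np.array([rng.uniform(150, 170), rng.uniform(95, 115), rng.uniform(110, 130)])
            bladder_semi = rng.uniform(24, 34, size=3)
            rectum_semi = (rng.uniform(11, 16), rng.uniform(11, 16), rng.uniform(38, 52))
        bladder_c = ptv_center + np.array(
            [rng.uniform(-5, 5), -(semi[1] + rng.uniform(26, 34)), semi[2] + rng.uniform(22, 30)]
        )
        rectum_c = ptv_center + np.array(
            [rng.uniform(-4, 4), semi[1] + rng.uniform(18, 26), rng.uniform(5, 15)]
        )
        bone = []
        if with_bone:
            for sx in (-1.0, 1.0):  # femoral heads / acetabula as lateral capsules
                x = sx * (semi[0] + rng.uniform(38, 50))
                bone.append(
                    {
                        "kind": "capsule",
                        "a": (x, ptv_center[1] - 12.0, ptv_center[2] - 45.0),
                        "b": (x, ptv_center[1] - 12.0, ptv_center[2] + 35.0),
                        "radius": rng.uniform(16, 22),
                    }
                )
            bone.append(  # sacrum as a posterior box
                {
                    "kind": "box",
                    "lo": (-35.0, rectum_c[1] + 22.0, ptv_center[2] - 30.0),
                    "hi": (35.0, rectum_c[1] + 52.0, ptv_center[2] + 60.0),
                }
            )
        gas = []
        for _ in range(n_gas):  # bowel gas, superior-anterior of the target
            gas.append(
                {
                    "center": (
                        rng.uniform(-60, 60),
                        rng.uniform(-45, 10),
                        ptv_center[2] + rng.uniform(55, 85),
                    ),
                    "radius": rng.uniform(8, 16),
                }
            )
        return PhantomSpec(
            body_semiaxes=tuple(body),
            ptv_center=tuple(ptv_center),
            ptv_semiaxes=tuple(semi),
            bladder_center=tuple(bladder_c),
            bladder_semiaxes=tuple(bladder_semi),
            rectum_center=tuple(rectum_c),
            rectum_semiaxes=tuple(rectum_semi),
            bone_elements=bone,
            gas_pockets=gas,
            spacing=spacing,
            seed=seed,
        )


def _segment_point_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((pts - a) @ ab) / max(float(ab @ ab), 1e-12), 0.0, 1.0)
    return np.linalg.norm(pts - (a + t[:, None] * ab), axis=-1)


def generate_phantom(spec: PhantomSpec) -> tuple[CtVolume, StructureSet]:
    """Rasterize a phantom spec into a CT volume and structure set.

    Deterministic for a fixed spec (the seed only matters through
    ``PhantomSpec.random``). Raises :class:`InvalidSpecError` if PTV, bladder
    and rectum overlap after rasterization or an organ center leaves the body.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    body_c = np.asarray(spec.body_center, dtype=float)
    body_s = np.asarray(spec.body_semiaxes, dtype=float)
    margin = 2.0 * spacing  # one air voxel ring around the body
    lo = body_c - body_s - margin
    shape = np.ceil(2 * (body_s + margin) / spacing).astype(int) + 1
    origin = lo + 0.5 * spacing

    body_e = Ellipsoid(body_c, body_s)
    organs = {
        PTV: Ellipsoid(np.asarray(spec.ptv_center, float), np.asarray(spec.ptv_semiaxes, float)),
        BLADDER: Ellipsoid(
            np.asarray(spec.bladder_center, float), np.asarray(spec.bladder_semiaxes, float)
        ),
        RECTUM: Ellipsoid(
            np.asarray(spec.rectum_center, float), np.asarray(spec.rectum_semiaxes, float)
        ),
    }
    for label, e in organs.items():
        d = (e.center - body_c) / body_s
        if (d * d).sum() > 1.0:
            raise InvalidSpecError(f"{label} center lies outside the body ellipsoid")

    centers = (
        np.stack(
            np.meshgrid(
                *(origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)), indexing="ij"
            ),
            axis=-1,
        )
        .reshape(-1, 3)
    )
    body = body_e.contains(centers)
    gray = np.where(body, spec.tissue_gray, AIR_GRAY)

    for el in spec.bone_elements:
        if el.get("kind", "box") == "box":
            lo_b, hi_b = np.asarray(el["lo"], float), np.asarray(el["hi"], float)
            inside = np.all((centers >= lo_b) & (centers <= hi_b), axis=1)
        else:  # capsule
            inside = (
                _segment_point_distance(
                    centers, np.asarray(el["a"], float), np.asarray(el["b"], float)
                )
                <= float(el["radius"])
            )
        gray = np.where(body & inside, el.get("gray", spec.bone_gray), gray)

    for pocket in spec.gas_pockets:
        c = np.asarray(pocket["center"], float)
        inside = np.linalg.norm(centers - c, axis=1) <= float(pocket["radius"])
        gray = np.where(body & inside, pocket.get("gray", spec.gas_gray), gray)

    masks = {BODY: body.reshape(shape)}
    for label, e in organs.items():
        masks[label] = (e.contains(centers) & body).reshape(shape)

    for i, a in enumerate((PTV, BLADDER, RECTUM)):
        for b in (PTV, BLADDER, RECTUM)[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise InvalidSpecError(f"{a} and {b} overlap after rasterization")

    ct = CtVolume(gray.reshape(shape).astype(np.float32), spacing, origin)
    return ct, StructureSet(masks, spacing, origin)


def build_shells(
    structures: StructureSet, distances: list[float] | tuple[float, ...] = (3.0, 9.0)
) -> StructureSet:
    """Add SHELL bands around the PTV at the given distances (mm).

    Band k contains voxels whose Euclidean distance to the nearest PTV voxel
    center lies in (d_{k-1}, d_k] (d_0 = 0), restricted to the body and minus
    PTV and OAR voxels, so region labels stay disjoint.
    """
    ptv = structures.mask(PTV)
    if not ptv.any():
        raise ValueError("empty PTV")
    dist = ndimage.distance_transform_edt(~ptv, sampling=structures.spacing)
    exclude = ptv.copy()
    for oar in OAR_LABELS:
        if oar in structures.masks:
            exclude |= structures.mask(oar)
    body = structures.mask(BODY) if BODY in structures.masks else np.ones_like(ptv)

    masks = dict(structures.masks)
    prev = 0.0
    names = {0: SHELL3, 1: SHELL9}
    for k, d in enumerate(distances):
        band = (dist > prev) & (dist <= d) & ~exclude & body
        masks[names.get(k, f"SHELL{int(d)}")] = band
        prev = max(prev, d)
    return StructureSet(masks, structures.spacing, structures.origin)


def voxelize(structures: StructureSet, resolution: float = 3.0) -> VoxelGrid:
    """Discretize regions onto a regular planning lattice.

    Lattice centers sit at ``origin + k * resolution`` so that, when the
    planning resolution equals the native spacing, lattice and native centers
    coincide. A cell belongs to the region covering its center; ties resolve
    PTV > bladder/rectum > SHELL3 > SHELL9.
    """
    if resolution < float(np.max(structures.spacing)) - 1e-9:
        raise ValueError("planning resolution must be >= native spacing")
    shape = next(iter(structures.masks.values())).shape
    extent = (np.asarray(shape) - 1) * structures.spacing
    n = np.floor(extent / resolution).astype(int) + 1
    axes = [structures.origin[a] + resolution * np.arange(n[a]) for a in range(3)]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    idx = np.round((centers - structures.origin) / structures.spacing).astype(int)
    valid = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    idx, centers = idx[valid], centers[valid]

    priority = [PTV, BLADDER, RECTUM, SHELL3, SHELL9]
    taken = np.zeros(len(centers), dtype=bool)
    regions: dict[str, np.ndarray] = {}
    for label in priority:
        if label not in structures.masks:
            regions[label] = np.empty((0, 3))
            continue
        hit = structures.masks[label][idx[:, 0], idx[:, 1], idx[:, 2]] & ~taken
        regions[label] = centers[hit]
        taken |= hit
    return VoxelGrid(regions, float(resolution))


def default_phantom(seed: int = 0, **kwargs) -> tuple[CtVolume, StructureSet, VoxelGrid]:
    """Random phantom → shells → 3 mm planning grid, in one call."""
    spec = PhantomSpec.random(seed, **kwargs)
    ct, structures = generate_phantom(spec)
    structures = build_shells(structures)
    grid = voxelize(structures, 3.0)
    return ct, structures, grid
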