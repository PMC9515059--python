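"""Ultrasound viewport feasibility by ray tracing CT gray values.

A viewport is a skin point from which the transducer can image the target:
the ray to the PTV centroid must cross no dense tissue (max gray > 1300),
no gas (min gray < 400), and no more than 120 mm of tissue. Rejection reasons
are reported with priority dense > gas > depth when several apply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import BODY_THRESHOLD, BONE_THRESHOLD, GAS_THRESHOLD, CtVolume

MAX_TISSUE_DEPTH_MM = 120.0
SKIN_TRIM_MM = 2.0  # skin-side samples excluded from the gray tests (partial volume)


@dataclass
class Viewport:
    skin_point: np.ndarray
    direction: np.ndarray      # unit vector toward the PTV centroid
    max_gray: float
    min_gray: float
    tissue_depth: float
    feasible: bool
    reject_reason: str         # dense | gas | depth | none


@dataclass
class ViewportMap:
    viewports: list[Viewport]
    step: float

    def __len__(self) -> int:
        return len(self.viewports)

    @property
    def feasible_indices(self) -> np.ndarray:
        return np.array([i for i, v in enumerate(self.viewports) if v.feasible], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": [v.skin_point[0] for v in self.viewports],
                "y": [v.skin_point[1] for v in self.viewports],
                "z": [v.skin_point[2] for v in self.viewports],
                "max_gray": [v.max_gray for v in self.viewports],
                "min_gray": [v.min_gray for v in self.viewports],
                "depth_mm": [v.tissue_depth for v in self.viewports],
                "feasible": [v.feasible for v in self.viewports],
                "reason": [v.reject_reason for v in self.viewports],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def body_mask_of(ct: CtVolume) -> np.ndarray:
    """Filled body mask (gray >= 500 with interior gas/air holes closed)."""
    return ndimage.binary_fill_holes(ct.values >= BODY_THRESHOLD)


def default_accessibility(radial: np.ndarray) -> np.ndarray:
    """Accessible skin directions: anterior/lateral/perineal, not posterior/table.

    ``radial`` holds outward unit directions (skin point relative to the body
    centroid); points whose outward direction has a posterior component
    (y > 0.2) are excluded unless they face inferior (z < -0.6, perineal).
    """
    radial = np.atleast_2d(radial)
    return (radial[:, 1] <= 0.2) | (radial[:, 2] <= -0.6)


def extract_skin_surface(
    ct: CtVolume,
    step: float = 5.0,
    accessibility=default_accessibility,
    body_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Discretized accessible skin points (mm), spaced roughly ``step`` apart.

    Surface voxels are body voxels with a non-body face neighbor; they are
    subsampled by keeping one point per ``step``-sized spatial bin.
    """
    body = body_mask_of(ct) if body_mask is None else body_mask
    if not body.any():
        raise ValueError("no body surface found (volume is all air)")
    surface = body & ~ndimage.binary_erosion(body)
    pts = ct.index_to_world(np.argwhere(surface))
    centroid = ct.index_to_world(np.argwhere(body)).mean(axis=0)
    radial = pts - centroid
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    pts = pts[accessibility(radial)]
    if len(pts) == 0:
        raise ValueError("no accessible skin points under the accessibility mask")
    # deterministic bin-wise subsampling, binned relative to the body centroid
    # so the map is equivariant under volume translation
    bins = np.floor((pts - centroid) / step).astype(int)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    seen: dict[tuple, int] = {}
    keep = []
    for i in order:
        key = tuple(bins[i])
        if key not in seen:
            seen[key] = i
            keep.append(i)
    return pts[np.array(keep)]


def assess_viewport(
    ct: CtVolume,
    skin_point: np.ndarray,
    target_centroid: np.ndarray,
    body_mask: np.ndarray | None = None,
    step: float = 1.0,
    max_depth: float = MAX_TISSUE_DEPTH_MM,
) -> Viewport:
    """Classify one skin point by marching the ray to the target centroid.

    Gray statistics are taken over samples strictly inside the body, skipping
    the first 2 mm after the skin so the air/skin partial-volume boundary does
    not trigger the gas rule. Depth is the geometric in-body path length.
    """
    skin_point = np.asarray(skin_point, float)
    target_centroid = np.asarray(target_centroid, float)
    body = body_mask_of(ct) if body_mask is None else body_mask
    seg = target_centroid - skin_point
    length = float(np.linalg.norm(seg))
    if length == 0:
        raise ValueError("skin point coincides with the target centroid")
    direction = seg / length
    n = max(int(np.ceil(length / step)), 1)
    t = (np.arange(n) + 0.5) * (length / n)
    pts = skin_point + t[:, None] * direction
    idx = np.round(ct.world_to_index(pts)).astype(int)
    shape = np.asarray(body.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    inside = np.zeros(n, dtype=bool)
    inside[ok] = body[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    depth = float(inside.sum() * (length / n))

    tested = inside & (t >= t[inside].min() + SKIN_TRIM_MM) if inside.any() else inside
    if tested.any():
        gray = ct.sample(pts[tested])
        gmax, gmin = float(gray.max()), float(gray.min())
    else:
        gmax, gmin = 0.0, 0.0

    if gmax > BONE_THRESHOLD:
        reason = "dense"
    elif gmin < GAS_THRESHOLD:
        reason = "gas"
    elif depth > max_depth:
        reason = "depth"
    else:
        reason = "none"
    return Viewport(skin_point, direction, gmax, gmin, depth, reason == "none", reason)


def viewport_map(
    ct: CtVolume,
    target_centroid: np.ndarray,
    step: float = 5.0,
    accessibility=default_accessibility,
    body_mask: np.ndarray | None = None,
    require_feasible: bool = True,
) -> ViewportMap:
    """Assess every accessible skin point toward the target centroid."""
    body = body_mask_of(ct) if body_mask is None else body_mask
    skin = extract_skin_surface(ct, step, accessibility, body)
    vps = [assess_viewport(ct, p, target_centroid, body) for p in skin]
    vmap = ViewportMap(vps, step)
    if require_feasible and len(vmap.feasible_indices) == 0:
        raise ValueError(
            "no feasible viewport: every ray hits dense tissue, gas, or exceeds "
            "the 120 mm depth limit; revise the phantom or accessibility mask"
        )
    return vmap
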