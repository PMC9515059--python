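"""Volume and spec I/O: NRRD/NIfTI via SimpleITK, phantom specs via YAML/JSON.

Arrays are stored internally as (x, y, z); SimpleITK images use (z, y, x) in
their NumPy views, so axes are transposed on the way in and out.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .phantom import CtVolume, PhantomSpec, StructureSet


def write_volume(ct: CtVolume, path) -> None:
    """Write a volume as NRRD (preferred) or NIfTI, chosen by file suffix."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(ct.values.T))
    img.SetSpacing(tuple(float(s) for s in ct.spacing))
    img.SetOrigin(tuple(float(o) for o in ct.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> CtVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    return CtVolume(values, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def write_structures(structures: StructureSet, directory, fmt: str = "nrrd") -> None:
    """One label volume per region, as <REGION>.<fmt> under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for label, mask in structures.masks.items():
        write_volume(
            CtVolume(mask.astype(np.float32), structures.spacing, structures.origin),
            directory / f"{label}.{fmt}",
        )


def read_structures(directory, labels=None) -> StructureSet:
    """Load a structure set written by :func:`write_structures` (or any label
    volumes on a shared lattice), so real segmentations can replace phantoms."""
    directory = Path(directory)
    files = sorted(directory.glob("*.nrrd")) + sorted(directory.glob("*.nii*"))
    masks, spacing, origin = {}, None, None
    for f in files:
        label = f.name.split(".")[0]
        if labels is not None and label not in labels:
            continue
        vol = read_volume(f)
        masks[label] = vol.values > 0.5
        spacing, origin = vol.spacing, vol.origin
    if not masks:
        raise FileNotFoundError(f"no label volumes found in {directory}")
    return StructureSet(masks, spacing, origin)


def load_phantom_spec(path) -> PhantomSpec:
    path = Path(path)
    with open(path) as f:
        data = json.load(f) if path.suffix == ".json" else yaml.safe_load(f)
    return PhantomSpec(**data)


def save_phantom_spec(spec: PhantomSpec, path) -> None:
    path = Path(path)
    data = dataclasses.asdict(spec)
    data = json.loads(json.dumps(data, default=lambda o: list(o)))  # tuples → lists
    with open(path, "w") as f:
        if path.suffix == ".json":
            json.dump(data, f, indent=1)
        else:
            yaml.safe_dump(data, f)
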