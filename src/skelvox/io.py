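"""Phantom and report serialization.

Voxel phantoms are written as NRRD (default) or MetaImage through SimpleITK,
with the voxel size in the image spacing and the provenance (segment key,
seed, database mode, generator version) in the header metadata; morphometry
reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .geometry import VoxelPhantom

LABEL_LEGEND = "0=background 1=marrow 2=trabecular_bone 3=cortical_bone"


def write_phantom(phantom: VoxelPhantom, path: str | Path) -> Path:
    """Write a labelled phantom; the format follows the extension (.nrrd/.mha)."""
    import SimpleITK as sitk

    path = Path(path)
    if path.suffix not in (".nrrd", ".mha", ".mhd"):
        raise ValueError(f"unsupported phantom format {path.suffix!r}; use .nrrd or .mha")
    # SimpleITK expects [z, y, x]; our arrays are [x, y, z]
    img = sitk.GetImageFromArray(np.ascontiguousarray(phantom.labels.transpose(2, 1, 0)))
    img.SetSpacing((phantom.voxel_size,) * 3)
    img.SetMetaData("skelvox_version", __version__)
    img.SetMetaData("label_legend", LABEL_LEGEND)
    for key, value in phantom.meta.items():
        img.SetMetaData(f"skelvox_{key}", str(value))
    sitk.WriteImage(img, str(path), useCompression=False)
    return path


def read_phantom(path: str | Path) -> VoxelPhantom:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    labels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    meta = {k: img.GetMetaData(k) for k in img.GetMetaDataKeys()}
    return VoxelPhantom(labels=labels.astype(np.uint8), voxel_size=float(img.GetSpacing()[0]), meta=meta)


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
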