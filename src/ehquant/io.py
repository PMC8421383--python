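"""File interchange: NIfTI volumes, PNG sections and masks, CSV tables.

Volumes travel as NIfTI-1 (.nii or .nii.gz) with the voxel size in the
header zooms.  Label images and sections are 16-bit PNGs with a JSON
sidecar mapping label integers to names and carrying pixel size and
provenance; ROI masks are 0/255 PNGs with a sidecar for the slice index.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from . import labels as L
from .roi_select import ROIMask
from .volumes import LabelVolume, SectionImage, Volume


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size_mm))
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def load_volume(path: str | Path, contrast: str = "other") -> Volume:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.dataobj, dtype=np.float64), zooms, contrast)


def save_label_volume(labels: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int16), _affine(labels.voxel_size_mm))
    img.header.set_zooms(labels.voxel_size_mm)
    nib.save(img, str(path))


def load_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(np.asarray(img.dataobj).astype(np.int16), zooms)


def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def save_section(section: SectionImage, path: str | Path) -> None:
    iio.imwrite(Path(path), section.labels.astype(np.uint16))
    sidecar = dict(
        pixel_size_mm=section.pixel_size_mm,
        site=section.site,
        labels={str(k): v for k, v in L.NAMES.items()},
    )
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_section(path: str | Path) -> SectionImage:
    data = np.asarray(iio.imread(Path(path))).astype(np.int16)
    meta = json.loads(_sidecar_path(path).read_text())
    return SectionImage(data, float(meta["pixel_size_mm"]), site=meta.get("site", ""))


def save_mask(roi: ROIMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (roi.mask.astype(np.uint8)) * 255)
    sidecar = dict(slice_index=roi.slice_index, site=roi.site, provenance=roi.provenance)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_mask(path: str | Path) -> ROIMask:
    data = np.asarray(iio.imread(Path(path))) > 0
    meta = json.loads(_sidecar_path(path).read_text())
    return ROIMask(
        data,
        int(meta["slice_index"]),
        meta.get("site", ""),
        meta.get("provenance", ""),
    )
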