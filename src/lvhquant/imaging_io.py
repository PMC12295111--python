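"""Short-axis stack container, readers/writers and intensity normalization.

Pixel coordinates are 0-based ``(row, col)`` with the origin at the top
left; all geometry modules inherit this convention. Pixel spacing is in
millimetres per pixel, ``(row, col)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ShortAxisStack:
    """Ordered 2-D short-axis slices with shared shape and pixel spacing."""

    slices: list[np.ndarray]
    pixel_spacing: tuple[float, float]
    level_labels: list[str] | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        if not self.slices:
            raise ValueError("stack must contain at least one slice")
        shape = self.slices[0].shape
        if any(s.shape != shape for s in self.slices):
            raise ValueError("all slices in a stack must share one shape")
        if self.level_labels is not None and len(self.level_labels) != len(self.slices):
            raise ValueError("level_labels must cover each slice exactly once")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    def __len__(self) -> int:
        return len(self.slices)


def normalize_minmax(image: np.ndarray) -> np.ndarray:
    """Rescale an image linearly onto [0, 1].

    Output is ``(X - Xmin) / (Xmax - Xmin)``. A constant image maps to all
    zeros rather than raising: the formula is undefined there and uniform
    (e.g. black-background) slices should pass through silently. Applied
    per slice, never per stack, so scanners with different intensity scales
    are normalized independently.
    """
    image = np.asarray(image, dtype=float)
    if image.size < 1:
        raise ValueError("image must have at least one pixel")
    lo = image.min()
    hi = image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def read_stack(
    path: str,
    format: str | None = None,
    spacing: tuple[float, float] | None = None,
    level_labels: list[str] | None = None,
    subject_id: str = "",
) -> ShortAxisStack:
    """Read a short-axis stack from a DICOM series, NIfTI volume or PNG set.

    Slices are ordered by slice location (DICOM), by the third axis (NIfTI)
    or lexicographically by filename (PNG). ``spacing`` overrides metadata;
    PNG has no spacing metadata, so the override is mandatory there.
    """
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        return _read_nifti(path, spacing, level_labels, subject_id)
    if fmt == "dicom":
        return _read_dicom(path, spacing, level_labels, subject_id)
    if fmt == "png_dir":
        return _read_png_dir(path, spacing, level_labels, subject_id)
    raise ValueError(f"unknown stack format {fmt!r}")


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        names = sorted(os.listdir(path))
        if any(n.lower().endswith(".png") for n in names):
            return "png_dir"
        return "dicom"
    if path.endswith((".nii", ".nii.gz")):
        return "nifti"
    return "dicom"


def _read_nifti(path, spacing, level_labels, subject_id) -> ShortAxisStack:
    import nibabel as nib

    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    slices = [data[:, :, k] for k in range(data.shape[2])]
    if spacing is None:
        zooms = img.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
    return ShortAxisStack(slices, spacing, level_labels, subject_id)


def _read_dicom(path, spacing, level_labels, subject_id) -> ShortAxisStack:
    import pydicom

    files = sorted(
        os.path.join(path, n) for n in os.listdir(path) if not n.startswith(".")
    )
    datasets = [pydicom.dcmread(f) for f in files]
    if not datasets:
        raise ValueError(f"no DICOM files under {path}")

    def location(ds):
        if hasattr(ds, "SliceLocation"):
            return float(ds.SliceLocation)
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=location)
    slices = [ds.pixel_array.astype(float) for ds in datasets]
    if spacing is None:
        ds0 = datasets[0]
        if hasattr(ds0, "PixelSpacing"):
            spacing = (float(ds0.PixelSpacing[0]), float(ds0.PixelSpacing[1]))
        else:
            raise ValueError("DICOM series has no PixelSpacing and no override given")
    return ShortAxisStack(slices, spacing, level_labels, subject_id)


def _read_png_dir(path, spacing, level_labels, subject_id) -> ShortAxisStack:
    import imageio.v3 as iio

    if spacing is None:
        raise ValueError("PNG slice sets carry no pixel spacing: pass spacing=(mm, mm)")
    names = sorted(n for n in os.listdir(path) if n.lower().endswith(".png"))
    if not names:
        raise ValueError(f"no PNG files under {path}")
    slices = []
    for n in names:
        arr = np.asarray(iio.imread(os.path.join(path, n)), dtype=float)
        if arr.ndim == 3:  # collapse RGB(A) to gray
            arr = arr[..., :3].mean(axis=2)
        slices.append(arr)
    return ShortAxisStack(slices, spacing, level_labels, subject_id)


def write_stack_nifti(stack: ShortAxisStack, path: str) -> str:
    import nibabel as nib

    vol = np.stack(stack.slices, axis=2)
    affine = np.diag([stack.pixel_spacing[0], stack.pixel_spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((stack.pixel_spacing[0], stack.pixel_spacing[1], 1.0))
    nib.save(img, path)
    return path


def write_stack_png(stack: ShortAxisStack, out_dir: str) -> list[str]:
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for k, sl in enumerate(stack.slices):
        arr = (normalize_minmax(sl) * 255).round().astype(np.uint8)
        p = os.path.join(out_dir, f"slice_{k:03d}.png")
        iio.imwrite(p, arr)
        paths.append(p)
    return paths
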