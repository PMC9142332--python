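"""Data model and I/O for 3D grayscale volumes.

A :class:`Volume` is a dense 3D grid of integer gray levels with axis order
``(depth, height, width)`` — i.e. ``(z, y, x)``, 0-based.  Volumes can be read
from and written to NIfTI-1 files, multi-page TIFF stacks, and directories of
2D slice images (PNG/TIFF) sorted lexicographically; a stack of k slices of
shape h×w becomes a volume of shape (k, h, w) with slice i preserved verbatim.

Floating-point sources carry no natural gray-level scale, so they are min–max
rescaled onto [0, 255] with half-up rounding; integer sources are preserved
bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Volume",
    "BinaryVolume",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "binarize",
    "stack_slices",
]

_SUPPORTED_FORMATS = ("nifti", "tiff-stack", "slice-dir")


class VolumeFormatError(ValueError):
    """Raised when a file cannot be parsed as a supported volume format."""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass
class Volume:
    """A 3D grid of grayscale intensities.

    Parameters
    ----------
    voxels : ndarray, shape (depth, height, width)
        Integer gray levels in ``[0, 2**bit_depth - 1]``.
    bit_depth : int
        Number of intensity bits (default 8).
    voxel_spacing : tuple of float, optional
        Physical voxel size in mm, metadata only.
    """

    voxels: np.ndarray
    bit_depth: int = 8
    voxel_spacing: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {v.shape}")
        if any(s < 1 for s in v.shape):
            raise ValueError(f"all dimensions must be >= 1, got {v.shape}")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        hi = self.max_intensity
        if np.issubdtype(v.dtype, np.floating):
            raise TypeError("Volume stores integer gray levels; rescale floats first")
        if v.min() < 0 or v.max() > hi:
            raise ValueError(
                f"intensities must lie in [0, {hi}] for bit_depth={self.bit_depth}"
            )
        self.voxels = v

    @property
    def depth(self) -> int:
        return self.voxels.shape[0]

    @property
    def height(self) -> int:
        return self.voxels.shape[1]

    @property
    def width(self) -> int:
        return self.voxels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """Copy of this volume with new voxel data, same metadata."""
        return Volume(voxels, bit_depth=self.bit_depth, voxel_spacing=self.voxel_spacing)


@dataclass
class BinaryVolume:
    """A 3D mask: every voxel is exactly 0 or 1."""

    voxels: np.ndarray
    voxel_spacing: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {v.shape}")
        vals = np.unique(v)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask voxels must be exactly 0 or 1")
        self.voxels = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())


def stack_slices(slices: Sequence[np.ndarray], bit_depth: int = 8) -> Volume:
    """Stack an ordered sequence of 2D arrays into a Volume (slice i -> depth i)."""
    if not slices:
        raise ValueError("cannot stack an empty slice sequence")
    shapes = {s.shape for s in map(np.asarray, slices)}
    if len(shapes) != 1:
        raise VolumeFormatError(f"inconsistent slice shapes: {sorted(shapes)}")
    return Volume(np.stack([np.asarray(s) for s in slices], axis=0), bit_depth=bit_depth)


def _rescale_float(data: np.ndarray) -> np.ndarray:
    """Min–max rescale floating-point data onto [0, 255], half-up rounding."""
    lo, hi = float(np.min(data)), float(np.max(data))
    if hi == lo:
        return np.zeros(data.shape, dtype=np.uint8)
    scaled = (data.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return _round_half_up(scaled).astype(np.uint8)


def _as_volume(data: np.ndarray, spacing=None) -> Volume:
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating):
        return Volume(_rescale_float(data), bit_depth=8, voxel_spacing=spacing)
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    return Volume(data.astype(np.uint16 if bit_depth == 16 else np.uint8),
                  bit_depth=bit_depth, voxel_spacing=spacing)


def _sniff_format(path: Path) -> str:
    if path.is_dir():
        return "slice-dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff-stack"
    raise VolumeFormatError(
        f"cannot infer format of {path}; supported: {', '.join(_SUPPORTED_FORMATS)}"
    )


def read_volume(path: str | os.PathLike, format_hint: Optional[str] = None) -> Volume:
    """Read a volume from disk.

    Integer voxel data are preserved bit-exactly; floating-point sources are
    min–max rescaled to [0, 255].

    Parameters
    ----------
    path : path-like
        File (.nii/.nii.gz/.tif/.tiff) or a directory of 2D slices.
    format_hint : {"nifti", "tiff-stack", "slice-dir"}, optional
        Skip extension sniffing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or _sniff_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected 3D NIfTI, got shape {data.shape}")
        # stored as (x, y, z); present as (z, y, x)
        zooms = img.header.get_zooms()[:3]
        return _as_volume(data.T, spacing=tuple(float(z) for z in zooms[::-1]))
    if fmt == "tiff-stack":
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise VolumeFormatError(f"{path}: expected a grayscale page stack, got shape {data.shape}")
        return _as_volume(data)
    if fmt == "slice-dir":
        return _read_slice_dir(path)
    raise VolumeFormatError(
        f"unknown format {fmt!r}; supported: {', '.join(_SUPPORTED_FORMATS)}"
    )


def _read_slice_dir(path: Path) -> Volume:
    from PIL import Image
    import tifffile

    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise VolumeFormatError(f"{path}: no PNG/TIFF slices found")
    slices, shapes = [], {}
    for f in files:
        if f.suffix.lower() == ".png":
            arr = np.asarray(Image.open(f).convert("I"))
        else:
            arr = tifffile.imread(str(f))
        if arr.ndim != 2:
            raise VolumeFormatError(f"{f}: slice is not 2D grayscale (shape {arr.shape})")
        shapes.setdefault(arr.shape, []).append(f.name)
        slices.append(arr)
    if len(shapes) > 1:
        detail = "; ".join(f"{s}: {names}" for s, names in shapes.items())
        raise VolumeFormatError(f"inconsistent slice shapes in {path}: {detail}")
    data = np.stack(slices, axis=0)
    return _as_volume(data)


def write_volume(v: Volume, path: str | os.PathLike, format: Optional[str] = None) -> None:
    """Write a volume; ``read_volume(write_volume(v))`` is voxel-identical for
    integer volumes."""
    path = Path(path)
    fmt = format or _sniff_format(path)
    dtype = np.uint16 if v.bit_depth > 8 else np.uint8
    data = v.voxels.astype(dtype)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.eye(4)
        if v.voxel_spacing is not None:
            affine[0, 0], affine[1, 1], affine[2, 2] = v.voxel_spacing[::-1]
        nib.save(nib.Nifti1Image(data.T, affine), str(path))
    elif fmt == "tiff-stack":
        import tifffile

        tifffile.imwrite(str(path), data, photometric="minisblack")
    elif fmt == "slice-dir":
        from PIL import Image

        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(4, len(str(v.depth)))
        for i in range(v.depth):
            Image.fromarray(data[i]).save(path / f"slice_{i:0{ndigits}d}.png")
    else:
        raise VolumeFormatError(
            f"unsupported format {fmt!r}; supported: {', '.join(_SUPPORTED_FORMATS)}"
        )


def binarize(v: Volume, threshold: int = 128) -> BinaryVolume:
    """Threshold a volume: output voxel is 1 iff input voxel >= threshold."""
    if not (0 <= threshold <= v.max_intensity):
        raise ValueError(
            f"threshold {threshold} outside intensity range [0, {v.max_intensity}]"
        )
    return BinaryVolume((v.voxels >= threshold).astype(np.uint8),
                        voxel_spacing=v.voxel_spacing)
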