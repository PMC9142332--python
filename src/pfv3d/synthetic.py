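"""Synthetic phantoms and exact fixtures for every pipeline stage.

Three generators:

* :func:`make_phantom` — MRI-like volumes with a compact high-intensity
  inclusion ("tumor") of a chosen shape class on a darker background,
  optionally corrupted by salt-and-pepper impulse noise.  Ground truth (the
  clean volume and the object mask) is returned alongside.
* :func:`plant_patterns` — binary volumes whose stride-3 window grid contains
  exactly the requested corner patterns, together with the exact expected
  pattern frequency vector.  This is the definitional oracle for PFV
  extraction.
* :func:`make_labeled_dataset` — seeded labelled collections of phantoms with
  jittered object size and position, for classifier training.

Shape classes emulate gross tumor morphology only: a solid ellipsoid, a
hollow shell (rim-enhancing lesion), and a multi-focal cluster of small
blobs.  Their wireframes produce distinct corner-pattern statistics, which is
what the classifier end of the pipeline needs; none of this models MRI
physics (no bias fields, Rician noise or partial-volume effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .patterns import PatternFrequencyVector, build_vocabulary
from .volumes import BinaryVolume, Volume

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "plant_patterns",
    "make_labeled_dataset",
    "SHAPE_CLASSES",
]

SHAPE_CLASSES = ("solid_ellipsoid", "hollow_shell", "multi_blob")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom volume.

    shape_class : {"solid_ellipsoid", "hollow_shell", "multi_blob"}
    volume_shape : (depth, height, width)
    intensity_levels : (background, object) gray levels on the 8-bit scale.
        Defaults 30/200 keep both far from the default binarization
        threshold of 128.
    noise_density : fraction of voxels hit by salt-and-pepper impulses,
        split evenly between salt (255) and pepper (0).
    radius_fraction : object semi-axis as a fraction of the half-extent.
    """

    shape_class: str = "solid_ellipsoid"
    volume_shape: tuple[int, int, int] = (30, 30, 30)
    intensity_levels: tuple[int, int] = (30, 200)
    noise_density: float = 0.0
    seed: int = 0
    radius_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(
                f"shape_class must be one of {SHAPE_CLASSES}, got {self.shape_class!r}"
            )
        if not 0 <= self.noise_density <= 0.5:
            raise ValueError("noise_density must be in [0, 0.5]")
        if any(s < 5 for s in self.volume_shape):
            raise ValueError("volume_shape must be at least 5 per axis")
        if not 0.05 <= self.radius_fraction <= 0.9:
            raise ValueError(
                "radius_fraction must leave >=1 voxel margin (0.05..0.9), "
                f"got {self.radius_fraction}"
            )


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _object_mask(spec: PhantomSpec, rng: np.random.Generator,
                 jitter: bool = False) -> np.ndarray:
    shape = spec.volume_shape
    center = [s / 2 - 0.5 for s in shape]
    semi = [max(2.0, spec.radius_fraction * (s / 2 - 1)) for s in shape]
    if jitter:
        center = [c + rng.uniform(-0.1, 0.1) * s for c, s in zip(center, shape)]
        semi = [a * rng.uniform(0.8, 1.1) for a in semi]
    semi = [min(a, s / 2 - 1) for a, s in zip(semi, shape)]  # keep a margin

    if spec.shape_class == "solid_ellipsoid":
        return _ellipsoid_mask(shape, center, semi)
    if spec.shape_class == "hollow_shell":
        outer = _ellipsoid_mask(shape, center, semi)
        inner = _ellipsoid_mask(shape, center, [max(1.0, a - 2.5) for a in semi])
        return outer & ~inner
    # multi_blob: several small spheres scattered inside the ellipsoidal support
    mask = np.zeros(shape, dtype=bool)
    n_blobs = int(rng.integers(3, 6)) if jitter else 4
    blob_r = max(2.0, min(semi) * 0.35)
    for _ in range(n_blobs):
        offs = [rng.uniform(-0.55, 0.55) * a for a in semi]
        c = [ci + o for ci, o in zip(center, offs)]
        c = [min(max(ci, blob_r + 1), s - blob_r - 2) for ci, s in zip(c, shape)]
        mask |= _ellipsoid_mask(shape, c, [blob_r] * 3)
    return mask


def _apply_salt_pepper(clean: np.ndarray, density: float,
                       rng: np.random.Generator) -> np.ndarray:
    noisy = clean.copy()
    u = rng.random(clean.shape)
    noisy[u < density / 2] = 0
    noisy[(u >= density / 2) & (u < density)] = 255
    return noisy


def make_phantom(spec: PhantomSpec) -> tuple[Volume, Volume, BinaryVolume]:
    """Generate (noisy, clean, object-mask) for a phantom spec.

    Deterministic given ``spec.seed``; with ``noise_density`` 0 the noisy and
    clean volumes are identical.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _object_mask(spec, rng, jitter=False)
    bg, obj = spec.intensity_levels
    clean = np.full(spec.volume_shape, bg, dtype=np.uint8)
    clean[mask] = obj
    noisy = _apply_salt_pepper(clean, spec.noise_density, rng)
    return (
        Volume(noisy),
        Volume(clean),
        BinaryVolume(mask.astype(np.uint8)),
    )


def plant_patterns(volume_shape: tuple[int, int, int],
                   placements: Sequence[tuple[int, tuple[int, int, int]]],
                   ) -> tuple[BinaryVolume, PatternFrequencyVector]:
    """Plant corner patterns on the stride-3 window grid, with exact ground truth.

    Parameters
    ----------
    volume_shape : (depth, height, width), each a multiple of 3.
    placements : sequence of (pattern_id, grid_cell)
        grid_cell indexes the stride-3 grid, i.e. the window origin is
        ``3 * grid_cell``.  Cells must be distinct and inside the grid.

    Returns the mask and the exact expected PFV: the planted pattern counts
    plus the all-absent pattern for every untouched grid cell.
    """
    if any(s % 3 != 0 or s < 3 for s in volume_shape):
        raise ValueError(f"volume_shape must be positive multiples of 3, got {volume_shape}")
    grid_shape = tuple(s // 3 for s in volume_shape)
    vocab = build_vocabulary()

    seen: set[tuple[int, int, int]] = set()
    mask = np.zeros(volume_shape, dtype=np.uint8)
    counts = np.zeros(256, dtype=np.int64)
    for pid, cell in placements:
        cell = tuple(int(c) for c in cell)
        if len(cell) != 3 or any(not 0 <= c < g for c, g in zip(cell, grid_shape)):
            raise ValueError(f"grid cell {cell} outside grid {grid_shape}")
        if cell in seen:
            raise ValueError(f"duplicate grid cell {cell}")
        seen.add(cell)
        origin = tuple(3 * c for c in cell)
        window = vocab[pid].render_window()
        mask[origin[0]: origin[0] + 3,
             origin[1]: origin[1] + 3,
             origin[2]: origin[2] + 3] = window
        counts[pid] += 1
    n_windows = int(np.prod(grid_shape))
    counts[0] += n_windows - len(seen)  # untouched cells show the all-absent pattern
    pfv = PatternFrequencyVector(
        counts=counts, stride=3,
        padded_shape=volume_shape, n_windows=n_windows,
    )
    return BinaryVolume(mask), pfv


def make_labeled_dataset(n_per_class: int,
                         classes: Sequence[PhantomSpec],
                         seed: int = 0) -> list[tuple[Volume, str]]:
    """Seeded labelled phantom collection with per-sample jitter.

    Each sample jitters object size and position around its class template;
    labels are the template shape classes.  Class proportions are exact:
    ``n_per_class`` samples for each template, in template order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if len(classes) < 2:
        raise ValueError("need at least 2 class templates")
    rng = np.random.default_rng(seed)
    dataset: list[tuple[Volume, str]] = []
    for template in classes:
        for _ in range(n_per_class):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            srng = np.random.default_rng(sample_seed)
            spec = replace(template, seed=sample_seed)
            obj = _object_mask(spec, srng, jitter=True)
            bg, fg = spec.intensity_levels
            clean = np.full(spec.volume_shape, bg, dtype=np.uint8)
            clean[obj] = fg
            noisy = _apply_salt_pepper(clean, spec.noise_density, srng)
            dataset.append((Volume(noisy), spec.shape_class))
    return dataset
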