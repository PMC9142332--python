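"""CLAP wireframe extraction: iterative deletion of interior voxels.

Cellular logic array processing (CLAP) scans a binary volume with a 3×3×3
window and deletes every foreground center that is *interior*, leaving only
the skeletal shell of each object.  A center counts as interior when every
axis-aligned line of 3 cells through its window — 9 lines along each of the
three axes, 27 in total — contains at least one foreground voxel, i.e. the
local occupancy spans every row, column and pillar of the window.  Passes
repeat, with all deletions applied synchronously at the end of each pass so
the result does not depend on raster order, until a pass deletes nothing.

Borders are zero-padded: the world outside the volume is background, so
object voxels on the volume boundary survive.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryVolume, Volume, binarize

__all__ = ["WireframeResult", "is_interior", "clap_wireframe", "wireframe_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class WireframeResult:
    """Outcome of wireframe extraction.

    mask : BinaryVolume
        Retained shell voxels (a subset of the input foreground).
    iterations : int
        Number of full passes executed (including the final no-op pass).
    deleted_count : int
        Input foreground voxels minus retained foreground voxels.
    """

    mask: BinaryVolume
    iterations: int
    deleted_count: int


def is_interior(window: np.ndarray) -> bool:
    """True iff a 3×3×3 binary window's foreground center is deletable.

    The criterion: every axis-aligned line of 3 voxels through the window
    (all 27 of them) contains at least one foreground voxel.
    """
    w = np.asarray(window)
    if w.shape != (3, 3, 3):
        raise ValueError(f"window must be 3x3x3, got shape {w.shape}")
    if not np.all(np.isin(w, (0, 1))):
        raise ValueError("window must be binary")
    if not w[1, 1, 1]:
        raise ValueError("is_interior requires a foreground center")
    return bool(
        w.any(axis=0).all() and w.any(axis=1).all() and w.any(axis=2).all()
    )


def _interior_mask(m: np.ndarray) -> np.ndarray:
    """Vectorized is_interior over all voxels (zero-padded borders).

    For axis a: maximum_filter1d marks positions whose 3-line along a is
    occupied; a minimum filter over the orthogonal 3×3 then requires *every*
    line of the window along a to be occupied.
    """
    occ = m.astype(np.uint8)
    interior = m.astype(bool)
    for axis in range(3):
        line = ndimage.maximum_filter1d(occ, size=3, axis=axis, mode="constant", cval=0)
        size = [3, 3, 3]
        size[axis] = 1
        all_lines = ndimage.minimum_filter(line, size=size, mode="constant", cval=0)
        interior &= all_lines.astype(bool)
    return interior


def clap_wireframe(mask: BinaryVolume, max_iterations: int = 100) -> WireframeResult:
    """Iteratively delete interior voxels until a fixpoint (or max_iterations).

    Every pass marks all currently-interior foreground voxels, then deletes
    them simultaneously; iteration stops when a pass deletes nothing.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    m = mask.voxels.astype(np.uint8)
    initial_fg = int(m.sum())
    iterations = 0
    for _ in range(max_iterations):
        iterations += 1
        interior = _interior_mask(m)
        n_delete = int(interior.sum())
        logger.info("wireframe pass %d: deleting %d voxels", iterations, n_delete)
        if n_delete == 0:
            break
        m = np.where(interior, 0, m).astype(np.uint8)
    result_mask = BinaryVolume(m, voxel_spacing=mask.voxel_spacing)
    return WireframeResult(
        mask=result_mask,
        iterations=iterations,
        deleted_count=initial_fg - result_mask.foreground_count,
    )


def wireframe_pipeline(v: Volume, threshold: int = 128,
                       max_iterations: int = 100) -> WireframeResult:
    """Binarize a grayscale volume, then extract its CLAP wireframe."""
    t0 = time.perf_counter()
    fg = binarize(v, threshold)
    t1 = time.perf_counter()
    result = clap_wireframe(fg, max_iterations=max_iterations)
    t2 = time.perf_counter()
    logger.info(
        "wireframe_pipeline: binarize %.3fs (%d fg voxels), clap %.3fs "
        "(%d passes, %d deleted)",
        t1 - t0, fg.foreground_count, t2 - t1, result.iterations, result.deleted_count,
    )
    return result
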