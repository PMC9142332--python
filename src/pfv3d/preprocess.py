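"""Denoising and contrast enhancement for grayscale volumes.

Two operations: the classical two-stage adaptive median filter for impulse
(salt-and-pepper) noise, and linear contrast stretching that remaps an input
intensity range [c, d] onto an output range [a, b].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import Volume

__all__ = [
    "StretchParams",
    "AdaptiveMedianParams",
    "adaptive_median_filter",
    "contrast_stretch",
    "auto_stretch_limits",
    "DegenerateRangeError",
]

logger = logging.getLogger(__name__)


class DegenerateRangeError(ValueError):
    """Raised when an intensity range collapses to a single value."""


@dataclass(frozen=True)
class StretchParams:
    """Linear stretch limits: input range [c, d] maps onto output range [a, b]."""

    c: float
    d: float
    a: float = 0.0
    b: float = 255.0

    def __post_init__(self) -> None:
        if self.d == self.c:
            raise DegenerateRangeError(
                f"input limits collapse (c = d = {self.c}); stretching is "
                "undefined — pass the volume through unchanged instead"
            )
        if self.c > self.d:
            raise ValueError(f"need c < d, got c={self.c}, d={self.d}")
        if self.a >= self.b:
            raise ValueError(f"need a < b, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class AdaptiveMedianParams:
    """Window schedule for the adaptive median filter.

    initial_window, max_window : odd cube sides; the filter starts at
    initial_window and grows by 2 while the local median is itself an
    impulse extreme.
    """

    initial_window: int = 3
    max_window: int = 7
    mode: str = "3d"  # "3d": cubic neighborhoods; "2d": per-slice squares

    def __post_init__(self) -> None:
        for name, w in (("initial_window", self.initial_window),
                        ("max_window", self.max_window)):
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 3, got {w}")
        if self.max_window < self.initial_window:
            raise ValueError("max_window must be >= initial_window")
        if self.mode not in ("3d", "2d"):
            raise ValueError(f"mode must be '3d' or '2d', got {self.mode!r}")


def _local_stats(data: np.ndarray, size: tuple[int, ...]):
    kw = dict(size=size, mode="reflect")
    return (ndimage.minimum_filter(data, **kw),
            ndimage.median_filter(data, **kw),
            ndimage.maximum_filter(data, **kw))


def adaptive_median_filter(v: Volume,
                           p: AdaptiveMedianParams | None = None) -> Volume:
    """Two-stage adaptive median filter for impulse noise.

    Stage A asks whether the local median is strictly between the local min
    and max; if not, the window grows (by 2 per step, up to ``max_window``)
    and stage A repeats.  Once the median is a non-extreme, stage B keeps the
    center voxel if it too is strictly between the local extremes (it is not
    an impulse) and otherwise replaces it with the local median.  If the
    window reaches ``max_window`` without a usable median, the local median
    at ``max_window`` is output.  Borders use reflect padding; shape and bit
    depth are preserved.
    """
    p = p or AdaptiveMedianParams()
    if min(v.shape) < 3:
        raise ValueError(f"volume must be at least 3 in every dimension, got {v.shape}")
    if p.mode == "3d" and p.max_window > min(v.shape):
        raise ValueError(
            f"max_window {p.max_window} exceeds smallest volume dimension {min(v.shape)}"
        )

    data = v.voxels
    out = np.empty_like(data)
    undecided = np.ones(data.shape, dtype=bool)

    window = p.initial_window
    while True:
        size = (window,) * 3 if p.mode == "3d" else (1, window, window)
        zmin, zmed, zmax = _local_stats(data, size)
        usable = (zmed > zmin) & (zmed < zmax)  # stage A
        here = undecided & usable
        center_ok = (data > zmin) & (data < zmax)  # stage B
        out[here & center_ok] = data[here & center_ok]
        out[here & ~center_ok] = zmed[here & ~center_ok]
        undecided &= ~usable
        if not undecided.any():
            break
        if window >= p.max_window:
            # window exhausted: output the local median (removes the impulse
            # even inside constant patches, where min == med == max)
            out[undecided] = zmed[undecided]
            break
        window += 2
    return v.with_voxels(out)


def contrast_stretch(v: Volume, p: StretchParams, clip: bool = True) -> Volume:
    """Linearly remap intensities: r -> (r - c)(b - a)/(d - c) + a, half-up
    rounded.

    With ``clip`` on, inputs below c map to a and above d map to b.  If the
    input already spans the requested range and the map is the identity
    ([c, d] = [a, b]), the volume is returned unchanged.
    """
    if (p.c, p.d) == (p.a, p.b):
        return v  # already spanning the target range: stretching not required
    r = v.voxels.astype(np.float64)
    out = (r - p.c) * (p.b - p.a) / (p.d - p.c) + p.a
    out = np.floor(out + 0.5)  # round half-up
    if clip:
        out = np.clip(out, p.a, p.b)
    out = np.clip(out, 0, v.max_intensity)
    return v.with_voxels(out.astype(v.voxels.dtype))


def auto_stretch_limits(v: Volume, low_pct: float = 1.0,
                        high_pct: float = 99.0) -> StretchParams:
    """Derive stretch limits from the intensity histogram.

    c and d are the low/high percentiles of the voxel intensities; the output
    range is the full bit-depth range [0, 2^bit_depth - 1].
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError(
            f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})"
        )
    c = float(np.percentile(v.voxels, low_pct))
    d = float(np.percentile(v.voxels, high_pct))
    if c == d:
        raise DegenerateRangeError(
            f"percentiles ({low_pct}, {high_pct}) both give {c}; the histogram "
            "is too concentrated — skip stretching (clip-free passthrough)"
        )
    return StretchParams(c=c, d=d, a=0.0, b=float(v.max_intensity))
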