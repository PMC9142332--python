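"""The 256-pattern corner-occupancy vocabulary and pattern frequency vectors.

A 3×3×3 window has 27 cells, numbered 1–27 row-major within each slice, front
slice first (the center is cell 14).  Only the 8 corner cells — positions
1, 3, 7, 9, 19, 21, 25 and 27 — are inspected, so a window falls into one of
2^8 = 256 occupancy configurations.  Patterns are grouped by how many corners
are *absent*: group P (none absent, 1 pattern), Q (one absent, 8), R (two, 28),
S (56), T (70), U (56), V (28), W (7 absent, 8) and X (all absent, 1) — the
binomial coefficients C(8, k).

The canonical pattern id is the occupancy bitmask: bit k of the id is set iff
the k-th corner, in ascending cell order (1, 3, 7, 9, 19, 21, 25, 27), is
foreground.  The all-present pattern P1 therefore has id 255 and the
all-absent pattern X has id 0.  This indexing is fixed so that a pattern
always lands on the same component of the frequency vector for every image.

Scanning a binary volume with a stride-3 sliding window and counting the
pattern seen at each placement yields the 3D pattern frequency vector
(3D-PFV): 256 non-negative counts whose sum equals the number of window
placements.  A 2D analogue uses the 8 neighbors of a 3×3 window (directions
R, DR, D, DL, L, UL, U, UR).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .volumes import BinaryVolume

__all__ = [
    "CORNER_CELLS",
    "GROUP_NAMES",
    "CornerPattern",
    "PatternVocabulary",
    "PatternFrequencyVector",
    "build_vocabulary",
    "match_window",
    "extract_pfv",
    "extract_pfv_2d",
    "pfv_to_feature",
    "cell_to_zyx",
    "corner_offsets",
    "NEIGHBOR_DIRECTIONS_2D",
]

#: Corner cells of the 27-cell window numbering, ascending.
CORNER_CELLS: tuple[int, ...] = (1, 3, 7, 9, 19, 21, 25, 27)

#: Group letter by number of absent corners (0 absent -> P ... 8 absent -> X).
GROUP_NAMES: tuple[str, ...] = ("P", "Q", "R", "S", "T", "U", "V", "W", "X")

#: 2D direction convention for the 8 neighbors of a 3×3 window, in the order
#: they map onto occupancy bits 0..7.
NEIGHBOR_DIRECTIONS_2D: tuple[str, ...] = ("R", "DR", "D", "DL", "L", "UL", "U", "UR")

# (dy, dx) offsets matching NEIGHBOR_DIRECTIONS_2D, center at (1, 1).
_NEIGHBOR_OFFSETS_2D: tuple[tuple[int, int], ...] = (
    (1, 2), (2, 2), (2, 1), (2, 0), (1, 0), (0, 0), (0, 1), (0, 2)
)


def cell_to_zyx(cell: int) -> tuple[int, int, int]:
    """Map a 1-based window cell number (1..27) to (z, y, x) offsets in 0..2."""
    if not 1 <= cell <= 27:
        raise ValueError(f"cell must be in 1..27, got {cell}")
    i = cell - 1
    return i // 9, (i % 9) // 3, i % 3


def corner_offsets() -> list[tuple[int, int, int]]:
    """(z, y, x) offsets of the 8 corner cells, in ascending cell order."""
    return [cell_to_zyx(c) for c in CORNER_CELLS]


@dataclass(frozen=True)
class CornerPattern:
    """One of the 256 corner-occupancy configurations of a 3×3×3 window."""

    id: int
    present_corners: frozenset[int]

    def __post_init__(self) -> None:
        if not 0 <= self.id <= 255:
            raise ValueError(f"pattern id must be in [0, 255], got {self.id}")
        if not self.present_corners <= set(CORNER_CELLS):
            raise ValueError("present_corners must be a subset of the corner cells")

    @property
    def absent_corners(self) -> frozenset[int]:
        return frozenset(CORNER_CELLS) - self.present_corners

    @property
    def group(self) -> str:
        return GROUP_NAMES[len(self.absent_corners)]

    @property
    def name(self) -> str:
        """Human-readable name: group letter + ascending absent-corner subscript.

        ``P1`` (nothing absent), ``Q1`` .. ``Q27`` (the absent corner), and
        ``R{1,3}``-style ASCII subscripts beyond that.
        """
        absent = sorted(self.absent_corners)
        if not absent:
            return "P1"
        if len(absent) == 1:
            return f"Q{absent[0]}"
        return self.group + "{" + ",".join(map(str, absent)) + "}"

    def render_window(self) -> np.ndarray:
        """A 3×3×3 uint8 window with exactly this pattern's corners foreground."""
        w = np.zeros((3, 3, 3), dtype=np.uint8)
        for cell in self.present_corners:
            w[cell_to_zyx(cell)] = 1
        return w


@dataclass(frozen=True)
class PatternVocabulary:
    """The ordered catalogue of all 256 corner patterns, indexed by id."""

    patterns: tuple[CornerPattern, ...]

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, pattern_id: int) -> CornerPattern:
        return self.patterns[pattern_id]

    def __iter__(self):
        return iter(self.patterns)

    def by_name(self, name: str) -> CornerPattern:
        for p in self.patterns:
            if p.name == name:
                return p
        raise KeyError(name)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUP_NAMES}
        for p in self.patterns:
            sizes[p.group] += 1
        return sizes

    def id_for_present(self, present: Iterable[int]) -> int:
        present = set(present)
        pid = 0
        for k, cell in enumerate(CORNER_CELLS):
            if cell in present:
                pid |= 1 << k
        return pid


def build_vocabulary() -> PatternVocabulary:
    """Enumerate all 256 corner patterns in canonical id order.

    Deterministic: id k has exactly the corners whose bit is set in k, bits
    assigned in ascending cell order (1, 3, 7, 9, 19, 21, 25, 27).
    """
    patterns = []
    for pid in range(256):
        present = frozenset(
            cell for k, cell in enumerate(CORNER_CELLS) if pid >> k & 1
        )
        patterns.append(CornerPattern(id=pid, present_corners=present))
    return PatternVocabulary(patterns=tuple(patterns))


def match_window(window: np.ndarray, vocab: Optional[PatternVocabulary] = None) -> int:
    """Return the pattern id of a 3×3×3 binary window.

    Only the 8 corner cells are read; all other cells are ignored.
    """
    window = np.asarray(window)
    if window.shape != (3, 3, 3):
        raise ValueError(f"window must be 3x3x3, got shape {window.shape}")
    if not np.all(np.isin(window, (0, 1))):
        raise ValueError("window must be binary")
    pid = 0
    for k, (z, y, x) in enumerate(corner_offsets()):
        if window[z, y, x]:
            pid |= 1 << k
    return pid


@dataclass
class PatternFrequencyVector:
    """256 pattern counts from scanning a binary volume (the 3D-PFV).

    ``sum(counts)`` always equals ``n_windows``, the number of window
    placements over the padded volume.
    """

    counts: np.ndarray
    stride: int
    padded_shape: tuple[int, ...]
    n_windows: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError(f"counts must have length 256, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if int(c.sum()) != self.n_windows:
            raise ValueError(
                f"count conservation violated: sum={int(c.sum())} != n_windows={self.n_windows}"
            )
        self.counts = c

    def to_json(self, vocab: Optional[PatternVocabulary] = None) -> str:
        vocab = vocab or build_vocabulary()
        return json.dumps({vocab[i].name: int(c) for i, c in enumerate(self.counts)})

    def to_row(self, label: str = "") -> list:
        """257-field row (label + 256 counts) for CSV/TSV serialization."""
        return [label] + [int(c) for c in self.counts]


def _pad_to_multiple(a: np.ndarray, multiple: int, pad_value: int) -> np.ndarray:
    pads = [(0, (-s) % multiple) for s in a.shape]
    if any(p[1] for p in pads):
        a = np.pad(a, pads, mode="constant", constant_values=pad_value)
    return a


def extract_pfv(mask: BinaryVolume | np.ndarray, stride: int = 3,
                pad_value: int = 0) -> PatternFrequencyVector:
    """Scan a binary volume with a 3×3×3 window and count corner patterns.

    Each axis is padded up to the next multiple of 3 with ``pad_value``
    (appended at the high end), then the window slides in raster order with
    the given stride; every placement increments the count of the pattern it
    encloses.

    Parameters
    ----------
    mask : BinaryVolume or binary ndarray
    stride : int
        Step between placements along every axis (default 3: non-overlapping).
    pad_value : {0, 1}
        Value used for edge padding (default 0 = background).
    """
    m = mask.voxels if isinstance(mask, BinaryVolume) else np.asarray(mask)
    if m.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {m.shape}")
    if not np.all(np.isin(m, (0, 1))):
        raise ValueError("mask must be binary")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if pad_value not in (0, 1):
        raise ValueError("pad_value must be 0 or 1")

    m = _pad_to_multiple(m.astype(np.uint8), 3, pad_value)
    # window origins along one padded axis of length n: 0, stride, ... while
    # origin + 3 <= n
    ids = np.zeros(tuple((s - 3) // stride + 1 for s in m.shape), dtype=np.int64)
    for k, (dz, dy, dx) in enumerate(corner_offsets()):
        sub = m[dz: m.shape[0] - 2 + dz: stride,
                dy: m.shape[1] - 2 + dy: stride,
                dx: m.shape[2] - 2 + dx: stride]
        ids += sub.astype(np.int64) << k
    counts = np.bincount(ids.ravel(), minlength=256)
    return PatternFrequencyVector(
        counts=counts, stride=stride, padded_shape=m.shape, n_windows=int(ids.size)
    )


def match_window_2d(window: np.ndarray) -> int:
    """Pattern id of a 3×3 binary window from its 8 surrounding cells.

    Bit k corresponds to the k-th direction of ``NEIGHBOR_DIRECTIONS_2D``
    (R, DR, D, DL, L, UL, U, UR); the center cell is ignored.
    """
    window = np.asarray(window)
    if window.shape != (3, 3):
        raise ValueError(f"window must be 3x3, got shape {window.shape}")
    pid = 0
    for k, (dy, dx) in enumerate(_NEIGHBOR_OFFSETS_2D):
        if window[dy, dx]:
            pid |= 1 << k
    return pid


def extract_pfv_2d(slice_mask: np.ndarray, stride: int = 3,
                   pad_value: int = 0) -> PatternFrequencyVector:
    """2D analogue of :func:`extract_pfv` over 3×3 windows.

    The 8 neighbors of the window center, in the direction order
    R, DR, D, DL, L, UL, U, UR, form the occupancy bits — again 2^8 = 256
    configurations indexed by bit pattern.
    """
    m = np.asarray(slice_mask)
    if m.ndim != 2:
        raise ValueError(f"slice mask must be 2D, got shape {m.shape}")
    if not np.all(np.isin(m, (0, 1))):
        raise ValueError("mask must be binary")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    m = _pad_to_multiple(m.astype(np.uint8), 3, pad_value)
    ids = np.zeros(tuple((s - 3) // stride + 1 for s in m.shape), dtype=np.int64)
    for k, (dy, dx) in enumerate(_NEIGHBOR_OFFSETS_2D):
        sub = m[dy: m.shape[0] - 2 + dy: stride,
                dx: m.shape[1] - 2 + dx: stride]
        ids += sub.astype(np.int64) << k
    counts = np.bincount(ids.ravel(), minlength=256)
    return PatternFrequencyVector(
        counts=counts, stride=stride, padded_shape=m.shape, n_windows=int(ids.size)
    )


def pfv_to_feature(pfv: PatternFrequencyVector, normalize: str = "none") -> np.ndarray:
    """Turn a PFV into a 256-length real feature vector.

    normalize : {"none", "l1", "l2"}
        Raw counts, counts/sum, or counts/Euclidean norm.  Pattern order is
        preserved in every case.
    """
    counts = pfv.counts.astype(np.float64)
    if normalize == "none":
        return counts
    if normalize == "l1":
        total = counts.sum()
    elif normalize == "l2":
        total = float(np.linalg.norm(counts))
    else:
        raise ValueError(f"normalize must be one of none/l1/l2, got {normalize!r}")
    if total == 0:
        warnings.warn("normalizing an all-zero pattern frequency vector", stacklevel=2)
        return counts
    return counts / total
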