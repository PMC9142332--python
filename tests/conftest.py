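"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by direct enumeration
(triple loops, per-window predicates) and never call the vectorized code
paths they are used to check.
"""

import numpy as np
import pytest

from pfv3d.patterns import corner_offsets
from pfv3d.wireframe import is_interior


def pfv_oracle(mask: np.ndarray, stride: int = 3, pad_value: int = 0) -> np.ndarray:
    """Naive pattern counting: pad, then triple-loop over window origins."""
    m = np.asarray(mask, dtype=np.uint8)
    pads = [(0, (-s) % 3) for s in m.shape]
    m = np.pad(m, pads, constant_values=pad_value)
    counts = np.zeros(256, dtype=np.int64)
    offsets = corner_offsets()
    for z in range(0, m.shape[0] - 2, stride):
        for y in range(0, m.shape[1] - 2, stride):
            for x in range(0, m.shape[2] - 2, stride):
                pid = 0
                for k, (dz, dy, dx) in enumerate(offsets):
                    if m[z + dz, y + dy, x + dx]:
                        pid |= 1 << k
                counts[pid] += 1
    return counts


def pfv_oracle_2d(mask: np.ndarray, stride: int = 3, pad_value: int = 0) -> np.ndarray:
    """Naive 2D pattern counting over the 8 window neighbors."""
    from pfv3d.patterns import _NEIGHBOR_OFFSETS_2D

    m = np.asarray(mask, dtype=np.uint8)
    pads = [(0, (-s) % 3) for s in m.shape]
    m = np.pad(m, pads, constant_values=pad_value)
    counts = np.zeros(256, dtype=np.int64)
    for y in range(0, m.shape[0] - 2, stride):
        for x in range(0, m.shape[1] - 2, stride):
            pid = 0
            for k, (dy, dx) in enumerate(_NEIGHBOR_OFFSETS_2D):
                if m[y + dy, x + dx]:
                    pid |= 1 << k
            counts[pid] += 1
    return counts


def clap_pass_oracle(mask: np.ndarray) -> np.ndarray:
    """One synchronous deletion pass by direct per-voxel window inspection."""
    m = np.asarray(mask, dtype=np.uint8)
    padded = np.pad(m, 1)
    out = m.copy()
    for z in range(m.shape[0]):
        for y in range(m.shape[1]):
            for x in range(m.shape[2]):
                if not m[z, y, x]:
                    continue
                window = padded[z:z + 3, y:y + 3, x:x + 3]
                if is_interior(window):
                    out[z, y, x] = 0
    return out


def clap_oracle(mask: np.ndarray, max_iterations: int = 100) -> np.ndarray:
    m = np.asarray(mask, dtype=np.uint8)
    for _ in range(max_iterations):
        nxt = clap_pass_oracle(m)
        if np.array_equal(nxt, m):
            break
        m = nxt
    return m


def median_filter_oracle(data: np.ndarray, initial: int, maximum: int) -> np.ndarray:
    """Per-voxel two-stage adaptive median with edge-including reflect padding."""
    out = np.empty_like(data)
    for z in range(data.shape[0]):
        for y in range(data.shape[1]):
            for x in range(data.shape[2]):
                w = initial
                while True:
                    h = w // 2
                    pad = np.pad(data, h, mode="symmetric")
                    block = pad[z:z + w, y:y + w, x:x + w]
                    zmin, zmax = block.min(), block.max()
                    zmed = np.median(block)
                    if zmin < zmed < zmax:
                        v = data[z, y, x]
                        out[z, y, x] = v if zmin < v < zmax else zmed
                        break
                    if w >= maximum:
                        out[z, y, x] = zmed
                        break
                    w += 2
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
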