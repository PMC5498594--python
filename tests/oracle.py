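"""Brute-force reference implementation of the interruption detector.

Deliberately written with explicit offset loops and shift-based set
operations only — no morphology routines shared with the package — so it
is an independent check of the dilation/selection/reconstruction pipeline.
"""

from __future__ import annotations

import numpy as np


def _shift(a: np.ndarray, off, fill=False) -> np.ndarray:
    """Translate a boolean grid by an integer offset, filling exposed cells."""
    out = np.full_like(a, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(off):
        if o > 0:
            src[ax], dst[ax] = slice(0, a.shape[ax] - o), slice(o, None)
        elif o < 0:
            src[ax], dst[ax] = slice(-o, None), slice(0, a.shape[ax] + o)
    out[tuple(dst)] = a[tuple(src)]
    return out


def diamond_offsets(k: int):
    return [
        (dz, dy, dx)
        for dz in range(-k, k + 1)
        for dy in range(-k, k + 1)
        for dx in range(-k, k + 1)
        if abs(dz) + abs(dy) + abs(dx) <= k
    ]


def box_offsets():
    return [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]


def label26(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components by flood fill over the 26-neighborhood."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    offs = box_offsets()
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offs:
                p = (z + dz, y + dy, x + dx)
                if (
                    0 <= p[0] < mask.shape[0]
                    and 0 <= p[1] < mask.shape[1]
                    and 0 <= p[2] < mask.shape[2]
                    and mask[p]
                    and not labels[p]
                ):
                    labels[p] = current
                    stack.append(p)
    return labels, current


def adjacent26(mask: np.ndarray) -> np.ndarray:
    """Voxels 26-adjacent to (or inside) the mask."""
    out = mask.copy()
    for off in box_offsets():
        out |= _shift(mask, off)
    return out


def detect_oracle(bone: np.ndarray, region: np.ndarray, k: int) -> np.ndarray:
    """Labeled interruptions: opening-style erosion of the void by the
    k-step diamond, two-boundary selection, geodesic reconstruction."""
    cortical = region == 1
    interior = region == 2
    outside = region == 0
    void = cortical & ~bone

    # erosion of the bone-free phase: no bone within L1 distance k
    no_bone_near = np.ones_like(bone)
    for off in diamond_offsets(k):
        no_bone_near &= ~_shift(bone, off)
    remaining = void & no_bone_near

    labels, n = label26(remaining)
    near_out = adjacent26(outside)
    near_in = adjacent26(interior)
    seeds = np.zeros_like(remaining)
    for lab in range(1, n + 1):
        comp = labels == lab
        if (comp & near_out).any() and (comp & near_in).any():
            seeds |= comp

    # geodesic reconstruction inside the original void by repeated growth
    recon = seeds & void
    while True:
        grown = adjacent26(recon) & void
        if (grown == recon).all():
            break
        recon = grown
    out, _ = label26(recon)
    return out
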