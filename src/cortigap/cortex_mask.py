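"""Constant-thickness cortical mask with periosteal/endosteal layers.

The cortical region is the rind of the filled periosteal mask: the mask
minus its morphological erosion by ``thickness_voxels`` single-voxel steps
(face-connected cross by default, so a thickness of 4 voxels means 4
one-voxel erosions). The thickness is constant per modality — e.g. 4 voxels
(0.328 mm) on an 0.082 mm grid and 18 voxels (0.324 mm) on an 0.018 mm
grid — which is robust but introduces a known systematic error where the
true cortex is thinner or thicker than the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cortigap.errors import ConfigError, DegenerateMaskWarning
from cortigap.segmentation import PeriostealMask

OUTSIDE, CORTICAL, INTERIOR = 0, 1, 2

_CROSS = ndimage.generate_binary_structure(3, 1)  # face-connected (6-neighborhood)
_BALL_CACHE: dict[int, np.ndarray] = {}
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _euclidean_ball(radius: int) -> np.ndarray:
    if radius not in _BALL_CACHE:
        ax = np.arange(-radius, radius + 1)
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        _BALL_CACHE[radius] = zz**2 + yy**2 + xx**2 <= radius**2
    return _BALL_CACHE[radius]


@dataclass
class CorticalMask:
    """Ternary region grid {outside, cortical, interior} plus boundary layers.

    ``periosteal_layer`` is the outermost cortical shell (26-adjacent to
    outside); ``endosteal_layer`` the innermost shell (26-adjacent to the
    trabecular interior). Both are subsets of the cortical region.
    """

    region: np.ndarray
    thickness_voxels: int
    periosteal_layer: np.ndarray
    endosteal_layer: np.ndarray
    voxel_size_mm: float

    @property
    def cortical(self) -> np.ndarray:
        return self.region == CORTICAL

    @property
    def interior(self) -> np.ndarray:
        return self.region == INTERIOR

    @property
    def outside(self) -> np.ndarray:
        return self.region == OUTSIDE


def build_cortical_mask(
    mask: PeriostealMask,
    thickness_mm: float,
    element: str = "cross",
) -> CorticalMask:
    """Erode the filled periosteal mask to delimit a constant-thickness cortex.

    ``thickness_voxels = round(thickness_mm / voxel_size_mm)``; the erosion
    uses ``thickness_voxels`` iterations of the face-connected cross
    (``element='cross'``, canonical) or a single Euclidean ball of that
    radius (``element='ball'``).
    """
    voxel = mask.voxel_size_mm
    if thickness_mm < voxel:
        raise ConfigError(
            f"thickness {thickness_mm} mm is below one voxel ({voxel} mm)"
        )
    tv = int(round(thickness_mm / voxel))
    inside = mask.inside
    # border_value=1: scans crop the anatomy, so beyond-volume counts as
    # inside and no artificial rind forms at the field-of-view faces
    if element == "cross":
        interior = ndimage.binary_erosion(inside, _CROSS, iterations=tv, border_value=1)
    elif element == "ball":
        interior = ndimage.binary_erosion(inside, _euclidean_ball(tv), border_value=1)
    else:
        raise ConfigError(f"unknown structuring element {element!r}")
    if not interior.any():
        warnings.warn(
            f"{tv}-voxel erosion emptied the interior; object thinner than "
            f"2 x {thickness_mm} mm",
            DegenerateMaskWarning,
            stacklevel=2,
        )
    region = np.zeros(inside.shape, dtype=np.int8)
    region[inside] = CORTICAL
    region[interior] = INTERIOR

    cortical = region == CORTICAL
    outside = ~inside
    periosteal = cortical & ndimage.binary_dilation(outside, _STRUCT26)
    endosteal = cortical & ndimage.binary_dilation(interior, _STRUCT26)
    return CorticalMask(region, tv, periosteal, endosteal, voxel)
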