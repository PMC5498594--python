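"""Shared fixtures: analytic phantoms and slab geometries built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cortigap.phantom import Hole, PhantomSpec, generate_phantom
from cortigap.registration_matching import RigidTransform
from cortigap.segmentation import BoneSegmentation, PeriostealMask
from cortigap.cortex_mask import build_cortical_mask

#: hole diameters chosen so every tested cut-off k in {1,2,3} on the
#: 0.082 mm grid has one hole safely above (d >= 2k+1.5 voxels, so a
#: diamond of radius k fits at any rasterization phase) and one safely
#: below (d <= 2k voxels) its exclusive 2k-voxel bound
LADDER_DIAMETERS_MM = (0.14, 0.30, 0.46, 0.65)


def ladder_spec(**overrides) -> PhantomSpec:
    holes = [
        Hole((0.0, -0.7), LADDER_DIAMETERS_MM[0]),
        Hole((90.0, 0.0), LADDER_DIAMETERS_MM[1]),
        Hole((180.0, 0.6), LADDER_DIAMETERS_MM[2]),
        Hole((270.0, -0.2), LADDER_DIAMETERS_MM[3]),
    ]
    return PhantomSpec(holes=holes, **overrides)


@pytest.fixture(scope="session")
def clean_ladder_phantom():
    """Noise-free, unit-supersampled tube pair: exact two-level voxelization."""
    return generate_phantom(ladder_spec(noise_sd=0.0, supersample_factor=1, seed=1))


@pytest.fixture(scope="session")
def noisy_pair_table():
    """Full two-modality experiment on one seeded noisy misaligned pair."""
    from cortigap.pipeline import phantom_pair_experiment

    spec = ladder_spec(
        seed=7,
        transform=RigidTransform.from_euler_deg((2.0, 0.0, 0.0), (0.10, 0.15, -0.08)),
    )
    return phantom_pair_experiment(spec, ks=(1, 2, 3))


def slab_geometry(hole_specs, nz=16, ny=40, nx=40, voxel=0.082, cortex_top=3, cortex_thickness=9):
    """A cortex slab on top of marrow, pierced by vertical channels.

    ``hole_specs``: list of (cy, cx, radius_voxels, depth_voxels|None);
    depth None means a through hole. Returns (seg, cmask).
    """
    inside = np.zeros((nz, ny, nx), bool)
    inside[cortex_top:] = True  # slab plus marrow down to the lower border
    bone = np.zeros_like(inside)
    bone[cortex_top:cortex_top + cortex_thickness] = True
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for cy, cx, r, depth in hole_specs:
        circle = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        z_hi = cortex_top + (cortex_thickness if depth is None else depth)
        bone[cortex_top:z_hi, circle] = False
    mask = PeriostealMask(inside, voxel)
    cmask = build_cortical_mask(mask, cortex_thickness * voxel)
    seg = BoneSegmentation(bone, voxel, "lowres", 0.0, mask)
    seg.bvtv = seg.recompute_bvtv()
    return seg, cmask
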