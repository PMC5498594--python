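"""Reading and writing 3D volumes with isotropic voxel-size metadata.

One internal geometry convention is enforced everywhere: arrays are indexed
``(z, y, x)`` = (slice, row, column), coordinates are voxel-center based and
0-indexed, and the voxel size is a single isotropic length in millimetres.
Every supported on-disk format is converted to this convention on load.

Supported formats: NIfTI (via nibabel), MetaImage (via SimpleITK), multipage
TIFF with a JSON sidecar carrying the spacing, and raw binary with a JSON
header. Scanner-native formats (AIM/ISQ) are not parsed; convert externally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from cortigap.errors import LabelGapError, MetadataError, UnsupportedGeometryError

#: relative tolerance when asserting spacing isotropy on load
ISOTROPY_RTOL = 1e-3

_FORMATS = ("nifti", "metaimage", "tiff_stack", "raw")


def _validate_geometry(data: np.ndarray, voxel_size_mm: float) -> None:
    if data.ndim != 3 or min(data.shape) < 1:
        raise UnsupportedGeometryError(f"expected a 3D grid, got shape {data.shape}")
    if not np.isfinite(voxel_size_mm) or voxel_size_mm <= 0:
        raise MetadataError(f"voxel size must be a positive length in mm, got {voxel_size_mm!r}")


@dataclass
class GrayVolume:
    """A 3D scalar grid with isotropic voxel size.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities in arbitrary units, axis order (z, y, x).
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    origin_mm : ndarray, shape (3,)
        World position of the center of voxel (0, 0, 0), in (z, y, x) order.
    """

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        _validate_geometry(self.data, self.voxel_size_mm)
        if self.origin_mm.shape != (3,):
            raise MetadataError("origin_mm must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other: "GrayVolume | LabelVolume") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.voxel_size_mm, other.voxel_size_mm, rtol=ISOTROPY_RTOL)
            and np.allclose(self.origin_mm, other.origin_mm, atol=1e-6)
        )


@dataclass
class LabelVolume:
    """A 3D non-negative integer label grid; 0 is background, labels 1..K."""

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        _validate_geometry(self.data, self.voxel_size_mm)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise MetadataError(f"label data must be integer, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise MetadataError("labels must be non-negative")

    @property
    def labels_present(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        u = np.unique(self.data)
        return u[u > 0]

    @property
    def is_contiguous(self) -> bool:
        lab = self.labels_present
        return lab.size == 0 or (lab[0] == 1 and lab[-1] == lab.size)

    same_geometry = GrayVolume.same_geometry


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if name.endswith(".raw"):
        return "raw"
    raise MetadataError(f"cannot infer volume format from file name {path.name!r}")


def _check_isotropic(spacing_mm) -> float:
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.size != 3:
        raise MetadataError(f"expected 3 spacing values, got {spacing!r}")
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise MetadataError(f"voxel spacing must be positive, got {tuple(spacing)}")
    if np.ptp(spacing) > ISOTROPY_RTOL * spacing.mean():
        raise UnsupportedGeometryError(
            f"anisotropic voxel spacing {tuple(spacing)} is not supported; resample externally"
        )
    return float(spacing.mean())


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing JSON sidecar {sidecar} declaring voxel_size_mm")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "voxel_size_mm" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks 'voxel_size_mm'")
    return meta


def read_volume(path, format: str | None = None) -> GrayVolume:
    """Read a 3D grayscale volume into the internal (z, y, x) convention.

    Parameters
    ----------
    path : path-like
        Input file. For ``tiff_stack`` and ``raw`` a JSON sidecar with the
        same stem must declare ``voxel_size_mm``.
    format : {'nifti', 'metaimage', 'tiff_stack', 'raw'}, optional
        Explicit format; inferred from the extension when omitted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise MetadataError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if fmt == "nifti":
        img = nib.load(str(path))
        voxel = _check_isotropic(img.header.get_zooms()[:3])
        # nibabel arrays are (x, y, z); flip to (z, y, x)
        data = np.ascontiguousarray(np.asanyarray(img.dataobj).T)
        origin = np.asarray(img.affine[:3, 3], dtype=float)[::-1]
        return GrayVolume(data, voxel, origin)

    if fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        voxel = _check_isotropic(img.GetSpacing())
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        origin = np.asarray(img.GetOrigin(), dtype=float)[::-1]
        return GrayVolume(data, voxel, origin)

    if fmt == "tiff_stack":
        meta = _read_sidecar(path)
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        voxel = _check_isotropic([meta["voxel_size_mm"]] * 3)
        origin = np.asarray(meta.get("origin_mm", (0.0, 0.0, 0.0)), dtype=float)
        return GrayVolume(data, voxel, origin)

    # raw binary + JSON header
    meta = _read_sidecar(path)
    for key in ("shape", "dtype"):
        if key not in meta:
            raise MetadataError(f"raw-format sidecar lacks {key!r}")
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    voxel = _check_isotropic([meta["voxel_size_mm"]] * 3)
    origin = np.asarray(meta.get("origin_mm", (0.0, 0.0, 0.0)), dtype=float)
    return GrayVolume(data, voxel, origin)


def _write_array(data: np.ndarray, voxel: float, origin: np.ndarray, path: Path, fmt: str) -> None:
    if fmt == "nifti":
        affine = np.diag([voxel, voxel, voxel, 1.0])
        affine[:3, 3] = origin[::-1]
        nib.save(nib.Nifti1Image(np.ascontiguousarray(data.T), affine), str(path))
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((voxel,) * 3)
        img.SetOrigin(tuple(float(v) for v in origin[::-1]))
        sitk.WriteImage(img, str(path))
    elif fmt == "tiff_stack":
        tifffile.imwrite(str(path), data, photometric="minisblack")
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"voxel_size_mm": voxel, "origin_mm": list(map(float, origin))}, fh)
    elif fmt == "raw":
        np.ascontiguousarray(data).tofile(path)
        with open(_sidecar_path(path), "w") as fh:
            json.dump(
                {
                    "shape": list(data.shape),
                    "dtype": data.dtype.name,
                    "voxel_size_mm": voxel,
                    "origin_mm": list(map(float, origin)),
                },
                fh,
            )
    else:
        raise MetadataError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_volume(vol: GrayVolume, path, format: str | None = None) -> None:
    """Write a GrayVolume; the inverse of :func:`read_volume`."""
    path = Path(path)
    _write_array(vol.data, float(vol.voxel_size_mm), vol.origin_mm, path, format or _infer_format(path))


def write_labels(labels: LabelVolume, path, format: str | None = None, gap_policy: str = "renumber") -> None:
    """Write an integer label volume losslessly.

    Labels must be contiguous 1..K. When they are not, ``gap_policy``
    decides: ``'renumber'`` (default) compacts them with a warning,
    ``'error'`` raises :class:`LabelGapError`.
    """
    if gap_policy not in ("renumber", "error"):
        raise MetadataError(f"gap_policy must be 'renumber' or 'error', got {gap_policy!r}")
    data = labels.data
    if not labels.is_contiguous:
        if gap_policy == "error":
            raise LabelGapError(f"labels {labels.labels_present.tolist()} are not contiguous 1..K")
        warnings.warn("non-contiguous labels renumbered on write", stacklevel=2)
        present = labels.labels_present
        lut = np.zeros(int(present[-1]) + 1, dtype=data.dtype)
        lut[present] = np.arange(1, present.size + 1, dtype=data.dtype)
        data = lut[data]
    path = Path(path)
    _write_array(data, float(labels.voxel_size_mm), labels.origin_mm, path, format or _infer_format(path))


def read_labels(path, format: str | None = None) -> LabelVolume:
    """Read an integer label volume written by :func:`write_labels`."""
    vol = read_volume(path, format=format)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise MetadataError("file does not contain integer labels")
        data = rounded.astype(np.int32)
    return LabelVolume(data, vol.voxel_size_mm, vol.origin_mm)
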