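"""Core volumetric containers, NIfTI-1 I/O, and the atlas reference space.

Conventions
-----------
* Voxel indices are 0-based; world coordinates are in millimetres on a
  RAS-like axis order. All grids produced by this package are axis aligned
  with positive spacing on the affine diagonal.
* Displacement fields store millimetre displacements along the world axes
  in a 4-D array whose last axis has the 3 vector components; they are
  written as 4-D NIfTI volumes of shape (X, Y, Z, 3).
* Label volumes are unsigned integers with a sidecar TSV (``id<TAB>name``)
  next to the NIfTI file.

The packaged atlas reference space is a 181 x 217 x 180 grid at 1 mm
isotropic resolution with the world origin (anterior commissure) at voxel
(90, 126, 72); :func:`atlas_reference_space` returns it.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ParameterError, SpaceError, VolumeFormatError

__all__ = [
    "SpaceDef",
    "Volume",
    "LabelVolume",
    "TissueMaps",
    "DeformationField",
    "TISSUE_CLASSES",
    "make_reference_space",
    "atlas_reference_space",
    "read_volume",
    "write_volume",
    "read_space",
    "write_space",
    "resample_to_spacing",
]

#: Canonical tissue-class order used throughout the package. Hard labels use
#: 1=CSF, 2=GM, 3=WM with 0 background; argmax ties break to the lower index.
TISSUE_CLASSES = ("CSF", "GM", "WM")


@dataclass(frozen=True)
class SpaceDef:
    """An axis-aligned voxel grid: dimensions, spacing (mm) and the voxel
    index that sits at the world origin (the anterior commissure for the
    packaged atlas space)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin_voxel: tuple[int, int, int]

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(int(o) for o in self.origin_voxel)
        if len(dims) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ParameterError("SpaceDef needs 3-vectors for dims, spacing, origin")
        if any(d <= 0 for d in dims):
            raise ParameterError(f"dims must be positive, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing must be positive, got {spacing}")
        if any(not (0 <= o < d) for o, d in zip(origin, dims)):
            raise ParameterError(
                f"origin_voxel {origin} outside grid of dims {dims}"
            )
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin_voxel", origin)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world map; world origin lands on ``origin_voxel``."""
        aff = np.eye(4)
        for i in range(3):
            aff[i, i] = self.spacing[i]
            aff[i, 3] = -self.spacing[i] * self.origin_voxel[i]
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * np.array(self.spacing) + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.affine[:3, 3]) / np.array(self.spacing)

    @property
    def center_world(self) -> np.ndarray:
        """World coordinate of the grid centre."""
        return self.voxel_to_world((np.array(self.dims) - 1) / 2.0)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.dims, dtype=np.float32)


def make_reference_space(dims, spacing_mm, origin_voxel) -> SpaceDef:
    """Build a :class:`SpaceDef`; raises on an origin outside the grid."""
    return SpaceDef(tuple(dims), tuple(spacing_mm), tuple(origin_voxel))


def atlas_reference_space() -> SpaceDef:
    """Full-resolution atlas space: 181x217x180 voxels, 1 mm isotropic,
    anterior commissure at voxel (90, 126, 72)."""
    return make_reference_space((181, 217, 180), (1.0, 1.0, 1.0), (90, 126, 72))


def _space_from_affine(shape, affine) -> SpaceDef:
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    origin = -affine[:3, 3] / np.array(spacing)
    origin_v = tuple(int(np.clip(round(o), 0, d - 1)) for o, d in zip(origin, shape))
    return SpaceDef(tuple(int(s) for s in shape[:3]), spacing, origin_v)


@dataclass
class Volume:
    """A 3-D scalar image with its voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"Volume data must be 3-D, got shape {self.data.shape}"
            )
        if any(d < 8 for d in self.data.shape):
            raise VolumeFormatError(
                f"Volume dimensions must be >= 8 per axis, got {self.data.shape}"
            )
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise VolumeFormatError("Volume affine is not invertible")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def space(self) -> SpaceDef:
        return _space_from_affine(self.data.shape, self.affine)

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.affine.copy())


@dataclass
class LabelVolume:
    """An integer label image plus its id -> region-name table (0 = background)."""

    data: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeFormatError("LabelVolume data must have integer dtype")
        if self.data.min() < 0:
            raise VolumeFormatError("LabelVolume ids must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"LabelVolume data must be 3-D, got shape {self.data.shape}"
            )
        present = set(int(v) for v in np.unique(self.data)) - {0}
        if not self.label_table:
            self.label_table = {i: f"region_{i}" for i in sorted(present)}
        missing = present - set(self.label_table)
        if missing:
            raise VolumeFormatError(
                f"labels {sorted(missing)} present in volume but not in label_table"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def space(self) -> SpaceDef:
        return _space_from_affine(self.data.shape, self.affine)

    def copy_with(self, data: np.ndarray) -> "LabelVolume":
        return LabelVolume(np.asarray(data), self.affine.copy(), dict(self.label_table))


#: A parcellation is simply a LabelVolume whose table names anatomical regions.
ParcellationMap = LabelVolume


@dataclass
class TissueMaps:
    """Per-voxel CSF/GM/WM probabilities plus the brain mask.

    Inside the mask the three class probabilities sum to 1 (to 1e-6); they
    are identically zero outside it.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        if tuple(self.maps.keys()) != TISSUE_CLASSES:
            self.maps = {k: self.maps[k] for k in TISSUE_CLASSES}
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)

    @classmethod
    def from_stack(cls, stack: np.ndarray, mask: np.ndarray, affine) -> "TissueMaps":
        """``stack`` has shape (3, X, Y, Z) in CSF/GM/WM order."""
        maps = {k: np.asarray(stack[i], dtype=np.float32) for i, k in enumerate(TISSUE_CLASSES)}
        tm = cls(maps, mask, affine)
        tm.renormalise()
        return tm

    @property
    def stack(self) -> np.ndarray:
        return np.stack([self.maps[k] for k in TISSUE_CLASSES])

    @property
    def space(self) -> SpaceDef:
        return _space_from_affine(self.mask.shape, self.affine)

    def renormalise(self) -> None:
        """Clip to [0, 1], renormalise to sum 1 inside the mask, zero outside."""
        s = self.stack.astype(np.float64)
        s = np.clip(s, 0.0, None)
        tot = s.sum(axis=0)
        inside = self.mask & (tot > 0)
        for i, k in enumerate(TISSUE_CLASSES):
            m = np.zeros(self.mask.shape, dtype=np.float32)
            m[inside] = (s[i][inside] / tot[inside]).astype(np.float32)
            # mask voxels with zero total get a uniform split
            dead = self.mask & ~inside
            m[dead] = 1.0 / len(TISSUE_CLASSES)
            self.maps[k] = m

    def validate(self) -> None:
        s = self.stack
        if s.min() < -1e-6 or s.max() > 1 + 1e-6:
            raise ParameterError("tissue probabilities outside [0, 1]")
        tot = s.sum(axis=0)
        if self.mask.any() and not np.allclose(tot[self.mask], 1.0, atol=1e-5):
            raise ParameterError("tissue probabilities do not sum to 1 in mask")
        if (~self.mask).any() and np.abs(tot[~self.mask]).max() > 1e-6:
            raise ParameterError("tissue probabilities nonzero outside mask")

    def hard(self) -> LabelVolume:
        """Argmax labels (1=CSF, 2=GM, 3=WM; ties -> lower class index)."""
        lab = np.zeros(self.mask.shape, dtype=np.uint8)
        s = self.stack
        lab[self.mask] = np.argmax(s[:, self.mask], axis=0).astype(np.uint8) + 1
        return LabelVolume(lab, self.affine.copy(), {1: "CSF", 2: "GM", 3: "WM"})

    @classmethod
    def from_hard(cls, labels: LabelVolume) -> "TissueMaps":
        """One-hot tissue maps from a 1/2/3 label image."""
        mask = labels.data > 0
        stack = np.stack([(labels.data == i + 1).astype(np.float32) for i in range(3)])
        return cls.from_stack(stack, mask, labels.affine)


@dataclass
class DeformationField:
    """Dense displacement (mm along world axes) on an axis-aligned grid.

    ``disp`` has shape (X, Y, Z, 3). The field lives on the FIXED/target
    grid and is applied by pull-back: warping image I by field u yields
    I(x + u(x)) sampled at every target voxel x.
    """

    disp: np.ndarray
    space: SpaceDef

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=np.float32)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise VolumeFormatError(
                f"DeformationField must be (X, Y, Z, 3), got {self.disp.shape}"
            )
        if tuple(self.disp.shape[:3]) != tuple(self.space.dims):
            raise SpaceError("field shape does not match its SpaceDef dims")
        if not np.all(np.isfinite(self.disp)):
            raise VolumeFormatError("DeformationField contains non-finite values")

    @classmethod
    def zero(cls, space: SpaceDef) -> "DeformationField":
        return cls(np.zeros(tuple(space.dims) + (3,), dtype=np.float32), space)

    @property
    def disp_voxels(self) -> np.ndarray:
        """Displacement in voxel units per axis."""
        return self.disp / np.array(self.space.spacing, dtype=np.float32)

    def magnitude_mm(self) -> np.ndarray:
        return np.linalg.norm(self.disp, axis=-1)

    def mean_magnitude_voxels(self) -> float:
        return float(np.linalg.norm(self.disp_voxels, axis=-1).mean())


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def _sidecar_path(path: str) -> str:
    base = path
    for ext in (".nii.gz", ".nii"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    return base + ".labels.tsv"


def write_volume(obj, path: str) -> None:
    """Write a Volume / LabelVolume / DeformationField as NIfTI-1.

    Integer data round-trips bit-exactly; floats are stored as float32.
    Label tables go to an ``<name>.labels.tsv`` sidecar.
    """
    if isinstance(obj, DeformationField):
        img = nib.Nifti1Image(np.asarray(obj.disp, dtype=np.float32), obj.space.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)
        return
    if isinstance(obj, LabelVolume):
        data = np.asarray(obj.data)
        dtype = np.uint16 if data.max() < 2**16 else np.uint32
        img = nib.Nifti1Image(data.astype(dtype), obj.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)
        with open(_sidecar_path(path), "w") as fh:
            fh.write("id\tname\n")
            for k in sorted(obj.label_table):
                fh.write(f"{k}\t{obj.label_table[k]}\n")
        return
    if isinstance(obj, Volume):
        img = nib.Nifti1Image(np.asarray(obj.data, dtype=np.float32), obj.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)
        return
    raise ParameterError(f"cannot write object of type {type(obj).__name__}")


def read_volume(path: str, expect: str | None = None):
    """Read a NIfTI-1 file; returns a :class:`Volume`, :class:`LabelVolume`
    or :class:`DeformationField` depending on dtype and dimensionality.

    4-D files must have exactly 3 components on the last axis (displacement
    fields). Integer 3-D files become LabelVolumes, with the sidecar TSV
    label table loaded when present. ``expect`` in {"volume", "labels",
    "field"} forces an interpretation and errors on mismatch.
    """
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises various types on bad files
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    affine = img.affine
    if data.ndim == 4:
        if expect in ("volume", "labels"):
            raise VolumeFormatError(
                f"{path}: expected a 3-D {expect} image, got 4-D shape {data.shape}"
            )
        if data.shape[-1] != 3:
            raise VolumeFormatError(
                f"{path}: 4-D image must have 3 components, got shape {data.shape}"
            )
        space = _space_from_affine(data.shape[:3], affine)
        return DeformationField(data.astype(np.float32), space)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D data, got shape {data.shape}")
    if expect == "field":
        raise VolumeFormatError(f"{path}: expected a 4-D displacement field")
    is_int = np.issubdtype(data.dtype, np.integer)
    if expect == "labels" or (expect is None and is_int):
        table: dict[int, str] = {}
        side = _sidecar_path(path)
        if os.path.exists(side):
            with open(side) as fh:
                next(fh)  # header
                for line in fh:
                    i, name = line.rstrip("\n").split("\t", 1)
                    table[int(i)] = name
        return LabelVolume(data.astype(np.int64), affine, table)
    return Volume(data.astype(np.float32), affine)


def write_space(space: SpaceDef, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "dims": list(space.dims),
                "spacing_mm": list(space.spacing),
                "origin_voxel": list(space.origin_voxel),
            },
            fh,
            indent=2,
        )


def read_space(path: str) -> SpaceDef:
    with open(path) as fh:
        d = json.load(fh)
    return SpaceDef(tuple(d["dims"]), tuple(d["spacing_mm"]), tuple(d["origin_voxel"]))


# ---------------------------------------------------------------------------
# Resampling


def resample_to_spacing(vol, spacing_mm, interp: str = "trilinear"):
    """Resample a Volume or LabelVolume to a new isotropic/anisotropic
    spacing, preserving the world position of voxel (0,0,0) and the world
    extent to within one output voxel.

    ``interp`` is "trilinear" for intensities or "nearest" for labels.
    """
    spacing_mm = tuple(float(s) for s in np.atleast_1d(spacing_mm).repeat(3)[:3]) \
        if np.isscalar(spacing_mm) or len(np.atleast_1d(spacing_mm)) == 1 \
        else tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in spacing_mm):
        raise ParameterError(f"spacing must be positive, got {spacing_mm}")
    if interp not in ("trilinear", "nearest"):
        raise ParameterError(f"interp must be trilinear|nearest, got {interp!r}")
    old_spacing = np.array(vol.spacing)
    new_spacing = np.array(spacing_mm)
    old_dims = np.array(vol.data.shape)
    new_dims = np.maximum(1, np.round(old_dims * old_spacing / new_spacing)).astype(int)
    # output voxel i samples input at i * new/old (corner-aligned)
    matrix = np.diag(new_spacing / old_spacing)
    order = 1 if interp == "trilinear" else 0
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=np.float64),
        matrix,
        output_shape=tuple(new_dims),
        order=order,
        mode="nearest",
    )
    new_affine = vol.affine.copy()
    for i in range(3):
        new_affine[:3, i] = vol.affine[:3, i] / old_spacing[i] * new_spacing[i]
    if isinstance(vol, LabelVolume):
        return LabelVolume(np.round(out).astype(vol.data.dtype), new_affine,
                           dict(vol.label_table))
    return Volume(out.astype(np.float32), new_affine)
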