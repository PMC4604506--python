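"""Voxel-grid data model and NIfTI I/O.

All downstream analysis (resection estimation, VOI construction, PET
asymmetry classification) operates on four container types sharing a common
voxel geometry:

``VoxelGrid``
    shape, voxel size and the NIfTI affine mapping 0-based voxel indices to
    world millimetre coordinates (RAS+).
``LabelVolume``
    one integer anatomical label per voxel (0 = background) plus a label
    dictionary mapping ids to (structure name, hemisphere).
``BinaryMask``
    a set of voxels; the unit of all set algebra in the pipeline.
``PETVolume``
    static or multi-frame tracer uptake (FDG or FMZ).

Volumes are compared and combined voxel-by-voxel, so every operation first
requires its operands to live on the same grid; re-slicing everything to a
common 1 mm isotropic grid is the caller's job (see :func:`resample_isotropic`
and :func:`apply_rigid`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

Hemisphere = Literal["left", "right", "none"]
Tracer = Literal["FDG", "FMZ"]

__all__ = [
    "VoxelGrid",
    "LabelVolume",
    "BinaryMask",
    "PETVolume",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "read_label_table",
    "write_label_table",
    "resample_isotropic",
    "apply_rigid",
    "resample_pet_to_grid",
    "volume_mm3",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Shared voxel geometry: shape, isotropic-or-not voxel size, affine."""

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        object.__setattr__(self, "affine", aff)
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine must be invertible")

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 1.0) -> "VoxelGrid":
        """Axis-aligned RAS+ grid with cubic voxels and origin at index (0,0,0)."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(shape=tuple(shape), voxel_size_mm=(voxel_mm,) * 3, affine=aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def __eq__(self, other: object) -> bool:  # affine is an array -> custom eq
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return self.same_geometry(other)

    def __hash__(self) -> int:
        return hash((self.shape, self.voxel_size_mm))


def _require_same_grid(a: VoxelGrid, b: VoxelGrid, what: str = "operands") -> None:
    if not a.same_geometry(b):
        raise ValueError(f"{what} must share a voxel grid (shape/affine mismatch)")


@dataclass
class LabelVolume:
    """Integer anatomical labels on a grid plus a bilateral label dictionary.

    ``label_map`` maps each label id to ``(structure_name, hemisphere)``.
    Every labelled structure of one hemisphere is expected to have a homotopic
    partner on the other, which the asymmetry method relies on;
    :meth:`validate` checks this.
    """

    grid: VoxelGrid
    data: np.ndarray
    label_map: dict[int, tuple[str, Hemisphere]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer-valued")
        if self.data.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")

    def validate(self, require_homotopic: bool = True) -> None:
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels present in volume but not in label_map: {sorted(missing)}")
        if require_homotopic:
            by_name: dict[str, set[Hemisphere]] = {}
            for _, (name, hemi) in self.label_map.items():
                by_name.setdefault(name, set()).add(hemi)
            unpaired = [
                n for n, h in by_name.items()
                if h != {"none"} and h != {"left", "right"}
            ]
            if unpaired:
                raise ValueError(f"structures without a homotopic partner: {sorted(unpaired)}")

    def ids_for(self, names: list[str] | set[str], side: Hemisphere) -> list[int]:
        """Label ids of the given structures on the given hemisphere."""
        wanted = set(names)
        ids = [i for i, (n, h) in self.label_map.items() if n in wanted and h == side]
        found = {self.label_map[i][0] for i in ids}
        missing = wanted - found
        if missing:
            raise KeyError(f"structures missing on side {side!r}: {sorted(missing)}")
        return sorted(ids)

    def structure_mask(self, names: list[str] | set[str], side: Hemisphere) -> "BinaryMask":
        ids = self.ids_for(names, side)
        return BinaryMask(self.grid, np.isin(self.data, ids))


@dataclass
class BinaryMask:
    """A set of voxels on a grid; supports |, &, -, ^ between same-grid masks."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise ValueError("mask array shape does not match grid")

    def _binop(self, other: "BinaryMask", op) -> "BinaryMask":
        _require_same_grid(self.grid, other.grid, "mask set operations")
        return BinaryMask(self.grid, op(self.data, other.data))

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return self._binop(other, np.logical_or)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return self._binop(other, np.logical_and)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        return self._binop(other, lambda a, b: a & ~b)

    def __xor__(self, other: "BinaryMask") -> "BinaryMask":
        return self._binop(other, np.logical_xor)

    def issubset(self, other: "BinaryMask") -> bool:
        _require_same_grid(self.grid, other.grid, "mask comparison")
        return bool(np.all(~self.data | other.data))

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def empty_like(self) -> "BinaryMask":
        return BinaryMask(self.grid, np.zeros(self.grid.shape, dtype=bool))


@dataclass
class PETVolume:
    """Tracer uptake on a grid; one frame (static) or several (dynamic).

    ``data`` is ``(x, y, z)`` for a static volume or ``(n_frames, x, y, z)``
    for a dynamic one, with ``frame_times_s`` holding the (start, end) of each
    frame in seconds.
    """

    grid: VoxelGrid
    data: np.ndarray
    tracer: Tracer = "FDG"
    frame_times_s: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            if self.data.shape != self.grid.shape:
                raise ValueError("PET array shape does not match grid")
        elif self.data.ndim == 4:
            if self.data.shape[1:] != self.grid.shape:
                raise ValueError("PET frame shape does not match grid")
            if self.frame_times_s is None or len(self.frame_times_s) != self.data.shape[0]:
                raise ValueError("dynamic PET requires one (start, end) per frame")
            prev_end = -np.inf
            for start, end in self.frame_times_s:
                if not (end > start >= prev_end):
                    raise ValueError("frame intervals must be increasing and non-overlapping")
                prev_end = end
        else:
            raise ValueError("PET data must be 3-D (static) or 4-D (dynamic)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PET uptake contains non-finite values (corrupt input)")

    @property
    def is_dynamic(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.is_dynamic else 1


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body (rotation + translation) map between world mm coordinates."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform must be a 4x4 matrix")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
            raise ValueError("upper-left 3x3 block must be a proper rotation")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation_mm: np.ndarray
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation_mm
        return cls(m)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_img(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    shape = img.shape[:3]
    return VoxelGrid(shape=tuple(shape), voxel_size_mm=tuple(float(z) for z in zooms),
                     affine=np.asarray(img.affine, dtype=float))


def read_volume(
    path: str | Path,
    kind: Literal["label", "mask", "pet"],
    *,
    label_map: Mapping[int, tuple[str, Hemisphere]] | None = None,
    tracer: Tracer = "FDG",
    frame_times_s: list[tuple[float, float]] | None = None,
) -> LabelVolume | BinaryMask | PETVolume:
    """Read a NIfTI volume as a label volume, binary mask or PET volume.

    Label/mask voxels are cast to integer/boolean without value change; a
    label file containing non-integer values or a PET file containing NaNs is
    rejected as corrupt.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    arr = np.asarray(img.dataobj)
    if kind == "label":
        if arr.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=0, rtol=0):
                raise ValueError(f"{path}: non-integer values in a label volume")
            arr = rounded
        return LabelVolume(grid, arr.astype(np.int32), dict(label_map or {}))
    if kind == "mask":
        if arr.ndim != 3:
            raise ValueError("mask volume must be 3-D")
        return BinaryMask(grid, arr != 0)
    if kind == "pet":
        arr = arr.astype(float)
        if np.isnan(arr).any():
            raise ValueError(f"{path}: NaN voxels in PET volume (corrupt input)")
        if arr.ndim == 4:
            arr = np.moveaxis(arr, -1, 0)  # NIfTI stores time last
        return PETVolume(grid, arr, tracer=tracer, frame_times_s=frame_times_s)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(vol: LabelVolume | BinaryMask | PETVolume, path: str | Path) -> Path:
    """Write any volume type to NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int32)
    elif isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    elif isinstance(vol, PETVolume):
        data = np.moveaxis(vol.data, 0, -1) if vol.is_dynamic else vol.data
        data = data.astype(np.float32)
    else:
        raise TypeError(type(vol))
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.voxel_size_mm + ((1.0,) if data.ndim == 4 else ()))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_label_table(path: str | Path) -> dict[int, tuple[str, Hemisphere]]:
    """Read a label dictionary from a 3-column whitespace table: id name hemisphere.

    Lines starting with ``#`` are comments; hemisphere is one of
    ``left``/``right``/``none``.
    """
    table: dict[int, tuple[str, Hemisphere]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"label table line must have 3 columns: {line!r}")
        lid, name, hemi = parts
        if hemi not in ("left", "right", "none"):
            raise ValueError(f"unknown hemisphere {hemi!r} in label table")
        table[int(lid)] = (name, hemi)  # type: ignore[assignment]
    return table


def write_label_table(label_map: Mapping[int, tuple[str, Hemisphere]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["# id name hemisphere"]
    for lid in sorted(label_map):
        name, hemi = label_map[lid]
        lines.append(f"{lid} {name} {hemi}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Resampling and transforms


def _resample_to_grid(
    data: np.ndarray, src: VoxelGrid, dst: VoxelGrid, order: int,
    world_map: np.ndarray | None = None,
) -> np.ndarray:
    """Pull-back resampling of ``data`` from grid ``src`` onto grid ``dst``.

    ``world_map`` (4x4) maps source world coordinates into destination world
    coordinates (identity when both volumes are already aligned in world
    space). Implemented as a single affine pull-back through
    scipy.ndimage.affine_transform.
    """
    if world_map is None:
        world_map = np.eye(4)
    # dst voxel -> dst world -> src world -> src voxel
    full = np.linalg.inv(src.affine) @ np.linalg.inv(world_map) @ dst.affine
    # linear interpolation replicates edge samples across the half-voxel FOV
    # margin; nearest-neighbour fills truly outside voxels with background
    mode = "nearest" if order >= 1 else "constant"
    return ndimage.affine_transform(
        data, full[:3, :3], offset=full[:3, 3], output_shape=dst.shape,
        order=order, mode=mode, cval=0.0,
    )


def resample_isotropic(
    vol: LabelVolume | PETVolume | BinaryMask, target_mm: float = 1.0
) -> LabelVolume | PETVolume | BinaryMask:
    """Re-slice a volume to cubic voxels of side ``target_mm``.

    Labels and masks use nearest-neighbour interpolation (no new labels are
    ever created); PET uptake uses trilinear interpolation. The world extent
    is preserved: the output grid spans the same physical field of view with
    ``round(extent / target_mm)`` voxels per axis.
    """
    if target_mm <= 0:
        raise ValueError("target voxel size must be > 0")
    src = vol.grid
    new_shape = tuple(
        int(round(s * v / target_mm)) for s, v in zip(src.shape, src.voxel_size_mm)
    )
    if any(n < 1 for n in new_shape):
        raise ValueError("degenerate grid: an axis would round to 0 voxels")
    # keep orientation, scale direction cosines to the new voxel size
    dirs = src.affine[:3, :3] / np.array(src.voxel_size_mm)[None, :]
    new_aff = np.eye(4)
    new_aff[:3, :3] = dirs * target_mm
    new_aff[:3, 3] = src.affine[:3, 3]
    dst = VoxelGrid(new_shape, (target_mm,) * 3, new_aff)
    if src.same_geometry(dst):
        return vol
    if isinstance(vol, LabelVolume):
        out = _resample_to_grid(vol.data.astype(np.int32), src, dst, order=0)
        return LabelVolume(dst, out.astype(np.int32), dict(vol.label_map))
    if isinstance(vol, BinaryMask):
        out = _resample_to_grid(vol.data.astype(np.uint8), src, dst, order=0)
        return BinaryMask(dst, out.astype(bool))
    if isinstance(vol, PETVolume):
        if vol.is_dynamic:
            frames = np.stack(
                [_resample_to_grid(f, src, dst, order=1) for f in vol.data]
            )
            return PETVolume(dst, frames, tracer=vol.tracer,
                             frame_times_s=list(vol.frame_times_s or []))
        out = _resample_to_grid(vol.data, src, dst, order=1)
        return PETVolume(dst, out, tracer=vol.tracer)
    raise TypeError(type(vol))


def apply_rigid(
    vol: LabelVolume | BinaryMask,
    t: RigidTransform,
    reference: VoxelGrid,
) -> LabelVolume | BinaryMask:
    """Resample a label volume or mask onto ``reference`` through a rigid map.

    ``t`` maps the input volume's world coordinates into the reference world
    frame (the convention of a registration that aligns the moving image to
    the reference). Nearest-neighbour interpolation keeps labels intact; the
    identity transform between identical grids is a voxel-wise no-op.
    """
    if isinstance(vol, LabelVolume):
        if np.allclose(t.matrix, np.eye(4)) and vol.grid.same_geometry(reference):
            return LabelVolume(reference, vol.data.copy(), dict(vol.label_map))
        out = _resample_to_grid(vol.data.astype(np.int32), vol.grid, reference,
                                order=0, world_map=t.matrix)
        return LabelVolume(reference, out.astype(np.int32), dict(vol.label_map))
    if isinstance(vol, BinaryMask):
        if np.allclose(t.matrix, np.eye(4)) and vol.grid.same_geometry(reference):
            return BinaryMask(reference, vol.data.copy())
        out = _resample_to_grid(vol.data.astype(np.uint8), vol.grid, reference,
                                order=0, world_map=t.matrix)
        return BinaryMask(reference, out.astype(bool))
    raise TypeError("apply_rigid accepts LabelVolume or BinaryMask")


def resample_pet_to_grid(
    pet: PETVolume, reference: VoxelGrid, t: RigidTransform | None = None
) -> PETVolume:
    """Re-slice a (co-registered) PET volume onto a reference grid.

    Trilinear interpolation; ``t`` optionally maps PET world coordinates
    into the reference world frame (an externally estimated registration —
    estimating one is out of scope here). A no-op when grids already match
    and no transform is given.
    """
    world = None if t is None else t.matrix
    if world is None and pet.grid.same_geometry(reference):
        return pet
    if pet.is_dynamic:
        frames = np.stack(
            [_resample_to_grid(f, pet.grid, reference, order=1, world_map=world)
             for f in pet.data]
        )
        return PETVolume(reference, frames, tracer=pet.tracer,
                         frame_times_s=list(pet.frame_times_s or []))
    out = _resample_to_grid(pet.data, pet.grid, reference, order=1, world_map=world)
    return PETVolume(reference, out, tracer=pet.tracer)


def volume_mm3(mask: BinaryMask) -> float:
    """Volume of a mask: member-voxel count times the voxel volume."""
    return mask.count * mask.grid.voxel_volume_mm3
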