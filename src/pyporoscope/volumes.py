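"""Volume containers and I/O for 3D micro-CT data.

Coordinate convention (used throughout the package): 0-based voxel indices,
axis order ``(x, y, z)`` where ``z`` is the slice index of a tomographic
stack.  Arrays are indexed ``data[x, y, z]``.  Voxels are isotropic cubes of
edge ``voxel_size`` micrometres; all physically scaled outputs are reported
in millimetres.

Two on-disk containers are supported:

* raw: headerless little-endian binary, x-fastest ordering, with a JSON
  sidecar ``<path>.json`` holding ``{nx, ny, nz, bits, voxel_size_um}``;
* TIFF: multipage grayscale stacks (8/16-bit), one page per z slice.
  Voxel size is *not* read from TIFF tags — it is required metadata, since
  every reported quantity carries physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

__all__ = [
    "GrayVolume",
    "BinaryVolume",
    "LabelVolume",
    "VolumeMeta",
    "read_volume",
    "write_volume",
    "crop_voi",
    "MalformedInputError",
    "UnsupportedFormatError",
]


class MalformedInputError(ValueError):
    """File contents inconsistent with the declared geometry."""


class UnsupportedFormatError(ValueError):
    """Bit depth or container not supported."""


def _check_geometry(data: np.ndarray, voxel_size: float) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got {data.shape}")
    if not voxel_size > 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")


@dataclass
class GrayVolume:
    """Gray-level reconstruction: unsigned 8- or 16-bit scalar field."""

    data: np.ndarray
    voxel_size: float  # um, isotropic edge length

    def __post_init__(self) -> None:
        if self.data.dtype not in (np.uint8, np.uint16):
            raise UnsupportedFormatError(
                f"gray volumes must be uint8 or uint16, got {self.data.dtype}"
            )
        _check_geometry(self.data, self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0


@dataclass
class BinaryVolume:
    """Object/background mask; ``True`` marks the object (segmented phase)."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        _check_geometry(self.data, self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3


@dataclass
class LabelVolume:
    """Non-negative integer component/phase labels, 0 = background.

    Positive labels are compacted to ``1..n_labels`` at construction so that
    downstream per-component tables have dense ids.
    """

    data: np.ndarray
    voxel_size: float
    n_labels: int = field(init=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {data.dtype}")
        if data.min() < 0:
            raise ValueError("labels must be non-negative")
        _check_geometry(data, self.voxel_size)
        present = np.unique(data)
        present = present[present > 0]
        if present.size and not np.array_equal(
            present, np.arange(1, present.size + 1)
        ):
            # compact to {1..n}
            lut = np.zeros(int(present.max()) + 1, dtype=np.int64)
            lut[present] = np.arange(1, present.size + 1)
            data = lut[data]
        self.data = data
        self.n_labels = int(present.size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0


Volume = Union[GrayVolume, BinaryVolume, LabelVolume]


@dataclass
class VolumeMeta:
    """Sidecar descriptor for raw volumes: dims, bit depth, voxel size."""

    nx: int = 0
    ny: int = 0
    nz: int = 0
    bits: int = 0
    voxel_size_um: float = 1.0

    @classmethod
    def from_json(cls, path: Path) -> "VolumeMeta":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            nx=int(d["nx"]),
            ny=int(d["ny"]),
            nz=int(d["nz"]),
            bits=int(d["bits"]),
            voxel_size_um=float(d["voxel_size_um"]),
        )

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "nx": self.nx,
                    "ny": self.ny,
                    "nz": self.nz,
                    "bits": self.bits,
                    "voxel_size_um": self.voxel_size_um,
                },
                fh,
                indent=2,
            )
            fh.write("\n")


_DTYPES = {8: np.uint8, 16: np.uint16}


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_volume(path, meta: VolumeMeta | None = None) -> GrayVolume:
    """Read a gray volume from a raw file (with sidecar/meta) or a TIFF stack.

    For raw input ``meta`` (or the ``<path>.json`` sidecar) must fully specify
    dimensions and bit depth; for TIFF only ``voxel_size_um`` is used.
    File order is z-slowest/x-fastest, so the returned array is ``(nx, ny, nz)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_tiff(path):
        pages = tifffile.imread(path)  # (nz, ny, nx) or (ny, nx)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.ndim != 3:
            raise UnsupportedFormatError(
                f"expected a grayscale stack, got shape {pages.shape}"
            )
        if pages.dtype not in (np.uint8, np.uint16):
            raise UnsupportedFormatError(f"unsupported TIFF dtype {pages.dtype}")
        vs = meta.voxel_size_um if meta is not None else 1.0
        return GrayVolume(np.ascontiguousarray(pages.transpose(2, 1, 0)), vs)

    if meta is None or meta.bits == 0 or 0 in (meta.nx, meta.ny, meta.nz):
        sidecar = path.with_name(path.name + ".json")
        if not sidecar.exists():
            raise MalformedInputError(
                f"raw volume {path} has no metadata (pass meta= or provide {sidecar})"
            )
        side = VolumeMeta.from_json(sidecar)
        if meta is not None:  # explicit fields override the sidecar
            side.voxel_size_um = meta.voxel_size_um
            for name in ("nx", "ny", "nz", "bits"):
                if getattr(meta, name):
                    setattr(side, name, getattr(meta, name))
        meta = side
    if meta.bits not in _DTYPES:
        raise UnsupportedFormatError(f"unsupported bit depth {meta.bits}")
    dtype = _DTYPES[meta.bits]
    expected = meta.nx * meta.ny * meta.nz * (meta.bits // 8)
    actual = path.stat().st_size
    if expected != actual:
        raise MalformedInputError(
            f"{path}: file is {actual} bytes but {meta.nx}x{meta.ny}x{meta.nz}"
            f" @ {meta.bits}-bit needs {expected}"
        )
    flat = np.fromfile(path, dtype=np.dtype(dtype).newbyteorder("<"))
    data = flat.reshape(meta.nz, meta.ny, meta.nx).transpose(2, 1, 0)
    return GrayVolume(
        np.ascontiguousarray(data.astype(dtype)), meta.voxel_size_um
    )


def _storage_array(vol: Volume) -> np.ndarray:
    """uint8/uint16 array actually written to disk."""
    if isinstance(vol, GrayVolume):
        return vol.data
    if isinstance(vol, BinaryVolume):
        return np.where(vol.data, np.uint8(255), np.uint8(0))
    if isinstance(vol, LabelVolume):
        if vol.n_labels <= 255:
            return vol.data.astype(np.uint8)
        if vol.n_labels <= 65535:
            return vol.data.astype(np.uint16)
        raise OverflowError(
            f"{vol.n_labels} labels exceed the 16-bit storage container"
        )
    # duck-typed masks (e.g. skeleton volumes) store like binary volumes
    data = getattr(vol, "data", None)
    if isinstance(data, np.ndarray) and data.dtype == bool:
        return np.where(data, np.uint8(255), np.uint8(0))
    raise TypeError(f"not a volume: {type(vol)!r}")


def write_volume(vol: Volume, path, format: str | None = None) -> None:
    """Write a volume as raw (+ JSON sidecar) or a multipage TIFF stack.

    Binary masks are stored as 0/255 uint8; label volumes use the smallest
    sufficient unsigned width.  Round-trips through :func:`read_volume` are
    lossless at the storage-array level.
    """
    path = Path(path)
    if format is None:
        format = "tiff" if _is_tiff(path) else "raw"
    if format not in ("raw", "tiff"):
        raise ValueError(f"format must be 'raw' or 'tiff', got {format!r}")
    arr = _storage_array(vol)
    if format == "tiff":
        tifffile.imwrite(path, np.ascontiguousarray(arr.transpose(2, 1, 0)))
        return
    stored = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(
        arr.dtype.newbyteorder("<")
    )
    stored.tofile(path)
    nx, ny, nz = arr.shape
    VolumeMeta(
        nx=nx,
        ny=ny,
        nz=nz,
        bits=arr.dtype.itemsize * 8,
        voxel_size_um=vol.voxel_size,
    ).to_json(path.with_name(path.name + ".json"))


def crop_voi(vol: Volume, origin: tuple[int, int, int], shape: tuple[int, int, int]):
    """Extract a volume of interest; out-of-bounds requests raise (no clamping)."""
    origin = tuple(int(o) for o in origin)
    shape = tuple(int(s) for s in shape)
    for axis in range(3):
        if origin[axis] < 0 or shape[axis] < 1:
            raise IndexError(f"invalid VOI origin/shape on axis {axis}")
        if origin[axis] + shape[axis] > vol.shape[axis]:
            raise IndexError(
                f"VOI exceeds volume extent on axis {axis}: "
                f"{origin[axis]}+{shape[axis]} > {vol.shape[axis]}"
            )
    sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
    return type(vol)(vol.data[sl].copy(), vol.voxel_size)
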