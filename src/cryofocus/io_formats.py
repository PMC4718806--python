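"""MRC2014 volumes/stacks and STAR particle metadata, with strict validation.

Volumes are held as cubic ``[z, y, x]`` arrays (MRC section-slowest order;
gemmi exposes ``[x, y, z]``-indexed grids, transposed here at the boundary).
Only a single-block STAR dialect is supported: the classic particle table
with ``_rlnImageName``, Euler angles, pixel offsets and per-particle CTF
columns.  Slice indices in ``_rlnImageName`` are 1-based on disk and 0-based
in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from gemmi import cif

from .geometry import CTFParams

__all__ = [
    "FormatError",
    "DimensionError",
    "SchemaError",
    "VolumeGrid",
    "ParticleImage",
    "ImageStack",
    "ParticleRecord",
    "ParticleSet",
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "read_star",
    "write_star",
]


class FormatError(ValueError):
    """File is not in a supported on-disk format."""


class DimensionError(ValueError):
    """Array dimensions violate a contract (e.g. non-cubic map)."""


class SchemaError(ValueError):
    """STAR table lacks a mandatory column or holds an unparsable value."""


@dataclass(frozen=True)
class VolumeGrid:
    """A cubic density map of side N voxels with a physical pixel size.

    The rotation center is fixed at voxel ``(N/2, N/2, N/2)`` (0-based).
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        if data.ndim != 3 or len(set(data.shape)) != 1:
            raise DimensionError(f"volume must be cubic, got shape {data.shape}")
        n = data.shape[0]
        if n < 8 or n % 2:
            raise DimensionError(f"volume side must be even and >= 8, got {n}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")

    @property
    def box(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ParticleImage:
    """One square particle image with its pixel size."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] != data.shape[1]:
            raise DimensionError(f"image must be square, got shape {data.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(data)):
            raise ValueError("image contains non-finite values")

    @property
    def box(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ImageStack:
    """An ordered stack of same-size particle images, ``data[i]`` = image i."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        if data.ndim != 3 or data.shape[1] != data.shape[2]:
            raise DimensionError(f"stack must be n x N x N, got shape {data.shape}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(data)):
            raise ValueError("stack contains non-finite values")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def box(self) -> int:
        return self.data.shape[1]

    def image(self, i: int) -> ParticleImage:
        return ParticleImage(self.data[i], self.pixel_size)


def _wrap_angle(a: float) -> float:
    """Wrap into [-180, 180)."""
    return float((a + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class ParticleRecord:
    """One particle's image reference, orientation, offsets and CTF.

    ``image_ref`` is ``(stack filename, 1-based slice index)`` as stored in
    ``_rlnImageName``.  Angles in degrees, offsets in pixels.
    ``class_label`` carries a ground-truth class in simulations.
    """

    image_ref: tuple[str, int]
    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    ctf: CTFParams = field(default_factory=CTFParams)
    class_label: int | None = None
    random_subset: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.image_ref) == 2 and self.image_ref[1] >= 1):
            raise ValueError("image_ref must be (filename, 1-based index)")
        for name in ("rot", "tilt", "psi", "origin_x", "origin_y"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        object.__setattr__(self, "rot", _wrap_angle(self.rot))
        object.__setattr__(self, "psi", _wrap_angle(self.psi))
        if not (0.0 <= self.tilt <= 180.0):
            raise ValueError(f"tilt must be in [0, 180], got {self.tilt}")


@dataclass(frozen=True)
class ParticleSet:
    """An ordered, homogeneous collection of particle records.

    ``pixel_size``/``box`` describe the images the records refer to; they may
    be None when the set was read from metadata alone.
    """

    records: tuple[ParticleRecord, ...]
    pixel_size: float | None = None
    box: int | None = None

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise ValueError("particle set must be non-empty")
        refs = [r.image_ref for r in records]
        if len(set(refs)) != len(refs):
            raise ValueError("image_refs must be unique")
        if self.box is not None:
            lim = self.box / 4.0
            for i, r in enumerate(records):
                if abs(r.origin_x) >= lim or abs(r.origin_y) >= lim:
                    raise ValueError(f"record {i}: offsets must satisfy |o| < box/4")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def subset(self, indices) -> "ParticleSet":
        return replace(self, records=tuple(self.records[i] for i in indices))


# ---------------------------------------------------------------------------
# MRC volumes and stacks


def _read_mrc_array(path) -> tuple[np.ndarray, float]:
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, SystemError) as exc:
        raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
    arr = np.array(m.grid, copy=True)  # indexed [x, y, z]
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path} contains non-finite values")
    cell_a = m.grid.unit_cell.a
    nx = arr.shape[0]
    pixel_size = cell_a / nx if cell_a > 0 else 1.0
    return arr.transpose(2, 1, 0).astype(np.float64), pixel_size


def _write_mrc_array(data_zyx: np.ndarray, pixel_size: float, path) -> None:
    arr = np.ascontiguousarray(data_zyx.transpose(2, 1, 0), dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    nx, ny, nz = arr.shape
    m.grid.unit_cell = gemmi.UnitCell(
        nx * pixel_size, ny * pixel_size, nz * pixel_size, 90.0, 90.0, 90.0
    )
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path) -> VolumeGrid:
    """Read a cubic MRC2014 map; pixel size from CELLA / grid size."""
    data, pixel_size = _read_mrc_array(path)
    if len(set(data.shape)) != 1:
        raise DimensionError(f"{path}: expected cubic map, got shape {data.shape}")
    return VolumeGrid(data, pixel_size)


def write_volume(vol: VolumeGrid, path) -> None:
    """Write a volume as a 32-bit float (mode 2) MRC2014 map."""
    _write_mrc_array(vol.data, vol.pixel_size, path)


def read_stack(path) -> ImageStack:
    """Read an MRC image stack; slice i on disk becomes ``data[i]``."""
    data, pixel_size = _read_mrc_array(path)
    if data.shape[1] != data.shape[2]:
        raise DimensionError(f"{path}: stack images must be square, got {data.shape}")
    return ImageStack(data, pixel_size)


def write_stack(stack: ImageStack, path) -> None:
    """Write an image stack as a mode-2 MRC file with NZ = number of images."""
    _write_mrc_array(stack.data, stack.pixel_size, path)


# ---------------------------------------------------------------------------
# STAR metadata

_MANDATORY = [
    "_rlnImageName",
    "_rlnAngleRot",
    "_rlnAngleTilt",
    "_rlnAnglePsi",
    "_rlnOriginX",
    "_rlnOriginY",
    "_rlnDefocusU",
    "_rlnDefocusV",
    "_rlnDefocusAngle",
    "_rlnVoltage",
    "_rlnSphericalAberration",
    "_rlnAmplitudeContrast",
]
_OPTIONAL = ["_rlnPhaseShift", "_rlnClassNumber", "_rlnRandomSubset"]


def _parse_image_ref(token: str, row: int) -> tuple[str, int]:
    if "@" not in token:
        raise SchemaError(f"row {row}: _rlnImageName '{token}' lacks 'index@file'")
    idx, fname = token.split("@", 1)
    try:
        return fname, int(idx)
    except ValueError as exc:
        raise SchemaError(f"row {row}: bad slice index in '{token}'") from exc


def read_star(path) -> ParticleSet:
    """Read a single-block particle STAR table, order preserved."""
    try:
        doc = cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse STAR file {path}: {exc}") from exc
    if len(doc) == 0:
        raise SchemaError(f"{path}: no data block")
    block = doc[0]
    cols: dict[str, list[str]] = {}
    for tag in _MANDATORY + _OPTIONAL:
        col = block.find_loop(tag)
        values = list(col)
        if tag in _MANDATORY and not values:
            raise SchemaError(f"{path}: missing mandatory column {tag}")
        if values:
            cols[tag] = values
    n = len(cols["_rlnImageName"])

    def num(tag: str, row: int) -> float:
        try:
            return float(cols[tag][row])
        except ValueError as exc:
            raise SchemaError(
                f"{path}: row {row}: unparsable value '{cols[tag][row]}' in {tag}"
            ) from exc

    records = []
    for i in range(n):
        ctf = CTFParams(
            voltage=num("_rlnVoltage", i),
            cs=num("_rlnSphericalAberration", i),
            amplitude_contrast=num("_rlnAmplitudeContrast", i),
            defocus_u=num("_rlnDefocusU", i),
            defocus_v=num("_rlnDefocusV", i),
            astig_angle=num("_rlnDefocusAngle", i),
            phase_shift=num("_rlnPhaseShift", i) if "_rlnPhaseShift" in cols else 0.0,
        )
        records.append(
            ParticleRecord(
                image_ref=_parse_image_ref(cols["_rlnImageName"][i], i),
                rot=num("_rlnAngleRot", i),
                tilt=num("_rlnAngleTilt", i),
                psi=num("_rlnAnglePsi", i),
                origin_x=num("_rlnOriginX", i),
                origin_y=num("_rlnOriginY", i),
                ctf=ctf,
                class_label=(
                    int(num("_rlnClassNumber", i)) if "_rlnClassNumber" in cols else None
                ),
                random_subset=(
                    int(num("_rlnRandomSubset", i)) if "_rlnRandomSubset" in cols else None
                ),
            )
        )
    return ParticleSet(tuple(records))


def write_star(pset: ParticleSet, path) -> None:
    """Write a particle set as a single-block STAR table readable by read_star."""
    has_class = any(r.class_label is not None for r in pset)
    has_subset = any(r.random_subset is not None for r in pset)
    has_phase = any(r.ctf.phase_shift != 0.0 for r in pset)
    tags = list(_MANDATORY)
    if has_phase:
        tags.append("_rlnPhaseShift")
    if has_class:
        tags.append("_rlnClassNumber")
    if has_subset:
        tags.append("_rlnRandomSubset")

    doc = cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("", tags)
    fmt = "{:.8g}".format
    for r in pset:
        row = [
            f"{r.image_ref[1]:06d}@{r.image_ref[0]}",
            fmt(r.rot),
            fmt(r.tilt),
            fmt(r.psi),
            fmt(r.origin_x),
            fmt(r.origin_y),
            fmt(r.ctf.defocus_u),
            fmt(r.ctf.defocus_v),
            fmt(r.ctf.astig_angle),
            fmt(r.ctf.voltage),
            fmt(r.ctf.cs),
            fmt(r.ctf.amplitude_contrast),
        ]
        if has_phase:
            row.append(fmt(r.ctf.phase_shift))
        if has_class:
            row.append(str(r.class_label if r.class_label is not None else 0))
        if has_subset:
            row.append(str(r.random_subset if r.random_subset is not None else 0))
        loop.add_row(row)
    with open(path, "w") as fh:
        fh.write(doc.as_string())
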