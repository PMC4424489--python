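"""NXtomo-layout HDF5 reading and writing, plus volume output with embedded
process-list provenance.

The NXtomo application definition stores a tomography scan as one frame
stack (projections, flat fields and dark fields interleaved), a per-frame
``image_key`` (0 = projection, 1 = flat field, 2 = dark field — note some
facilities swap 1/2; the codes here follow the standard) and per-frame
rotation angles in degrees.  Default dataset paths follow the application
definition but are overridable for dialect files.

Volumes are written either as a single HDF5 file carrying the voxel data,
voxel size, provenance records and the full process list as a JSON string
attribute (so any output can be reproduced from itself alone), or as a
stack of 32-bit TIFF slices with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .framework import (
    DataBlock,
    PROJECTION_AXES,
    ProcessList,
    ProvenanceRecord,
    Space,
    TomoError,
)

__all__ = [
    "NXTomoLayout",
    "read_nxtomo",
    "write_nxtomo",
    "write_volume",
    "read_volume",
    "read_process_list",
    "write_block",
]

KEY_PROJECTION = 0
KEY_FLAT = 1
KEY_DARK = 2


@dataclass(frozen=True)
class NXTomoLayout:
    """HDF5 dataset paths of an NXtomo scan file."""

    data_path: str = "entry/instrument/detector/data"
    key_path: str = "entry/instrument/detector/image_key"
    angle_path: str = "entry/sample/rotation_angle"
    monitor_path: str = "entry/control/data"
    title_path: str = "entry/title"


DEFAULT_LAYOUT = NXTomoLayout()


def read_nxtomo(
    path: str | Path, layout: NXTomoLayout = DEFAULT_LAYOUT
) -> tuple[DataBlock, np.ndarray, np.ndarray]:
    """Read a scan file and split its frames by image_key.

    Returns ``(projections, flats, darks)``: a detector-space
    :class:`DataBlock` carrying the rotation angles of the key-0 frames only
    (flats and darks are plain frame stacks).  Monitor readings and the scan
    title, when present, land in the block's metadata.
    """
    path = Path(path)
    if not path.exists():
        raise TomoError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        for p in (layout.data_path, layout.key_path, layout.angle_path):
            if p not in f:
                raise TomoError(f"malformed NXtomo file {path}: missing {p!r}")
        data = f[layout.data_path][()]
        keys = np.asarray(f[layout.key_path][()]).astype(int)
        angles = np.asarray(f[layout.angle_path][()], dtype=float)
        meta: dict = {}
        if layout.monitor_path in f:
            meta["monitor"] = np.asarray(f[layout.monitor_path][()], dtype=float)
        if layout.title_path in f:
            title = f[layout.title_path][()]
            meta["title"] = title.decode() if isinstance(title, bytes) else str(title)

    if not (len(data) == len(keys) == len(angles)):
        raise TomoError(
            f"malformed NXtomo file {path}: frame/key/angle counts differ "
            f"({len(data)}/{len(keys)}/{len(angles)})"
        )
    bad = set(np.unique(keys)) - {KEY_PROJECTION, KEY_FLAT, KEY_DARK}
    if bad:
        raise TomoError(f"image_key contains invalid codes {sorted(bad)}")

    proj = data[keys == KEY_PROJECTION]
    flats = data[keys == KEY_FLAT]
    darks = data[keys == KEY_DARK]
    if len(flats) == 0:
        warnings.warn(f"{path}: no flat-field frames present")
    if len(darks) == 0:
        warnings.warn(f"{path}: no dark-field frames present")
    proj_angles = angles[keys == KEY_PROJECTION]
    if "monitor" in meta and len(meta["monitor"]) == len(keys):
        meta["monitor"] = meta["monitor"][keys == KEY_PROJECTION]

    meta["flats"] = flats
    meta["darks"] = darks
    block = DataBlock(
        values=proj,
        space=Space.DETECTOR,
        axes=PROJECTION_AXES,
        angles_deg=proj_angles,
        meta=meta,
    )
    return block, flats, darks


def write_nxtomo(
    path: str | Path,
    projections: np.ndarray,
    flats: np.ndarray,
    darks: np.ndarray,
    angles_deg: np.ndarray,
    meta: dict | None = None,
    layout: NXTomoLayout = DEFAULT_LAYOUT,
) -> Path:
    """Write an NXtomo-layout file: flats, then darks, then projections.

    ``angles_deg`` applies to the projection frames; flat/dark frames are
    written with the first/last projection angle respectively (their angle
    is irrelevant).  Array dtypes are preserved exactly, so 16-bit unsigned
    raw counts and 32/64-bit floats round-trip losslessly.
    """
    projections = np.asarray(projections)
    flats = np.asarray(flats)
    darks = np.asarray(darks)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if projections.ndim != 3:
        raise TomoError("projections must be a (frame, row, col) stack")
    if len(angles_deg) != len(projections):
        raise TomoError(
            f"{len(projections)} projections but {len(angles_deg)} angles"
        )
    frame_shape = projections.shape[1:]
    for name, stack in (("flats", flats), ("darks", darks)):
        if len(stack) and stack.shape[1:] != frame_shape:
            raise TomoError(
                f"{name} frame shape {stack.shape[1:]} != projection "
                f"frame shape {frame_shape}"
            )

    stacks = [s for s in (flats, darks, projections) if len(s)]
    data = np.concatenate(stacks) if stacks else projections
    keys = np.concatenate(
        [
            np.full(len(flats), KEY_FLAT, dtype=np.int32),
            np.full(len(darks), KEY_DARK, dtype=np.int32),
            np.full(len(projections), KEY_PROJECTION, dtype=np.int32),
        ]
    )
    pad_lo = angles_deg[0] if len(angles_deg) else 0.0
    pad_hi = angles_deg[-1] if len(angles_deg) else 0.0
    all_angles = np.concatenate(
        [np.full(len(flats), pad_lo), np.full(len(darks), pad_hi), angles_deg]
    )

    path = Path(path)
    meta = meta or {}
    with h5py.File(path, "w") as f:
        f.create_dataset(layout.data_path, data=data)
        f.create_dataset(layout.key_path, data=keys)
        f.create_dataset(layout.angle_path, data=all_angles)
        if "monitor" in meta:
            f.create_dataset(
                layout.monitor_path, data=np.asarray(meta["monitor"], dtype=float)
            )
        if "title" in meta:
            f.create_dataset(layout.title_path, data=str(meta["title"]))
        f.attrs["definition"] = "NXtomo"
    return path


def _provenance_json(records: list[ProvenanceRecord]) -> str:
    return json.dumps([r.to_dict() for r in records], indent=2)


def write_volume(
    path: str | Path,
    volume: DataBlock,
    process_list: ProcessList | None = None,
    fmt: str = "hdf5",
) -> Path:
    """Persist an image-space volume with its full processing provenance.

    ``fmt='hdf5'`` (default) writes one file holding the voxel data, voxel
    size, the provenance records and the embedded process list (as JSON
    string attributes).  ``fmt='tiff_stack'`` writes one 32-bit TIFF per
    z-slice named ``<stem>_zNNNN.tif`` plus a ``<stem>.json`` sidecar with
    the same metadata.
    """
    volume.require_space(Space.IMAGE)
    path = Path(path)
    plist_json = process_list.to_json() if process_list is not None else None

    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("entry/data/volume", data=volume.values)
            f["entry/data/volume"].attrs["voxel_size"] = volume.pixel_size
            f.attrs["provenance"] = _provenance_json(volume.provenance)
            if plist_json is not None:
                f.attrs["process_list"] = plist_json
        return path
    if fmt == "tiff_stack":
        import tifffile

        path.mkdir(parents=True, exist_ok=True)
        stem = path / path.name
        for z in range(volume.values.shape[0]):
            tifffile.imwrite(
                f"{stem}_z{z:04d}.tif", volume.values[z].astype(np.float32)
            )
        sidecar = {
            "voxel_size": volume.pixel_size,
            "n_slices": int(volume.values.shape[0]),
            "provenance": [r.to_dict() for r in volume.provenance],
        }
        if plist_json is not None:
            sidecar["process_list"] = json.loads(plist_json)
        (path / f"{path.name}.json").write_text(json.dumps(sidecar, indent=2))
        return path
    raise TomoError(f"unknown volume format {fmt!r}")


def read_volume(path: str | Path) -> tuple[np.ndarray, ProcessList | None]:
    """Read back an HDF5 volume written by :func:`write_volume`."""
    with h5py.File(path, "r") as f:
        vol = f["entry/data/volume"][()]
        plist = None
        if "process_list" in f.attrs:
            plist = ProcessList.from_json(f.attrs["process_list"])
    return vol, plist


def read_process_list(path: str | Path) -> ProcessList:
    """Load a process list from a JSON file or an HDF5 output that embeds one."""
    path = Path(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "process_list" not in f.attrs:
                raise TomoError(f"{path} contains no embedded process list")
            return ProcessList.from_json(f.attrs["process_list"])
    try:
        return ProcessList.from_json(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise TomoError(f"cannot parse process list {path}: {exc}") from exc


def write_block(path: str | Path, block: DataBlock) -> Path:
    """Persist any intermediate block (values + space + provenance) as HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("entry/data/values", data=block.values)
        f.attrs["space"] = block.space.value
        f.attrs["axes"] = json.dumps(list(block.axes))
        f.attrs["pixel_size"] = block.pixel_size
        if block.angles_deg is not None:
            f.create_dataset("entry/data/rotation_angle", data=block.angles_deg)
        f.attrs["provenance"] = _provenance_json(block.provenance)
    return Path(path)
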