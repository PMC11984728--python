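"""File I/O: NIfTI volumes and label maps, CSV tables, projection streams.

Conventions
-----------
* Volumes are written as NIfTI-1 with an isotropic diagonal affine carrying
  the voxel size in mm.  Array axes are stored (x, y, z[, t, e]) per NIfTI
  convention; the in-memory order is (z, y, x) for 3D and (t, e, z, y, x)
  for :class:`~cardiopcct.reconstruction.Volume5D`.  Round trips are
  bit-exact (dtype preserved).
* Label maps are uint8 NIfTI files with a JSON sidecar naming the classes
  (0 = background, 1..8 = the fixed structure set).
* On load, volumes whose affine is not in canonical (RAS) orientation are
  reoriented with :func:`nibabel.as_closest_canonical` and the reorientation
  is logged.
* Tables go through CSV with column order preserved and floats written in
  shortest round-trip representation (bit-exact on reload).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import STRUCTURES, ProjectionStream
from .reconstruction import Volume5D

__all__ = [
    "save_volume",
    "load_volume",
    "save_volume5d",
    "load_volume5d",
    "save_labels",
    "load_labels",
    "save_table",
    "load_table",
    "save_stream",
    "load_stream",
]

logger = logging.getLogger("cardiopcct.io")

_NIFTI1_SIZEOF_HDR = 348


def _check_nifti_magic(path: Path) -> None:
    """Fail early on corrupt NIfTI files, reporting the offending byte offset."""
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rb") as fh:
            head = fh.read(4)
    except OSError as exc:  # undecodable gzip container
        raise ValueError(f"parse error in {path} at byte offset 0: {exc}") from exc
    if len(head) < 4:
        raise ValueError(f"parse error in {path} at byte offset {len(head)}: "
                         "truncated header")
    sizeof_hdr = int(np.frombuffer(head, dtype="<i4")[0])
    sizeof_be = int(np.frombuffer(head, dtype=">i4")[0])
    if _NIFTI1_SIZEOF_HDR not in (sizeof_hdr, sizeof_be):
        raise ValueError(
            f"parse error in {path} at byte offset 0: sizeof_hdr is "
            f"{sizeof_hdr}, expected {_NIFTI1_SIZEOF_HDR} (not a NIfTI-1 file)")


def _affine(voxel_size: float) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = float(voxel_size)
    return a


def _load_canonical(path: Path) -> nib.Nifti1Image:
    _check_nifti_magic(path)
    img = nib.load(str(path))
    canonical = nib.as_closest_canonical(img)
    if canonical is not img and not np.allclose(canonical.affine, img.affine):
        logger.info("reoriented %s to canonical (RAS) axes per its affine", path)
    return canonical


def save_volume(volume: np.ndarray, voxel_size: float, path) -> Path:
    """Write a 3D (z, y, x) volume as NIfTI; returns the path."""
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("save_volume expects a 3D (z, y, x) array")
    path = Path(path)
    img = nib.Nifti1Image(np.transpose(vol, (2, 1, 0)), _affine(voxel_size))
    img.header.set_data_dtype(vol.dtype)
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, float]:
    """Read a 3D NIfTI volume -> ((z, y, x) array, voxel size in mm)."""
    img = _load_canonical(Path(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} holds a {data.ndim}D image, expected 3D")
    voxel = float(img.header.get_zooms()[0])
    return np.ascontiguousarray(np.transpose(data, (2, 1, 0))), voxel


def save_volume5d(volume: Volume5D, path) -> Path:
    """Write a Volume5D as a 5D NIfTI (x, y, z, phase, energy)."""
    path = Path(path)
    data = np.transpose(volume.values, (4, 3, 2, 0, 1))  # (x, y, z, t, e)
    img = nib.Nifti1Image(data, _affine(volume.voxel_size))
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))
    return path


def load_volume5d(path) -> Volume5D:
    """Read a 5D NIfTI back into a Volume5D (bit-exact round trip)."""
    img = _load_canonical(Path(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 5:
        raise ValueError(f"{path} holds a {data.ndim}D image, expected 5D "
                         "(x, y, z, phase, energy)")
    values = np.ascontiguousarray(np.transpose(data, (3, 4, 2, 1, 0)))
    voxel = float(img.header.get_zooms()[0])
    return Volume5D(values=values, voxel_size=voxel)


def save_labels(labels: np.ndarray, voxel_size: float, path,
                class_names=STRUCTURES) -> Path:
    """Write a 3D or (n_phases, z, y, x) label map plus a JSON class sidecar."""
    lab = np.asarray(labels)
    if lab.ndim not in (3, 4):
        raise ValueError("labels must be 3D or (n_phases, z, y, x)")
    path = Path(path)
    if lab.ndim == 3:
        data = np.transpose(lab, (2, 1, 0))
    else:
        data = np.transpose(lab, (3, 2, 1, 0))  # (x, y, z, t)
    img = nib.Nifti1Image(data.astype(np.uint8), _affine(voxel_size))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(
        {"0": "background", **{str(i + 1): n for i, n in enumerate(class_names)}},
        indent=2))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[:-len(suffix)] + ".classes.json")
    return path.with_suffix(".classes.json")


def load_labels(path) -> tuple[np.ndarray, float, dict]:
    """Read a label map -> (array, voxel size, {label value: class name})."""
    path = Path(path)
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        lab = np.transpose(data, (2, 1, 0))
    elif data.ndim == 4:
        lab = np.transpose(data, (3, 2, 1, 0))
    else:
        raise ValueError(f"{path} holds a {data.ndim}D label image")
    sidecar = _sidecar_path(path)
    classes = {}
    if sidecar.exists():
        classes = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    voxel = float(img.header.get_zooms()[0])
    return np.ascontiguousarray(lab).astype(np.uint8), voxel, classes


def save_table(table: pd.DataFrame, path) -> Path:
    """Write a table as CSV, preserving column order and float precision."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def load_table(path) -> pd.DataFrame:
    """Read a CSV table; raises a parse error naming the offending position."""
    path = Path(path)
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"parse error in {path}: {exc}") from exc


def save_stream(stream: ProjectionStream, directory) -> Path:
    """Write a projection stream (compressed arrays + JSON sidecar)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {
        "projections": stream.projections,
        "timestamps": stream.timestamps,
        "angles": stream.angles,
        "thresholds": stream.thresholds,
    }
    if stream.true_phase is not None:
        arrays["true_phase"] = stream.true_phase
    np.savez_compressed(directory / "stream.npz", **arrays)
    meta = {
        "flux": stream.flux,
        "log_transformed": bool(stream.log_transformed),
        "voxel_size": stream.voxel_size,
        "grid_shape": list(stream.grid_shape) if stream.grid_shape else None,
    }
    (directory / "stream.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_stream(directory) -> ProjectionStream:
    directory = Path(directory)
    npz = directory / "stream.npz"
    meta_path = directory / "stream.json"
    if not npz.exists() or not meta_path.exists():
        raise FileNotFoundError(f"no projection stream found in {directory}")
    with np.load(npz) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(meta_path.read_text())
    return ProjectionStream(
        projections=arrays["projections"],
        timestamps=arrays["timestamps"],
        angles=arrays["angles"],
        thresholds=arrays["thresholds"],
        flux=float(meta["flux"]),
        log_transformed=bool(meta["log_transformed"]),
        true_phase=arrays.get("true_phase"),
        voxel_size=meta["voxel_size"],
        grid_shape=tuple(meta["grid_shape"]) if meta["grid_shape"] else None,
    )
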