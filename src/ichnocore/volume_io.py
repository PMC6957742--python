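"""Readers and writers for every external format the pipeline touches.

Volumes use the package-wide (x, y, z) convention with z the downcore axis.
Image stacks and DICOM series store one slice per z position with the slice
array indexed (row, col) = (y, x); readers and writers transpose so that a
round trip is the identity.

Image-stack inputs carry no spacing metadata, so spacing is always explicit
configuration there; DICOM spacing is read from the pixel-spacing and
slice-position tags.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .synthetic_core import BurrowSpec, SceneSpec
from .types import CoreVolume

__all__ = [
    "read_dicom_series",
    "write_dicom_series",
    "read_image_stack",
    "write_image_stack",
    "write_tables",
    "read_table",
    "read_bi_log",
    "scene_to_yaml",
    "scene_from_yaml",
]

_TABLE_FLOAT_FORMAT = "%.6g"  # lossless round-trip at 6 significant digits


# ---------------------------------------------------------------------------
# DICOM series


def read_dicom_series(directory: str | os.PathLike) -> CoreVolume:
    """Read one DICOM series from ``directory`` into a :class:`CoreVolume`.

    Slices are sorted by slice position into ascending z regardless of
    filename order; rescale slope/intercept are applied when present.
    Raises on mixed series, inconsistent slice shapes or missing spacing tags,
    naming the offending file or tag.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"directory {directory} contains {len(uids)} distinct series UIDs")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError("inconsistent slice shapes across series: " + ", ".join(map(str, shapes)))

    def _zpos(pair):
        path, ds = pair
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        if "SliceLocation" in ds:
            return float(ds.SliceLocation)
        raise ValueError(f"{path.name}: no ImagePositionPatient or SliceLocation tag")

    order = sorted(zip(files, datasets), key=_zpos)
    files = [p for p, _ in order]
    datasets = [ds for _, ds in order]

    first = datasets[0]
    if "PixelSpacing" not in first:
        raise ValueError(f"{files[0].name}: missing PixelSpacing tag")
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if len(datasets) >= 2:
        dz = _zpos((files[1], datasets[1])) - _zpos((files[0], datasets[0]))
        if dz <= 0:
            raise ValueError("non-monotone slice positions after sorting")
    elif "SliceThickness" in first:
        dz = float(first.SliceThickness)
    else:
        raise ValueError(f"{files[0].name}: cannot determine slice spacing (single slice, no SliceThickness)")

    slices = []
    for path, ds in zip(files, datasets):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        slices.append(arr)
    stack = np.stack(slices, axis=0)  # (z, y, x)
    data = np.transpose(stack, (2, 1, 0))  # -> (x, y, z)
    meta = {
        "source_files": [p.name for p in files],
        "series_uid": str(first.SeriesInstanceUID),
    }
    for tag, key in (("KVP", "kV"), ("XRayTubeCurrent", "mA")):
        if tag in first:
            meta[key] = first[tag].value
    return CoreVolume(data=data, spacing_mm=(col_mm, row_mm, float(dz)), meta=meta)


def write_dicom_series(
    volume: CoreVolume, directory: str | os.PathLike, *, series_uid: str | None = None
) -> list[Path]:
    """Write ``volume`` as an int16 secondary-capture DICOM series (test fixtures).

    Values must be integral and fit int16; a lossy write would break the
    round-trip guarantee the readers are tested against.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = volume.data
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError("write_dicom_series requires integral data values")
    rounded = rounded.astype(np.int16)
    series_uid = series_uid or generate_uid()
    sx, sy, sz = volume.spacing_mm
    paths = []
    for z in range(volume.shape[2]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[0]
        ds.PixelSpacing = [f"{sy:g}", f"{sx:g}"]
        ds.SliceThickness = f"{sz:g}"
        ds.ImagePositionPatient = ["0", "0", f"{z * sz:g}"]
        ds.InstanceNumber = z + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "0"
        ds.PixelData = np.ascontiguousarray(rounded[:, :, z].T).tobytes()  # (y, x)
        path = directory / f"slice_{z:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# TIFF image stacks


def read_image_stack(
    source: str | os.PathLike | Sequence[str | os.PathLike],
    spacing_mm: tuple[float, float, float],
) -> CoreVolume:
    """Read an ordered grayscale image stack (multipage TIFF or file list).

    Page order is z order.  Stacks carry no spacing metadata, so
    ``spacing_mm`` must be given explicitly.
    """
    if isinstance(source, (str, os.PathLike)):
        pages = tifffile.imread(str(source))
        if pages.ndim == 2:
            pages = pages[None]
    else:
        arrays = [tifffile.imread(str(p)) for p in source]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"ragged page shapes: {sorted(shapes)}")
        pages = np.stack(arrays, axis=0)
    if pages.ndim != 3:
        raise ValueError(
            "image stack must be single-channel grayscale; "
            f"got page shape {pages.shape[1:]} (convert RGB input to one channel)"
        )
    data = np.transpose(pages, (2, 1, 0))  # (z, y, x) -> (x, y, z)
    return CoreVolume(data=data, spacing_mm=spacing_mm, meta={"source": str(source)})


def write_image_stack(volume: CoreVolume, path: str | os.PathLike) -> Path:
    """Write a volume as a multipage float32/native-dtype TIFF, one page per z slice."""
    path = Path(path)
    pages = np.transpose(volume.data, (2, 1, 0))  # (x, y, z) -> (z, y, x)
    tifffile.imwrite(str(path), np.ascontiguousarray(pages))
    return path


def write_mask_stack(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a boolean retained-voxel mask as a compressed uint8 TIFF stack."""
    path = Path(path)
    pages = np.transpose(mask.astype(np.uint8), (2, 1, 0))
    tifffile.imwrite(str(path), np.ascontiguousarray(pages), compression="zlib")
    return path


# ---------------------------------------------------------------------------
# tables


def write_tables(
    burrow_table: pd.DataFrame | None,
    slice_profiles: Iterable | None,
    path_prefix: str | os.PathLike,
) -> dict[str, Path]:
    """Export the burrow table and/or slice-profile log as CSV spreadsheets.

    Files are ``<prefix>_burrows.csv`` and ``<prefix>_profiles.csv``; numeric
    values keep 6 significant digits and re-read losslessly at that precision.
    An empty table still produces a file with the header row.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if burrow_table is not None:
        p = prefix.parent / (prefix.name + "_burrows.csv")
        burrow_table.to_csv(p, index=False, float_format=_TABLE_FLOAT_FORMAT)
        written["burrows"] = p
    if slice_profiles is not None:
        from .downcore import profiles_to_frame

        frame = (
            slice_profiles
            if isinstance(slice_profiles, pd.DataFrame)
            else profiles_to_frame(list(slice_profiles))
        )
        p = prefix.parent / (prefix.name + "_profiles.csv")
        frame.to_csv(p, index=False, float_format=_TABLE_FLOAT_FORMAT)
        written["profiles"] = p
    return written


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def read_bi_log(path: str | os.PathLike) -> list:
    """Read a depth-binned 2D-image ichnology log.

    Expected columns: ``top_cm, base_cm, bi`` and optionally ``taxa`` (free
    text) and ``disjoint_flag`` (0/1: the 2D structures are disjoint from
    what CT resolves).  Returns :class:`~ichnocore.downcore.BIRecord` rows
    with ``source='image2d'``.
    """
    from .downcore import BIRecord

    frame = pd.read_csv(path)
    required = {"top_cm", "base_cm", "bi"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"BI log {path} missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            BIRecord(
                top_cm=float(row.top_cm),
                base_cm=float(row.base_cm),
                bi=int(row.bi),
                source="image2d",
                taxa=str(getattr(row, "taxa", "")),
                disjoint_flag=bool(int(getattr(row, "disjoint_flag", 0))),
            )
        )
    return records


# ---------------------------------------------------------------------------
# scene configs


def scene_to_yaml(spec: SceneSpec, path: str | os.PathLike) -> Path:
    """Serialise a :class:`SceneSpec` (including burrows) as a YAML config."""
    path = Path(path)
    payload = asdict(spec)
    payload["burrows"] = [asdict(b) for b in spec.burrows]
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(payload), fh, sort_keys=False)
    return path


def scene_from_yaml(path: str | os.PathLike) -> SceneSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    burrows = tuple(BurrowSpec(**{**b, "anchor_mm": tuple(b["anchor_mm"])}) for b in payload.pop("burrows", []))
    for key in ("shape_voxels", "spacing_mm"):
        payload[key] = tuple(payload[key])
    return SceneSpec(burrows=burrows, **payload)


def _plain(obj):
    """Recursively convert numpy scalars/containers to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
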