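"""Dose/phantom persistence: flat binary + JSON sidecar, DICOM-RT, CSV.

The native format is a raw little-endian float64 array (C order) next to
a JSON sidecar describing shape, voxel size, origin and history count --
trivially readable from any language.  A minimal DICOM-RT Dose writer is
provided for interoperability with film/plan analysis software, and dose
planes can be imported from plain CSV matrices (the stand-in for scanned
film exports).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .transport import DoseGrid, VoxelGrid

__all__ = ["save_dose", "load_dose", "write_rtdose", "load_plane_csv"]

_FORMAT_VERSION = 1


def save_dose(dose: DoseGrid, stem) -> Path:
    """Write ``<stem>.raw`` + ``<stem>.json``; returns the sidecar path."""
    stem = Path(stem)
    raw_path = stem.with_suffix(".raw")
    dose.energy_deposited.astype("<f8").tofile(raw_path)
    meta = {
        "format_version": _FORMAT_VERSION,
        "quantity": "energy_deposited_mev",
        "dtype": "<f8",
        "order": "C",
        "shape": list(dose.grid.shape),
        "voxel_size_cm": list(dose.grid.voxel_size),
        "origin_cm": list(np.asarray(dose.grid.origin)),
        "table_top_height_cm": dose.grid.table_top_height,
        "histories": dose.histories,
        "counters": dose.counters,
    }
    sidecar = stem.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def load_dose(stem, grid: VoxelGrid | None = None) -> DoseGrid:
    """Load a dose written by :func:`save_dose`.

    If ``grid`` is omitted a water-density placeholder grid with the
    stored geometry is attached (sufficient for curve/plane extraction
    from homogeneous phantoms).
    """
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    if meta["format_version"] != _FORMAT_VERSION:
        raise ValueError("unsupported dose format version")
    shape = tuple(meta["shape"])
    arr = np.fromfile(stem.with_suffix(".raw"),
                      dtype=meta["dtype"]).reshape(shape)
    if grid is None:
        grid = VoxelGrid.from_hu(
            np.zeros(shape, dtype=np.float32),
            voxel_size=tuple(meta["voxel_size_cm"]),
            origin=np.asarray(meta["origin_cm"]),
            table_top_height=meta.get("table_top_height_cm", 6.0))
    return DoseGrid(energy_deposited=arr, grid=grid,
                    histories=int(meta["histories"]),
                    counters=meta.get("counters", {}))


def write_rtdose(dose: DoseGrid, path, quantity: str = "water") -> Path:
    """Write the dose volume as a minimal DICOM-RT Dose object."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    arr = dose.dose_water if quantity == "water" else dose.dose_medium
    # DICOM frames are axial (z), rows y, cols x
    frames = np.transpose(arr, (2, 1, 0))[::-1]  # top slice first
    scaling = float(frames.max() / (2**31 - 1)) or 1.0
    pixels = np.round(frames / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.DoseUnits = "RELATIVE"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.NumberOfFrames = frames.shape[0]
    ds.Rows = frames.shape[1]
    ds.Columns = frames.shape[2]
    sx, sy, sz = dose.grid.voxel_size
    ds.PixelSpacing = [sy * 10.0, sx * 10.0]  # mm, row then column
    ds.SliceThickness = sz * 10.0
    z_first = dose.grid.z_top - sz / 2.0
    ds.ImagePositionPatient = [
        (dose.grid.origin[0] + sx / 2.0) * 10.0,
        (dose.grid.origin[1] + sy / 2.0) * 10.0,
        z_first * 10.0,
    ]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [-sz * 10.0 * i
                                for i in range(frames.shape[0])]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(pixels, dtype="<u4").tobytes()
    ds.save_as(path, enforce_file_format=True)
    return Path(path)


def load_plane_csv(path) -> np.ndarray:
    """Load a 2D dose plane from a plain CSV matrix."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.ndim != 2:
        raise ValueError("expected a 2D matrix")
    return arr
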