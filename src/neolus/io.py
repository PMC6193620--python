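"""Frame and cohort-manifest input/output.

Frames are 8-bit grayscale B-mode stills. Two on-disk formats are supported:
uncompressed grayscale DICOM (the acquisition format) and 8-bit grayscale PNG
(the synthetic-fixture format). Pixel coordinates are (row, column), 0-based,
row 0 at the skin surface.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .exceptions import FormatError, ValidationError

#: four standard views (emiclavear, anterior/median/posterior axillary) per side
VIEWS = (
    "R_emiclavear", "R_ant_axillary", "R_mid_axillary", "R_post_axillary",
    "L_emiclavear", "L_ant_axillary", "L_mid_axillary", "L_post_axillary",
)

MANIFEST_COLUMNS = (
    "patient_id", "view", "frame_path", "true_grade",
    "rater1", "rater2", "fio2", "pao2", "paco2", "seed",
)


@dataclass
class Frame:
    """One 8-bit grayscale still frame with study metadata."""

    pixels: np.ndarray
    patient_id: str = ""
    view: str = ""
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("frame pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("frame pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _rescale_to_uint8(pixels: np.ndarray, bits_stored: int) -> np.ndarray:
    """Linearly map the full [0, 2**bits_stored - 1] range onto [0, 255]."""
    if bits_stored <= 8:
        return pixels.astype(np.uint8)
    full = (1 << bits_stored) - 1
    scaled = np.round(pixels.astype(np.float64) * 255.0 / full)
    return np.clip(scaled, 0, 255).astype(np.uint8)


def _read_dicom(path: str | os.PathLike) -> np.ndarray:
    ds = pydicom.dcmread(path)
    tsyn = getattr(ds.file_meta, "TransferSyntaxUID", None)
    if tsyn is not None and tsyn.is_compressed:
        raise FormatError(f"{path}: compressed DICOM transfer syntax {tsyn} not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise FormatError(f"{path}: color DICOM (SamplesPerPixel > 1) not supported; "
                          "expected a grayscale frame")
    pixels = ds.pixel_array
    if pixels.ndim != 2:
        raise FormatError(f"{path}: expected a single-frame 2-D DICOM image")
    bits = int(getattr(ds, "BitsStored", 8))
    return _rescale_to_uint8(pixels, bits)


def _read_image(path: str | os.PathLike) -> np.ndarray:
    pixels = iio.imread(path)
    if pixels.ndim == 3:
        raise FormatError(f"{path}: RGB/multichannel image not supported; "
                          "convert to 8-bit grayscale first")
    if pixels.dtype == np.uint16:
        return _rescale_to_uint8(pixels, 16)
    if pixels.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported pixel dtype {pixels.dtype}")
    return pixels


def read_frame(path: str | os.PathLike, patient_id: str = "", view: str = "") -> Frame:
    """Read a grayscale DICOM or PNG still frame as an 8-bit :class:`Frame`.

    Multi-bit DICOM is linearly rescaled to [0, 255]; color input is rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        pixels = _read_dicom(path)
    else:
        pixels = _read_image(path)
    return Frame(pixels=pixels, patient_id=patient_id, view=view, source_path=str(path))


def write_frame_png(frame: Frame | np.ndarray, path: str | os.PathLike) -> None:
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=np.uint8)
    iio.imwrite(path, pixels)


def write_frame_dicom(frame: Frame | np.ndarray, path: str | os.PathLike) -> None:
    """Write a minimal uncompressed monochrome secondary-capture DICOM file."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=np.uint8)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientID = getattr(frame, "patient_id", "") or "anon"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


@dataclass
class ManifestRecord:
    """One patient's rows from a cohort manifest; frames load lazily."""

    patient_id: str
    views: list[str]
    frame_paths: list[str]
    true_grades: list[int]
    rater_grades: tuple[list[int], list[int]]
    fio2: float
    pao2: float
    paco2: float
    _frames: list[Frame] | None = field(default=None, repr=False)

    def load_frames(self) -> list[Frame]:
        if self._frames is None:
            self._frames = [
                read_frame(p, patient_id=self.patient_id, view=v)
                for p, v in zip(self.frame_paths, self.views)
            ]
        return self._frames


def read_cohort_manifest(path: str | os.PathLike,
                         views_per_patient: int = 8) -> list[ManifestRecord]:
    """Read a cohort manifest CSV, grouping rows per patient.

    Validates that every patient has exactly ``views_per_patient`` rows and
    that all grades lie in {0..3}. Frames are loaded lazily on access.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty manifest") from None
    if table.empty:
        raise ValidationError(f"{path}: manifest has no rows")
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")

    for col in ("true_grade", "rater1", "rater2"):
        bad = table.loc[~table[col].isin([0, 1, 2, 3]), "patient_id"]
        if len(bad):
            raise ValidationError(
                f"{path}: {col} outside 0-3 for patient(s) {sorted(set(bad.astype(str)))}")

    records = []
    base = Path(path).parent
    for pid, rows in table.groupby("patient_id", sort=False):
        if len(rows) != views_per_patient:
            raise ValidationError(
                f"{path}: patient {pid} has {len(rows)} views, expected {views_per_patient}")
        paths = [str(p) if os.path.isabs(str(p)) else str(base / str(p))
                 for p in rows["frame_path"]]
        records.append(ManifestRecord(
            patient_id=str(pid),
            views=list(rows["view"].astype(str)),
            frame_paths=paths,
            true_grades=[int(g) for g in rows["true_grade"]],
            rater_grades=([int(g) for g in rows["rater1"]],
                          [int(g) for g in rows["rater2"]]),
            fio2=float(rows["fio2"].iloc[0]),
            pao2=float(rows["pao2"].iloc[0]),
            paco2=float(rows["paco2"].iloc[0]),
        ))
    return records
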