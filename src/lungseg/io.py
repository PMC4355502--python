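"""Readers and writers for radiographs and masks.

PNG/TIFF (8/16-bit) via imageio, DICOM via pydicom (MONOCHROME1 honored as
pre-inverted). Everything is normalized to [0, 1] floats at load time; masks
round-trip as 8-bit 0/255 PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from lungseg.preprocess import Radiograph


def load_image(path: str | Path, profile: str = "auto") -> Radiograph:
    """Load a radiograph from PNG/TIFF/DICOM, normalized to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _load_dicom(path, profile)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any color axis; radiographs are grayscale
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif arr.dtype == np.uint16:
        depth, scale = 16, 65535.0
    else:
        arr = arr.astype(np.float64)
        depth, scale = 16, max(float(arr.max()), 1.0)
    pixels = arr.astype(np.float64) / scale
    return Radiograph(pixels=np.clip(pixels, 0.0, 1.0), profile=profile, source_bit_depth=depth)


def _load_dicom(path: Path, profile: str) -> Radiograph:
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    bits = int(getattr(ds, "BitsStored", 16))
    pixels = arr / float(2**bits - 1)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        pixels = 1.0 - pixels
    return Radiograph(pixels=np.clip(pixels, 0.0, 1.0), profile=profile, source_bit_depth=bits)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask (any nonzero pixel is foreground)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr > 0


def save_image_png16(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(arr * 65535.0).astype(np.uint16))


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def write_dicom(pixels: np.ndarray, path: str | Path, bits: int = 12) -> None:
    """Write a minimal secondary-capture DICOM of a [0, 1] float image."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    data = np.round(arr * (2**bits - 1)).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CR"
    ds.Rows, ds.Columns = data.shape
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.SamplesPerPixel = 1
    ds.BitsAllocated = 16
    ds.BitsStored = bits
    ds.HighBit = bits - 1
    ds.PixelRepresentation = 0
    ds.PixelData = data.tobytes()
    ds.save_as(Path(path), enforce_file_format=True)
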