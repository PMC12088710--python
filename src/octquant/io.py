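"""Mask and pullback I/O, report writing, and the segmentation-backend
adapter contract.

Indexed 8-bit PNG is the canonical mask interchange (one file per frame,
zero-padded frame index in the filename); pixel spacing travels in a
sidecar YAML because PNG carries no reliable physical-units field. NIfTI
is supported for 3D stacks (spacing from the header) and DICOM pullbacks
are read-only sources of frames and PixelSpacing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import yaml
from PIL import Image

from .core import Frame, PixelGeometry, Pullback
from .errors import FormatError, MissingSpacingError, UnknownLabelError

SIDECAR_NAME = "spacing.yaml"

# fixed report precision: arcs 0.1 deg, radial 0.1 um, areas 1e-4 mm2, scores 3 dp
_REPORT_PRECISION = {
    "lipid_arc_deg": 1,
    "calcium_arc_deg": 1,
    "min_fct_um": 1,
    "calcium_depth_um": 1,
    "calcium_thickness_um": 1,
    "fibrous_cap_area_mm2": 4,
    "fibrous_cap_ratio_mm2_per_deg": 6,
    "correspondence_score": 3,
    "dice": 3,
}

_ISO_RTOL = 1e-3


class SegmentationBackend(Protocol):
    """Adapter contract for a pluggable segmentation model.

    Accepts a stack of consecutive grayscale frames (centre frame in the
    middle) and returns a label map for the central frame that obeys the
    ten-class schema. No model ships with this package.
    """

    def predict(self, frame_stack: np.ndarray) -> np.ndarray:  # pragma: no cover
        ...


def _check_labels(arr: np.ndarray, path: Path) -> None:
    if arr.min() < 0 or arr.max() > 9:
        bad = sorted(set(np.unique(arr)) - set(range(10)))
        raise UnknownLabelError(f"{path}: label codes outside 0..9: {bad}")


def write_mask_png(frame: Frame, path: str | Path) -> None:
    """Write a frame as an indexed 8-bit PNG plus a spacing sidecar."""
    path = Path(path)
    img = Image.fromarray(frame.labels.astype(np.uint8), mode="P")
    # 10-entry grayscale ramp palette so masks are inspectable by eye
    palette = []
    for i in range(256):
        v = min(255, i * 28)
        palette.extend([v, v, v])
    img.putpalette(palette)
    img.save(path)
    sidecar = path.parent / SIDECAR_NAME
    sidecar.write_text(yaml.safe_dump({"spacing_mm": frame.spacing_mm}))


def read_mask_png(path: str | Path, spacing_mm: float | None = None) -> Frame:
    """Read an indexed PNG mask; spacing from the sidecar unless given."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        arr = np.asarray(Image.open(path), dtype=np.int16)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable PNG ({exc})") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel indexed mask")
    _check_labels(arr, path)
    if spacing_mm is None:
        sidecar = path.parent / SIDECAR_NAME
        if not sidecar.exists():
            raise MissingSpacingError(f"{path}: no spacing given and no {SIDECAR_NAME} sidecar")
        spacing_mm = float(yaml.safe_load(sidecar.read_text())["spacing_mm"])
    geom = PixelGeometry(spacing_mm=spacing_mm, frame_shape=arr.shape)
    idx = _frame_index_from_name(path.stem)
    return Frame(arr.astype(np.uint8), geom, frame_index=idx)


def _frame_index_from_name(stem: str) -> int:
    digits = "".join(ch for ch in stem if ch.isdigit())
    return int(digits) if digits else 0


def write_pullback_nifti(pullback: Pullback, path: str | Path) -> None:
    """Write a pullback as a 3D NIfTI volume (frames along the last axis)."""
    import nibabel as nib

    vol = np.stack([f.labels for f in pullback.frames], axis=-1).astype(np.uint8)
    s = pullback.frames[0].spacing_mm
    affine = np.diag([s, s, pullback.frame_pitch_mm, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_mask_nifti(path: str | Path, frame_index: int = 0) -> Frame:
    """Read one frame of a NIfTI label volume; spacing from the header.

    Anisotropic in-plane spacing is rejected: the quantification geometry
    assumes square pixels.
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    sx, sy = float(zooms[0]), float(zooms[1])
    if abs(sx - sy) > _ISO_RTOL * max(sx, sy):
        raise MissingSpacingError(f"{path}: anisotropic in-plane spacing ({sx} x {sy} mm)")
    data = np.asarray(img.dataobj)
    arr = data[..., frame_index] if data.ndim == 3 else data
    arr = np.asarray(arr, dtype=np.int16)
    _check_labels(arr, path)
    geom = PixelGeometry(spacing_mm=sx, frame_shape=arr.shape)
    return Frame(arr.astype(np.uint8), geom, frame_index=frame_index)


def read_dicom_pullback(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Extract the frame stack and in-plane PixelSpacing from a DICOM file.

    Returns the raw image array (frames first) and the isotropic spacing
    in mm, or None when the file carries no PixelSpacing. Read-only; this
    package never writes DICOM.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is None:
        fgs = getattr(ds, "SharedFunctionalGroupsSequence", None)
        if fgs:
            pm = getattr(fgs[0], "PixelMeasuresSequence", None)
            if pm:
                ps = getattr(pm[0], "PixelSpacing", None)
    if ps is not None:
        sx, sy = float(ps[0]), float(ps[1])
        if abs(sx - sy) > _ISO_RTOL * max(sx, sy):
            raise MissingSpacingError(f"{path}: anisotropic PixelSpacing")
        spacing = sx
    return np.asarray(arr), spacing


def stack_frames(pullback: Pullback, center_index: int, k: int = 7) -> list[Frame]:
    """``k`` consecutive frames centred on ``center_index``.

    Matches the pseudo-3D input convention of channel-stacked
    segmentation models; frames beyond either end of the pullback are
    replicated from the nearest edge frame.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    half = k // 2
    n = len(pullback)
    return [pullback.frames[min(max(center_index + d, 0), n - 1)] for d in range(-half, half + 1)]


def _round_value(key: str, value):
    if value is None or isinstance(value, (bool, str)):
        return value
    if isinstance(value, (int, np.integer)):
        return int(value)
    nd = _REPORT_PRECISION.get(key)
    return round(float(value), nd) if nd is not None else float(value)


def write_report(rows: Sequence[dict], path: str | Path, fmt: str = "csv") -> None:
    """Write metric rows with deterministic column order and precision.

    Column order follows the first row's key order; reruns with the same
    inputs produce byte-identical files.
    """
    if not rows:
        raise IOError("refusing to write an empty report")
    path = Path(path)
    columns = list(rows[0].keys())
    rounded = [{c: _round_value(c, row.get(c)) for c in columns} for row in rows]
    if fmt == "csv":
        lines = [",".join(columns)]
        for row in rounded:
            lines.append(",".join("" if row[c] is None else str(row[c]) for c in columns))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        path.write_text(json.dumps(rounded, indent=2, sort_keys=False) + "\n")
    else:
        raise ValueError("fmt must be 'csv' or 'json'")


def metrics_to_row(frame_index: int, metrics) -> dict:
    """Flatten a PlaqueMetrics record into one report row."""
    row = {"frame_index": frame_index}
    for name in metrics.FIELD_ORDER:
        row[name] = getattr(metrics, name)
    for cls, flag in metrics.presence.items():
        row[f"present_{cls}"] = flag
    return row
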