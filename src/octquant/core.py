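"""Frame containers, geometry conventions and polar profile extraction.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, with pixel centers at
  integer coordinates;
* angles are measured in degrees counterclockwise from the +x (column)
  axis, i.e. a ray at angle theta advances by ``dcol = cos(theta)``,
  ``drow = -sin(theta)`` per unit radius;
* pixels are isotropic; all physical radii are ``pixel radius * spacing``.

Arc magnitudes are rotation invariant, so the angular origin is an
internal convention only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import NoLumenError, OriginOutOfBoundsError
from .schema import DEFAULT_SCHEMA, LUMEN, LabelSchema

ISSUE_NO_LUMEN = "ISSUE_NO_LUMEN"
ISSUE_UNKNOWN_LABEL = "ISSUE_UNKNOWN_LABEL"

#: 8-connectivity structuring element used for all blob operations.
STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PixelGeometry:
    """Isotropic pixel geometry of one cross-sectional frame.

    Parameters
    ----------
    spacing_mm : float
        Physical edge length of one pixel in millimetres.
    frame_shape : tuple of int
        ``(rows, cols)`` of the label grid.
    """

    spacing_mm: float
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        r, c = self.frame_shape
        if r < 32 or c < 32:
            raise ValueError("frame must be at least 32x32 pixels")


@dataclass
class Frame:
    """A single cross-sectional label map with its physical geometry."""

    labels: np.ndarray
    geometry: PixelGeometry
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.geometry.frame_shape:
            raise ValueError("label grid shape does not match geometry")

    @property
    def spacing_mm(self) -> float:
        return self.geometry.spacing_mm

    def copy(self) -> "Frame":
        return Frame(self.labels.copy(), self.geometry, self.frame_index)


@dataclass
class Pullback:
    """Ordered stack of frames from one motorized catheter withdrawal."""

    frames: list[Frame]
    pullback_id: str = "pullback"
    frame_pitch_mm: float = 0.1

    def __post_init__(self) -> None:
        geoms = {f.geometry for f in self.frames}
        if len(geoms) > 1:
            from .errors import GeometryMismatchError

            raise GeometryMismatchError("all frames must share one geometry")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RayProfileSet:
    """Per-angle ordered class intervals along rays from the lumen centroid.

    ``rays[k]`` is the ordered list of ``(class_code, r_start_mm, r_end_mm)``
    radial intervals along the ray at angle ``k * (360 / n_rays)`` degrees.
    """

    n_rays: int
    origin: tuple[float, float]
    rays: list[list[tuple[int, float, float]]]
    spacing_mm: float

    @property
    def bin_deg(self) -> float:
        return 360.0 / self.n_rays

    def ray_classes(self, k: int) -> set[int]:
        return {code for code, _, _ in self.rays[k]}


def validate_frame(frame: Frame, schema: LabelSchema = DEFAULT_SCHEMA) -> list[str]:
    """Report structural issues with a frame (report-only, never raises).

    Returns a list of issue codes: ``ISSUE_NO_LUMEN`` when the frame has no
    lumen pixel, ``ISSUE_UNKNOWN_LABEL`` when any pixel code falls outside
    the ten-class schema. An empty list marks a well-formed frame.
    """
    issues: list[str] = []
    labels = frame.labels
    if not np.any(labels == schema.code("lumen")):
        issues.append(ISSUE_NO_LUMEN)
    if labels.min() < 0 or labels.max() > 9:
        issues.append(ISSUE_UNKNOWN_LABEL)
    return issues


def lumen_centroid(frame: Frame, schema: LabelSchema = DEFAULT_SCHEMA) -> tuple[float, float]:
    """Sub-pixel centroid of the largest connected lumen component.

    Disjoint lumen speckles are ignored: the centroid is the arithmetic
    mean of pixel-center coordinates of the largest 8-connected lumen
    blob, so stray mislabelled pixels far from the vessel cannot drag the
    ray-cast origin.
    """
    mask = frame.labels == schema.code("lumen")
    if not mask.any():
        raise NoLumenError("frame contains no lumen pixels")
    lab, n = ndimage.label(mask, structure=STRUCT_8)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (int(np.argmax(sizes)) + 1)
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def cast_rays(
    frame: Frame,
    origin: tuple[float, float],
    n_rays: int = 720,
    step_px: float = 0.25,
) -> RayProfileSet:
    """Cast equiangular rays from ``origin`` and merge labels into intervals.

    Labels are sampled by nearest-neighbour lookup every ``step_px`` pixels
    (default a quarter pixel, so interval bounds carry sub-pixel
    resolution) from the origin to the frame edge; consecutive
    identical classes merge into radial intervals whose bounds sit at the
    midpoints between samples, converted to millimetres.
    """
    rows, cols = frame.geometry.frame_shape
    orow, ocol = origin
    if not (0 <= orow <= rows - 1 and 0 <= ocol <= cols - 1):
        raise OriginOutOfBoundsError(f"origin {origin} outside frame {frame.geometry.frame_shape}")
    if n_rays < 90:
        raise ValueError("n_rays must be at least 90")

    spacing = frame.spacing_mm
    theta = np.deg2rad(np.arange(n_rays) * (360.0 / n_rays))
    drow = -np.sin(theta)
    dcol = np.cos(theta)

    corners = [(0.0, 0.0), (0.0, cols - 1.0), (rows - 1.0, 0.0), (rows - 1.0, cols - 1.0)]
    r_max = max(np.hypot(orow - r, ocol - c) for r, c in corners) + 1.0
    radii = np.arange(0.0, r_max, step_px)  # in pixels
    # (n_rays, n_samples) sample coordinates
    rr = orow + np.outer(drow, radii)
    cc = ocol + np.outer(dcol, radii)
    ri = np.rint(rr).astype(np.intp)
    ci = np.rint(cc).astype(np.intp)
    inside = (ri >= 0) & (ri < rows) & (ci >= 0) & (ci < cols)
    # the rectangle is convex, so in-bounds samples form a prefix per ray
    counts = inside.sum(axis=1)
    ri = np.clip(ri, 0, rows - 1)
    ci = np.clip(ci, 0, cols - 1)
    samples = frame.labels[ri, ci]

    mm_per_step = step_px * spacing
    rays: list[list[tuple[int, float, float]]] = []
    for k in range(n_rays):
        m = int(counts[k])
        lab = samples[k, :m]
        if m == 0:
            rays.append([])
            continue
        change = np.flatnonzero(lab[1:] != lab[:-1])
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change, [m - 1]))
        ray: list[tuple[int, float, float]] = []
        for i0, i1 in zip(starts, ends):
            r_start = max(0.0, (i0 - 0.5)) * mm_per_step
            r_end = (i1 + 0.5) * mm_per_step
            ray.append((int(lab[i0]), r_start, r_end))
        rays.append(ray)
    return RayProfileSet(n_rays=n_rays, origin=(float(orow), float(ocol)), rays=rays, spacing_mm=spacing)


def pixel_angles(shape: tuple[int, int], origin: tuple[float, float]) -> np.ndarray:
    """Angle (degrees, [0, 360)) of every pixel center about ``origin``.

    Uses the package-wide convention: counterclockwise from the +column
    axis, with the row axis pointing down the image.
    """
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    ang = np.degrees(np.arctan2(-(rr - origin[0]), cc - origin[1]))
    return np.mod(ang, 360.0)


def pixel_radii_mm(
    shape: tuple[int, int], origin: tuple[float, float], spacing_mm: float
) -> np.ndarray:
    """Radial distance (mm) of every pixel center from ``origin``."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.hypot(rr - origin[0], cc - origin[1]) * spacing_mm
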