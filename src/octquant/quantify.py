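"""Per-frame plaque quantification from centroid ray casts.

The angular extent (arc) of lipid and calcified plaque is measured by
evaluating class presence along equiangular rays cast from the lumen
centroid. Radial measures (minimum fibrous cap thickness, calcium depth
and thickness) are read off the same ray profiles; the fibrous cap area
counts intima pixels inside the lipid arc. Plaques visible on both sides
of the guidewire shadow are measured continuously across it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import Frame, RayProfileSet, cast_rays, lumen_centroid, pixel_angles
from .errors import UndefinedScoreError, ZeroArcError
from .schema import (
    CALCIUM,
    DEFAULT_SCHEMA,
    GUIDEWIRE,
    INTIMA,
    LIPID,
    LUMEN,
    LabelSchema,
)

#: lipid-rich plaque threshold on the (cumulative) lipid arc, degrees
LRP_ARC_THRESHOLD_DEG = 90.0


@dataclass
class AngularSectorSet:
    """Disjoint angular sectors occupied by one class, on a fixed binning.

    Sectors are half-open ``[theta_start, theta_end)`` with
    ``theta_end = theta_start + extent`` (``theta_end`` may exceed 360 for
    sectors wrapping through 0°). ``bridged`` flags sectors that span a
    guidewire shadow; ``positive_bins``/``bridged_bins`` are the underlying
    angular indicator arrays (bin ``k`` covers ``[k*w, (k+1)*w)`` degrees
    with ``w = 360/n_bins``).
    """

    class_code: int
    n_bins: int
    positive_bins: np.ndarray
    bridged_bins: np.ndarray
    sectors: list[tuple[float, float]] = field(default_factory=list)
    bridged: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sectors:
            self.sectors, self.bridged = _bins_to_sectors(
                self.positive_bins, self.bridged_bins, 360.0 / self.n_bins
            )

    @property
    def bin_deg(self) -> float:
        return 360.0 / self.n_bins

    @classmethod
    def from_intervals(
        cls,
        class_code: int,
        intervals: Sequence[tuple[float, float]],
        n_bins: int = 3600,
    ) -> "AngularSectorSet":
        """Rasterize analytic ``[start, end)`` degree intervals onto bins."""
        pos = np.zeros(n_bins, dtype=bool)
        w = 360.0 / n_bins
        centers = (np.arange(n_bins) + 0.5) * w
        for start, end in intervals:
            span = (centers - start) % 360.0
            pos |= span < ((end - start) % 360.0 if (end - start) % 360.0 else 360.0)
        return cls(class_code, n_bins, pos, np.zeros(n_bins, dtype=bool))


def _bins_to_sectors(
    pos: np.ndarray, bridged: np.ndarray, bin_deg: float
) -> tuple[list[tuple[float, float]], list[bool]]:
    n = pos.size
    if pos.all():
        return [(0.0, 360.0)], [bool(bridged.any())]
    if not pos.any():
        return [], []
    # circular runs: rotate so index 0 is negative, then take linear runs
    first_neg = int(np.argmin(pos))
    rolled = np.roll(pos, -first_neg)
    rolled_br = np.roll(bridged, -first_neg)
    d = np.diff(rolled.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if rolled[-1]:
        ends = np.append(ends, n)
    sectors, flags = [], []
    for s, e in zip(starts, ends):
        theta0 = ((s + first_neg) % n) * bin_deg
        sectors.append((theta0, theta0 + (e - s) * bin_deg))
        flags.append(bool(rolled_br[s:e].any()))
    order = np.argsort([s for s, _ in sectors])
    return [sectors[i] for i in order], [flags[i] for i in order]


def class_sectors(
    profiles: RayProfileSet,
    class_code: int,
    bridge_guidewire: bool = True,
) -> AngularSectorSet:
    """Angular sectors where ``class_code`` is present on the ray casts.

    A ray's angular bin is positive when any interval along the ray has the
    class. With ``bridge_guidewire``, a maximal run of guidewire-shadowed
    rays immediately flanked on both sides by class-positive rays is
    absorbed into one continuous (bridged) sector, so a plaque visible on
    both sides of the guidewire is measured across the shadow.
    """
    n = profiles.n_rays
    pos = np.array([class_code in profiles.ray_classes(k) for k in range(n)])
    bridged = np.zeros(n, dtype=bool)
    if bridge_guidewire and pos.any():
        gw = np.array(
            [GUIDEWIRE in profiles.ray_classes(k) for k in range(n)]
        ) & ~pos
        if gw.any() and not gw.all():
            # rotate so index 0 is outside any shadow run, making all runs linear
            shift = int(np.argmin(gw))
            gw_r = np.roll(gw, -shift)
            pos_r = np.roll(pos, -shift)
            br_r = np.zeros(n, dtype=bool)
            lab, nruns = ndimage.label(gw_r)
            for run_id in range(1, nruns + 1):
                idx = np.flatnonzero(lab == run_id)
                before = (int(idx[0]) - 1) % n
                after = (int(idx[-1]) + 1) % n
                if pos_r[before] and pos_r[after]:
                    pos_r[idx] = True
                    br_r[idx] = True
            pos = np.roll(pos_r, shift)
            bridged = np.roll(br_r, shift)
    return AngularSectorSet(class_code, n, pos, bridged)


def arc_degrees(sectors: AngularSectorSet) -> float:
    """Cumulative arc: the sum of all sector extents, in degrees."""
    return float(sectors.positive_bins.sum()) * sectors.bin_deg


def min_radial_gap(
    profiles: RayProfileSet, target_class: int, schema: LabelSchema = DEFAULT_SCHEMA
) -> Optional[float]:
    """Minimum lumen-to-target radial gap over all rays, in micrometres.

    Implements the minimum fibrous cap thickness (``target_class`` lipid)
    and the calcium depth (``target_class`` calcium): on every ray where
    the target appears, the gap is the radial start of the first target
    interval minus the radial end of the lumen interval. Rays passing
    through the guidewire shadow are excluded (no tissue is visible
    behind it). Returns None when no qualifying ray exists.
    """
    lumen = schema.code("lumen")
    best: Optional[float] = None
    for ray in profiles.rays:
        classes = {c for c, _, _ in ray}
        if target_class not in classes or GUIDEWIRE in classes or lumen not in classes:
            continue
        lumen_end = next(r_end for c, _, r_end in ray if c == lumen)
        target_start = next(r_start for c, r_start, _ in ray if c == target_class)
        gap = max(0.0, target_start - lumen_end)
        if best is None or gap < best:
            best = gap
    return None if best is None else best * 1000.0


def max_radial_thickness(
    profiles: RayProfileSet, target_class: int = CALCIUM
) -> Optional[float]:
    """Maximum radial extent of ``target_class`` over all rays, in µm.

    Per ray the lengths of all target intervals are summed (adluminal to
    abluminal border as seen from the lumen centroid); the maximum over
    rays is returned, or None when the class is absent.
    """
    best: Optional[float] = None
    for ray in profiles.rays:
        total = sum(r_end - r_start for c, r_start, r_end in ray if c == target_class)
        if total > 0 and (best is None or total > best):
            best = total
    return None if best is None else best * 1000.0


def fibrous_cap_area(
    frame: Frame,
    lipid_sectors: AngularSectorSet,
    origin: tuple[float, float],
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> float:
    """Total intima area inside the (non-bridged) lipid arc, in mm².

    Counts intima pixels whose angular coordinate about the lumen centroid
    falls in a lipid-positive angular bin; bins bridged across the
    guidewire shadow contribute nothing (no tissue pixels exist behind
    the shadow).
    """
    counted = lipid_sectors.positive_bins & ~lipid_sectors.bridged_bins
    if not counted.any():
        return 0.0
    intima = frame.labels == schema.code("intima")
    if not intima.any():
        return 0.0
    ang = pixel_angles(frame.geometry.frame_shape, origin)
    bins = np.minimum(
        (ang / lipid_sectors.bin_deg).astype(np.intp), lipid_sectors.n_bins - 1
    )
    n_px = int(np.count_nonzero(counted[bins] & intima))
    return n_px * frame.spacing_mm**2


def fibrous_cap_ratio(area_mm2: float, arc_deg: float) -> float:
    """Fibrous cap area divided by the lipid arc (mm² per degree)."""
    if arc_deg <= 0:
        raise ZeroArcError("fibrous cap ratio undefined for a zero lipid arc")
    return area_mm2 / arc_deg


def classify_lrp(lipid_arc_deg: float) -> bool:
    """Lipid-rich plaque: lipid arc of at least 90 degrees (inclusive)."""
    return lipid_arc_deg >= LRP_ARC_THRESHOLD_DEG


def correspondence_score(ref: AngularSectorSet, pred: AngularSectorSet) -> float:
    """Arc correspondence: twice the angular overlap over the arc sum.

    This is the Dice coefficient of the two angular indicator sets: 1 for
    identical sectors, 0 for disjoint ones. Undefined when both arcs are
    zero.
    """
    if ref.n_bins != pred.n_bins:
        raise ValueError("sector sets must share one angular binning")
    arc_ref = arc_degrees(ref)
    arc_pred = arc_degrees(pred)
    if arc_ref + arc_pred == 0:
        raise UndefinedScoreError("both arcs are zero")
    inter = float((ref.positive_bins & pred.positive_bins).sum()) * ref.bin_deg
    return 2.0 * inter / (arc_ref + arc_pred)


def correspondence_from_arcs(arc_ref_deg: float, arc_pred_deg: float, overlap_deg: float) -> float:
    """Correspondence score from scalar arcs and their angular overlap."""
    if arc_ref_deg + arc_pred_deg == 0:
        raise UndefinedScoreError("both arcs are zero")
    return 2.0 * overlap_deg / (arc_ref_deg + arc_pred_deg)


def frame_presence(frame: Frame, class_code: int) -> bool:
    """Binary frame-wise presence: at least one pixel of the class remains."""
    return bool(np.any(frame.labels == class_code))


def _edt_min_gap(frame: Frame, target_class: int, schema: LabelSchema) -> Optional[float]:
    """Shortest Euclidean lumen-to-target distance (µm); sensitivity variant."""
    lumen = frame.labels == schema.code("lumen")
    target = frame.labels == target_class
    if not lumen.any() or not target.any():
        return None
    dist = ndimage.distance_transform_edt(~lumen) * frame.spacing_mm
    return float(dist[target].min()) * 1000.0


@dataclass
class QuantifyConfig:
    """Tunable parameters of the quantification pipeline."""

    n_rays: int = 720
    bridge_guidewire: bool = True
    fct_mode: str = "radial"  # "radial" (along centroid rays) or "edt"

    def __post_init__(self) -> None:
        if self.fct_mode not in ("radial", "edt"):
            raise ValueError("fct_mode must be 'radial' or 'edt'")


@dataclass
class PlaqueMetrics:
    """Per-frame plaque quantification record.

    Angular measures in degrees, radial measures in micrometres, areas in
    mm². Radial/area fields are None when the corresponding plaque class
    is absent from the frame.
    """

    lipid_arc_deg: float
    calcium_arc_deg: float
    min_fct_um: Optional[float]
    fibrous_cap_area_mm2: Optional[float]
    fibrous_cap_ratio_mm2_per_deg: Optional[float]
    calcium_depth_um: Optional[float]
    calcium_thickness_um: Optional[float]
    presence: dict[str, bool]
    is_lrp: bool

    FIELD_ORDER = (
        "lipid_arc_deg",
        "calcium_arc_deg",
        "min_fct_um",
        "fibrous_cap_area_mm2",
        "fibrous_cap_ratio_mm2_per_deg",
        "calcium_depth_um",
        "calcium_thickness_um",
        "is_lrp",
    )


def quantify_frame(
    frame: Frame,
    config: QuantifyConfig | None = None,
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> PlaqueMetrics:
    """Full per-frame quantification: centroid → rays → sectors → metrics."""
    config = config or QuantifyConfig()
    origin = lumen_centroid(frame, schema)
    profiles = cast_rays(frame, origin, n_rays=config.n_rays)

    lipid_sec = class_sectors(profiles, schema.code("lipid"), config.bridge_guidewire)
    calc_sec = class_sectors(profiles, schema.code("calcium"), config.bridge_guidewire)
    lipid_arc = arc_degrees(lipid_sec)
    calcium_arc = arc_degrees(calc_sec)

    presence = {
        name: frame_presence(frame, code)
        for name, code in schema.class_ids.items()
        if name != "background"
    }

    if presence["lipid"]:
        if config.fct_mode == "edt":
            min_fct = _edt_min_gap(frame, schema.code("lipid"), schema)
        else:
            min_fct = min_radial_gap(profiles, schema.code("lipid"), schema)
        cap_area = fibrous_cap_area(frame, lipid_sec, origin, schema)
        cap_ratio = fibrous_cap_ratio(cap_area, lipid_arc) if lipid_arc > 0 else None
    else:
        min_fct, cap_area, cap_ratio = None, None, None

    if presence["calcium"]:
        if config.fct_mode == "edt":
            calcium_depth = _edt_min_gap(frame, schema.code("calcium"), schema)
        else:
            calcium_depth = min_radial_gap(profiles, schema.code("calcium"), schema)
        calcium_thickness = max_radial_thickness(profiles, schema.code("calcium"))
    else:
        calcium_depth, calcium_thickness = None, None

    return PlaqueMetrics(
        lipid_arc_deg=lipid_arc,
        calcium_arc_deg=calcium_arc,
        min_fct_um=min_fct,
        fibrous_cap_area_mm2=cap_area,
        fibrous_cap_ratio_mm2_per_deg=cap_ratio,
        calcium_depth_um=calcium_depth,
        calcium_thickness_um=calcium_thickness,
        presence=presence,
        is_lrp=presence["lipid"] and classify_lrp(lipid_arc),
    )
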