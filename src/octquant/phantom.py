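"""Synthetic vessel-phantom label maps with closed-form quantification.

Phantoms emulate the concentric anatomy of a coronary cross-section on
OCT — lumen disc, intima and media annuli — with angular plaque sectors
of known arc, cap thickness and plaque thickness, an optional guidewire
shadow wedge, an optional side branch, and small isolated speckle blobs.
Every quantification measure of a phantom is known in closed form, which
makes rendered phantoms the package's ground-truth oracle.

Only label maps are produced; OCT signal intensities, speckle texture of
raw imagery and light attenuation are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .core import Frame, PixelGeometry, Pullback, pixel_angles, pixel_radii_mm
from .errors import GeometryMismatchError, SpecInfeasibleError
from .quantify import LRP_ARC_THRESHOLD_DEG, PlaqueMetrics
from .schema import (
    BACKGROUND,
    CALCIUM,
    DEFAULT_SCHEMA,
    GUIDEWIRE,
    INTIMA,
    LIPID,
    LUMEN,
    MEDIA,
    SIDE_BRANCH,
)

_ADJ_EPS_DEG = 1e-6


@dataclass(frozen=True)
class PlaqueSectorSpec:
    """One angular plaque sector.

    The plaque annulus starts at ``lumen_radius + cap_thickness_mm`` and
    extends radially by ``plaque_thickness_mm``; the cap between lumen
    border and plaque is rendered as intima. For lipid the cap is the
    fibrous cap; for calcium it is the tissue determining calcium depth.
    """

    plaque_class: int  # LIPID or CALCIUM
    theta_start_deg: float
    extent_deg: float
    cap_thickness_mm: float
    plaque_thickness_mm: float

    def __post_init__(self) -> None:
        if self.plaque_class not in (LIPID, CALCIUM):
            raise ValueError("plaque_class must be lipid or calcium")
        if not (0 < self.extent_deg <= 360):
            raise ValueError("extent_deg must be in (0, 360]")
        if self.cap_thickness_mm < 0 or self.plaque_thickness_mm <= 0:
            raise ValueError("cap >= 0 and plaque thickness > 0 required")

    @property
    def theta_end_deg(self) -> float:
        return self.theta_start_deg + self.extent_deg


@dataclass(frozen=True)
class SpeckleSpec:
    """Isolated noise blobs dropped on the background, away from anatomy."""

    class_code: int
    n_components: int = 3
    component_area_px: int = 10
    seed: int = 0


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic cross-section."""

    geometry: PixelGeometry
    lumen_center_px: tuple[float, float]
    lumen_radius_mm: float
    intima_thickness_mm: float
    media_thickness_mm: float
    sectors: list[PlaqueSectorSpec] = field(default_factory=list)
    guidewire: Optional[tuple[float, float]] = None  # (theta_center_deg, width_deg)
    side_branch: Optional[tuple[float, float]] = None
    speckle: Optional[SpeckleSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for cls in (LIPID, CALCIUM):
            ivals = sorted(
                ((s.theta_start_deg % 360.0, s.extent_deg) for s in self.sectors if s.plaque_class == cls)
            )
            for (a0, e0), (a1, _) in zip(ivals, ivals[1:]):
                if a1 < a0 + e0 - _ADJ_EPS_DEG:
                    raise ValueError("plaque sectors of one class must not overlap angularly")
        for wedge in (self.guidewire, self.side_branch):
            if wedge is None:
                continue
            w0 = (wedge[0] - wedge[1] / 2.0) % 360.0
            for s in self.sectors:
                if _angular_overlap(w0, wedge[1], s.theta_start_deg % 360.0, s.extent_deg) > _ADJ_EPS_DEG:
                    raise ValueError("guidewire/side-branch wedge overlaps a plaque sector")

    @property
    def max_outer_radius_mm(self) -> float:
        wall = self.intima_thickness_mm + self.media_thickness_mm
        plaque = max((s.cap_thickness_mm + s.plaque_thickness_mm for s in self.sectors), default=0.0)
        return self.lumen_radius_mm + max(wall, plaque)


def _angular_overlap(a_start: float, a_ext: float, b_start: float, b_ext: float) -> float:
    """Overlap in degrees of two circular intervals given as (start, extent)."""
    total = 0.0
    for sa in (a_start, a_start - 360.0):
        lo = max(sa, b_start)
        hi = min(sa + a_ext, b_start + b_ext)
        total += max(0.0, hi - lo)
        lo = max(sa, b_start - 360.0)
        hi = min(sa + a_ext, b_start - 360.0 + b_ext)
        total += max(0.0, hi - lo)
    return total


def _wedge_mask(ang: np.ndarray, center_deg: float, width_deg: float) -> np.ndarray:
    start = (center_deg - width_deg / 2.0) % 360.0
    return ((ang - start) % 360.0) < width_deg


def _sector_mask(ang: np.ndarray, start_deg: float, extent_deg: float) -> np.ndarray:
    return ((ang - start_deg) % 360.0) < extent_deg


def analytic_cap_area(spec: PhantomSpec) -> float:
    """Closed-form fibrous cap area: intima inside the lipid sectors, mm².

    Each lipid sector contributes the annulus-sector area between the
    lumen border and the plaque's adluminal border:
    ``(extent/360) * pi * ((r_lumen + cap)^2 - r_lumen^2)``.
    """
    r = spec.lumen_radius_mm
    total = 0.0
    for s in spec.sectors:
        if s.plaque_class == LIPID:
            total += (s.extent_deg / 360.0) * np.pi * ((r + s.cap_thickness_mm) ** 2 - r**2)
    return float(total)


def _bridged_extra_deg(spec: PhantomSpec, cls: int) -> float:
    """Guidewire width added to the arc when flanked by ``cls`` sectors."""
    if spec.guidewire is None:
        return 0.0
    center, width = spec.guidewire
    g0 = (center - width / 2.0) % 360.0
    g1 = (g0 + width) % 360.0
    touches_start = any(
        s.plaque_class == cls and abs((s.theta_end_deg - g0) % 360.0) < _ADJ_EPS_DEG
        for s in spec.sectors
    )
    touches_end = any(
        s.plaque_class == cls and abs((s.theta_start_deg - g1) % 360.0) < _ADJ_EPS_DEG
        for s in spec.sectors
    )
    return width if (touches_start and touches_end) else 0.0


def ground_truth_metrics(spec: PhantomSpec) -> PlaqueMetrics:
    """Closed-form quantification record implied by a phantom spec."""
    lipid = [s for s in spec.sectors if s.plaque_class == LIPID]
    calcium = [s for s in spec.sectors if s.plaque_class == CALCIUM]
    lipid_arc = sum(s.extent_deg for s in lipid) + _bridged_extra_deg(spec, LIPID)
    calcium_arc = sum(s.extent_deg for s in calcium) + _bridged_extra_deg(spec, CALCIUM)
    cap_area = analytic_cap_area(spec) if lipid else None
    presence = {
        "lumen": True,
        "guidewire_artefact": spec.guidewire is not None,
        "side_branch": spec.side_branch is not None,
        "intima": True,
        "media": True,
        "lipid": bool(lipid),
        "calcium": bool(calcium),
        "thrombus": bool(spec.speckle and spec.speckle.class_code == 8),
        "plaque_rupture": bool(spec.speckle and spec.speckle.class_code == 9),
    }
    return PlaqueMetrics(
        lipid_arc_deg=lipid_arc,
        calcium_arc_deg=calcium_arc,
        min_fct_um=min(s.cap_thickness_mm for s in lipid) * 1000.0 if lipid else None,
        fibrous_cap_area_mm2=cap_area,
        fibrous_cap_ratio_mm2_per_deg=(cap_area / lipid_arc) if lipid and lipid_arc > 0 else None,
        calcium_depth_um=min(s.cap_thickness_mm for s in calcium) * 1000.0 if calcium else None,
        calcium_thickness_um=max(s.plaque_thickness_mm for s in calcium) * 1000.0 if calcium else None,
        presence=presence,
        is_lrp=bool(lipid) and lipid_arc >= LRP_ARC_THRESHOLD_DEG,
    )


def render_phantom(spec: PhantomSpec) -> tuple[Frame, PlaqueMetrics]:
    """Rasterize a phantom spec into a label map plus its analytic metrics.

    Rendering is concentric from the lumen outward; within each plaque
    sector the intima forms the cap between lumen and plaque, and the
    media is interrupted (mimicking signal attenuation behind plaque).
    The guidewire wedge overwrites everything outside the lumen;
    side-branch wedges replace wall labels. Speckle blobs land on
    background at least 5 px from all structures, reproducibly under the
    spec seed.
    """
    rows, cols = spec.geometry.frame_shape
    spacing = spec.geometry.spacing_mm
    half_extent = min(
        spec.lumen_center_px[0],
        spec.lumen_center_px[1],
        rows - 1 - spec.lumen_center_px[0],
        cols - 1 - spec.lumen_center_px[1],
    ) * spacing
    if spec.max_outer_radius_mm >= half_extent:
        raise SpecInfeasibleError(
            f"outer radius {spec.max_outer_radius_mm:.2f} mm exceeds frame half-extent {half_extent:.2f} mm"
        )

    ang = pixel_angles((rows, cols), spec.lumen_center_px)
    rad = pixel_radii_mm((rows, cols), spec.lumen_center_px, spacing)
    r_lum = spec.lumen_radius_mm

    labels = np.full((rows, cols), BACKGROUND, dtype=np.uint8)
    labels[rad < r_lum + spec.intima_thickness_mm + spec.media_thickness_mm] = MEDIA
    labels[rad < r_lum + spec.intima_thickness_mm] = INTIMA
    labels[rad < r_lum] = LUMEN

    for s in spec.sectors:
        in_sector = _sector_mask(ang, s.theta_start_deg, s.extent_deg) & (rad >= r_lum)
        labels[in_sector] = BACKGROUND  # media interrupted behind plaque
        labels[in_sector & (rad < r_lum + s.cap_thickness_mm + s.plaque_thickness_mm)] = s.plaque_class
        labels[in_sector & (rad < r_lum + s.cap_thickness_mm)] = INTIMA

    if spec.side_branch is not None:
        wedge = _wedge_mask(ang, *spec.side_branch)
        wall = (labels == INTIMA) | (labels == MEDIA)
        labels[wedge & wall] = SIDE_BRANCH

    if spec.guidewire is not None:
        wedge = _wedge_mask(ang, *spec.guidewire)
        labels[wedge & (rad >= r_lum)] = GUIDEWIRE

    if spec.speckle is not None:
        _place_speckle(labels, spec.speckle)

    frame = Frame(labels, spec.geometry)
    return frame, ground_truth_metrics(spec)


def _place_speckle(labels: np.ndarray, spk: SpeckleSpec, margin_px: int = 5) -> None:
    """Drop isolated blobs on background, >= margin from any structure."""
    rng = np.random.default_rng(spk.seed)
    structure_dist = ndimage.distance_transform_edt(labels == BACKGROUND)
    side = int(np.ceil(np.sqrt(spk.component_area_px)))
    clearance = margin_px + side + 1
    rows, cols = labels.shape
    placed = 0
    for _ in range(10_000):
        if placed >= spk.n_components:
            break
        r = int(rng.integers(clearance, rows - clearance))
        c = int(rng.integers(clearance, cols - clearance))
        region = structure_dist[r : r + side + margin_px, c : c + side + margin_px]
        if region.min() < clearance:
            continue
        # fill exactly component_area_px pixels in raster order within the square
        filled = 0
        for dr in range(side):
            for dc in range(side):
                if filled < spk.component_area_px:
                    labels[r + dr, c + dc] = spk.class_code
                    filled += 1
        # keep blobs isolated from each other as well
        structure_dist[max(0, r - 1) : r + side + 1, max(0, c - 1) : c + side + 1] = 0.0
        placed += 1
    if placed < spk.n_components:
        raise SpecInfeasibleError("could not place all speckle components")


def render_pullback(specs: list[PhantomSpec], pitch_mm: float = 0.1, pullback_id: str = "phantom") -> Pullback:
    """Render an ordered list of phantom specs into one pullback."""
    if not specs:
        raise GeometryMismatchError("at least one phantom spec is required")
    geom = specs[0].geometry
    if any(s.geometry != geom for s in specs):
        raise GeometryMismatchError("all specs must share one geometry")
    frames = []
    for i, s in enumerate(specs):
        frame, _ = render_phantom(s)
        frame.frame_index = i
        frames.append(frame)
    return Pullback(frames=frames, pullback_id=pullback_id, frame_pitch_mm=pitch_mm)


DEFAULT_GEOMETRY = PixelGeometry(spacing_mm=0.005, frame_shape=(896, 896))


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """A representative single-frame phantom: one lipid and one calcium plaque."""
    return PhantomSpec(
        geometry=DEFAULT_GEOMETRY,
        lumen_center_px=(447.5, 447.5),
        lumen_radius_mm=0.9,
        intima_thickness_mm=0.25,
        media_thickness_mm=0.15,
        sectors=[
            PlaqueSectorSpec(LIPID, theta_start_deg=20.0, extent_deg=100.0,
                             cap_thickness_mm=0.10, plaque_thickness_mm=0.6),
            PlaqueSectorSpec(CALCIUM, theta_start_deg=200.0, extent_deg=60.0,
                             cap_thickness_mm=0.20, plaque_thickness_mm=0.5),
        ],
        guidewire=(150.0, 20.0),
        seed=seed,
    )


def random_phantom_spec(rng: np.random.Generator, geometry: PixelGeometry = DEFAULT_GEOMETRY) -> PhantomSpec:
    """Draw a random but anatomically plausible phantom spec.

    Dimensions follow coronary OCT practice: lumen radius 0.9–1.2 mm
    (lumen diameter 1.8–2.4 mm, a diseased but unoccluded segment),
    baseline intima 0.2–0.3 mm, media 0.1–0.18 mm, fibrous caps
    0.12–0.25 mm, plaque thickness 0.3–0.5 mm, sector arcs 45–80°.
    Angular features occupy distinct quadrants so same-class sectors
    never overlap and wedges never touch plaques.
    """
    rows, cols = geometry.frame_shape
    jitter = rng.uniform(-15.0, 15.0, size=2)
    center = ((rows - 1) / 2.0 + jitter[0], (cols - 1) / 2.0 + jitter[1])

    n_lipid = int(rng.integers(0, 3))
    n_calcium = int(rng.integers(0, 3))
    want_gw = bool(rng.random() < 0.5)
    slots = list(rng.permutation(4))
    sectors: list[PlaqueSectorSpec] = []

    def draw_sector(cls: int, quadrant: int) -> PlaqueSectorSpec:
        extent = float(rng.uniform(45.0, 80.0))
        start = quadrant * 90.0 + float(rng.uniform(0.0, 90.0 - extent))
        return PlaqueSectorSpec(
            cls,
            theta_start_deg=start,
            extent_deg=extent,
            cap_thickness_mm=float(rng.uniform(0.12, 0.25)),
            plaque_thickness_mm=float(rng.uniform(0.30, 0.50)),
        )

    gw = None
    for cls, count in ((LIPID, n_lipid), (CALCIUM, n_calcium)):
        for _ in range(count):
            if not slots:
                break
            sectors.append(draw_sector(cls, slots.pop()))
    if want_gw and slots:
        q = slots.pop()
        width = float(rng.uniform(15.0, 25.0))
        gw = (q * 90.0 + float(rng.uniform(width / 2.0, 90.0 - width / 2.0)), width)

    return PhantomSpec(
        geometry=geometry,
        lumen_center_px=center,
        lumen_radius_mm=float(rng.uniform(0.90, 1.20)),
        intima_thickness_mm=float(rng.uniform(0.20, 0.30)),
        media_thickness_mm=float(rng.uniform(0.10, 0.18)),
        sectors=sectors,
        guidewire=gw,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Serializable (YAML/JSON-friendly) form of a phantom spec."""
    d = {
        "spacing_mm": spec.geometry.spacing_mm,
        "frame_shape": list(spec.geometry.frame_shape),
        "lumen_center_px": list(spec.lumen_center_px),
        "lumen_radius_mm": spec.lumen_radius_mm,
        "intima_thickness_mm": spec.intima_thickness_mm,
        "media_thickness_mm": spec.media_thickness_mm,
        "sectors": [asdict(s) for s in spec.sectors],
        "seed": spec.seed,
    }
    if spec.guidewire is not None:
        d["guidewire"] = list(spec.guidewire)
    if spec.side_branch is not None:
        d["side_branch"] = list(spec.side_branch)
    if spec.speckle is not None:
        d["speckle"] = asdict(spec.speckle)
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    """Inverse of :func:`spec_to_dict`."""
    return PhantomSpec(
        geometry=PixelGeometry(d["spacing_mm"], tuple(d["frame_shape"])),
        lumen_center_px=tuple(d["lumen_center_px"]),
        lumen_radius_mm=d["lumen_radius_mm"],
        intima_thickness_mm=d["intima_thickness_mm"],
        media_thickness_mm=d["media_thickness_mm"],
        sectors=[PlaqueSectorSpec(**s) for s in d.get("sectors", [])],
        guidewire=tuple(d["guidewire"]) if "guidewire" in d else None,
        side_branch=tuple(d["side_branch"]) if "side_branch" in d else None,
        speckle=SpeckleSpec(**d["speckle"]) if "speckle" in d else None,
        seed=d.get("seed", 0),
    )
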