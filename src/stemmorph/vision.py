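"""2D geometric-optics model of larval simple-eye (stemma) visual fields.

The model works in the dorsal plane. Each eye is a flat lens of finite
aperture with a retina plane at some depth behind it. The field of view is
bounded by the *limiting rays* that connect each retina edge to the
opposite aperture edge (wide-acceptance convention, appropriate for a short
eye with a large opening angle); for an untilted eye the internal half
angle is

    alpha = arctan((retina_extent/2 + lens_aperture/2) / retina_depth).

With refraction at the single flat air-lens interface, an internal ray at
angle theta from the lens normal exits into air at

    beta = arcsin(min(1, n * sin(theta)))

so the external field is wider for n > 1 and saturates at grazing. The
binocular (stereoscopic) field is the intersection of the two monocular
field polygons; its position is compared against the capture zone swept by
the stylets, a circular sector in front of the head.

Conventions: y increases upward, anterior is +y, the head midline is x = 0.
All polygons are clipped to a finite bounding window (fields are unbounded
cones otherwise); circular arcs are discretized at 256 segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon, box

from .errors import ParameterError

ARC_SEGMENTS = 256

RELATION_NONE = "none"
RELATION_BETWEEN = "between_stylets"
RELATION_BEYOND = "beyond_stylets"


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = float(np.hypot(*v))
    if norm == 0:
        raise ParameterError("zero-length direction vector")
    return v / norm


def _rot(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class EyeGeometry:
    """A flat-lensed simple eye in the dorsal plane.

    Parameters
    ----------
    lens_center : (2,) point
    lens_normal : (2,) outward viewing direction (normalized on input)
    lens_aperture : float
        Width of the flat lens in the plane.
    retina_depth : float
        Distance from the lens plane to the retina plane along -normal.
    retina_extent : float
        Width of the retina in the plane.
    refractive_index : float, default 1.4
        Lens/eye-interior index; 1.0 disables refraction.
    tilt : float, default 0.0
        Angle (radians) of the retina axis relative to the lens normal;
        0 means the retina sits perpendicular to (centered behind) the
        lens. Positive tilt rotates the axis counterclockwise.
    """

    lens_center: tuple[float, float]
    lens_normal: tuple[float, float] = (0.0, 1.0)
    lens_aperture: float = 1.0
    retina_depth: float = 1.0
    retina_extent: float = 1.0
    refractive_index: float = 1.4
    tilt: float = 0.0

    def __post_init__(self) -> None:
        if self.lens_aperture <= 0:
            raise ParameterError("lens_aperture must be > 0")
        if self.retina_depth <= 0:
            raise ParameterError("retina_depth must be > 0")
        if self.retina_extent <= 0:
            raise ParameterError("retina_extent must be > 0")
        if self.refractive_index < 1.0:
            raise ParameterError("refractive_index must be >= 1")
        object.__setattr__(self, "lens_center",
                           tuple(np.asarray(self.lens_center, dtype=float)))
        object.__setattr__(self, "lens_normal", tuple(_unit(self.lens_normal)))

    # local frame: u = outward normal, v = 90 deg ccw from u
    @property
    def u(self) -> np.ndarray:
        return np.asarray(self.lens_normal)

    @property
    def v(self) -> np.ndarray:
        ux, uy = self.lens_normal
        return np.array([-uy, ux])

    def aperture_edges(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.lens_center)
        half = 0.5 * self.lens_aperture * self.v
        return c - half, c + half                      # (-v side, +v side)

    def retina_edges(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.lens_center)
        axis = _rot(self.tilt) @ self.u                # tilted retina axis
        center = c - self.retina_depth * axis
        lat = _rot(self.tilt) @ self.v
        half = 0.5 * self.retina_extent * lat
        return center - half, center + half            # (-v side, +v side)

    def body_polygon(self) -> Polygon:
        """Quadrilateral spanned by aperture and retina edges (the eye's
        footprint, used for head-capsule containment checks)."""
        am, ap = self.aperture_edges()
        rm, rp = self.retina_edges()
        return Polygon([tuple(am), tuple(ap), tuple(rp), tuple(rm)]).buffer(0)

    def mirrored(self) -> "EyeGeometry":
        """Mirror image across the midline x = 0."""
        return replace(
            self,
            lens_center=(-self.lens_center[0], self.lens_center[1]),
            lens_normal=(-self.lens_normal[0], self.lens_normal[1]),
            tilt=-self.tilt,
        )


@dataclass(frozen=True)
class HeadLayout:
    """Two-eye head arrangement with stylet capture geometry."""

    left_eye: EyeGeometry
    right_eye: EyeGeometry
    head_polygon: tuple                  # ccw vertex sequence
    stylet_length: float
    stylet_base_points: tuple            # pair of (x, y)
    stylet_span_angle: float             # radians
    symmetric: bool = True
    head_length: float = 1.0

    def __post_init__(self) -> None:
        if self.stylet_length <= 0:
            raise ParameterError("stylet_length must be > 0")
        if not (0 < self.stylet_span_angle <= 2 * math.pi):
            raise ParameterError("stylet_span_angle must be in (0, 2*pi]")

    def head_shapely(self) -> Polygon:
        return Polygon([tuple(p) for p in self.head_polygon])

    def default_window(self) -> Polygon:
        """10 x head-length square centered on the head (clipping window)."""
        cx, cy = np.asarray(self.head_shapely().centroid.coords[0])
        half = 5.0 * self.head_length
        return box(cx - half, cy - half, cx + half, cy + half)


@dataclass
class ViewField:
    """A monocular angular field clipped to a bounding window."""

    apex: np.ndarray                     # virtual crossing of boundary rays
    boundary_rays: tuple[np.ndarray, np.ndarray]   # unit dirs (-v side, +v side)
    exit_points: tuple[np.ndarray, np.ndarray]     # aperture exit points
    half_angle: float                    # radians
    central_direction: np.ndarray
    polygon: Polygon


@dataclass
class BinocularField:
    region: Polygon                      # possibly empty
    onset_distance: float | None        # along midline from head front
    relation_to_stylets: str = RELATION_NONE


# ---------------------------------------------------------------------------
# refraction
# ---------------------------------------------------------------------------


def snell_external_angle(theta_internal: float, n: float) -> float:
    """Air-side angle of a ray travelling at ``theta_internal`` inside the
    lens, for a flat interface with internal index ``n`` (air = 1).

    Saturates at pi/2 (grazing exit) when n * sin(theta) >= 1.
    """
    if theta_internal < 0:
        raise ParameterError("theta_internal must be >= 0")
    if theta_internal >= math.pi / 2:
        raise ParameterError("theta_internal must be < pi/2")
    if n < 1.0:
        raise ParameterError("refractive index must be >= 1")
    return math.asin(min(1.0, n * math.sin(theta_internal)))


# ---------------------------------------------------------------------------
# monocular field
# ---------------------------------------------------------------------------


def _signed_angle(frm: np.ndarray, to: np.ndarray) -> float:
    return math.atan2(frm[0] * to[1] - frm[1] * to[0], float(frm @ to))


def eye_field_of_view(eye: EyeGeometry, mode: str = "geometric",
                      window: Polygon | None = None,
                      convention: str = "wide") -> ViewField:
    """Field of view of one eye.

    ``mode="geometric"`` traces the limiting rays straight through the
    aperture; ``mode="refractive"`` bends them at the flat interface using
    the eye's refractive index. ``convention`` picks the limiting-ray rule:
    ``"wide"`` (default) connects each retina edge to the *opposite*
    aperture edge; ``"narrow"`` uses same-side edges (acceptance cone of a
    deep eye). Tilt produces asymmetric boundary rays.
    """
    if mode not in ("geometric", "refractive"):
        raise ParameterError(f"unknown mode {mode!r}")
    if convention not in ("wide", "narrow"):
        raise ParameterError(f"unknown convention {convention!r}")
    am, ap = eye.aperture_edges()
    rm, rp = eye.retina_edges()
    if convention == "wide":
        pairs = [(rp, am), (rm, ap)]       # retina edge -> opposite aperture edge
    else:
        pairs = [(rm, am), (rp, ap)]
    n = eye.refractive_index if mode == "refractive" else 1.0

    exits, dirs, angles = [], [], []
    for retina_pt, aperture_pt in pairs:
        d = _unit(aperture_pt - retina_pt)
        alpha = _signed_angle(eye.u, d)    # signed internal angle from normal
        beta = math.copysign(snell_external_angle(abs(alpha), n), alpha)
        dirs.append(_rot(beta) @ eye.u)
        exits.append(aperture_pt)
        angles.append(beta)
    # order as (-v side ray, +v side ray)
    if angles[0] > angles[1]:
        exits, dirs, angles = exits[::-1], dirs[::-1], angles[::-1]
    half_angle = 0.5 * (angles[1] - angles[0])
    central = _rot(0.5 * (angles[0] + angles[1])) @ eye.u

    apex = _ray_intersection(exits[0], dirs[0], exits[1], dirs[1])
    if window is None:
        span = 20.0 * (eye.retina_depth + eye.lens_aperture + eye.retina_extent)
        cx, cy = eye.lens_center
        window = box(cx - span, cy - span, cx + span, cy + span)
    L = 4.0 * math.sqrt(window.area) + 4.0 * float(
        Point(eye.lens_center).distance(window.centroid))
    quad = Polygon([
        tuple(exits[0]), tuple(exits[1]),
        tuple(exits[1] + L * dirs[1]), tuple(exits[0] + L * dirs[0]),
    ]).buffer(0)
    poly = quad.intersection(window)
    return ViewField(apex=apex, boundary_rays=(dirs[0], dirs[1]),
                     exit_points=(exits[0], exits[1]),
                     half_angle=half_angle, central_direction=central,
                     polygon=poly)


def _ray_intersection(p1, d1, p2, d2) -> np.ndarray:
    """Intersection of two lines p + t*d; midpoint fallback if parallel."""
    A = np.column_stack([d1, -d2])
    det = float(np.linalg.det(A))
    if abs(det) < 1e-14:
        return 0.5 * (np.asarray(p1) + np.asarray(p2))
    t = np.linalg.solve(A, np.asarray(p2) - np.asarray(p1))
    return np.asarray(p1) + t[0] * np.asarray(d1)


def view_field_from_apex(apex, direction, half_angle: float,
                         window: Polygon) -> ViewField:
    """Construct an ideal wedge field directly from apex and half-angle."""
    if not (0 < half_angle <= math.pi / 2):
        raise ParameterError("half_angle must be in (0, pi/2]")
    apex = np.asarray(apex, dtype=float)
    u = _unit(direction)
    d_minus = _rot(-half_angle) @ u
    d_plus = _rot(half_angle) @ u
    L = 4.0 * math.sqrt(window.area) + 4.0 * float(Point(apex).distance(window.centroid))
    quad = Polygon([tuple(apex), tuple(apex + L * d_plus),
                    tuple(apex + L * d_minus)]).buffer(0)
    return ViewField(apex=apex, boundary_rays=(d_minus, d_plus),
                     exit_points=(apex, apex), half_angle=half_angle,
                     central_direction=u, polygon=quad.intersection(window))


# ---------------------------------------------------------------------------
# binocular geometry
# ---------------------------------------------------------------------------


def binocular_overlap(left: ViewField, right: ViewField,
                      window: Polygon | None = None,
                      front_y: float = 0.0, midline_x: float = 0.0) -> BinocularField:
    """Intersection of two monocular fields and its onset on the midline.

    ``onset_distance`` is the distance along the midline (x = midline_x,
    measured from y = front_y, the anterior head margin) to the nearest
    point of the overlap region; None if the region is empty or never
    crosses the midline.
    """
    region = left.polygon.intersection(right.polygon)
    if window is not None:
        region = region.intersection(window)
    region = _largest_polygon(region)
    if region.is_empty or region.area <= 0:
        return BinocularField(region=Polygon(), onset_distance=None,
                              relation_to_stylets=RELATION_NONE)
    reach = region.bounds[3] - front_y + 1.0
    midline = LineString([(midline_x, front_y), (midline_x, front_y + reach)])
    cut = region.intersection(midline)
    onset = None if cut.is_empty else float(cut.bounds[1] - front_y)
    return BinocularField(region=region, onset_distance=onset,
                          relation_to_stylets=RELATION_NONE)


def _largest_polygon(geom) -> Polygon:
    if geom.is_empty:
        return Polygon()
    if isinstance(geom, Polygon):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    if not polys:
        return Polygon()
    return max(polys, key=lambda g: g.area)


def stylet_zone(layout: HeadLayout) -> Polygon:
    """Circular sector swept by the stylets (the prey-capture zone).

    Apex midway between the stylet bases, radius = stylet length, angular
    width = stylet span centered on the anterior (+y) direction.
    """
    b1, b2 = (np.asarray(p, dtype=float) for p in layout.stylet_base_points)
    apex = 0.5 * (b1 + b2)
    half = 0.5 * layout.stylet_span_angle
    angles = np.linspace(math.pi / 2 - half, math.pi / 2 + half, ARC_SEGMENTS + 1)
    arc = apex + layout.stylet_length * np.column_stack(
        [np.cos(angles), np.sin(angles)])
    return Polygon([tuple(apex), *map(tuple, arc)])


def classify_overlap(binocular: BinocularField, zone: Polygon) -> tuple[str, float]:
    """Classify the stereoscopic region against the stylet capture zone.

    Returns (relation, intersection area): ``between_stylets`` if the
    region intersects the zone with positive area, ``beyond_stylets`` if
    the region exists but is disjoint from the zone, ``none`` if empty.
    """
    if binocular.region.is_empty or binocular.region.area <= 0:
        return RELATION_NONE, 0.0
    inter = binocular.region.intersection(zone)
    area = float(inter.area)
    if area > 0:
        return RELATION_BETWEEN, area
    return RELATION_BEYOND, 0.0


# ---------------------------------------------------------------------------
# scenario evaluation
# ---------------------------------------------------------------------------

#: Named eye-geometry variants of a baseline layout. Values are overrides
#: (fractions of head length) applied to both eyes, mirrored for the left.
SCENARIOS: Mapping[str, dict] = {
    # short perpendicular eye, large opening angle (baseline)
    "flat_short": dict(lens_aperture=0.30, retina_depth=0.30,
                       retina_extent=0.30, tilt=0.0),
    # longer inner structure, strong posterior taper (narrow retina)
    "tapering_long": dict(lens_aperture=0.32, retina_depth=0.70,
                          retina_extent=0.135, tilt=0.0),
    # long untapered eye; retina protrudes behind the head capsule
    "long_clipped": dict(lens_aperture=0.30, retina_depth=1.30,
                         retina_extent=0.30, tilt=0.0),
    # long eye accommodated by tilting the retina axis off the lens normal
    # (toe-out: boundary rays diverge away from the midline)
    "tilted": dict(lens_aperture=0.30, retina_depth=0.75,
                   retina_extent=0.15, tilt=-math.pi / 6),
}


@dataclass
class ScenarioResult:
    scenario: str
    mode: str
    left: ViewField
    right: ViewField
    binocular: BinocularField
    relation: str
    overlap_area: float
    zone_intersection_area: float
    feasible: bool


def apply_scenario(layout: HeadLayout, scenario: str) -> HeadLayout:
    """Return the layout with both eyes replaced by the scenario variant."""
    if scenario not in SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}")
    ov = SCENARIOS[scenario]
    scale = layout.head_length
    right = replace(
        layout.right_eye,
        lens_aperture=ov["lens_aperture"] * scale,
        retina_depth=ov["retina_depth"] * scale,
        retina_extent=ov["retina_extent"] * scale,
        tilt=ov["tilt"],
    )
    return replace(layout, right_eye=right, left_eye=right.mirrored())


def evaluate_scenarios(layout: HeadLayout,
                       scenarios: Iterable[str] = tuple(SCENARIOS),
                       modes: Sequence[str] = ("geometric", "refractive"),
                       window: Polygon | None = None) -> list[ScenarioResult]:
    """Per-eye fields, binocular overlap, classification and feasibility
    for each named scenario x mode.

    Feasibility requires both eye footprints (aperture-to-retina quads) to
    fit inside the head capsule polygon.
    """
    window = window or layout.default_window()
    head = layout.head_shapely()
    zone = stylet_zone(layout)
    front_y = float(head.bounds[3])
    results = []
    for name in scenarios:
        variant = apply_scenario(layout, name)
        feasible = all(
            head.buffer(1e-9).covers(eye.body_polygon())
            for eye in (variant.left_eye, variant.right_eye)
        )
        for mode in modes:
            lf = eye_field_of_view(variant.left_eye, mode=mode, window=window)
            rf = eye_field_of_view(variant.right_eye, mode=mode, window=window)
            bino = binocular_overlap(lf, rf, front_y=front_y)
            relation, zone_area = classify_overlap(bino, zone)
            bino.relation_to_stylets = relation
            results.append(ScenarioResult(
                scenario=name, mode=mode, left=lf, right=rf, binocular=bino,
                relation=relation, overlap_area=float(bino.region.area),
                zone_intersection_area=zone_area, feasible=feasible,
            ))
    return results
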