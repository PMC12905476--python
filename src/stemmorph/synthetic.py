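"""Parametric generators for every input the analysis consumes.

Three families of synthetic data emulate the statistical structure of the
study system without requiring any downloads:

* head + stylet outlines: a single closed counterclockwise loop built from
  a radial function around the head center — a rounded-rectangle capsule,
  two anterior stylet lobes (optionally curved and toothed), anterolateral
  eye-protrusion bulges, and smooth angular noise;
* measurement tables following a log-log power law with gaussian noise in
  log10 space and optional implanted outliers;
* two-eye head layouts for the named visual-field scenarios.

All generators are pure functions of (parameters, seed): a master seed is
split per specimen with ``numpy.random.SeedSequence(master, spawn_key)`` so
any subset regenerates identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError
from .io import MeasurementRecord, Outline, OutlineSet
from .vision import SCENARIOS, EyeGeometry, HeadLayout

# angular positions (radians from the anterior +y direction); stylet lobes
# hug the midline so head width is set by the capsule and eye bulges
_STYLET_ANGLE = 0.22       # stylet lobe centers at +/- this angle
_STYLET_WIDTH = 0.08       # angular sigma of the stylet lobes
_EYE_ANGLE = 1.31          # anterolateral eye bulges
_EYE_WIDTH = 0.18
_TOOTH_OFFSET = 0.55       # teeth sit on the inner flank of each stylet
_TOOTH_WIDTH = 0.045


@dataclass(frozen=True)
class HeadShapeParams:
    """Latent shape parameters of one synthetic larva head.

    Ratios are relative to head (capsule) length; defaults follow the
    study system: capsule clearly wider than long, stylets about 1.5x the
    head length, modest eye protrusions.
    """

    head_width_ratio: float = 1.2      # capsule width / length
    stylet_length_ratio: float = 1.5   # stylet length / head length
    stylet_curvature: float = 0.3      # dimensionless inward lean
    tooth_size: float = 0.3            # fraction of stylet width; 0 = none
    eye_protrusion: float = 0.15       # fraction of head width
    noise_sd: float = 0.02             # radial perturbation scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_width_ratio <= 0 or self.stylet_length_ratio <= 0:
            raise ParameterError("ratios must be > 0")
        if self.tooth_size < 0 or self.eye_protrusion < 0:
            raise ParameterError("tooth_size and eye_protrusion must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    """Sampling description of one specimen group."""

    n: int
    means: HeadShapeParams
    sds: dict = field(default_factory=dict)   # parameter name -> sd

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ParameterError("group size must be >= 0")
        if any(s < 0 for s in self.sds.values()):
            raise ParameterError("sds must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """A synthetic population: per-group distributions plus explicit
    outliers appended with group label "new"."""

    groups: dict           # group name -> GroupSpec
    outliers: tuple = ()   # HeadShapeParams, appended as group "new"
    seed: int = 0
    n_points: int = 240


# sampling bounds keeping the radial construction valid
_PARAM_BOUNDS = {
    "head_width_ratio": (0.4, 4.0),
    "stylet_length_ratio": (0.3, 4.0),
    "stylet_curvature": (-1.0, 1.0),
    "tooth_size": (0.0, 1.0),
    "eye_protrusion": (0.0, 2.0),
}

#: Baseline study conditions: a tight extant cluster, fossils three times
#: as dispersed, and one wide-headed large-eyed outlier (protrusion four
#: fossil standard deviations above the fossil mean).
_EXTANT_SD = 0.04
_FOSSIL_SD = 3 * _EXTANT_SD


def default_population_spec(seed: int = 0, n_extant: int = 20,
                            n_fossil: int = 20) -> PopulationSpec:
    base = HeadShapeParams()
    extant_sds = {k: _EXTANT_SD for k in _PARAM_BOUNDS}
    fossil_sds = {k: _FOSSIL_SD for k in _PARAM_BOUNDS}
    outlier = replace(base, head_width_ratio=2.0,
                      eye_protrusion=base.eye_protrusion + 4 * _FOSSIL_SD)
    return PopulationSpec(
        groups={
            "extant": GroupSpec(n=n_extant, means=base, sds=extant_sds),
            "fossil": GroupSpec(n=n_fossil, means=base, sds=fossil_sds),
        },
        outliers=(outlier,),
        seed=seed,
    )


def _wrapped_gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    d = np.angle(np.exp(1j * (t - center)))        # wrapped angular distance
    return np.exp(-0.5 * (d / sigma) ** 2)


def gen_head_outline(params: HeadShapeParams, n_points: int = 240) -> Outline:
    """One closed ccw head + stylet outline.

    The radial function is even in the angle from the anterior midline, so
    with ``noise_sd = 0`` the outline is exactly mirror-symmetric about
    x = 0. The first point sits on the anterior midline.
    """
    if n_points < 16:
        raise ParameterError("n_points must be >= 16")
    t = 2.0 * np.pi * np.arange(n_points) / n_points   # angle from +y, ccw
    H = 0.5                                            # capsule half-length
    W = 0.5 * params.head_width_ratio                  # capsule half-width
    # rounded-rectangle capsule via a p-norm superellipse radius
    p = 5.0
    r = (np.abs(np.sin(t) / W) ** p + np.abs(np.cos(t) / H) ** p) ** (-1.0 / p)

    # stylet lobes: skewed gaussian bumps reaching stylet_length beyond rim
    amp_s = params.stylet_length_ratio * 2 * H
    for sign in (+1.0, -1.0):
        center = sign * _STYLET_ANGLE
        u = np.angle(np.exp(1j * (t - center))) / _STYLET_WIDTH
        u = u * (1.0 + params.stylet_curvature * np.tanh(sign * u) * 0.4)
        r = r + amp_s * np.exp(-0.5 * u**2)
        if params.tooth_size > 0:
            tooth_c = center - sign * _TOOTH_OFFSET * _STYLET_WIDTH * 3
            r = r + params.tooth_size * 0.08 * _wrapped_gaussian(
                t, tooth_c, _TOOTH_WIDTH)

    # anterolateral eye-protrusion bulges
    if params.eye_protrusion > 0:
        amp_e = params.eye_protrusion * 2 * W
        r = r + amp_e * (_wrapped_gaussian(t, _EYE_ANGLE, _EYE_WIDTH)
                         + _wrapped_gaussian(t, -_EYE_ANGLE, _EYE_WIDTH))

    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        n_bumps = 12
        centers = rng.uniform(0, 2 * np.pi, n_bumps)
        sigmas = rng.uniform(0.1, 0.4, n_bumps)
        amps = rng.normal(0.0, params.noise_sd, n_bumps)
        for c, s, a in zip(centers, sigmas, amps):
            r = r + a * _wrapped_gaussian(t, c, s)
    if np.any(r <= 0):
        raise ParameterError("parameters yield a non-star-shaped outline")
    pts = np.column_stack([-r * np.sin(t), r * np.cos(t)])  # ccw from +y
    return Outline(specimen_id=f"synthetic_{params.seed}", points=pts)


def _sample_params(means: HeadShapeParams, sds: dict,
                   rng: np.random.Generator, seed: int) -> HeadShapeParams:
    """Truncated-gaussian draw of each latent parameter (bounds keep the
    radial construction valid)."""
    values = {}
    for name, (lo, hi) in _PARAM_BOUNDS.items():
        mu = getattr(means, name)
        sd = sds.get(name, 0.0)
        if sd == 0.0:
            values[name] = mu
        else:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            values[name] = float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                                     random_state=rng))
    return HeadShapeParams(noise_sd=means.noise_sd, seed=seed, **values)


def gen_population(spec: PopulationSpec) -> OutlineSet:
    """Sample a labeled outline population from per-group distributions."""
    outlines = []
    idx = 0
    for group, gspec in spec.groups.items():
        for _ in range(gspec.n):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx,))
            sub_seed = int(ss.generate_state(1)[0] % 2**31)
            rng = np.random.default_rng(ss)
            params = _sample_params(gspec.means, gspec.sds, rng, sub_seed)
            o = gen_head_outline(params, spec.n_points)
            outlines.append(replace(o, specimen_id=f"{group}_{idx:03d}",
                                    group=group))
            idx += 1
    for params in spec.outliers:
        ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx,))
        sub_seed = int(ss.generate_state(1)[0] % 2**31)
        o = gen_head_outline(replace(params, seed=sub_seed), spec.n_points)
        outlines.append(replace(o, specimen_id=f"new_{idx:03d}", group="new"))
        idx += 1
    return OutlineSet(outlines=outlines, provenance=f"synthetic(seed={spec.seed})")


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------


def gen_measurements(n: int, slope: float = 0.8, intercept: float = -1.0,
                     sigma: float = 0.05,
                     outliers: Sequence[tuple[float, str]] = (),
                     seed: int = 0,
                     head_range: tuple[float, float] = (0.5, 10.0),
                     ) -> list[MeasurementRecord]:
    """Synthetic head-length / lens-diameter table on a log-log power law.

    Head lengths are log-uniform over ``head_range``; lens diameters follow
    10**(intercept + slope*log10(head) + eps) with eps ~ N(0, sigma^2).
    ``outliers`` is a sequence of (log10 offset, group) records appended
    after the n law-following specimens.
    """
    if n < 3:
        raise ParameterError("n must be >= 3")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    log_head = rng.uniform(math.log10(head_range[0]), math.log10(head_range[1]), n)
    eps = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    records = [
        MeasurementRecord(
            specimen_id=f"M{i:03d}",
            head_length=10.0 ** lh,
            lens_diameter=10.0 ** (intercept + slope * lh + e),
            group="extant",
        )
        for i, (lh, e) in enumerate(zip(log_head, eps))
    ]
    for j, (offset, group) in enumerate(outliers):
        lh = rng.uniform(math.log10(head_range[0]), math.log10(head_range[1]))
        e = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        records.append(
            MeasurementRecord(
                specimen_id=f"O{j:03d}",
                head_length=10.0 ** lh,
                lens_diameter=10.0 ** (intercept + slope * lh + e + offset),
                group=group,
            )
        )
    return records


# ---------------------------------------------------------------------------
# head layouts
# ---------------------------------------------------------------------------


def gen_layout(preset: str = "flat_short", head_scale: float = 1.0) -> HeadLayout:
    """A mirror-symmetric two-eye head layout for a named scenario preset.

    The head capsule is a rectangle twice as wide as long (anterior margin
    at y = 0), the stylets reach 1.5 head lengths forward, and the eyes sit
    on the anterolateral corners facing forward. ``preset`` selects the eye
    variant (see :data:`stemmorph.vision.SCENARIOS`).
    """
    if preset not in SCENARIOS:
        raise ParameterError(
            f"unknown preset {preset!r}; known: {sorted(SCENARIOS)}")
    s = head_scale
    ov = SCENARIOS[preset]
    head_polygon = ((-1.0 * s, -1.0 * s), (1.0 * s, -1.0 * s),
                    (1.0 * s, 0.0), (-1.0 * s, 0.0))
    right = EyeGeometry(
        lens_center=(0.7 * s, 0.0),
        lens_normal=(0.0, 1.0),
        lens_aperture=ov["lens_aperture"] * s,
        retina_depth=ov["retina_depth"] * s,
        retina_extent=ov["retina_extent"] * s,
        refractive_index=1.4,
        tilt=ov["tilt"],
    )
    return HeadLayout(
        left_eye=right.mirrored(),
        right_eye=right,
        head_polygon=head_polygon,
        stylet_length=1.5 * s,
        stylet_base_points=((-0.3 * s, 0.0), (0.3 * s, 0.0)),
        stylet_span_angle=math.pi / 2,
        symmetric=True,
        head_length=1.0 * s,
    )
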