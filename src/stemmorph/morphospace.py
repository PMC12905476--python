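"""Morphospace construction: coefficient matrix, PCA, shape rendering,
and convex-hull occupancy of specimen groups.

PCA is performed on the column-centered coefficient matrix without column
rescaling (covariance PCA): after per-specimen shape scaling all coefficient
columns share units, and rescaling them would distort the harmonic
weighting. Eigenvector signs are fixed so the largest-magnitude entry of
each loading vector is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint, Point, Polygon
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .efa import EFACoefficients, EllipticalFourierFeaturizer, efa_reconstruct
from .errors import DegeneracyError, ParameterError
from .io import Outline, OutlineSet


@dataclass
class CoefficientMatrix:
    """Specimens-by-coefficients matrix (rows follow manifest order)."""

    values: np.ndarray               # (n_specimens, 4 * n_harmonics)
    row_ids: list[str]
    groups: list[str]
    n_harmonics: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 4 * self.n_harmonics:
            raise ParameterError(
                f"matrix shape {v.shape} inconsistent with {self.n_harmonics} harmonics"
            )
        if not np.all(np.isfinite(v)):
            raise ParameterError("coefficient matrix contains non-finite cells")
        if len(self.row_ids) != v.shape[0] or len(self.groups) != v.shape[0]:
            raise ParameterError("row metadata length mismatch")
        self.values = v


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # nonincreasing, >= 0
    variance_fraction: np.ndarray    # sums to 1 (all-zero if no variance)
    loadings: np.ndarray             # (n_features, k), orthonormal columns
    scores: np.ndarray               # (n_specimens, k)
    column_means: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class GroupHull:
    group: str
    vertices: np.ndarray             # (m, 2) hull vertices (ccw), possibly degenerate
    area: float
    degenerate: bool


@dataclass
class OccupancyReport:
    hulls: dict[str, GroupHull]
    overlap_areas: dict[tuple[str, str], float]
    outside_all: dict[str, bool]     # specimen_id -> outside every group hull
    axes: tuple[int, int] = (0, 1)


# ---------------------------------------------------------------------------
# matrix and PCA
# ---------------------------------------------------------------------------


def build_matrix(outline_set: OutlineSet, n_harmonics: int, center: bool = True,
                 scale: bool = True, align: bool = False,
                 on_degenerate: str = "raise") -> CoefficientMatrix:
    """Flattened normalized coefficients, one row per specimen.

    ``on_degenerate`` controls what happens when a specimen's coefficients
    cannot be normalized (zero first harmonic): ``"raise"`` propagates a
    :class:`DegeneracyError` naming the specimen; ``"warn"`` excludes the
    specimen with a warning.
    """
    if on_degenerate not in ("raise", "warn"):
        raise ParameterError("on_degenerate must be 'raise' or 'warn'")
    feat = EllipticalFourierFeaturizer(n_harmonics=n_harmonics, center=center,
                                       scale=scale, align=align).fit(outline_set)
    rows, ids, groups = [], [], []
    for o in outline_set:
        try:
            rows.append(feat.transform([o])[0])
        except DegeneracyError:
            if on_degenerate == "raise":
                raise
            warnings.warn(f"excluding degenerate specimen {o.specimen_id!r}")
            continue
        ids.append(o.specimen_id)
        groups.append(o.group)
    return CoefficientMatrix(values=np.asarray(rows), row_ids=ids, groups=groups,
                             n_harmonics=n_harmonics)


class ShapePCA(TransformerMixin, BaseEstimator):
    """Covariance PCA with deterministic loading signs.

    Thin, reproducibility-oriented wrapper: full-SVD PCA on the centered
    matrix, components sorted by eigenvalue, each loading's
    largest-magnitude entry made positive (eigenvector sign is otherwise
    arbitrary).

    Attributes
    ----------
    eigenvalues_ : (k,) ndarray
    variance_fraction_ : (k,) ndarray, sums to 1 (zeros for constant data)
    loadings_ : (p, k) ndarray with orthonormal columns
    mean_ : (p,) ndarray
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ParameterError("PCA requires a 2D matrix with >= 2 rows")
        k = min(X.shape[0] - 1, X.shape[1])
        self._pca = PCA(n_components=k, svd_solver="full")
        with np.errstate(invalid="ignore"):   # constant data: 0/0 ratio
            self._pca.fit(X)
        self.mean_ = self._pca.mean_
        self.eigenvalues_ = self._pca.explained_variance_.copy()
        total = self.eigenvalues_.sum()
        if total > 0:
            self.variance_fraction_ = self.eigenvalues_ / total
        else:
            self.variance_fraction_ = np.zeros_like(self.eigenvalues_)
        loadings = self._pca.components_.T.copy()
        # deterministic sign: largest-|entry| of each loading positive
        flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])] < 0
        loadings[:, flip] *= -1.0
        self.loadings_ = loadings
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.loadings_


def run_pca(matrix: CoefficientMatrix | np.ndarray) -> PCAResult:
    """Run covariance PCA on a coefficient matrix."""
    if isinstance(matrix, CoefficientMatrix):
        values, ids, groups = matrix.values, matrix.row_ids, matrix.groups
    else:
        values = np.asarray(matrix, dtype=float)
        ids, groups = [], []
    est = ShapePCA().fit(values)
    return PCAResult(
        eigenvalues=est.eigenvalues_,
        variance_fraction=est.variance_fraction_,
        loadings=est.loadings_,
        scores=est.transform(values),
        column_means=est.mean_,
        row_ids=list(ids),
        groups=list(groups),
    )


def count_components_for_threshold(pca: PCAResult, threshold: float) -> int:
    """Smallest k whose cumulative variance fraction exceeds ``threshold``."""
    if not (0.0 <= threshold < 1.0):
        raise ParameterError(f"threshold must be in [0, 1), got {threshold}")
    cum = np.cumsum(pca.variance_fraction)
    above = np.nonzero(cum > threshold)[0]
    if len(above) == 0:                      # numerically flat tail
        return len(cum)
    return int(above[0]) + 1


def shape_at_position(pca: PCAResult, component_index: int, score: float,
                      n_points: int = 256) -> Outline:
    """Reconstruct the outline at a given score along one component.

    The coefficient vector mean + score * loading is reinterpreted as
    flattened elliptical-Fourier coefficients and inverse-transformed.
    score 0 renders the mean shape.
    """
    if not (0 <= component_index < pca.n_components):
        raise ParameterError(
            f"component_index {component_index} out of range "
            f"[0, {pca.n_components})"
        )
    vec = pca.column_means + score * pca.loadings[:, component_index]
    coeffs = EFACoefficients.from_flat(vec)
    return efa_reconstruct(coeffs, n_points,
                           specimen_id=f"PC{component_index + 1}@{score:g}")


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def _hull_of(points: np.ndarray, group: str) -> GroupHull:
    geom = MultiPoint([tuple(p) for p in points]).convex_hull
    if isinstance(geom, Polygon):
        verts = np.asarray(geom.exterior.coords)[:-1]
        return GroupHull(group=group, vertices=verts, area=float(geom.area),
                         degenerate=False)
    # Point or LineString: degenerate hull, zero area
    verts = np.atleast_2d(np.asarray(geom.coords))
    return GroupHull(group=group, vertices=verts, area=0.0, degenerate=True)


def occupancy(pca: PCAResult, axes: tuple[int, int] = (0, 1),
              groups: Sequence[str] | None = None) -> OccupancyReport:
    """Convex-hull occupancy of each group in a 2D morphospace plane.

    Hull boundaries count as inside (conservative outlier calls); groups
    with collinear or too few points yield a degenerate hull of zero area
    which is reported, not raised. ``outside_all`` flags specimens falling
    outside every non-degenerate group hull.
    """
    groups = list(groups) if groups is not None else list(pca.groups)
    if len(groups) != pca.scores.shape[0]:
        raise ParameterError("groups length must match number of score rows")
    pts = pca.scores[:, list(axes)]
    hulls: dict[str, GroupHull] = {}
    polys: dict[str, Polygon] = {}
    for g in dict.fromkeys(groups):          # preserve first-seen order
        sub = pts[[i for i, gi in enumerate(groups) if gi == g]]
        hull = _hull_of(sub, g)
        hulls[g] = hull
        if not hull.degenerate:
            polys[g] = Polygon(hull.vertices)
    names = list(hulls)
    overlap: dict[tuple[str, str], float] = {}
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            if g1 in polys and g2 in polys:
                area = float(polys[g1].intersection(polys[g2]).area)
            else:
                area = 0.0
            overlap[(g1, g2)] = area
            overlap[(g2, g1)] = area
    ids = pca.row_ids if pca.row_ids else [str(i) for i in range(len(pts))]
    outside = {}
    for sid, p in zip(ids, pts):
        point = Point(*p)
        outside[sid] = not any(poly.covers(point) for poly in polys.values())
    return OccupancyReport(hulls=hulls, overlap_areas=overlap,
                           outside_all=outside, axes=tuple(axes))
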