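"""Elliptical Fourier analysis of closed outlines.

A closed outline traversed at constant speed over its perimeter T defines
periodic signals x(t), y(t). Each is expanded in a truncated Fourier series;
harmonic n contributes the quadruple (a_n, b_n, c_n, d_n):

    x(t) = a0 + sum_n [ a_n cos(2*pi*n*t/T) + b_n sin(2*pi*n*t/T) ]
    y(t) = c0 + sum_n [ c_n cos(2*pi*n*t/T) + d_n sin(2*pi*n*t/T) ]

For a piecewise-linear contour the integrals have closed forms as sums over
segments (the classical closed-contour formulation); those are used here.
The DC terms (a0, c0) equal the centroid of the arc-length parameterization.

Harmonic power is P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2; its cumulative
fraction over harmonics (DC excluded) is the criterion used to calibrate how
many harmonics a dataset needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CalibrationError, DegeneracyError, ParameterError
from .io import Outline, OutlineSet, normalize_orientation


@dataclass(frozen=True)
class NormalizationState:
    centered: bool = False
    scaled: bool = False
    rotation_aligned: bool = False


@dataclass(frozen=True)
class EFACoefficients:
    """Elliptical Fourier coefficients of one outline.

    ``harmonics`` is an (N, 4) array with rows (a_n, b_n, c_n, d_n).
    """

    a0: float
    c0: float
    harmonics: np.ndarray
    normalized: NormalizationState = field(default_factory=NormalizationState)

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ParameterError(f"harmonics must be (N>=1, 4), got {h.shape}")
        object.__setattr__(self, "harmonics", h)

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def first_harmonic_matrix(self) -> np.ndarray:
        a, b, c, d = self.harmonics[0]
        return np.array([[a, b], [c, d]])

    def scale_functional(self) -> float:
        """Semi-major axis length of the first-harmonic ellipse."""
        return float(np.linalg.svd(self.first_harmonic_matrix(), compute_uv=False)[0])

    def flatten(self) -> np.ndarray:
        """Row vector (a_1, b_1, c_1, d_1, ..., a_N, b_N, c_N, d_N)."""
        return self.harmonics.reshape(-1)

    @classmethod
    def from_flat(
        cls, vector: np.ndarray, a0: float = 0.0, c0: float = 0.0,
        normalized: NormalizationState | None = None,
    ) -> "EFACoefficients":
        v = np.asarray(vector, dtype=float)
        if v.size % 4 != 0:
            raise ParameterError(f"flat coefficient vector length {v.size} not divisible by 4")
        return cls(a0=a0, c0=c0, harmonics=v.reshape(-1, 4),
                   normalized=normalized or NormalizationState())


@dataclass(frozen=True)
class HarmonicPowerProfile:
    per_harmonic_power: np.ndarray
    cumulative_fraction: np.ndarray


# ---------------------------------------------------------------------------
# decomposition / reconstruction
# ---------------------------------------------------------------------------


def _closed_segments(points: np.ndarray):
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return closed, d, dt, t, t[-1]


def efa_decompose(outline: Outline, n_harmonics: int) -> EFACoefficients:
    """Decompose a counterclockwise outline into ``n_harmonics`` harmonics.

    ``n_harmonics`` must not exceed floor(point_count / 2) (the Nyquist
    bound of the polygonal sampling).
    """
    if n_harmonics < 1:
        raise ParameterError("n_harmonics must be >= 1")
    npts = len(outline)
    if n_harmonics > npts // 2:
        raise ParameterError(
            f"n_harmonics={n_harmonics} exceeds Nyquist bound {npts // 2} "
            f"for {npts} points"
        )
    outline = normalize_orientation(outline)
    closed, d, dt, t, T = _closed_segments(outline.points)

    # DC terms: centroid of the arc-length parameterization (exact)
    mids = 0.5 * (closed[:-1] + closed[1:])
    a0, c0 = (mids * dt[:, None]).sum(axis=0) / T

    n = np.arange(1, n_harmonics + 1)[:, None]          # (N, 1)
    phi = 2.0 * np.pi * t / T                            # (K+1,)
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])    # (N, K)
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    coef = T / (2.0 * np.pi**2 * n[:, 0] ** 2)           # (N,)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = coef * (dcos @ dxdt)
    b = coef * (dsin @ dxdt)
    c = coef * (dcos @ dydt)
    dd = coef * (dsin @ dydt)
    return EFACoefficients(a0=float(a0), c0=float(c0),
                           harmonics=np.column_stack([a, b, c, dd]))


def efa_reconstruct(coeffs: EFACoefficients, n_points: int,
                    specimen_id: str = "reconstruction", group: str = "new") -> Outline:
    """Evaluate the truncated series at ``n_points`` equally spaced phases."""
    if n_points < 3:
        raise ParameterError(f"n_points must be >= 3, got {n_points}")
    phi = 2.0 * np.pi * np.arange(n_points) / n_points   # (P,)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]    # (N, 1)
    cos_t = np.cos(n * phi)                              # (N, P)
    sin_t = np.sin(n * phi)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.a0 + a @ cos_t + b @ sin_t
    y = coeffs.c0 + c @ cos_t + d @ sin_t
    return Outline(specimen_id=specimen_id, points=np.column_stack([x, y]), group=group)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _rot(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


def _apply_phase(harmonics: np.ndarray, theta: float) -> np.ndarray:
    """Shift the start point by phase theta: H_n <- H_n R(n*theta)."""
    out = np.empty_like(harmonics)
    for i in range(harmonics.shape[0]):
        H = harmonics[i].reshape(2, 2)
        out[i] = (H @ _rot((i + 1) * theta)).reshape(4)
    return out


def _apply_spatial(harmonics: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the coordinate frame by -psi: H_n <- R(-psi) H_n."""
    R = _rot(-psi)
    out = np.empty_like(harmonics)
    for i in range(harmonics.shape[0]):
        out[i] = (R @ harmonics[i].reshape(2, 2)).reshape(4)
    return out


def normalize(coeffs: EFACoefficients, center: bool = True, scale: bool = True,
              align: bool = False) -> EFACoefficients:
    """Center, scale and optionally rotation/start-point align coefficients.

    * ``center`` zeroes the DC terms (removes position).
    * ``scale`` divides every harmonic by the first-harmonic semi-major axis
      length, so the scale functional of the result equals 1.
    * ``align`` standardizes start point and in-plane rotation via the
      first-harmonic ellipse (phase normalization), making the result
      invariant to rotations of the digitized shape.

    Already-normalized input is returned unchanged in the requested aspects
    (idempotent).
    """
    h = coeffs.harmonics.copy()
    a0, c0 = coeffs.a0, coeffs.c0
    state = coeffs.normalized

    if (scale or align) and coeffs.scale_functional() < 1e-300:
        raise DegeneracyError("zero first-harmonic magnitude; cannot scale/align")

    if align:
        a1, b1, c1, d1 = h[0]
        # phase diagonalizing the first-harmonic ellipse; candidates differ
        # by pi/2 (axis swap); pick the one putting the semi-major axis in
        # the first column so alignment is idempotent and axis-ordered
        theta0 = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                                  a1**2 + c1**2 - b1**2 - d1**2)
        best, best_len = None, -np.inf
        for k in range(4):
            theta = theta0 + k * np.pi / 2.0
            H1 = h[0].reshape(2, 2) @ _rot(theta)
            col1_len = float(np.hypot(H1[0, 0], H1[1, 0]))
            if col1_len > best_len + 1e-12:
                best, best_len = theta, col1_len
        h = _apply_phase(h, best)
        psi = np.arctan2(h[0, 2], h[0, 0])
        h = _apply_spatial(h, psi)
    if center:
        a0, c0 = 0.0, 0.0
    if scale:
        s = float(np.linalg.svd(h[0].reshape(2, 2), compute_uv=False)[0])
        h = h / s
    new_state = NormalizationState(
        centered=state.centered or center,
        scaled=state.scaled or scale,
        rotation_aligned=state.rotation_aligned or align,
    )
    return EFACoefficients(a0=a0, c0=c0, harmonics=h, normalized=new_state)


# ---------------------------------------------------------------------------
# harmonic power
# ---------------------------------------------------------------------------


def harmonic_power(coeffs: EFACoefficients) -> HarmonicPowerProfile:
    """Per-harmonic power P_n and its cumulative fraction (DC excluded)."""
    p = 0.5 * np.sum(coeffs.harmonics**2, axis=1)
    total = p.sum()
    if total == 0.0:
        raise DegeneracyError("all harmonic power is zero")
    return HarmonicPowerProfile(per_harmonic_power=p,
                                cumulative_fraction=np.cumsum(p) / total)


def signal_power(outline: Outline) -> float:
    """Time-averaged centered signal power of the outline traversal.

    Exact piecewise-quadratic integral of (x - a0)^2 + (y - c0)^2 over the
    arc-length parameterization; by Parseval this is the limit of the
    cumulative harmonic power, so truncated decompositions always hold a
    fraction strictly below 1 of it (unless the shape is band-limited).
    """
    closed, _, dt, _, T = _closed_segments(outline.points)
    mids = 0.5 * (closed[:-1] + closed[1:])
    a0, c0 = (mids * dt[:, None]).sum(axis=0) / T
    dc = np.array([a0, c0])
    f0 = np.sum((closed[:-1] - dc) ** 2, axis=1)
    f1 = np.sum((closed[1:] - dc) ** 2, axis=1)
    fm = np.sum((mids - dc) ** 2, axis=1)
    return float(np.sum(dt * (f0 + 4.0 * fm + f1) / 6.0) / T)


def calibrate_harmonics(outline_set: OutlineSet, threshold: float = 0.99,
                        max_harmonics: int = 20, per_specimen: bool = False) -> int:
    """Smallest harmonic count whose mean cumulative power reaches threshold.

    Every outline is decomposed to ``max_harmonics``; cumulative harmonic
    power as a fraction of each outline's total signal power (see
    :func:`signal_power`) is averaged across specimens (dataset-level
    criterion) and the smallest N with mean fraction >= threshold is
    returned. With ``per_specimen=True`` the criterion must hold for every
    specimen individually (worst-case mode).
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    if max_harmonics < 1:
        raise ParameterError("max_harmonics must be >= 1")
    fractions = []
    for o in outline_set:
        if max_harmonics > len(o) // 2:
            raise ParameterError(
                f"specimen {o.specimen_id!r}: max_harmonics={max_harmonics} "
                f"exceeds Nyquist bound {len(o) // 2}"
            )
        coeffs = efa_decompose(o, max_harmonics)
        p = 0.5 * np.sum(coeffs.harmonics**2, axis=1)
        fractions.append(np.cumsum(p) / signal_power(o))
    frac = np.array(fractions)
    profile = frac.min(axis=0) if per_specimen else frac.mean(axis=0)
    reached = np.nonzero(profile >= threshold)[0]
    if len(reached) == 0:
        raise CalibrationError(
            f"threshold {threshold} unreachable at max_harmonics={max_harmonics}; "
            f"achieved {profile[-1]:.6f}",
            achieved=float(profile[-1]),
        )
    return int(reached[0]) + 1


# ---------------------------------------------------------------------------
# sklearn-style transformer
# ---------------------------------------------------------------------------


class EllipticalFourierFeaturizer(TransformerMixin, BaseEstimator):
    """Turn outlines into flattened elliptical-Fourier coefficient rows.

    Parameters
    ----------
    n_harmonics : int or None, default=None
        Number of harmonics; if None, ``fit`` calibrates the smallest count
        whose mean cumulative harmonic power reaches ``threshold``.
    threshold : float, default=0.99
        Cumulative-power target used when calibrating.
    max_harmonics : int, default=20
        Calibration search bound.
    center, scale, align : bool
        Normalization applied to each specimen's coefficients before
        flattening (see :func:`normalize`).

    Attributes
    ----------
    n_harmonics_ : int
        Harmonic count actually used (calibrated or fixed).
    """

    def __init__(self, n_harmonics: int | None = None, threshold: float = 0.99,
                 max_harmonics: int = 20, center: bool = True, scale: bool = True,
                 align: bool = False):
        self.n_harmonics = n_harmonics
        self.threshold = threshold
        self.max_harmonics = max_harmonics
        self.center = center
        self.scale = scale
        self.align = align

    def fit(self, X: OutlineSet | Sequence[Outline], y=None):
        outlines = list(X)
        if self.n_harmonics is not None:
            self.n_harmonics_ = int(self.n_harmonics)
        else:
            oset = X if isinstance(X, OutlineSet) else OutlineSet(outlines=outlines)
            self.n_harmonics_ = calibrate_harmonics(
                oset, threshold=self.threshold, max_harmonics=self.max_harmonics
            )
        return self

    def transform(self, X: OutlineSet | Sequence[Outline]) -> np.ndarray:
        if not hasattr(self, "n_harmonics_"):
            raise ParameterError("featurizer not fitted; call fit first")
        rows = []
        for o in X:
            try:
                coeffs = normalize(
                    efa_decompose(o, self.n_harmonics_),
                    center=self.center, scale=self.scale, align=self.align,
                )
            except DegeneracyError as exc:
                raise DegeneracyError(f"specimen {o.specimen_id!r}: {exc}") from exc
            rows.append(coeffs.flatten())
        return np.asarray(rows)


# ---------------------------------------------------------------------------
# coefficient CSV round trip
# ---------------------------------------------------------------------------


def write_coefficients_csv(coeff_map: dict[str, EFACoefficients], path) -> None:
    """Export coefficients as CSV rows (specimen_id, n, a, b, c, d)."""
    import csv as _csv

    states = {c.normalized for c in coeff_map.values()}
    if len(states) > 1:
        raise ParameterError("mixed normalization states in one export")
    st = next(iter(states)) if states else NormalizationState()
    with open(path, "w", newline="") as fh:
        fh.write(f"# centered={st.centered} scaled={st.scaled} "
                 f"rotation_aligned={st.rotation_aligned}\n")
        w = _csv.writer(fh)
        w.writerow(["specimen_id", "n", "a", "b", "c", "d"])
        for sid, c in coeff_map.items():
            w.writerow([sid, 0, repr(float(c.a0)), "0.0", repr(float(c.c0)), "0.0"])
            for i, (a, b, cc, d) in enumerate(c.harmonics, start=1):
                w.writerow([sid, i, repr(float(a)), repr(float(b)),
                            repr(float(cc)), repr(float(d))])


def read_coefficients_csv(path) -> dict[str, EFACoefficients]:
    import csv as _csv

    st = NormalizationState()
    rows: dict[str, dict[int, tuple[float, float, float, float]]] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            kv = dict(tok.split("=") for tok in first[1:].split())
            st = NormalizationState(
                centered=kv.get("centered") == "True",
                scaled=kv.get("scaled") == "True",
                rotation_aligned=kv.get("rotation_aligned") == "True",
            )
        else:
            fh.seek(0)
        for rec in _csv.DictReader(fh):
            rows.setdefault(rec["specimen_id"], {})[int(rec["n"])] = (
                float(rec["a"]), float(rec["b"]), float(rec["c"]), float(rec["d"]))
    out = {}
    for sid, by_n in rows.items():
        a0, _, c0, _ = by_n.get(0, (0.0, 0.0, 0.0, 0.0))
        ns = sorted(k for k in by_n if k > 0)
        harm = np.array([by_n[k] for k in ns])
        out[sid] = EFACoefficients(a0=a0, c0=c0, harmonics=harm, normalized=st)
    return out
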