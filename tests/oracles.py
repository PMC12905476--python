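"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: Fourier coefficients by
trapezoidal quadrature of the defining integrals, PCA by a direct
covariance eigendecomposition, visual-field membership by dense ray
sampling, and point-in-hull by half-plane tests.
"""

import numpy as np


def efa_by_quadrature(points, n_harmonics, oversample=20000):
    """Trapezoidal integration of the Fourier integrals on a densely
    resampled closed polygon. Returns (a0, c0, harmonics[N, 4])."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    t = np.concatenate([[0.0], np.cumsum(lens)])
    T = t[-1]
    # dense equal-arclength sampling of the polygon, including the endpoint
    s = np.linspace(0.0, T, oversample + 1)
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    a0 = np.trapezoid(x, s) / T
    c0 = np.trapezoid(y, s) / T
    harm = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        cn = np.cos(2 * np.pi * n * s / T)
        sn = np.sin(2 * np.pi * n * s / T)
        harm[n - 1] = [
            2.0 / T * np.trapezoid(x * cn, s),
            2.0 / T * np.trapezoid(x * sn, s),
            2.0 / T * np.trapezoid(y * cn, s),
            2.0 / T * np.trapezoid(y * sn, s),
        ]
    return a0, c0, harm


def pca_by_eigh(X):
    """Eigendecomposition of the sample covariance (ddof=1), eigenvalues
    descending; returns (eigenvalues, loadings, scores)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    return w, V, (X - mu) @ V


def in_wedge(points, apex, direction, half_angle):
    """Membership of points in an ideal angular field (ray-membership)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - np.asarray(apex, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.hypot(*u)
    ang = np.abs(np.arctan2(d[:, 0] * u[1] - d[:, 1] * u[0], d @ u))
    return (ang <= half_angle + 1e-12) & (np.hypot(d[:, 0], d[:, 1]) > 0)


def eye_max_internal_angle(aperture, depth, extent, n_samples=400):
    """Largest |angle to lens normal| over dense (retina point, aperture
    point) ray pairs of an untilted flat eye."""
    r = np.linspace(-extent / 2, extent / 2, n_samples)
    a = np.linspace(-aperture / 2, aperture / 2, n_samples)
    rr, aa = np.meshgrid(r, a)
    return np.arctan(np.abs(aa - rr) / depth).max()


def point_in_hull(point, vertices, tol=1e-12):
    """Half-plane test against a convex polygon; boundary counts in."""
    v = np.asarray(vertices, dtype=float)
    p = np.asarray(point, dtype=float)
    # force ccw orientation for the half-plane sign convention
    area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    if area2 < 0:
        v = v[::-1]
    for i in range(len(v)):
        e = v[(i + 1) % len(v)] - v[i]
        if e[0] * (p[1] - v[i][1]) - e[1] * (p[0] - v[i][0]) < -tol:
            return False
    return True


def ols_loglog(head, lens):
    """Closed-form simple OLS of log10(lens) on log10(head)."""
    lx, ly = np.log10(np.asarray(head)), np.log10(np.asarray(lens))
    slope = np.sum((lx - lx.mean()) * (ly - ly.mean())) / np.sum((lx - lx.mean()) ** 2)
    intercept = ly.mean() - slope * lx.mean()
    return slope, intercept
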