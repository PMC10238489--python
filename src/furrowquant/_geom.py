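"""Polyline geometry helpers shared by the generator and the quantification modules.

Contours are ``(N, 2)`` float arrays in image ``(row, col)`` order, implicitly
closed (the last point is NOT a repeat of the first).  "Positive" orientation
means a positive shoelace area when the polygon is read as ``x = col``,
``y = row``.
"""

from __future__ import annotations

import numpy as np


def signed_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polyline, x = col, y = row."""
    y = points[:, 0]
    x = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_positive_orientation(points: np.ndarray) -> np.ndarray:
    if signed_area(points) < 0:
        return points[::-1].copy()
    return points


def cumulative_arclength(points: np.ndarray, closed: bool = True) -> np.ndarray:
    """Cumulative arclength at each vertex; for closed curves the returned
    array has ``N + 1`` entries, the last being the full perimeter."""
    if closed:
        pts = np.vstack([points, points[:1]])
    else:
        pts = points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def perimeter(points: np.ndarray) -> float:
    return float(cumulative_arclength(points, closed=True)[-1])


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` vertices at uniform arclength."""
    pts = np.vstack([points, points[:1]])
    s = cumulative_arclength(points, closed=True)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, pts[:, 0])
    out[:, 1] = np.interp(target, s, pts[:, 1])
    return out


def resample_open(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline to ``n`` vertices at uniform arclength."""
    s = cumulative_arclength(points, closed=False)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate path with zero length")
    target = np.linspace(0.0, total, n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, points[:, 0])
    out[:, 1] = np.interp(target, s, points[:, 1])
    return out


def is_simple_closed(points: np.ndarray) -> bool:
    """True when the closed polyline does not self-intersect."""
    from shapely.geometry import LinearRing

    if len(points) < 3:
        return False
    try:
        ring = LinearRing(points)
    except Exception:
        return False
    return bool(ring.is_valid and ring.is_simple)


def circ_frac_distance(a: np.ndarray | float, b: float) -> np.ndarray:
    """Shortest distance between arclength fractions on the unit circle."""
    d = np.abs(np.asarray(a, dtype=float) - b) % 1.0
    return np.minimum(d, 1.0 - d)


def tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at each vertex of a closed polyline (central differences)."""
    d = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    norm = np.linalg.norm(d, axis=1)
    norm[norm == 0] = 1.0
    return d / norm[:, None]


def fit_circle_radius(pts: np.ndarray) -> float:
    """Algebraic (Kasa) circle fit; returns the radius (inf for collinear points)."""
    x = pts[:, 1]
    y = pts[:, 0]
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError:
        return np.inf
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        return np.inf
    return float(np.sqrt(r2))


def signed_curvature(points: np.ndarray, window: int = 11) -> np.ndarray:
    """Signed discrete curvature of a closed polyline, in 1/px.

    Magnitude from a local circle fit over ``window`` samples; sign from the
    local turning direction relative to the polygon orientation, so that
    concave (inward-bending) stretches are NEGATIVE regardless of traversal
    direction.
    """
    n = len(points)
    if n < window:
        raise ValueError(f"contour too short ({n} points) for window {window}")
    half = window // 2
    orient = 1.0 if signed_area(points) > 0 else -1.0
    kappa = np.empty(n)
    k = max(2, half // 2)
    prev = points[np.arange(n) - k]
    nxt = points[(np.arange(n) + k) % n]
    v1 = points - prev
    v2 = nxt - points
    # cross product with x = col, y = row
    turn = v1[:, 1] * v2[:, 0] - v1[:, 0] * v2[:, 1]
    idx = np.arange(-half, half + 1)
    for i in range(n):
        win = points[(i + idx) % n]
        r = fit_circle_radius(win)
        mag = 0.0 if not np.isfinite(r) or r == 0 else 1.0 / r
        sign = np.sign(turn[i]) * orient
        if sign == 0:
            sign = 1.0
        kappa[i] = sign * mag
    return kappa
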