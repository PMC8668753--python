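"""Planar geometry on locally projected coordinates.

Telemetry positions and survey grids arrive as WGS84 lon/lat.  All distance
computations (minimum enclosing circles, buffer membership) happen in a local
azimuthal equidistant projection in kilometres, centred on the data centroid,
which preserves distances from the centre and keeps distortion negligible at
the few-hundred-km scale of a coastal study region.
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


class AzimuthalEquidistant:
    """Azimuthal equidistant projection on the sphere, centred at (lon0, lat0).

    ``forward`` maps degrees lon/lat to (x, y) in km; ``inverse`` maps back.
    Distances from the projection centre are exact great-circle distances.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = math.radians(lon0)
        self._phi0 = math.radians(lat0)

    @classmethod
    def for_points(cls, lon: np.ndarray, lat: np.ndarray) -> "AzimuthalEquidistant":
        return cls(float(np.mean(lon)), float(np.mean(lat)))

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cos_c = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with the removable singularity at c = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.where(
            c > 1e-12,
            np.arcsin(cos_c * np.sin(self._phi0) + y * sin_c * np.cos(self._phi0) / safe_c),
            self._phi0,
        )
        lam = self._lam0 + np.where(
            c > 1e-12,
            np.arctan2(x * sin_c, safe_c * np.cos(self._phi0) * cos_c - y * sin_c * np.sin(self._phi0)),
            0.0,
        )
        return np.degrees(lam), np.degrees(phi)


def _circle_from(points: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Circle (cx, cy, r) through 0–3 boundary points."""
    if not points:
        return 0.0, 0.0, 0.0
    if len(points) == 1:
        return points[0][0], points[0][1], 0.0
    if len(points) == 2:
        (ax, ay), (bx, by) = points
        cx, cy = (ax + bx) / 2.0, (ay + by) / 2.0
        return cx, cy, math.hypot(ax - cx, ay - cy)
    (ax, ay), (bx, by), (cx_, cy_) = points
    d = 2.0 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
    if abs(d) < 1e-14:
        # collinear: fall back to the widest pair
        pairs = [
            _circle_from([points[0], points[1]]),
            _circle_from([points[0], points[2]]),
            _circle_from([points[1], points[2]]),
        ]
        return max(pairs, key=lambda c: c[2])
    a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx_ * cx_ + cy_ * cy_
    ux = (a2 * (by - cy_) + b2 * (cy_ - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx_ - bx) + b2 * (ax - cx_) + c2 * (bx - ax)) / d
    return ux, uy, math.hypot(ax - ux, ay - uy)


def _in_circle(p: tuple[float, float], circle: tuple[float, float, float], eps: float = 1e-9) -> bool:
    return math.hypot(p[0] - circle[0], p[1] - circle[1]) <= circle[2] + eps


def minimum_enclosing_circle(
    points: np.ndarray, rng: np.random.Generator | None = None
) -> tuple[tuple[float, float], float]:
    """Smallest circle containing all ``points`` ((n, 2) array, km).

    Welzl's move-to-front algorithm, expected O(n) after a random shuffle.
    Returns ``((cx, cy), radius)``.

    Raises ``ValueError`` on an empty point set.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("minimum enclosing circle of an empty point set is undefined")
    if pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {pts.shape}")
    # deduplicate; MEC is a set property and duplicates slow the recursion
    pts = np.unique(pts, axis=0)
    p_list = [tuple(p) for p in pts]
    rng = rng or np.random.default_rng(0)
    rng.shuffle(p_list)

    circle = (p_list[0][0], p_list[0][1], 0.0)
    for i, p in enumerate(p_list):
        if _in_circle(p, circle):
            continue
        circle = (p[0], p[1], 0.0)
        for j in range(i):
            q = p_list[j]
            if _in_circle(q, circle):
                continue
            circle = _circle_from([p, q])
            for k in range(j):
                s = p_list[k]
                if _in_circle(s, circle):
                    continue
                circle = _circle_from([p, q, s])
    return (circle[0], circle[1]), circle[2]


def points_in_circle(x: np.ndarray, y: np.ndarray, cx: float, cy: float, radius: float) -> np.ndarray:
    """Boolean mask of points whose centres fall inside the circle (closed)."""
    return (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2 <= radius**2
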