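"""Polyline helpers shared by the contour generators and the polymer statistics.

All polylines are (N, 2) float arrays of (x, y) positions in nanometres.
"""
from __future__ import annotations

import numpy as np


def segment_lengths(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return np.hypot(*np.diff(points, axis=0).T)


def polyline_length(points: np.ndarray) -> float:
    """Total arc length (sum of chord lengths)."""
    return float(segment_lengths(points).sum())


def arc_positions(points: np.ndarray) -> np.ndarray:
    """Cumulative arc-length coordinate of each vertex, starting at 0."""
    return np.concatenate([[0.0], np.cumsum(segment_lengths(points))])


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length *spacing* (endpoint kept)."""
    points = np.asarray(points, dtype=float)
    s = arc_positions(points)
    total = s[-1]
    if total <= 0:
        return points[:1].copy()
    n = max(int(round(total / spacing)), 1)
    target = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(target, s, points[:, 0]),
                            np.interp(target, s, points[:, 1])])


def resample_to_count(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to exactly *n* points, uniform in arc length."""
    points = np.asarray(points, dtype=float)
    s = arc_positions(points)
    if s[-1] <= 0:
        return np.repeat(points[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, points[:, 0]),
                            np.interp(target, s, points[:, 1])])


def sub_polyline(points: np.ndarray, s0: float, s1: float) -> np.ndarray:
    """The portion of a polyline between arc-length coordinates s0 and s1."""
    points = np.asarray(points, dtype=float)
    s = arc_positions(points)
    s0 = max(s0, 0.0)
    s1 = min(s1, s[-1])
    if s1 <= s0:
        raise ValueError("empty sub-polyline")
    inner = points[(s > s0) & (s < s1)]
    p0 = np.array([np.interp(s0, s, points[:, 0]), np.interp(s0, s, points[:, 1])])
    p1 = np.array([np.interp(s1, s, points[:, 0]), np.interp(s1, s, points[:, 1])])
    return np.vstack([p0, inner, p1])


def tangent_angles(points: np.ndarray) -> np.ndarray:
    """Per-vertex tangent direction by central difference (one-sided at ends)."""
    points = np.asarray(points, dtype=float)
    d = np.empty_like(points)
    d[1:-1] = points[2:] - points[:-2]
    d[0] = points[1] - points[0]
    d[-1] = points[-1] - points[-2]
    return np.arctan2(d[:, 1], d[:, 0])


def unit_tangents(points: np.ndarray) -> np.ndarray:
    psi = tangent_angles(points)
    return np.column_stack([np.cos(psi), np.sin(psi)])


def transform(points: np.ndarray, rotation: float = 0.0,
              offset: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Rotate about the polyline centroid, then translate the centroid to *offset*."""
    points = np.asarray(points, dtype=float)
    c = points.mean(axis=0)
    rot = np.array([[np.cos(rotation), -np.sin(rotation)],
                    [np.sin(rotation), np.cos(rotation)]])
    return (points - c) @ rot.T + np.asarray(offset, dtype=float)


def _orient(p, q, r):
    return (q[..., 0] - p[..., 0]) * (r[..., 1] - p[..., 1]) \
        - (q[..., 1] - p[..., 1]) * (r[..., 0] - p[..., 0])


def self_intersects(points: np.ndarray, min_separation: int = 2) -> bool:
    """True if any two non-adjacent segments of the polyline cross transversally.

    Segments closer than *min_separation* indices are skipped so that the
    shared-vertex contact of consecutive segments does not count as a crossing.
    """
    points = np.asarray(points, dtype=float)
    n = len(points) - 1
    for i in range(n):
        a, b = points[i], points[i + 1]
        js = np.arange(i + min_separation + 1, n)
        if js.size == 0:
            continue
        c, d = points[js], points[js + 1]
        o1 = _orient(a[None], b[None], c)
        o2 = _orient(a[None], b[None], d)
        o3 = _orient(c, d, a[None])
        o4 = _orient(c, d, b[None])
        if np.any((o1 * o2 < 0) & (o3 * o4 < 0)):
            return True
    return False


def signed_curvature(points: np.ndarray) -> np.ndarray:
    """Signed curvature at interior vertices from the tangent-angle increment.

    Returns one value per interior vertex: turn angle divided by the mean of the
    adjacent chord lengths. Positive = left turn.
    """
    points = np.asarray(points, dtype=float)
    seg = np.diff(points, axis=0)
    ang = np.arctan2(seg[:, 1], seg[:, 0])
    turn = np.angle(np.exp(1j * np.diff(ang)))
    ds = segment_lengths(points)
    denom = 0.5 * (ds[:-1] + ds[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, turn / denom, 0.0)


def circumradius(p1, p2, p3, cap: float = np.inf) -> float:
    """Radius of the circle through three points; *cap* if (near-)collinear."""
    a = np.hypot(*(np.asarray(p2) - p3))
    b = np.hypot(*(np.asarray(p1) - p3))
    c = np.hypot(*(np.asarray(p1) - p2))
    area2 = abs(_orient(np.asarray(p1), np.asarray(p2), np.asarray(p3)))
    if area2 <= 1e-12 * max(a * b, 1e-300):
        return cap
    return min(a * b * c / (2.0 * area2), cap)
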