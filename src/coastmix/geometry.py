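"""Minimum convex polygons (MCPs) in isotope space.

A consumer outside the convex hull of the sources (after removing trophic
enrichment) cannot be written as any convex mixture of those sources, so
point-in-polygon counts against the raw-value hull and the group-mean hull
provide a cheap plausibility screen for candidate trophic enrichment factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

BOUNDARY_TOL = 1e-9  # permil; boundary points count as inside


@dataclass
class ConvexPolygon:
    """Strictly convex polygon: counter-clockwise vertices, first not repeated."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.vertices, dtype=float)
        if V.ndim != 2 or V.shape[1] != 2 or len(V) < 3:
            raise ValueError("need >= 3 two-dimensional vertices")
        if self.signed_area_of(V) <= 0:
            raise ValueError("vertices must be counter-clockwise with positive area")
        self.vertices = V

    @staticmethod
    def signed_area_of(V: np.ndarray) -> float:
        x, y = V[:, 0], V[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return self.signed_area_of(self.vertices)


def convex_hull(points) -> ConvexPolygon:
    """Convex hull of >= 3 non-collinear points.

    Interior and collinear boundary points are dropped from the vertex list;
    an all-collinear input is a degenerate polygon and raises ValueError.
    """
    P = np.asarray(points, dtype=float)
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    try:
        hull = ConvexHull(P)
    except QhullError as exc:
        raise ValueError("degenerate polygon: points are collinear") from exc
    return ConvexPolygon(P[hull.vertices])  # Qhull returns CCW order in 2-D


def contains(polygon: ConvexPolygon, point, tol: float = BOUNDARY_TOL) -> bool:
    """True iff the point is inside or on the boundary (half-plane signs).

    For a CCW polygon every interior point lies to the left of (or on) each
    directed edge; the cross-product sign test with a small tolerance keeps
    values sitting exactly on an edge from flipping with rounding.
    """
    p = np.asarray(point, dtype=float)
    V = polygon.vertices
    a = V
    b = np.roll(V, -1, axis=0)
    cross = (b[:, 0] - a[:, 0]) * (p[1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (p[0] - a[:, 0])
    return bool(np.all(cross >= -tol))


def contains_many(polygon: ConvexPolygon, points, tol: float = BOUNDARY_TOL) -> np.ndarray:
    P = np.atleast_2d(np.asarray(points, dtype=float))
    V = polygon.vertices
    a = V[None, :, :]
    b = np.roll(V, -1, axis=0)[None, :, :]
    cross = ((b[..., 0] - a[..., 0]) * (P[:, None, 1] - a[..., 1])
             - (b[..., 1] - a[..., 1]) * (P[:, None, 0] - a[..., 0]))
    return np.all(cross >= -tol, axis=1)


def tef_plausibility(consumers, source_points, group_means, scenario):
    """Count TEF-corrected consumers inside the raw and group-mean MCPs.

    Each consumer point is shifted by subtracting the scenario's mean
    enrichment per axis (d13C - eps13C, d15N - eps15N) — i.e. moved back to
    diet space — then tested against (a) the hull of all raw source values
    and (b) the hull of the group means. TEF SDs play no role here; this is
    the point-value mixing-polygon screen.

    Parameters
    ----------
    consumers : sequence of ConsumerRecord or (d13C, d15N) pairs
    source_points : (n, 2) raw source deltas
    group_means : (g, 2) per-group mean deltas (g >= 3)
    scenario : TEFScenario

    Returns
    -------
    (n_inside_raw, n_inside_mean, flags) where flags is a DataFrame-ready list
    of dicts with per-consumer inside/outside booleans.
    """
    pts = np.array([
        (c.d13C, c.d15N) if hasattr(c, "d13C") else tuple(c) for c in consumers
    ], dtype=float)
    ids = [getattr(c, "consumer_id", str(i)) for i, c in enumerate(consumers)]
    group_means = np.asarray(group_means, dtype=float)
    if len(group_means) < 3:
        raise ValueError("need at least 3 group means to form a polygon")
    shifted = pts - np.array([scenario.eps13C_mean, scenario.eps15N_mean])
    raw_hull = convex_hull(source_points)
    mean_hull = convex_hull(group_means)
    in_raw = contains_many(raw_hull, shifted)
    in_mean = contains_many(mean_hull, shifted)
    flags = [
        {"consumer_id": cid, "inside_raw_mcp": bool(r), "inside_mean_mcp": bool(m)}
        for cid, r, m in zip(ids, in_raw, in_mean)
    ]
    return int(in_raw.sum()), int(in_mean.sum()), flags
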