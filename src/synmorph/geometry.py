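"""Planar geometry primitives shared by the measurement modules.

Everything here is exact segment geometry (no resampling): point-to-
polyline distance via per-segment projection, arc-length parameterization
of a trace, and the outward walk used to measure plasma-membrane
evaginations.  All lengths in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from shapely.geometry import LineString, Point as ShapelyPoint

from .annotations import Point2D, Polyline, ValidationError

__all__ = [
    "point_to_polyline_distance",
    "project_onto_polyline",
    "EvaginationSide",
    "walk_to_chord_distance",
]


def _as_xy(p) -> tuple[float, float]:
    if isinstance(p, Point2D):
        return p.x, p.y
    return float(p[0]), float(p[1])


def point_to_polyline_distance(p, polyline: Polyline) -> float:
    """Minimum Euclidean distance from a point to any segment of a polyline.

    Zero iff the point lies on the polyline.  Rigid-motion invariant by
    construction.
    """
    x, y = _as_xy(p)
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValidationError(f"non-finite query point ({x}, {y})")
    return float(ShapelyPoint(x, y).distance(LineString(polyline.vertices)))


def project_onto_polyline(p, polyline: Polyline) -> tuple[float, np.ndarray]:
    """Arc-length position and coordinates of the nearest point on a polyline."""
    x, y = _as_xy(p)
    line = LineString(polyline.vertices)
    s = line.project(ShapelyPoint(x, y))
    q = line.interpolate(s)
    return float(s), np.array([q.x, q.y])


def _cumulative_arclength(vertices: np.ndarray) -> np.ndarray:
    seg = np.diff(vertices, axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


@dataclass(frozen=True)
class EvaginationSide:
    """One side of an evagination measurement.

    ``arc_length`` is the curved distance along the membrane trace from the
    active-zone edge to the first trace point whose straight-line (chord)
    distance from that edge equals the probe length; ``None`` when the
    trace ends before the chord distance is reached.
    """

    arc_length: Optional[float]
    reached: bool


def walk_to_chord_distance(
    trace: Polyline,
    start_arc: float,
    origin: np.ndarray,
    probe_length: float,
    direction: int,
) -> EvaginationSide:
    """Walk along ``trace`` from arc position ``start_arc`` in ``direction``
    (+1 toward the end, -1 toward the start) and return the arc length to the
    first point whose chord distance from ``origin`` equals ``probe_length``.

    The crossing is located exactly within a segment: the squared chord
    distance is quadratic in the segment parameter, so the first root with
    the chord rising through ``probe_length`` is solved in closed form.
    Robust to traces that re-approach the origin (non-monotone chord).
    """
    if probe_length <= 0:
        raise ValidationError("probe_length must be > 0")
    verts = trace.vertices
    cum = _cumulative_arclength(verts)
    total = cum[-1]
    if not (0.0 <= start_arc <= total):
        raise ValidationError("start position is outside the trace")

    # Build the ordered list of (point, arc-from-start) along the walk.
    if direction > 0:
        idx = np.searchsorted(cum, start_arc, side="right")
        ahead = verts[idx:]
        arcs = cum[idx:] - start_arc
    else:
        idx = np.searchsorted(cum, start_arc, side="left")
        ahead = verts[:idx][::-1]
        arcs = start_arc - cum[:idx][::-1]

    line = LineString(verts)
    prev_pt = np.asarray(line.interpolate(start_arc).coords[0])
    prev_arc = 0.0
    prev_chord = float(np.hypot(*(prev_pt - origin)))
    if prev_chord >= probe_length:
        return EvaginationSide(arc_length=0.0, reached=True)

    for pt, arc in zip(ahead, arcs):
        chord = float(np.hypot(*(pt - origin)))
        seg = pt - prev_pt
        seg_len = arc - prev_arc
        if seg_len > 0 and chord >= probe_length:
            # solve |prev_pt + t*seg - origin| = probe_length for t in (0, 1]
            d = prev_pt - origin
            a = float(seg @ seg)
            b = 2.0 * float(d @ seg)
            c = float(d @ d) - probe_length**2
            disc = b * b - 4 * a * c
            disc = max(disc, 0.0)
            t = (-b + math.sqrt(disc)) / (2 * a)
            t = min(max(t, 0.0), 1.0)
            return EvaginationSide(arc_length=prev_arc + t * seg_len, reached=True)
        prev_pt, prev_arc, prev_chord = pt, arc, chord
    return EvaginationSide(arc_length=None, reached=False)
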