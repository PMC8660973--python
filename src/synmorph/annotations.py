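"""Core data model for per-section synapse annotations.

A *section* is a single ~70 nm EM section through one synapse, annotated by
hand: vesicle centers and diameters, an open polyline tracing the active
zone (AZ), an open polyline tracing the axolemma (plasma membrane) around
the synapse, and closed outlines for cisternae.  All planar coordinates and
lengths are in nanometers; the coordinate origin and orientation are
arbitrary per section, and every downstream computation is rigid-motion
invariant.  Distances from the antibody injection site are in micrometers,
matching how dose zones are defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SchemaError",
    "Point2D",
    "Polyline",
    "VesicleAnnotation",
    "SectionAnnotation",
    "VESICLE_KINDS",
    "TREATMENTS",
]

#: Recognized vesicle kinds: plain (uncoated) vesicles, clathrin-coated
#: pits and clathrin-coated vesicles.  Developmental stage labels for
#: coated structures are accepted as input, never computed.
VESICLE_KINDS = ("uncoated", "ccp", "ccv")

#: Conventional treatment labels.  Free-form labels are allowed; these are
#: the ones the pipeline knows how to group.
TREATMENTS = ("untreated", "control_igg", "synuclein_ab", "sv2_ab", "vamp_ab")

#: Hand-traced AZ endpoints never lie exactly on the membrane trace; they
#: are accepted when within this distance (nm) of it.
DEFAULT_SNAP_TOLERANCE_NM = 5.0


class ValidationError(ValueError):
    """An annotation violates a structural invariant."""


class SchemaError(ValueError):
    """A dataset file does not conform to the documented schema."""


@dataclass(frozen=True)
class Point2D:
    """A point in the section plane, in nm."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinate: ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


class Polyline:
    """An ordered planar polyline in nm; ``closed=True`` makes it a polygon.

    Open polylines represent the active zone and the axolemma trace; closed
    ones represent cisterna outlines.  Consecutive duplicate points are
    rejected so that arc length is strictly positive and every segment has
    a well-defined direction.
    """

    __slots__ = ("points", "closed")

    def __init__(self, points: Iterable, closed: bool = False):
        pts = np.asarray(
            [(p.x, p.y) if isinstance(p, Point2D) else (p[0], p[1]) for p in points],
            dtype=float,
        )
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValidationError("polyline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("polyline contains non-finite coordinates")
        seg = np.diff(pts, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValidationError("polyline has coincident consecutive points")
        if closed and np.hypot(*(pts[-1] - pts[0])) == 0.0:
            # store closed outlines without the repeated closing vertex
            pts = pts[:-1]
            if pts.shape[0] < 2:
                raise ValidationError("degenerate closed outline")
        self.points = pts
        self.points.setflags(write=False)
        self.closed = bool(closed)

    @property
    def vertices(self) -> np.ndarray:
        """Vertex array including the closing vertex for polygons."""
        if self.closed:
            return np.vstack([self.points, self.points[:1]])
        return self.points

    def arc_length(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    # perimeter of a closed outline is its arc length
    perimeter = arc_length

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Polyline)
            and self.closed == other.closed
            and self.points.shape == other.points.shape
            and bool(np.all(self.points == other.points))
        )

    def __repr__(self) -> str:
        kind = "closed" if self.closed else "open"
        return f"Polyline({len(self.points)} pts, {kind})"


@dataclass(frozen=True)
class VesicleAnnotation:
    """One annotated vesicular structure.

    ``diameter`` is the annotated outer diameter in nm; the radius
    ``diameter / 2`` enters the spherical surface-area term 4*pi*r**2 of the
    membrane budget.  ``stage`` is meaningful only for coated structures
    (ccp/ccv) and is carried through untouched.
    """

    id: str
    center: Point2D
    diameter: float
    kind: str = "uncoated"
    stage: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("vesicle id must be non-empty")
        if not (math.isfinite(self.diameter) and self.diameter > 0):
            raise ValidationError(
                f"vesicle {self.id!r}: diameter must be > 0, got {self.diameter}"
            )
        if self.kind not in VESICLE_KINDS:
            raise ValidationError(
                f"vesicle {self.id!r}: unknown kind {self.kind!r}"
            )
        if self.stage is not None and self.kind == "uncoated":
            raise ValidationError(
                f"vesicle {self.id!r}: stage is only valid for coated structures"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class SectionAnnotation:
    """One annotated EM section of one synapse."""

    synapse_id: str
    axon_id: str
    treatment: str
    vesicles: list[VesicleAnnotation]
    active_zone: Polyline
    membrane_trace: Polyline
    cisternae: list[Polyline] = field(default_factory=list)
    distance_from_injection: Optional[float] = None  # um
    section_thickness: float = 70.0  # nm

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sid = self.synapse_id
        if not sid:
            raise ValidationError("synapse_id must be non-empty")
        if not (math.isfinite(self.section_thickness) and self.section_thickness > 0):
            raise ValidationError(f"section {sid!r}: section_thickness must be > 0")
        if self.active_zone.closed:
            raise ValidationError(f"section {sid!r}: active zone must be an open polyline")
        if self.membrane_trace.closed:
            raise ValidationError(f"section {sid!r}: membrane trace must be an open polyline")
        if self.active_zone.arc_length() <= 0:
            raise ValidationError(f"section {sid!r}: active zone has zero length")
        if self.distance_from_injection is not None:
            d = self.distance_from_injection
            if not math.isfinite(d) or d < 0:
                raise ValidationError(
                    f"section {sid!r}: distance_from_injection must be >= 0 um, got {d}"
                )
        for c in self.cisternae:
            if not c.closed:
                raise ValidationError(f"section {sid!r}: cisterna outlines must be closed")
        seen: set[str] = set()
        for v in self.vesicles:
            if v.id in seen:
                raise ValidationError(f"section {sid!r}: duplicate vesicle id {v.id!r}")
            seen.add(v.id)

    def vesicles_of_kind(self, *kinds: str) -> list[VesicleAnnotation]:
        return [v for v in self.vesicles if v.kind in kinds]


def check_unique_synapse_ids(sections: Sequence[SectionAnnotation]) -> None:
    """Raise if two sections share a synapse_id (dataset-level invariant)."""
    seen: set[str] = set()
    for s in sections:
        if s.synapse_id in seen:
            raise ValidationError(f"duplicate synapse_id {s.synapse_id!r} in dataset")
        seen.add(s.synapse_id)
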