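"""Reading and writing annotation datasets.

The on-disk container is a single self-describing JSON document per
dataset (format tag ``synmorph-annotation``, version 1) holding a list of
sections.  Field order is fixed, floats are serialized with ``repr``
round-trip fidelity, and writing the same dataset twice produces identical
bytes, so files can be diffed and hashed.  A flat CSV export of the vesicle
table is provided for spreadsheet use.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .annotations import (
    Point2D,
    Polyline,
    SchemaError,
    SectionAnnotation,
    ValidationError,
    VesicleAnnotation,
    check_unique_synapse_ids,
)

__all__ = ["read_dataset", "write_dataset", "export_vesicle_csv", "FORMAT_TAG", "FORMAT_VERSION"]

FORMAT_TAG = "synmorph-annotation"
FORMAT_VERSION = 1

_PathLike = Union[str, Path]


def _vesicle_to_json(v: VesicleAnnotation) -> dict:
    d = {
        "id": v.id,
        "x_nm": v.center.x,
        "y_nm": v.center.y,
        "diameter_nm": v.diameter,
        "kind": v.kind,
    }
    if v.stage is not None:
        d["stage"] = v.stage
    return d


def _polyline_to_json(p: Polyline) -> list:
    return [[float(x), float(y)] for x, y in p.points]


def _section_to_json(s: SectionAnnotation) -> dict:
    return {
        "synapse_id": s.synapse_id,
        "axon_id": s.axon_id,
        "treatment": s.treatment,
        "distance_from_injection_um": s.distance_from_injection,
        "section_thickness_nm": s.section_thickness,
        "active_zone": _polyline_to_json(s.active_zone),
        "membrane_trace": _polyline_to_json(s.membrane_trace),
        "cisternae": [_polyline_to_json(c) for c in s.cisternae],
        "vesicles": [_vesicle_to_json(v) for v in s.vesicles],
    }


def _require(record: dict, key: str, where: str):
    if key not in record:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return record[key]


def _vesicle_from_json(d: dict, where: str) -> VesicleAnnotation:
    vid = _require(d, "id", where)
    try:
        return VesicleAnnotation(
            id=str(vid),
            center=Point2D(float(_require(d, "x_nm", where)), float(_require(d, "y_nm", where))),
            diameter=float(_require(d, "diameter_nm", where)),
            kind=d.get("kind", "uncoated"),
            stage=(int(d["stage"]) if d.get("stage") is not None else None),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise SchemaError(f"{where}, vesicle {vid!r}: {exc}") from exc


def _section_from_json(d: dict, index: int) -> SectionAnnotation:
    where = f"section #{index}"
    sid = _require(d, "synapse_id", where)
    where = f"section {sid!r}"
    dist = d.get("distance_from_injection_um")
    return SectionAnnotation(
        synapse_id=str(sid),
        axon_id=str(_require(d, "axon_id", where)),
        treatment=str(_require(d, "treatment", where)),
        distance_from_injection=(None if dist is None else float(dist)),
        section_thickness=float(d.get("section_thickness_nm", 70.0)),
        active_zone=Polyline(_require(d, "active_zone", where), closed=False),
        membrane_trace=Polyline(_require(d, "membrane_trace", where), closed=False),
        cisternae=[Polyline(c, closed=True) for c in d.get("cisternae", [])],
        vesicles=[
            _vesicle_from_json(v, where) for v in _require(d, "vesicles", where)
        ],
    )


def read_dataset(path: _PathLike) -> list[SectionAnnotation]:
    """Read and validate a dataset file.

    Raises :class:`SchemaError` for structural problems (missing fields,
    wrong format tag) and :class:`ValidationError` for invariant violations
    (non-finite coordinates, non-positive diameters, duplicate ids); both
    errors name the offending record.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_TAG:
        raise SchemaError(f"{path}: missing or wrong format tag (expected {FORMAT_TAG!r})")
    if doc.get("version") != FORMAT_VERSION:
        raise SchemaError(f"{path}: unsupported version {doc.get('version')!r}")
    sections = [_section_from_json(s, i) for i, s in enumerate(doc.get("sections", []))]
    check_unique_synapse_ids(sections)
    return sections


def write_dataset(sections: Sequence[SectionAnnotation], path: _PathLike) -> None:
    """Write a validated dataset; output is byte-stable for equal inputs."""
    check_unique_synapse_ids(sections)
    doc = {
        "format": FORMAT_TAG,
        "version": FORMAT_VERSION,
        "sections": [_section_to_json(s) for s in sections],
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def export_vesicle_csv(sections: Sequence[SectionAnnotation], path: _PathLike) -> pd.DataFrame:
    """Export the flat vesicle table (one row per vesicle) as CSV."""
    rows = [
        {
            "synapse_id": s.synapse_id,
            "vesicle_id": v.id,
            "x_nm": v.center.x,
            "y_nm": v.center.y,
            "diameter_nm": v.diameter,
            "kind": v.kind,
            "stage": v.stage,
        }
        for s in sections
        for v in s.vesicles
    ]
    df = pd.DataFrame(
        rows,
        columns=["synapse_id", "vesicle_id", "x_nm", "y_nm", "diameter_nm", "kind", "stage"],
    )
    df.to_csv(path, index=False)
    return df
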