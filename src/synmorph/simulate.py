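"""Synthetic annotated-synapse generator.

Emulates hand-annotated EM sections of giant reticulospinal synapses with
the statistical structure the analysis pipeline assumes: a ~1 um active
zone on a locally flat axolemma, a tight vesicle cluster whose density
decays with distance from the active zone (truncated at 800 nm), a docked
subpopulation within 50 nm, vesicle diameters around 51.5 nm, occasional
cisternae and coated pits/vesicles, and a programmable de-clustering model
(removal and/or dispersal into satellite subclusters and singletons) tied
to an injection-distance dose gradient.

It is a static point-pattern emulator: it reproduces per-section geometry
and counts, not antibody diffusion kinetics or vesicle trafficking.  All
randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning, so per-section streams are independent yet fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .annotations import Point2D, Polyline, SectionAnnotation, ValidationError, VesicleAnnotation
from .dose import DEFAULT_ZONE_BOUNDS, ZoneBounds

__all__ = ["SyntheticParams", "generate_section", "generate_experiment", "generate_csr_field"]

#: Extent of flat membrane trace beyond each active-zone edge (nm); long
#: enough for the 1 um evagination probe on both sides.
MEMBRANE_MARGIN_NM = 1600.0


@dataclass(frozen=True)
class SyntheticParams:
    """Full parameterization of the synthetic synapse/experiment generator.

    Defaults mirror the magnitudes of resting lamprey reticulospinal
    synapses: ~130 SVs per control section, mean SV diameter 51.5 nm,
    clusters within 800 nm of a 1 um active zone, and a severe (75%)
    high-dose depletion.
    """

    n_synapses_per_zone: int = 30
    az_length: float = 1000.0  # nm
    base_sv_count_mean: float = 130.0
    sv_diameter_mean: float = 51.5  # nm
    sv_diameter_sd: float = 4.0  # nm
    cluster_decay_nm: float = 250.0  # e-folding of SV density with AZ distance
    density_profile: Literal["exponential", "uniform"] = "exponential"
    max_cluster_distance: float = 800.0  # nm
    docked_fraction: float = 0.10
    docked_band: tuple[float, float] = (10.0, 49.0)  # nm from the AZ
    min_separation: float = 40.0  # nm, hard-core spacing of vesicle centers
    decluster_fraction: dict[str, float] = field(
        default_factory=lambda: {"untreated": 0.0, "low": 0.4, "high": 0.75}
    )
    decluster_mode: Literal["remove", "disperse"] = "remove"
    n_subclusters: int = 3
    subcluster_displacement: float = 400.0  # nm
    subcluster_spread: float = 40.0  # nm, scatter within a satellite subcluster
    singleton_fraction: float = 0.2  # of the dispersed vesicles
    cisterna_rate: float = 1.0  # Poisson mean per section
    ccpv_rate: float = 2.0  # Poisson mean per section
    section_thickness: float = 70.0  # nm
    zone_bounds: ZoneBounds = DEFAULT_ZONE_BOUNDS
    untreated_distance_range: tuple[float, float] = (410.0, 600.0)  # um
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("docked_fraction", "singleton_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name, v in self.decluster_fraction.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"decluster_fraction[{name!r}] must be in [0, 1]")
        for name in (
            "az_length",
            "cluster_decay_nm",
            "max_cluster_distance",
            "section_thickness",
            "subcluster_displacement",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.n_subclusters < 1:
            raise ValidationError("n_subclusters must be >= 1")


def _place_with_separation(
    rng, sampler, accepted: np.ndarray, m: int, min_sep: float, max_tries: int = 100
):
    """Draw a point from ``sampler`` rejecting candidates closer than
    ``min_sep`` to the ``m`` accepted points; falls back to the last
    candidate when the region is too crowded to satisfy the hard core."""
    pt = None
    for _ in range(max_tries):
        pt = sampler(rng)
        if m == 0 or np.min(
            np.hypot(accepted[:m, 0] - pt[0], accepted[:m, 1] - pt[1])
        ) >= min_sep:
            return pt
    return pt


def _sample_az_distance(rng, params: SyntheticParams) -> float:
    lo = params.docked_band[1] + 1.0
    hi = params.max_cluster_distance
    if params.density_profile == "uniform":
        return float(rng.uniform(lo, hi))
    # exponential decay, truncated by resampling
    for _ in range(1000):
        d = lo + rng.exponential(params.cluster_decay_nm)
        if d < hi:
            return float(d)
    return float(rng.uniform(lo, hi))


def _truncated_normal(rng, mean: float, sd: float, lower: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lower:
            return float(v)
    return max(lower + 1e-6, mean)


def _flat_membrane(az_length: float) -> Polyline:
    return Polyline(
        [(-MEMBRANE_MARGIN_NM, 0.0), (az_length + MEMBRANE_MARGIN_NM, 0.0)], closed=False
    )


def _circle_outline(cx: float, cy: float, radius: float, n_vertices: int = 24) -> Polyline:
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    pts = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    return Polyline(pts, closed=True)


def generate_section(
    params: SyntheticParams,
    zone: str,
    seed: Optional[int] = None,
    synapse_id: str = "synthetic-001",
    axon_id: str = "axon-1",
    treatment: str = "synuclein_ab",
    distance_from_injection: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> SectionAnnotation:
    """Generate one annotated section for the given dose zone.

    The de-clustering model applies the zone's programmed fraction either
    by removing vesicles (``decluster_mode='remove'``; emulates loss of
    membrane from the section) or by dispersing them into satellite
    subclusters and singletons (``'disperse'``; emulates dispersal with
    conserved vesicle number).
    """
    if zone not in params.decluster_fraction:
        raise ValidationError(f"no decluster_fraction programmed for zone {zone!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    L = params.az_length
    n = int(rng.poisson(params.base_sv_count_mean))
    n_docked = int(round(params.docked_fraction * n))

    pts = np.empty((n, 2), dtype=float)
    for i in range(n):
        if i < n_docked:
            sampler = lambda r: (r.uniform(0.0, L), r.uniform(*params.docked_band))
        else:
            sampler = lambda r: (r.uniform(0.0, L), _sample_az_distance(r, params))
        pts[i] = _place_with_separation(rng, sampler, pts, i, params.min_separation)
    accepted = [tuple(p) for p in pts]

    frac = params.decluster_fraction[zone]
    k = int(round(frac * len(accepted)))
    if k > 0:
        idx = rng.choice(len(accepted), size=k, replace=False)
        if params.decluster_mode == "remove":
            accepted = [p for i, p in enumerate(accepted) if i not in set(idx.tolist())]
        else:
            accepted = _disperse(rng, params, accepted, idx)

    vesicles = [
        VesicleAnnotation(
            id=f"sv-{i:04d}",
            center=Point2D(float(x), float(y)),
            diameter=_truncated_normal(rng, params.sv_diameter_mean, params.sv_diameter_sd, 10.0),
            kind="uncoated",
        )
        for i, (x, y) in enumerate(accepted)
    ]
    for j in range(int(rng.poisson(params.ccpv_rate))):
        vesicles.append(
            VesicleAnnotation(
                id=f"ccpv-{j:03d}",
                center=Point2D(float(rng.uniform(-200.0, L + 200.0)), float(rng.uniform(5.0, 80.0))),
                diameter=_truncated_normal(rng, 80.0, 10.0, 30.0),
                kind=str(rng.choice(["ccp", "ccv"])),
                stage=int(rng.integers(1, 5)),
            )
        )
    cisternae = [
        _circle_outline(
            float(rng.uniform(0.0, L)),
            float(rng.uniform(400.0, 900.0)),
            float(rng.uniform(75.0, 200.0)),
        )
        for _ in range(int(rng.poisson(params.cisterna_rate)))
    ]
    return SectionAnnotation(
        synapse_id=synapse_id,
        axon_id=axon_id,
        treatment=treatment,
        distance_from_injection=distance_from_injection,
        section_thickness=params.section_thickness,
        vesicles=vesicles,
        active_zone=Polyline([(0.0, 0.0), (L, 0.0)], closed=False),
        membrane_trace=_flat_membrane(L),
        cisternae=cisternae,
    )


def _disperse(
    rng, params: SyntheticParams, accepted: list, idx: np.ndarray
) -> list[tuple[float, float]]:
    """Reassign the selected vesicles to satellite subclusters + singletons."""
    keep = [p for i, p in enumerate(accepted) if i not in set(idx.tolist())]
    k = len(idx)
    n_single = int(round(params.singleton_fraction * k))
    arr = np.asarray(accepted)
    centroid = arr.mean(axis=0)
    placed = np.empty((len(accepted), 2), dtype=float)
    m = len(keep)
    if m:
        placed[:m] = np.asarray(keep)

    # satellite subcluster centers, displaced from the main-cluster centroid
    sat_centers = []
    for _ in range(params.n_subclusters):
        ang = rng.uniform(0.0, math.pi)  # stay on the vesicle side of the membrane
        cx = centroid[0] + params.subcluster_displacement * math.cos(ang)
        cy = abs(centroid[1] + params.subcluster_displacement * math.sin(ang))
        sat_centers.append((cx, max(cy, 60.0)))

    n_sub = k - n_single
    for j in range(n_sub):
        cx, cy = sat_centers[j % params.n_subclusters]
        sampler = lambda r: (
            r.normal(cx, params.subcluster_spread),
            max(5.0, r.normal(cy, params.subcluster_spread)),
        )
        placed[m] = _place_with_separation(rng, sampler, placed, m, params.min_separation)
        m += 1
    for _ in range(n_single):
        sampler = lambda r: (
            r.uniform(-400.0, params.az_length + 400.0),
            r.uniform(60.0, params.max_cluster_distance),
        )
        placed[m] = _place_with_separation(rng, sampler, placed, m, params.min_separation)
        m += 1
    return [tuple(p) for p in placed[:m]]


def generate_experiment(
    params: SyntheticParams, seed: Optional[int] = None
) -> list[SectionAnnotation]:
    """Generate a full injection-gradient experiment.

    ``n_synapses_per_zone`` synapses per zone, with injection distances
    sampled uniformly within each zone's range (high 30-140 um, low
    150-390 um, untreated internal controls beyond 400 um) and the zone's
    programmed de-clustering applied.  Sections beyond the diffusion range
    are labeled ``untreated``; treated zones carry the injected-antibody
    label.
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    zones = ["untreated", "low", "high"]
    children = root.spawn(len(zones) * params.n_synapses_per_zone)
    b = params.zone_bounds
    ranges = {
        "untreated": params.untreated_distance_range,
        "low": b.low,
        "high": b.high,
    }
    sections = []
    ci = 0
    for zone in zones:
        for i in range(params.n_synapses_per_zone):
            rng = np.random.default_rng(children[ci])
            ci += 1
            dist = float(rng.uniform(*ranges[zone]))
            sections.append(
                generate_section(
                    params,
                    zone,
                    synapse_id=f"{zone}-{i:03d}",
                    axon_id=f"axon-{i % 2 + 1}",
                    treatment="untreated" if zone == "untreated" else "synuclein_ab",
                    distance_from_injection=dist,
                    rng=rng,
                )
            )
    return sections


def generate_csr_field(
    intensity: float,
    box: tuple[float, float],
    seed: int = 0,
    diameter: float = 51.5,
) -> SectionAnnotation:
    """Homogeneous Poisson (complete spatial randomness) vesicle field.

    Theory anchor for the nearest-neighbor statistics: in 2D the mean
    nearest-neighbor distance is 1 / (2 sqrt(intensity)).  No hard-core
    spacing is applied, so the field matches the Poisson closed form.
    """
    if intensity <= 0:
        raise ValidationError("intensity must be > 0")
    w, h = box
    if w <= 0 or h <= 0:
        raise ValidationError("box dimensions must be > 0")
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(intensity * w * h))
    xs = rng.uniform(0.0, w, size=n)
    ys = rng.uniform(0.0, h, size=n)
    vesicles = [
        VesicleAnnotation(
            id=f"csr-{i:05d}", center=Point2D(float(x), float(y)), diameter=diameter
        )
        for i, (x, y) in enumerate(zip(xs, ys))
    ]
    return SectionAnnotation(
        synapse_id=f"csr-{seed}",
        axon_id="csr",
        treatment="untreated",
        vesicles=vesicles,
        active_zone=Polyline([(0.0, 0.0), (w, 0.0)], closed=False),
        membrane_trace=_flat_membrane(w),
        cisternae=[],
    )
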