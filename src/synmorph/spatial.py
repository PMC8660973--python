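"""Spatial statistics of synaptic-vesicle fields.

Distance-to-active-zone profiles (binned, optionally normalized to a
control condition), per-vesicle nearest-neighbor records, the pooled
nearest-neighbor-vs-AZ-distance regression used to quantify de-clustering,
and single-linkage subcluster detection.  Nearest-neighbor distances are
center-to-center and computed within the SV pool only (cisterna-like and
coated structures excluded), per section.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .annotations import SectionAnnotation, ValidationError
from .morphometry import SV_MAX_DIAMETER_NM, classify_vesicles, distance_to_active_zone

__all__ = [
    "SpatialProfile",
    "NNRecord",
    "RegressionResult",
    "SubclusterLabeling",
    "sv_distance_profile",
    "normalize_profile",
    "nearest_neighbor_records",
    "nn_vs_az_regression",
    "holm_adjust",
    "detect_subclusters",
    "expected_csr_nn_distance",
]

PROFILE_BIN_WIDTH_NM = 50.0
PROFILE_MAX_DISTANCE_NM = 800.0

#: Single-linkage threshold for subcluster detection: about one vesicle
#: diameter, the center spacing of tightly clustered SVs.
LINK_THRESHOLD_NM = 60.0


def _sv_centers(section: SectionAnnotation, sv_max_diameter: float) -> tuple[list[str], np.ndarray]:
    svs = {c.vesicle_id for c in classify_vesicles(section, sv_max_diameter) if c.pool == "sv"}
    ids = [v.id for v in section.vesicles if v.id in svs]
    pts = np.array(
        [(v.center.x, v.center.y) for v in section.vesicles if v.id in svs], dtype=float
    ).reshape(-1, 2)
    return ids, pts


@dataclass(frozen=True)
class SpatialProfile:
    """Binned SV counts by distance to the active zone.

    ``counts`` holds the mean count per synapse per half-open bin
    ``[lo, hi)`` for ``kind='raw'``, or per-bin treated/control ratios for
    ``kind='normalized'`` (NaN where the control bin is empty).
    ``excluded_total`` counts SVs beyond the last edge, so for raw profiles
    ``sum(counts) * n_synapses + excluded_total`` equals the pooled SV
    count (mass conservation).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_synapses: int
    kind: str = "raw"
    excluded_total: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (edges.size - 1,):
            raise ValidationError("counts must have one entry per bin")
        if self.kind == "raw" and np.any(counts < 0):
            raise ValidationError("raw counts must be >= 0")
        if self.kind == "normalized" and np.any(counts[np.isfinite(counts)] < 0):
            raise ValidationError("normalized values must be >= 0")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class NNRecord:
    """One SV's nearest-neighbor distance paired with its AZ distance (nm)."""

    synapse_id: str
    vesicle_id: str
    nn_distance: float
    az_distance: float

    def __post_init__(self) -> None:
        if not self.nn_distance > 0:
            raise ValidationError(
                f"vesicle {self.vesicle_id!r}: nearest-neighbor distance must be > 0 "
                "(coincident vesicle centers?)"
            )
        if self.az_distance < 0:
            raise ValidationError("az_distance must be >= 0")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("regression needs n >= 2")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class SubclusterLabeling:
    """Partition of a section's SVs into single-linkage subclusters.

    Labels are deterministic: 0, 1, ... ordered by descending cluster size,
    ties broken by the smallest member vesicle id.  Singletons (fully
    de-clustered SVs) are legitimate clusters of size 1.
    """

    labels: dict[str, int]
    n_clusters: int
    cluster_sizes: tuple[int, ...] = field(default_factory=tuple)


def sv_distance_profile(
    sections: Sequence[SectionAnnotation],
    bin_width: float = PROFILE_BIN_WIDTH_NM,
    max_distance: float = PROFILE_MAX_DISTANCE_NM,
    sv_max_diameter: float = SV_MAX_DIAMETER_NM,
) -> SpatialProfile:
    """Mean-per-synapse SV counts in distance-to-AZ bins up to ``max_distance``.

    Bins are half-open ``[lo, hi)`` of equal ``bin_width``; SVs at or beyond
    ``max_distance`` are excluded from the bins and tallied in
    ``excluded_total``.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    n_bins = max_distance / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9 or round(n_bins) < 1:
        raise ValidationError(
            f"bin_width {bin_width} must evenly divide max_distance {max_distance}"
        )
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, max_distance, n_bins + 1)
    totals = np.zeros(n_bins)
    excluded = 0
    for s in sections:
        _, pts = _sv_centers(s, sv_max_diameter)
        for p in pts:
            d = distance_to_active_zone(p, s.active_zone)
            if d >= max_distance:
                excluded += 1
            else:
                totals[int(d // bin_width)] += 1
    n = len(sections)
    counts = totals / n if n else totals
    return SpatialProfile(
        bin_edges=edges, counts=counts, n_synapses=n, kind="raw", excluded_total=excluded
    )


def normalize_profile(treated: SpatialProfile, control: SpatialProfile) -> SpatialProfile:
    """Per-bin ratio of treated to control mean counts.

    Bins where the control is zero are undefined and returned as NaN
    (neither 0 nor infinity), so downstream summaries can skip them.
    """
    if treated.bin_edges.shape != control.bin_edges.shape or np.any(
        treated.bin_edges != control.bin_edges
    ):
        raise ValidationError("profiles have mismatched bin edges")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(control.counts > 0, treated.counts / control.counts, np.nan)
    return SpatialProfile(
        bin_edges=treated.bin_edges.copy(),
        counts=ratio,
        n_synapses=treated.n_synapses,
        kind="normalized",
    )


def nearest_neighbor_records(
    section: SectionAnnotation, sv_max_diameter: float = SV_MAX_DIAMETER_NM
) -> list[NNRecord]:
    """One record per SV: distance to its nearest SV and to the active zone.

    Sections with fewer than two SVs yield an empty list with a warning —
    a lone vesicle has no neighbor.
    """
    ids, pts = _sv_centers(section, sv_max_diameter)
    if len(ids) < 2:
        warnings.warn(
            f"section {section.synapse_id!r}: fewer than 2 SVs, no nearest-neighbor "
            "records",
            stacklevel=2,
        )
        return []
    dm = squareform(pdist(pts))
    np.fill_diagonal(dm, np.inf)
    nn = dm.min(axis=1)
    return [
        NNRecord(
            synapse_id=section.synapse_id,
            vesicle_id=ids[i],
            nn_distance=float(nn[i]),
            az_distance=distance_to_active_zone(pts[i], section.active_zone),
        )
        for i in range(len(ids))
    ]


def _ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if x.size < 2:
        raise ValidationError("regression needs at least 2 points")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in the predictor")
    if np.ptp(y) == 0:
        # constant response: exactly flat fit, no explainable variance
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=int(x.size)
        )
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def nn_vs_az_regression(records: Sequence[NNRecord]) -> RegressionResult:
    """OLS of nearest-neighbor distance on AZ distance, pooled across the
    synapses of a condition (n counts SVs, not synapses).

    A positive slope with distance means vesicles far from the active zone
    sit farther from their neighbors — the de-clustering signature; tightly
    clustered conditions stay near-flat around one vesicle diameter.
    """
    x = np.array([r.az_distance for r in records], dtype=float)
    y = np.array([r.nn_distance for r in records], dtype=float)
    return _ols(x, y)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment for a family of regression p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def detect_subclusters(
    section: SectionAnnotation,
    link_threshold: float = LINK_THRESHOLD_NM,
    sv_max_diameter: float = SV_MAX_DIAMETER_NM,
) -> SubclusterLabeling:
    """Single-linkage subclusters: connected components of the graph joining
    SV pairs with center distance <= ``link_threshold``.

    The threshold defaults to roughly one vesicle diameter, the spacing of
    tightly packed SVs, so an intact cluster is one component and dispersal
    shows up as extra components and singletons.  This is an exploratory
    statistic: the de-clustering phenotype it quantifies is otherwise
    assessed qualitatively.
    """
    ids, pts = _sv_centers(section, sv_max_diameter)
    if len(ids) == 0:
        return SubclusterLabeling(labels={}, n_clusters=0, cluster_sizes=())
    if len(ids) == 1:
        return SubclusterLabeling(labels={ids[0]: 0}, n_clusters=1, cluster_sizes=(1,))
    adj = squareform(pdist(pts)) <= link_threshold
    np.fill_diagonal(adj, False)
    n_comp, raw = connected_components(csr_matrix(adj), directed=False)
    # deterministic relabeling: descending size, then smallest member id
    members: dict[int, list[str]] = {}
    for vid, lab in zip(ids, raw):
        members.setdefault(int(lab), []).append(vid)
    order = sorted(members, key=lambda c: (-len(members[c]), min(members[c])))
    remap = {old: new for new, old in enumerate(order)}
    labels = {vid: remap[int(lab)] for vid, lab in zip(ids, raw)}
    sizes = tuple(len(members[c]) for c in order)
    return SubclusterLabeling(labels=labels, n_clusters=n_comp, cluster_sizes=sizes)


def expected_csr_nn_distance(intensity: float) -> float:
    """Closed-form mean nearest-neighbor distance, 1 / (2 sqrt(lambda)), for
    a homogeneous 2D Poisson process of the given intensity (points/nm^2)."""
    if intensity <= 0:
        raise ValidationError("intensity must be > 0")
    return 1.0 / (2.0 * math.sqrt(intensity))
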