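"""Dose-response analysis of the antibody injection gradient.

Axonal microinjection creates a concentration gradient along the axon, so
distance from the injection site is an inverse dose proxy.  Synapses are
zoned by that distance (high concentration near the site, low farther out,
internal untreated controls beyond the diffusion range), per-synapse
metrics are regressed on distance, and grouped comparisons use one-way
ANOVA with Tukey HSD post hoc tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .annotations import SectionAnnotation, ValidationError
from .morphometry import SV_MAX_DIAMETER_NM, classify_vesicles
from .spatial import RegressionResult, _ols

__all__ = [
    "ZoneBounds",
    "DEFAULT_ZONE_BOUNDS",
    "GroupComparison",
    "assign_zone",
    "cluster_size_vs_distance",
    "group_compare",
    "percent_change",
    "profile_two_way_anova",
]

ZONES = ("untreated", "low", "high", "unassigned")


@dataclass(frozen=True)
class ZoneBounds:
    """Closed distance ranges (um from the injection site) defining dose zones.

    Defaults: high concentration 30-140 um, low 150-390 um, untreated
    internal control beyond 400 um.  Distances in the unnamed gaps are
    left unassigned and excluded from grouped analyses rather than snapped.
    """

    high: tuple[float, float] = (30.0, 140.0)
    low: tuple[float, float] = (150.0, 390.0)
    untreated_min: float = 400.0

    def __post_init__(self) -> None:
        if not (0 <= self.high[0] <= self.high[1] <= self.low[0] <= self.low[1] <= self.untreated_min):
            raise ValidationError("zone bounds must be ordered and non-overlapping")


DEFAULT_ZONE_BOUNDS = ZoneBounds()


def assign_zone(
    distance_from_injection: Optional[float],
    treatment: Optional[str] = None,
    bounds: ZoneBounds = DEFAULT_ZONE_BOUNDS,
) -> str:
    """Zone label for a synapse given its distance from the injection site.

    ``None`` distance is allowed for preparations annotated as untreated
    (no injection); any other missing distance is unassigned.
    """
    d = distance_from_injection
    if d is None:
        return "untreated" if treatment == "untreated" else "unassigned"
    if not math.isfinite(d) or d < 0:
        raise ValidationError(f"distance_from_injection must be >= 0 um, got {d}")
    if d > bounds.untreated_min:
        return "untreated"
    if bounds.low[0] <= d <= bounds.low[1]:
        return "low"
    if bounds.high[0] <= d <= bounds.high[1]:
        return "high"
    return "unassigned"


def cluster_size_vs_distance(
    sections: Sequence[SectionAnnotation],
    sv_max_diameter: float = SV_MAX_DIAMETER_NM,
) -> RegressionResult:
    """OLS of per-synapse SV count on distance from the injection site (um).

    A positive slope means clusters shrink toward the injection site, i.e.
    with increasing antibody dose.
    """
    pts = [
        (s.distance_from_injection, sum(c.pool == "sv" for c in classify_vesicles(s, sv_max_diameter)))
        for s in sections
        if s.distance_from_injection is not None
    ]
    if len(pts) < 3:
        raise ValidationError("need >= 3 synapses with injection distances")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    return _ols(x, y)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA across groups of per-synapse values with Tukey HSD."""

    group_stats: dict[str, dict[str, float]]  # group -> {mean, sem, n}
    f_statistic: float
    p_value: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def group_compare(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Fixed-effects one-way ANOVA on per-synapse values, with Tukey HSD
    adjusted pairwise p-values from the studentized-range distribution.

    Identical groups (zero between-group variance) return F = 0, p = 1
    rather than the 0/0 indeterminate form.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} needs n >= 2")
    stats_out = {
        k: {
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / math.sqrt(v.size)),
            "n": int(v.size),
        }
        for k, v in groups.items()
    }
    arrays = list(groups.values())
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    if ss_between <= 1e-12 * max(ss_within, 1.0):
        f_stat, p = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    # Tukey HSD via the studentized-range distribution
    pairwise: dict[tuple[str, str], float] = {}
    if ss_within > 0:
        names = list(groups)
        values = np.concatenate([groups[k] for k in names])
        labels = np.concatenate([[k] * groups[k].size for k in names])
        tk = pairwise_tukeyhsd(values, labels)
        for row, padj in zip(tk._results_table.data[1:], tk.pvalues):
            pairwise[(str(row[0]), str(row[1]))] = float(padj)
    return GroupComparison(
        group_stats=stats_out, f_statistic=float(f_stat), p_value=p, pairwise=pairwise
    )


def percent_change(mean_reference: float, mean_treated: float) -> float:
    """Percent reduction of a treated mean relative to a reference mean:
    100 * (reference - treated) / reference.  Negative values indicate an
    increase.  Scale-invariant in the pair."""
    if not (math.isfinite(mean_reference) and mean_reference > 0):
        raise ValidationError(f"reference mean must be > 0, got {mean_reference}")
    return 100.0 * (mean_reference - mean_treated) / mean_reference


def profile_two_way_anova(counts: pd.DataFrame) -> dict[str, float]:
    """Two-way fixed-effects ANOVA of per-synapse binned SV counts on
    zone x distance-bin, without an interaction term.

    ``counts`` must be long-format with columns ``count``, ``zone``,
    ``bin`` (one row per synapse per bin).  Returns the F and p for each
    main effect.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"count", "zone", "bin"}
    if not required.issubset(counts.columns):
        raise ValidationError(f"counts table needs columns {sorted(required)}")
    fit = smf.ols("count ~ C(zone) + C(bin)", data=counts).fit()
    table = anova_lm(fit, typ=2)
    return {
        "zone_F": float(table.loc["C(zone)", "F"]),
        "zone_p": float(table.loc["C(zone)", "PR(>F)"]),
        "bin_F": float(table.loc["C(bin)", "F"]),
        "bin_p": float(table.loc["C(bin)", "PR(>F)"]),
    }
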