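"""End-to-end report assembly.

``run_pipeline`` ties the stages together: read a dataset, measure every
section (counts, docked pool, membrane budget), zone synapses by injection
distance, compare groups, build distance profiles (raw and normalized to
the untreated control), pool nearest-neighbor records per condition and
regress them on AZ distance, regress cluster size on injection distance,
and summarize subcluster structure.  The report is deterministic for a
fixed dataset and configuration: every threshold used is echoed in the
provenance block together with a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import SectionAnnotation, ValidationError
from .dose import (
    DEFAULT_ZONE_BOUNDS,
    ZoneBounds,
    assign_zone,
    cluster_size_vs_distance,
    group_compare,
    percent_change,
)
from .io import read_dataset
from .morphometry import section_metrics
from .spatial import (
    detect_subclusters,
    holm_adjust,
    nearest_neighbor_records,
    nn_vs_az_regression,
    normalize_profile,
    sv_distance_profile,
)

log = logging.getLogger("synmorph")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and options of the measurement pipeline.

    Lengths in nm except the zone bounds (um).  Defaults are the standard
    operating point: SV/cisterna boundary 100 nm, docked cutoff 50 nm,
    subcluster linkage 60 nm, evagination probe 1 um, 50 nm profile bins to
    800 nm.
    """

    sv_max_diameter: float = 100.0
    docked_threshold: float = 50.0
    link_threshold: float = 60.0
    probe_length: float = 1000.0
    bin_width: float = 50.0
    max_profile_distance: float = 800.0
    zone_bounds: ZoneBounds = DEFAULT_ZONE_BOUNDS
    budget_radius_mode: str = "per_vesicle"
    snap_tolerance: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sv_max_diameter",
            "docked_threshold",
            "link_threshold",
            "probe_length",
            "bin_width",
            "max_profile_distance",
            "snap_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zone_bounds"] = asdict(self.zone_bounds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        raw = dict(raw or {})
        if "zone_bounds" in raw and isinstance(raw["zone_bounds"], dict):
            zb = raw["zone_bounds"]
            raw["zone_bounds"] = ZoneBounds(
                high=tuple(zb.get("high", DEFAULT_ZONE_BOUNDS.high)),
                low=tuple(zb.get("low", DEFAULT_ZONE_BOUNDS.low)),
                untreated_min=zb.get("untreated_min", DEFAULT_ZONE_BOUNDS.untreated_min),
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _condition(section: SectionAnnotation, zone: str) -> str:
    """Analysis group of a section: untreated internal controls fold into
    'untreated'; injected-antibody sections split by dose zone."""
    if section.treatment == "untreated" or zone == "untreated":
        return "untreated"
    if zone == "unassigned":
        return "unassigned"
    return f"{section.treatment}_{zone}"


@dataclass
class RunReport:
    """Everything the pipeline computed, plus provenance."""

    config: dict
    provenance: dict
    metrics: pd.DataFrame
    nn_records: pd.DataFrame
    group_comparisons: dict
    percent_changes: dict
    profiles: dict
    nn_regressions: dict
    dose_regression: Optional[dict]
    subcluster_summary: dict

    def summary_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "config": self.config,
            "group_comparisons": self.group_comparisons,
            "percent_changes": self.percent_changes,
            "profiles": self.profiles,
            "nn_regressions": self.nn_regressions,
            "dose_regression": self.dose_regression,
            "subcluster_summary": self.subcluster_summary,
        }

    def write(self, outdir: Union[str, Path]) -> None:
        """Write CSV tables and the JSON summary; byte-stable across reruns
        with identical inputs and config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "section_metrics.csv", index=False)
        self.nn_records.to_csv(outdir / "nn_records.csv", index=False)
        with open(outdir / "report.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.summary_dict(), fh, indent=1, sort_keys=True, allow_nan=True)
            fh.write("\n")


def _regression_dict(reg) -> dict:
    return {
        "slope": reg.slope,
        "intercept": reg.intercept,
        "r_squared": reg.r_squared,
        "p_value": reg.p_value,
        "n": reg.n,
    }


def _comparison_dict(cmp) -> dict:
    return {
        "groups": cmp.group_stats,
        "F": cmp.f_statistic,
        "p_value": cmp.p_value,
        "pairwise": {" vs ".join(k): v for k, v in sorted(cmp.pairwise.items())},
    }


def run_pipeline(
    config: PipelineConfig,
    dataset: Union[str, Path, Sequence[SectionAnnotation]],
) -> RunReport:
    """Run the full morphometric pipeline on a dataset file or section list."""
    if isinstance(dataset, (str, Path)):
        sections = read_dataset(dataset)
    else:
        sections = list(dataset)
    log.info("pipeline start: %d sections, config %s", len(sections), config.config_hash())

    metrics = section_metrics(
        sections,
        sv_max_diameter=config.sv_max_diameter,
        docked_threshold=config.docked_threshold,
        probe_length=config.probe_length,
        budget_radius_mode=config.budget_radius_mode,
    )
    zones = [
        assign_zone(s.distance_from_injection, s.treatment, config.zone_bounds)
        for s in sections
    ]
    metrics["zone"] = zones
    conditions = [_condition(s, z) for s, z in zip(sections, zones)]
    metrics["condition"] = conditions
    by_condition: dict[str, list[SectionAnnotation]] = {}
    for s, c in zip(sections, conditions):
        if c != "unassigned":
            by_condition.setdefault(c, []).append(s)

    # grouped comparisons and percent changes vs the untreated reference
    group_comparisons: dict[str, dict] = {}
    percent_changes: dict[str, dict] = {}
    grouped = metrics[metrics["condition"] != "unassigned"]
    for metric in ("sv_count", "total_area_um2", "docked_count"):
        values = {
            c: sub[metric].to_numpy(dtype=float)
            for c, sub in grouped.groupby("condition")
            if len(sub) >= 2
        }
        if len(values) >= 2:
            group_comparisons[metric] = _comparison_dict(group_compare(values))
        if "untreated" in values:
            ref = float(np.mean(values["untreated"]))
            if ref > 0:
                percent_changes[metric] = {
                    c: percent_change(ref, float(np.mean(v)))
                    for c, v in values.items()
                    if c != "untreated"
                }

    # distance-to-AZ profiles, with the high-dose condition normalized to
    # the untreated control when both exist
    profiles: dict[str, dict] = {}
    raw_profiles = {}
    for c, secs in sorted(by_condition.items()):
        prof = sv_distance_profile(
            secs,
            bin_width=config.bin_width,
            max_distance=config.max_profile_distance,
            sv_max_diameter=config.sv_max_diameter,
        )
        raw_profiles[c] = prof
        profiles[c] = {
            "bin_edges_nm": prof.bin_edges.tolist(),
            "mean_count_per_synapse": prof.counts.tolist(),
            "n_synapses": prof.n_synapses,
            "excluded_total": prof.excluded_total,
        }
    high = next((c for c in raw_profiles if c.endswith("_high")), None)
    if high and "untreated" in raw_profiles:
        norm = normalize_profile(raw_profiles[high], raw_profiles["untreated"])
        profiles[f"{high}_normalized_to_untreated"] = {
            "bin_edges_nm": norm.bin_edges.tolist(),
            "ratio": [None if not np.isfinite(v) else v for v in norm.counts],
            "n_synapses": norm.n_synapses,
        }

    # pooled nearest-neighbor records and per-condition regressions
    nn_rows = []
    nn_regressions: dict[str, dict] = {}
    cond_order = []
    raw_p = []
    for c, secs in sorted(by_condition.items()):
        records = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in secs:
                records.extend(nearest_neighbor_records(s, config.sv_max_diameter))
        nn_rows.extend(
            {
                "condition": c,
                "synapse_id": r.synapse_id,
                "vesicle_id": r.vesicle_id,
                "az_distance_nm": r.az_distance,
                "nn_distance_nm": r.nn_distance,
            }
            for r in records
        )
        if len(records) >= 3:
            try:
                reg = nn_vs_az_regression(records)
            except ValidationError:
                continue
            nn_regressions[c] = _regression_dict(reg)
            cond_order.append(c)
            raw_p.append(reg.p_value)
    if raw_p:
        for c, p_adj in zip(cond_order, holm_adjust(raw_p)):
            nn_regressions[c]["p_value_holm"] = float(p_adj)
    nn_records = pd.DataFrame(
        nn_rows,
        columns=["condition", "synapse_id", "vesicle_id", "az_distance_nm", "nn_distance_nm"],
    )

    # dose-response regression over injected sections with known distances
    dose_regression = None
    treated = [
        s
        for s in sections
        if s.treatment not in ("untreated",) and s.distance_from_injection is not None
    ]
    if len(treated) >= 3:
        try:
            dose_regression = _regression_dict(
                cluster_size_vs_distance(treated, config.sv_max_diameter)
            )
        except ValidationError:
            dose_regression = None

    # subcluster structure per condition
    subcluster_summary: dict[str, dict] = {}
    for c, secs in sorted(by_condition.items()):
        n_clusters = []
        singleton_counts = []
        for s in secs:
            lab = detect_subclusters(s, config.link_threshold, config.sv_max_diameter)
            n_clusters.append(lab.n_clusters)
            singleton_counts.append(sum(1 for sz in lab.cluster_sizes if sz == 1))
        subcluster_summary[c] = {
            "mean_n_subclusters": float(np.mean(n_clusters)) if n_clusters else 0.0,
            "mean_n_singletons": float(np.mean(singleton_counts)) if singleton_counts else 0.0,
            "n_synapses": len(secs),
        }

    provenance = {
        "software": "synmorph",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sections": len(sections),
    }
    log.info("pipeline done: %d conditions", len(by_condition))
    return RunReport(
        config=config.to_dict(),
        provenance=provenance,
        metrics=metrics,
        nn_records=nn_records,
        group_comparisons=group_comparisons,
        percent_changes=percent_changes,
        profiles=profiles,
        nn_regressions=nn_regressions,
        dose_regression=dose_regression,
        subcluster_summary=subcluster_summary,
    )
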