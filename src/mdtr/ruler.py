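"""Aggregate weighted pathway distances into mechanism-level distances and
render the multi-dimensional ruler as a radar chart.

The mechanism-level toxic distance for a sample x and mechanism M is

    D_M(x) = sum_{p in M} w(p, x) * d_p(x)

over the mechanism's scored pathways (skipped pathways are excluded and
logged; a mechanism with no surviving pathway is reported missing rather
than zero). Each mechanism is one radar axis; display values can be min-max
normalised per mechanism across the cohort so the chart spans [0, 1] while
raw sums are always retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import ExpressionDataset, MDTRProfile, MechanismMap, SampleTable
from .pathway import PathwayDistanceResult, PathwayToxicitySpace, compute_pathway_distances

logger = logging.getLogger(__name__)


@dataclass
class RulerConfig:
    """Radar-chart rendering options."""

    display_normalization: str = "minmax_per_mechanism"  # or "none"
    output_format: str = "svg"  # svg | png | json

    def __post_init__(self) -> None:
        if self.display_normalization not in ("none", "minmax_per_mechanism"):
            raise ValueError(
                f"unknown display normalization {self.display_normalization!r}"
            )
        if self.output_format not in ("svg", "png", "json"):
            raise ValueError(f"unknown output format {self.output_format!r}")


class MissingMechanismError(RuntimeError):
    """A mechanism had no scored pathway for the requested operation."""


def mechanism_distance(
    pathway_results: list[PathwayDistanceResult], sample_id: str
) -> float:
    """``D_M(x) = sum_p w(p, x) * d_p(x)`` over the scored pathways of M."""
    if not pathway_results:
        raise MissingMechanismError("no scored pathways for this mechanism")
    total = 0.0
    for res in pathway_results:
        d, w = res.value_for(sample_id)
        total += w * d
    return total


def compute_mdtr(
    expr: ExpressionDataset,
    meta: SampleTable,
    spaces: dict[str, PathwayToxicitySpace],
    mechanism_map: MechanismMap,
    pt_ids: set[str] | list[str] | None = None,
    weight_tail: str = "survival",
    pathway_results: dict[str, PathwayDistanceResult] | None = None,
) -> list[MDTRProfile]:
    """Score every sample on the five-mechanism ruler.

    Pathways are scored once each (via :func:`compute_pathway_distances`,
    unless precomputed results are supplied), then summed per mechanism.
    ``pt_ids`` is required when results are not precomputed.
    """
    if pathway_results is None:
        if pt_ids is None:
            raise ValueError("pt_ids required to score pathways")
        pathway_results = {
            pid: compute_pathway_distances(space, expr, meta, pt_ids, weight_tail)
            for pid, space in spaces.items()
        }
    profiles: list[MDTRProfile] = []
    for idx, sid in enumerate(expr.sample_ids):
        mech_d: dict[str, float] = {}
        missing: list[str] = []
        pw_d: dict[str, float] = {}
        pw_w: dict[str, float] = {}
        for mech, pids in mechanism_map.mechanisms:
            scored = [pathway_results[p] for p in pids if p in pathway_results]
            if not scored:
                missing.append(mech)
                logger.warning("mechanism %r: no scored pathways", mech)
                continue
            total = 0.0
            for res in scored:
                d = float(res.normalized[idx])
                w = float(res.weights[idx])
                pw_d[res.pathway_id] = d
                pw_w[res.pathway_id] = w
                total += w * d
            mech_d[mech] = total
        if not mech_d:
            raise MissingMechanismError(f"sample {sid}: no mechanism could be scored")
        profiles.append(
            MDTRProfile(
                sample_id=sid,
                mechanism_distances=mech_d,
                pathway_distances=pw_d,
                pathway_weights=pw_w,
                missing_mechanisms=missing,
            )
        )
    return profiles


def display_values(
    profiles: list[MDTRProfile], config: RulerConfig
) -> dict[str, dict[str, float]]:
    """Per-sample radar values under the configured display normalization.

    ``minmax_per_mechanism`` rescales each mechanism axis to [0, 1] across
    the cohort; raw D_M values are untouched on the profiles themselves.
    """
    if not profiles:
        return {}
    mechs = list(profiles[0].mechanism_distances)
    if config.display_normalization == "none":
        return {p.sample_id: dict(p.mechanism_distances) for p in profiles}
    out: dict[str, dict[str, float]] = {p.sample_id: {} for p in profiles}
    for m in mechs:
        col = np.array([p.mechanism_distances[m] for p in profiles])
        lo, hi = col.min(), col.max()
        scaled = np.zeros_like(col) if hi == lo else (col - lo) / (hi - lo)
        for p, v in zip(profiles, scaled):
            out[p.sample_id][m] = float(v)
    return out


def render_radar(
    profile: MDTRProfile,
    config: RulerConfig,
    path: str | Path,
    values: dict[str, float] | None = None,
) -> None:
    """Render one sample's ruler.

    ``values`` overrides the plotted axis values (e.g. cohort-normalised
    display values from :func:`display_values`); otherwise the profile's raw
    mechanism distances are plotted. ``json`` output writes the plotted
    values verbatim. SVG output is deterministic (fixed hash salt, no
    timestamp metadata).
    """
    path = Path(path)
    plotted = dict(values) if values is not None else dict(profile.mechanism_distances)
    missing = [m for m in profile.missing_mechanisms if m not in plotted]
    if missing:
        raise MissingMechanismError(
            f"sample {profile.sample_id}: cannot render, missing mechanisms {missing}"
        )
    if config.output_format == "json":
        with open(path, "w") as fh:
            json.dump({"sample_id": profile.sample_id, "values": plotted}, fh, indent=1)
        return

    labels = list(plotted)
    vals = [plotted[m] for m in labels]
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False).tolist()
    vals_closed = vals + vals[:1]
    angles_closed = angles + angles[:1]

    with matplotlib.rc_context({"svg.hashsalt": "mdtr"}):
        fig, ax = plt.subplots(subplot_kw={"polar": True}, figsize=(5, 5))
        ax.plot(angles_closed, vals_closed, color="#c0392b", linewidth=1.5)
        ax.fill(angles_closed, vals_closed, color="#c0392b", alpha=0.25)
        ax.set_xticks(angles)
        ax.set_xticklabels(labels, fontsize=8)
        if config.display_normalization == "minmax_per_mechanism":
            ax.set_ylim(0, 1)
        ax.set_title(profile.sample_id, fontsize=10)
        fig.savefig(path, format=config.output_format, metadata=_no_date(config))
        plt.close(fig)


def _no_date(config: RulerConfig) -> dict | None:
    return {"Date": None} if config.output_format == "svg" else None
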