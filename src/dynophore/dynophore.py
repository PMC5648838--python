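"""Superfeature aggregation and the three dynophore reporting channels.

Per-frame interaction events sharing the same interaction type and the same
ligand atoms are grouped into a *superfeature*. Each superfeature is
monitored spatially (a point cloud of per-frame feature centroids in the
aligned coordinate system), statistically (occurrence frequencies over all
frames, partner frequencies relative to the superfeature's own occurrences,
interaction distance histograms) and sequentially (boolean per-frame bar
codes and distance series).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DynophoreError
from .geometry import align_trajectory
from .percept import (
    EnvironmentPartner,
    FeatureTemplate,
    FeatureType,
    InteractionCriteria,
    InteractionEvent,
    classify_environment,
    detect_frame_interactions,
    perceive_features,
)
from .trajio import Topology, Trajectory, as_selection, write_pseudoatom_pdb

SCHEMA_VERSION = "1.0"

PartnerKey = tuple[str, int, str]


@dataclass
class Superfeature:
    """All events sharing (interaction type, ligand atom set)."""

    template: FeatureTemplate
    events: list[InteractionEvent] = field(default_factory=list)

    @property
    def id(self) -> tuple[str, tuple[int, ...]]:
        return self.template.key

    @property
    def label(self) -> str:
        return self.template.label

    @property
    def feature_type(self) -> FeatureType:
        return self.template.feature_type

    @property
    def occurrence_frames(self) -> list[int]:
        return sorted({e.frame_index for e in self.events})

    @property
    def occurrence_count(self) -> int:
        return len({e.frame_index for e in self.events})

    def partner_keys(self) -> list[PartnerKey]:
        seen: dict[PartnerKey, None] = {}
        for e in self.events:
            seen.setdefault(e.partner.key, None)
        return list(seen)

    def events_for(self, partner_key: PartnerKey) -> list[InteractionEvent]:
        return [e for e in self.events if e.partner.key == partner_key]


@dataclass(frozen=True)
class PartnerProfile:
    partner_key: PartnerKey
    partner_class: str
    event_count: int
    frequency: float  # % relative to superfeature occurrences
    distances: tuple[float, ...]


@dataclass(frozen=True)
class Histogram:
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class BarCode:
    key: str
    values: np.ndarray  # bool per frame

    @property
    def true_count(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass
class Dynophore:
    n_frames: int
    superfeatures: list[Superfeature]
    criteria: InteractionCriteria
    source: str = ""
    ligand_expression: str = ""
    alignment: str = ""

    def superfeature(self, label_or_id) -> Superfeature:
        for sf in self.superfeatures:
            if sf.label == label_or_id or sf.id == label_or_id:
                return sf
        raise KeyError(f"no superfeature {label_or_id!r}")


# ---------------------------------------------------------------------------
# Pipeline


def build_dynophore(
    traj: Trajectory,
    ligand_selection,
    criteria: InteractionCriteria | None = None,
    fit_selection="calpha",
    align: bool = True,
    include_water: bool = False,
    neighbor_list: bool = True,
) -> Dynophore:
    """Full pipeline: align, perceive, detect per frame, aggregate.

    A superfeature *occurrence* means the frame holds at least one detected
    environment interaction for that template; templates that never interact
    are omitted from the result.
    """
    criteria = criteria or InteractionCriteria()
    topo = traj.topology
    lig = as_selection(topo, ligand_selection)
    work = (
        align_trajectory(traj, fit_selection, reference_frame=0)
        if align
        else traj
    )
    templates = perceive_features(topo, lig)
    partners = classify_environment(topo, lig)

    by_key: dict[tuple, Superfeature] = {}
    for frame in work.frames:
        for ev in detect_frame_interactions(
            topo,
            frame,
            templates,
            partners,
            criteria,
            include_water=include_water,
            neighbor_list=neighbor_list,
        ):
            sf = by_key.setdefault(
                ev.template.key, Superfeature(template=ev.template)
            )
            sf.events.append(ev)

    superfeatures = sorted(by_key.values(), key=lambda s: s.id)
    if not superfeatures:
        warnings.warn("no interactions detected; dynophore is empty")
    return Dynophore(
        n_frames=work.n_frames,
        superfeatures=superfeatures,
        criteria=criteria,
        source=traj.topology.source_path or "",
        ligand_expression=lig.expression,
        alignment=(
            f"Kabsch fit of {fit_selection!r} onto frame 0"
            if align
            else "none (input taken as aligned)"
        ),
    )


# ---------------------------------------------------------------------------
# Statistics


def superfeature_frequency(sf: Superfeature, n_frames: int) -> float:
    """Percent of all frames in which the superfeature occurs."""
    if n_frames < 1:
        raise DynophoreError("n_frames must be >= 1")
    return 100.0 * sf.occurrence_count / n_frames


def partner_frequency(sf: Superfeature, partner_key: PartnerKey) -> float:
    """Percent of the superfeature's occurrence frames involving the partner.

    Several partners may interact simultaneously, so partner frequencies can
    sum to more than 100%.
    """
    occ = sf.occurrence_count
    if occ == 0:
        warnings.warn("partner frequency undefined: zero occurrences")
        return float("nan")
    frames = {e.frame_index for e in sf.events_for(partner_key)}
    return 100.0 * len(frames) / occ


def partner_profiles(sf: Superfeature) -> list[PartnerProfile]:
    out = []
    for key in sf.partner_keys():
        evs = sf.events_for(key)
        out.append(
            PartnerProfile(
                partner_key=key,
                partner_class=evs[0].partner.partner_class,
                event_count=len(evs),
                frequency=partner_frequency(sf, key),
                distances=tuple(e.distance for e in evs),
            )
        )
    return out


def distance_histogram(
    sf: Superfeature,
    criteria: InteractionCriteria,
    partner_key: PartnerKey | None = None,
    bin_width: float = 0.1,
) -> Histogram:
    """Histogram of interaction distances.

    Bins run from the minimum observed distance (floored to one decimal) to
    the type's maximum cutoff; bins are half-open with the last bin closed.
    """
    events = (
        sf.events if partner_key is None else sf.events_for(partner_key)
    )
    if not events:
        raise DynophoreError("cannot histogram an empty event set")
    dists = np.array([e.distance for e in events])
    lo = math.floor(dists.min() * 10.0) / 10.0
    hi = criteria.max_distance(sf.feature_type)
    n_bins = max(1, math.ceil(round((hi - lo) / bin_width, 9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)
    counts, _ = np.histogram(dists, bins=edges)
    return Histogram(bin_edges=edges, counts=counts)


def occurrence_barcode(
    sf: Superfeature, n_frames: int, partner_key: PartnerKey | None = None
) -> BarCode:
    """Boolean per-frame presence series for the superfeature or one partner."""
    values = np.zeros(n_frames, dtype=bool)
    events = (
        sf.events if partner_key is None else sf.events_for(partner_key)
    )
    for e in events:
        values[e.frame_index] = True
    key = sf.label if partner_key is None else f"{sf.label}@{partner_key}"
    return BarCode(key=key, values=values)


def point_cloud(
    sf: Superfeature, partner_key: PartnerKey | None = None
) -> tuple[np.ndarray, list[int]]:
    """One centroid point per occurrence frame, in aligned coordinates."""
    events = (
        sf.events if partner_key is None else sf.events_for(partner_key)
    )
    by_frame: dict[int, np.ndarray] = {}
    for e in events:
        by_frame.setdefault(e.frame_index, e.feature_centroid)
    frames = sorted(by_frame)
    if not frames:
        return np.zeros((0, 3)), []
    return np.array([by_frame[f] for f in frames]), frames


# ---------------------------------------------------------------------------
# Export / import


def _sf_record(sf: Superfeature, dyn: Dynophore) -> dict:
    freq = superfeature_frequency(sf, dyn.n_frames)
    return {
        "label": sf.label,
        "feature_type": sf.feature_type.value,
        "color": sf.feature_type.color,
        "ligand_atoms": list(sf.template.ligand_atoms),
        "occurrence_frames": sf.occurrence_frames,
        "occurrence_count": sf.occurrence_count,
        "frequency_pct": freq,
        "frequency_pct_1dp": round(freq, 1),
        "partners": [
            {
                "residue_name": p.partner_key[0],
                "residue_number": p.partner_key[1],
                "chain_id": p.partner_key[2],
                "partner_class": p.partner_class,
                "event_count": p.event_count,
                "frequency_pct": p.frequency,
                "frequency_pct_1dp": round(p.frequency, 1),
                "frames": sorted(
                    {e.frame_index for e in sf.events_for(p.partner_key)}
                ),
                "distances": list(p.distances),
            }
            for p in partner_profiles(sf)
        ],
    }


def export_report(
    dyn: Dynophore, out_dir: str | Path, plots: bool = False
) -> dict[str, Path]:
    """Write the JSON report, per-superfeature CSVs, cloud PDBs and plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    report = {
        "schema_version": SCHEMA_VERSION,
        "n_frames": dyn.n_frames,
        "source": dyn.source,
        "ligand_expression": dyn.ligand_expression,
        "alignment": dyn.alignment,
        "criteria": dyn.criteria.to_dict(),
        "superfeatures": [_sf_record(sf, dyn) for sf in dyn.superfeatures],
    }
    json_path = out / "dynophore.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    written["json"] = json_path

    for i, sf in enumerate(dyn.superfeatures):
        stem = f"superfeature_{i:02d}_{sf.feature_type.value}"
        csv_path = out / f"{stem}.csv"
        _write_sf_csv(sf, dyn.n_frames, csv_path)
        written[f"csv:{sf.label}"] = csv_path
        pts, frames = point_cloud(sf)
        pdb_path = out / f"{stem}_cloud.pdb"
        write_pseudoatom_pdb(
            pts, sf.feature_type.value[:3], pdb_path, frame_indices=frames
        )
        written[f"cloud:{sf.label}"] = pdb_path
    if plots:
        written.update(_write_plots(dyn, out))
    return written


def _write_sf_csv(sf: Superfeature, n_frames: int, path: Path) -> None:
    import pandas as pd

    data: dict[str, object] = {"frame": np.arange(n_frames)}
    data["occurs"] = occurrence_barcode(sf, n_frames).values.astype(int)
    for key in sf.partner_keys():
        col = f"{key[0]}{key[1]}.{key[2]}"
        data[f"{col}:occurs"] = occurrence_barcode(
            sf, n_frames, key
        ).values.astype(int)
        dist = np.full(n_frames, np.nan)
        for e in sf.events_for(key):
            dist[e.frame_index] = e.distance
        data[f"{col}:distance_A"] = dist
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.4f")


def _write_plots(dyn: Dynophore, out: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    for i, sf in enumerate(dyn.superfeatures):
        stem = f"superfeature_{i:02d}_{sf.feature_type.value}"
        keys = sf.partner_keys()
        rows = [(sf.label, occurrence_barcode(sf, dyn.n_frames))] + [
            (f"{k[0]}{k[1]}", occurrence_barcode(sf, dyn.n_frames, k))
            for k in keys
        ]
        fig, ax = plt.subplots(figsize=(8, 0.5 * len(rows) + 1))
        for j, (name, bc) in enumerate(rows):
            y = len(rows) - 1 - j
            on = np.nonzero(bc.values)[0]
            ax.vlines(on, y + 0.1, y + 0.9, color=sf.feature_type.color)
        ax.set_yticks([len(rows) - 1 - j + 0.5 for j in range(len(rows))])
        ax.set_yticklabels([name for name, _ in rows], fontsize=7)
        ax.set_xlim(0, dyn.n_frames)
        ax.set_xlabel("frame")
        ax.set_title(f"{sf.label} occurrence bar code")
        fig.tight_layout()
        p = out / f"{stem}_barcode.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written[f"barcode:{sf.label}"] = p

        hist = distance_histogram(sf, dyn.criteria)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(
            hist.bin_edges[:-1],
            hist.counts,
            width=np.diff(hist.bin_edges),
            align="edge",
            color=sf.feature_type.color,
            edgecolor="black",
            linewidth=0.3,
        )
        ax.set_xlabel("distance (Å)")
        ax.set_ylabel("events")
        ax.set_title(f"{sf.label} distance histogram")
        fig.tight_layout()
        p = out / f"{stem}_histogram.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written[f"histogram:{sf.label}"] = p
    return written


def load_report(path: str | Path) -> dict:
    """Load a dynophore JSON report back into a plain dictionary."""
    report = json.loads(Path(path).read_text())
    if report.get("schema_version") != SCHEMA_VERSION:
        warnings.warn(
            f"report schema {report.get('schema_version')} != "
            f"{SCHEMA_VERSION}; proceeding"
        )
    return report
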