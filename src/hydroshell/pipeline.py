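"""End-to-end analysis pipelines with manifests.

Three entry points mirror the three data types: labelled structures
(superpose → assign solvent → persistence → residue statistics → metals),
trajectories (windows → alignment → density → sites → residence), and
λ traces (deprotonation fractions → pKa fits → groups). Each run writes a
TSV/JSON report bundle plus a manifest with the config snapshot and
input/output checksums; identical inputs and config reproduce identical
bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import StructureModel, assign_all_solvent, read_structure, superpose_model
from .hydration import (accumulate_density, assign_site_residue, detect_sites,
                        merge_window_sites, smooth_density)
from .metals import ion_center_distances, ion_sites, ion_water_contacts
from .persistence import (CATEGORY_MOST_PERSISTENT, assign_nearest_residues,
                          classify_persistence, cluster_waters,
                          nearest_water_distances, residue_preferences)
from .residence import residence_time_over_windows
from .residue_stats import (count_bound_waters, desolvation_trend,
                            total_bound_waters)
from .titration import classify_pka_groups, read_manifest, titrate
from .trajectory import Trajectory, align_window, load_trajectory, sample_windows

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, str] = field(default_factory=dict)

    def record_input(self, path: Path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def record_output(self, path: Path) -> None:
        self.outputs[path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "inputs": self.inputs,
             "outputs": self.outputs, "stages": self.stages},
            indent=1, sort_keys=True))


def _parse_ph(label: str) -> float:
    """Extract the numeric pH from a condition label like 'pH7.0'."""
    cleaned = label.lower().replace("ph", "").strip("_- ")
    try:
        return float(cleaned)
    except ValueError as exc:
        raise PipelineError(
            f"cannot parse a pH value from condition label {label!r}") from exc


def pick_reference_label(labels: Sequence[str], override: str | None = None) -> str:
    """Reference condition for superposition: explicit override, else the
    label parsing to pH 7, else the ensemble's middle condition."""
    if override is not None:
        if override not in labels:
            raise PipelineError(f"reference label {override!r} not among {list(labels)}")
        return override
    for lab in labels:
        try:
            if abs(_parse_ph(lab) - 7.0) < 1e-9:
                return lab
        except PipelineError:
            continue
    ordered = sorted(labels)
    return ordered[len(ordered) // 2]


def run_structure_pipeline(models: Mapping[str, str | Path] | Mapping[str, StructureModel],
                           out_dir: str | Path,
                           config: AnalysisConfig | None = None,
                           reference_label: str | None = None,
                           assign_chains: bool = False) -> dict:
    """Full multi-condition structure analysis.

    ``models`` maps condition labels to PDB/mmCIF paths (or already-loaded
    models). Superposes everything onto the reference condition (pH 7 when
    present), optionally reassigns solvent chains, then runs persistence
    clustering, per-condition water statistics, the desolvation trend,
    water–water distance/KS comparisons, and — if iron or magnesium is
    present — ion geometry. Returns the result dict and writes the bundle.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.as_dict())

    if len(models) < 2:
        raise PipelineError("structure pipeline needs ≥2 labelled conditions")

    stage = "read"
    try:
        loaded: dict[str, StructureModel] = {}
        for label, src in models.items():
            if isinstance(src, StructureModel):
                m = src.copy()
                m.condition_label = label
            else:
                manifest.record_input(Path(src))
                m = read_structure(src, condition_label=label)
            loaded[label] = m
        manifest.stages[stage] = "ok"

        stage = "superpose"
        labels = list(loaded)
        ref_label = pick_reference_label(labels, reference_label)
        reference = loaded[ref_label]
        reference.superposed = True
        superposed: dict[str, StructureModel] = {}
        rmsds: dict[str, float] = {}
        for label, m in loaded.items():
            if label == ref_label:
                superposed[label] = reference
                rmsds[label] = 0.0
            else:
                sm, fit = superpose_model(m, reference)
                superposed[label] = sm
                rmsds[label] = fit.rmsd
        manifest.stages[stage] = "ok"

        if assign_chains:
            stage = "assign_chains"
            superposed = {lab: assign_all_solvent(m, tol=config.symmetry_tolerance)
                          for lab, m in superposed.items()}
            manifest.stages[stage] = "ok"

        stage = "persistence"
        ensemble = list(superposed.values())
        clusters = cluster_waters(ensemble, cutoff=config.cluster_cutoff)
        summary = classify_persistence(clusters, labels)
        assign_nearest_residues(clusters, reference, cutoff=config.residue_cutoff)
        preferences = residue_preferences(
            [c for c in clusters if c.category == CATEGORY_MOST_PERSISTENT])
        if len(labels) == 2:
            logger.info("two-condition ensemble: most_persistent coincides "
                        "with persistent (n=2 degenerate)")
        distributions, ks = nearest_water_distances(clusters, ensemble)
        manifest.stages[stage] = "ok"

        stage = "residue_stats"
        totals, ph_values = [], []
        bound_tables = {}
        for label in labels:
            m = superposed[label]
            bound_tables[label] = count_bound_waters(m, cutoff=config.residue_cutoff)
            totals.append(total_bound_waters(m).count)
            ph_values.append(_parse_ph(label))
        trend = desolvation_trend(totals, ph_values) if len(labels) >= 3 else None
        manifest.stages[stage] = "ok"

        stage = "metals"
        metal_report = {}
        for element in ("FE", "MG"):
            if any(m.ions(element=element) for m in ensemble):
                per_cond, summary_df = ion_center_distances(ensemble, element)
                contacts = {}
                for label in labels:
                    for k, ion in enumerate(ion_sites(superposed[label], element)):
                        cs = ion_water_contacts(ion, clusters, label,
                                                shell=config.shell_cutoff,
                                                hbond_distance=config.hbond_distance)
                        contacts[f"{label}:{element}{k}"] = [
                            {"distance": c.distance, "category": c.category,
                             "hbond": c.hydrogen_bond_range} for c in cs]
                metal_report[element] = {
                    "distances": {lab: d.tolist() for lab, d in per_cond.items()},
                    "summary": summary_df.to_dict(orient="records"),
                    "contacts": contacts}
        manifest.stages[stage] = "ok"
    except PipelineError:
        raise
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.write(out_dir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- report bundle ---
    sites_rows = []
    for c in clusters:
        nr = c.nearest_residue
        sites_rows.append({
            "x": round(float(c.centroid[0]), 4), "y": round(float(c.centroid[1]), 4),
            "z": round(float(c.centroid[2]), 4), "n_conditions": c.n_conditions,
            "n_members": len(c.members), "category": c.category,
            "nearest_residue": (f"{nr.residue_name}{nr.residue_id}:{nr.chain}"
                                if nr else "unassigned"),
            "nearest_distance": round(nr.distance, 4) if nr else np.nan})
    sites_df = pd.DataFrame(sites_rows)
    sites_df.to_csv(out_dir / "water_sites.tsv", sep="\t", index=False)

    counts = {
        "histogram": summary.histogram,
        "per_condition": summary.per_condition,
        "totals": dict(zip(labels, totals)),
        "rmsd_to_reference": rmsds,
        "reference": ref_label,
        "residue_preferences_most_persistent": preferences,
    }
    if trend is not None:
        counts["desolvation_trend"] = {
            "slope_waters_per_ph": trend.slope, "intercept": trend.intercept,
            "pearson_r": trend.pearson_r, "r_squared": trend.r_squared}
    (out_dir / "persistence_counts.json").write_text(
        json.dumps(counts, indent=1, sort_keys=True))

    dist_rows = []
    for cat, dist in distributions.items():
        for v in dist.values:
            dist_rows.append({"category": cat, "nearest_distance": round(float(v), 4)})
    pd.DataFrame(dist_rows).to_csv(out_dir / "water_distances.tsv", sep="\t",
                                   index=False)
    ks_rows = [{"category_a": a, "category_b": b, "ks": v}
               for (a, b), v in ks.items()]
    pd.DataFrame(ks_rows).to_csv(out_dir / "ks_matrix.tsv", sep="\t", index=False)
    for label, table in bound_tables.items():
        table.per_type.to_csv(out_dir / f"bound_waters_{label}.tsv", sep="\t",
                              header=["n_waters"])
    if metal_report:
        (out_dir / "metals.json").write_text(
            json.dumps(metal_report, indent=1, sort_keys=True))

    for p in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.json")):
        if p.name != "manifest.json":
            manifest.record_output(p)
    manifest.write(out_dir / "manifest.json")
    return {"clusters": clusters, "summary": summary, "preferences": preferences,
            "distributions": distributions, "ks": ks, "totals": dict(zip(labels, totals)),
            "trend": trend, "rmsd": rmsds, "metals": metal_report,
            "reference": ref_label}


def run_trajectory_pipeline(trajectory: Trajectory | tuple[str | Path, str | Path | None],
                            out_dir: str | Path,
                            config: AnalysisConfig | None = None,
                            window_frames: int = 500,
                            window_interval_ns: float = 1.0,
                            residence_selection: str = "GLU",
                            frame_interval_ps: float = 2.0) -> dict:
    """Hydration sites and residence times from a trajectory.

    ``trajectory`` is either an in-memory :class:`Trajectory` or a
    ``(topology_pdb, xyz_or_None)`` pair of paths. Windows are sampled, each
    aligned to the first window's first frame, densities accumulated and
    smoothed, sites detected per window and merged across windows
    (per-site density = mean over windows), residues voted per site, and
    residence times computed per window for the selected residue type.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.as_dict())

    stage = "load"
    try:
        if isinstance(trajectory, Trajectory):
            traj = trajectory
        else:
            topo, xyz = trajectory
            manifest.record_input(Path(topo))
            if xyz is not None:
                manifest.record_input(Path(xyz))
            traj = load_trajectory(topo, xyz, frame_interval_ps=frame_interval_ps)
        manifest.stages[stage] = "ok"

        stage = "windows"
        windows = sample_windows(traj, window_frames, window_interval_ns)
        reference = windows[0].coords[0][windows[0].protein_indices]
        aligned = [align_window(w, reference) for w in windows]
        manifest.stages[stage] = "ok"

        stage = "density"
        per_window_sites = []
        for w in aligned:
            grid = accumulate_density(w, config)
            sgrid = smooth_density(grid, neighbors=config.smoothing_neighbors)
            sites = detect_sites(sgrid, config, window=w)
            per_window_sites.append(sites)
        merged = merge_window_sites(per_window_sites, config.merge_distance)
        for s in merged:
            assign_site_residue(s, aligned[0], config)
        manifest.stages[stage] = "ok"

        stage = "residence"
        residence = residence_time_over_windows(
            aligned, residence_selection, cutoff=config.residue_cutoff,
            label=residence_selection)
        manifest.stages[stage] = "ok"
    except PipelineError:
        raise
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.write(out_dir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    rows = []
    for s in merged:
        res = s.closest_residue
        rows.append({"x": round(float(s.position[0]), 4),
                     "y": round(float(s.position[1]), 4),
                     "z": round(float(s.position[2]), 4),
                     "density_kgL": round(s.smoothed_density, 4),
                     "residue": f"{res[0]}{res[1]}:{res[2]}" if res else "unassigned",
                     "occupancy": (round(s.occupancy_fraction, 4)
                                   if s.occupancy_fraction is not None else np.nan)})
    pd.DataFrame(rows).to_csv(out_dir / "hydration_sites.tsv", sep="\t", index=False)
    tau_rows = [{"selection": residence.residue, "tau_ps": residence.tau_ps,
                 **{f"window_{i}": v for i, v in
                    enumerate(residence.window_values)}}]
    pd.DataFrame(tau_rows).to_csv(out_dir / "residence_times.tsv", sep="\t",
                                  index=False)
    for p in sorted(out_dir.glob("*.tsv")):
        manifest.record_output(p)
    manifest.write(out_dir / "manifest.json")
    return {"sites": merged, "per_window_sites": per_window_sites,
            "residence": residence, "n_windows": len(windows)}


def run_titration_pipeline(manifest_path: str | Path, out_dir: str | Path,
                           config: AnalysisConfig | None = None) -> dict:
    """Per-residue pKa estimation from a λ-trace manifest."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.as_dict())
    manifest.record_input(Path(manifest_path))
    stage = "titrate"
    try:
        traces = read_manifest(manifest_path)
        records = titrate(traces, lambda_low=config.lambda_low,
                          lambda_high=config.lambda_high,
                          literal=config.literal_deprotonation)
        groups = classify_pka_groups(records)
        manifest.stages[stage] = "ok"
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.write(out_dir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    rows = [{"residue": r.residue, "pka": round(r.pka, 4),
             "hill_n": round(r.hill_n, 4)} for r in records]
    pd.DataFrame(rows).to_csv(out_dir / "pka.tsv", sep="\t", index=False)
    (out_dir / "pka_groups.json").write_text(
        json.dumps(groups, indent=1, sort_keys=True))
    for p in sorted(out_dir.glob("*.tsv")) + [out_dir / "pka_groups.json"]:
        manifest.record_output(p)
    manifest.write(out_dir / "manifest.json")
    return {"records": records, "groups": groups}
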