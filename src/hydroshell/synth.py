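"""Seeded, ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the study's data types without any download:

* multi-condition solvated models — a deterministic toy-protein scaffold,
  identical across conditions, decorated with shared water sites (jittered
  below the clustering cutoff), condition-unique lone waters, optional filler
  waters realizing a planted desolvation slope, and optional ions;
* toy trajectories — a static scaffold with waters bound at planted sites
  under exponential (memoryless) residence times plus uniform bulk background;
* λ traces — two-state mixtures whose state probabilities follow a
  Henderson–Hasselbalch law at a planted pKa.

Every generator is reproducible bit-wise from (parameters, seed) and writes a
machine-readable ground-truth JSON next to its outputs. The generator plants
statistics, not physics: there are no water–water interactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import AtomRecord, StructureModel, write_structure
from .trajectory import Trajectory

AA20 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]

DEFAULT_PH_SERIES = (3.5, 4.0, 5.0, 7.0, 9.0)


class PackingError(Exception):
    """The requested sites cannot satisfy their separation constraints."""


@dataclass
class GroundTruth:
    """What was planted, for exact recovery checks."""
    seed: int
    payload: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, **self.payload}, indent=1, sort_keys=True,
            default=_jsonify))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        seed = data.pop("seed")
        return cls(seed=seed, payload=data)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Toy protein scaffolds
# ---------------------------------------------------------------------------

def toy_protein(n_copies_per_type: int = 2, chain_id: str = "A",
                ca_spacing: float = 3.8) -> StructureModel:
    """A deterministic rigid scaffold with all 20 amino-acid types.

    Residues are laid on a ring with ~Cα–Cα spacing ``ca_spacing``; each
    residue carries N, CA, C, O and (except glycine) CB heavy atoms in a
    fixed local geometry. The scaffold is identical on every call, so
    cross-condition models superpose exactly.
    """
    n_res = 20 * n_copies_per_type
    radius = ca_spacing * n_res / (2 * np.pi)
    atoms: list[AtomRecord] = []
    for i in range(n_res):
        theta = 2 * np.pi * i / n_res
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        up = np.array([0.0, 0.0, 1.0])
        ca = radius * radial
        resname = AA20[i % 20]
        resid = i + 1
        local = [
            ("N", "N", ca - 1.46 * tangent + 0.3 * up),
            ("CA", "C", ca),
            ("C", "C", ca + 1.52 * tangent + 0.3 * up),
            ("O", "O", ca + 1.52 * tangent + 1.2 * radial * 0.3 + 1.4 * up),
        ]
        if resname != "GLY":
            local.append(("CB", "C", ca + 1.53 * radial + 0.6 * up))
        for name, element, pos in local:
            atoms.append(AtomRecord(element=element, atom_name=name,
                                    residue_name=resname, residue_id=resid,
                                    chain_id=chain_id, position=pos,
                                    occupancy=1.0, b_factor=10.0))
    return StructureModel(atoms)


def _octahedral_rotations() -> list[np.ndarray]:
    """The 24 proper rotations of the octahedral group, generated by closure
    and ordered deterministically."""
    r4 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)   # 4-fold about z
    r3 = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], float)    # 3-fold about (1,1,1)
    mats = [np.eye(3)]
    changed = True
    while changed:
        changed = False
        for m in list(mats):
            for g in (r4, r3):
                cand = g @ m
                if not any(np.allclose(cand, x, atol=1e-9) for x in mats):
                    mats.append(cand)
                    changed = True
    assert len(mats) == 24
    mats.sort(key=lambda m: tuple(np.round(m.ravel(), 9)))
    return mats


CHAIN_IDS_24 = [chr(ord("A") + i) for i in range(24)]


def toy_assembly_24(n_copies_per_type: int = 1,
                    offset: float = 18.0) -> StructureModel:
    """A 24-chain octahedrally symmetric assembly of the toy scaffold,
    for symmetry-axis solvent-occupancy tests."""
    unit = toy_protein(n_copies_per_type=n_copies_per_type, chain_id="A")
    shift = np.array([offset, 0.35 * offset, 0.2 * offset])
    atoms: list[AtomRecord] = []
    for chain, rot in zip(CHAIN_IDS_24, _octahedral_rotations()):
        for a in unit.atoms:
            atoms.append(AtomRecord(
                element=a.element, atom_name=a.atom_name,
                residue_name=a.residue_name, residue_id=a.residue_id,
                chain_id=chain, position=rot @ (a.position + shift),
                occupancy=a.occupancy, b_factor=a.b_factor))
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Condition ensembles (multi-pH solvated models)
# ---------------------------------------------------------------------------

def _sample_shell_points(rng: np.random.Generator, protein_coords: np.ndarray,
                         n: int, shell: float, min_separation: float,
                         existing: list[np.ndarray], max_tries: int = 20000
                         ) -> list[np.ndarray]:
    """Rejection-sample points within ``shell`` of the protein, at least
    ``min_separation`` from each other and from ``existing`` points."""
    lo = protein_coords.min(axis=0) - shell
    hi = protein_coords.max(axis=0) + shell
    from scipy.spatial import cKDTree
    tree = cKDTree(protein_coords)
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < n:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {n} sites with separation {min_separation} Å "
                f"after {max_tries} attempts; reduce site count or separation")
        tries += 1
        p = rng.uniform(lo, hi)
        d, _ = tree.query(p)
        if not (1.5 <= d <= shell):
            continue
        others = existing + accepted
        if others and min(np.linalg.norm(p - q) for q in others) < min_separation:
            continue
        accepted.append(p)
    return accepted


def _water_atom(position: np.ndarray, resid: int, chain: str = "W") -> AtomRecord:
    return AtomRecord(element="O", atom_name="O", residue_name="HOH",
                      residue_id=resid, chain_id=chain, position=position,
                      occupancy=1.0, b_factor=20.0)


def generate_condition_ensemble(
    out_dir: str | Path | None,
    ph_values: Sequence[float] = DEFAULT_PH_SERIES,
    n_persistent_sites: int = 20,
    n_lone_per_condition: int | Mapping[str, int] = 7,
    jitter_sigma: float = 0.2,
    desolvation_slope: float | None = None,
    base_total: int = 600,
    total_noise_sigma: float = 30.0,
    cluster_cutoff: float = 1.0,
    shell: float = 5.0,
    ions: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, StructureModel], GroundTruth]:
    """Generate one solvated model per pH condition over a shared scaffold.

    ``n_persistent_sites`` water sites appear in every condition with
    isotropic Gaussian jitter ``jitter_sigma`` (keep it below half the
    clustering cutoff for clean recovery). Lone sites are placed at least
    2×cutoff + jitter margin from every other site. If ``desolvation_slope``
    is given, unconstrained filler waters bring each condition's total water
    count to ``base_total + slope·(pH − mean pH) + N(0, total_noise_sigma)``.
    ``ions`` maps a condition label to (element, distance-from-center) pairs.

    Returns the models keyed by condition label (e.g. ``"pH7.0"``) and the
    ground truth; files are written under ``out_dir`` when given.
    """
    if jitter_sigma >= cluster_cutoff / 2:
        # overlap/stress mode: recovery is not guaranteed, but allowed
        pass
    rng = np.random.default_rng(seed)
    labels = [f"pH{ph:g}" for ph in ph_values]
    if isinstance(n_lone_per_condition, Mapping):
        lone_counts = {lab: int(n_lone_per_condition.get(lab, 0)) for lab in labels}
    else:
        lone_counts = {lab: int(n_lone_per_condition) for lab in labels}

    scaffold = toy_protein()
    prot = scaffold.protein_coords()
    center = prot.mean(axis=0)
    min_sep = 2 * cluster_cutoff + 6 * jitter_sigma

    persistent = _sample_shell_points(rng, prot, n_persistent_sites, shell,
                                      min_sep, existing=[])
    all_sites = list(persistent)
    lone_sites: dict[str, list[np.ndarray]] = {}
    for lab in labels:
        pts = _sample_shell_points(rng, prot, lone_counts[lab], shell, min_sep,
                                   existing=all_sites)
        lone_sites[lab] = pts
        all_sites.extend(pts)

    mean_ph = float(np.mean(ph_values))
    totals: dict[str, int] = {}
    models: dict[str, StructureModel] = {}
    filler_counts: dict[str, int] = {}
    for lab, ph in zip(labels, ph_values):
        atoms = [AtomRecord(element=a.element, atom_name=a.atom_name,
                            residue_name=a.residue_name, residue_id=a.residue_id,
                            chain_id=a.chain_id, position=a.position.copy(),
                            occupancy=a.occupancy, b_factor=a.b_factor)
                 for a in scaffold.atoms]
        resid = 1000
        for p in persistent:
            resid += 1
            atoms.append(_water_atom(p + rng.normal(0.0, jitter_sigma, 3), resid))
        for p in lone_sites[lab]:
            resid += 1
            atoms.append(_water_atom(p + rng.normal(0.0, jitter_sigma, 3), resid))
        n_filler = 0
        if desolvation_slope is not None:
            target = base_total + desolvation_slope * (ph - mean_ph) \
                + rng.normal(0.0, total_noise_sigma)
            n_filler = max(int(round(target)) - n_persistent_sites
                           - lone_counts[lab], 0)
            lo = prot.min(axis=0) - shell
            hi = prot.max(axis=0) + shell
            from scipy.spatial import cKDTree
            tree = cKDTree(prot)
            placed = 0
            while placed < n_filler:
                p = rng.uniform(lo, hi)
                d, _ = tree.query(p)
                if 1.5 <= d <= shell:
                    resid += 1
                    atoms.append(_water_atom(p, resid))
                    placed += 1
        filler_counts[lab] = n_filler
        totals[lab] = n_persistent_sites + lone_counts[lab] + n_filler
        if ions:
            for k, (element, dist) in enumerate(ions.get(lab, [])):
                atoms.append(AtomRecord(
                    element=element, atom_name=element.upper(),
                    residue_name=element.upper(), residue_id=2000 + k,
                    chain_id="A",
                    position=center + np.array([dist, 0.0, 0.0]),
                    occupancy=1.0, b_factor=15.0))
        models[lab] = StructureModel(atoms, condition_label=lab)

    truth = GroundTruth(seed=seed, payload={
        "kind": "condition_ensemble",
        "ph_values": list(map(float, ph_values)),
        "labels": labels,
        "persistent_sites": np.array(persistent),
        "lone_sites": {lab: np.array(v).tolist() for lab, v in lone_sites.items()},
        "lone_counts": lone_counts,
        "filler_counts": filler_counts,
        "totals": totals,
        "jitter_sigma": jitter_sigma,
        "desolvation_slope": desolvation_slope,
        "base_total": base_total,
        "total_noise_sigma": total_noise_sigma,
        "ions": {lab: [[e, float(d)] for e, d in v]
                 for lab, v in (ions or {}).items()},
    })
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for lab, m in models.items():
            write_structure(m, out_dir / f"{lab}.pdb")
        truth.to_json(out_dir / "ground_truth.json")
    return models, truth


# ---------------------------------------------------------------------------
# Trajectories with planted hydration sites and residence times
# ---------------------------------------------------------------------------

@dataclass
class PlantedSite:
    position: np.ndarray
    occupancy: float
    tau_ps: float


def auto_site_positions(scaffold: StructureModel, n_sites: int,
                        distance: float = 3.0, min_separation: float = 3.0,
                        residue_name: str | None = None) -> list[np.ndarray]:
    """Deterministic site positions: outward offsets from evenly spaced
    scaffold residues (optionally of one type), mutually separated."""
    atoms = [a for a in scaffold.protein_atoms(heavy_only=True)
             if a.atom_name == ("CB" if a.residue_name != "GLY" else "CA")
             and (residue_name is None or a.residue_name == residue_name)]
    center = scaffold.protein_coords().mean(axis=0)
    positions: list[np.ndarray] = []
    step = max(len(atoms) // max(n_sites, 1), 1)
    for a in atoms[::step]:
        if len(positions) >= n_sites:
            break
        v = a.position - center
        v[2] = 0.0
        u = v / np.linalg.norm(v)
        p = a.position + distance * u
        if positions and min(np.linalg.norm(p - q) for q in positions) < min_separation:
            continue
        positions.append(p)
    if len(positions) < n_sites:
        raise PackingError(
            f"could only place {len(positions)} of {n_sites} sites on the scaffold")
    return positions


def generate_trajectory(
    out_dir: str | Path | None = None,
    n_frames: int = 5000,
    frame_interval_ps: float = 2.0,
    sites: Sequence[PlantedSite] | None = None,
    n_sites: int = 12,
    site_occupancy: float = 0.8,
    site_tau_ps: float = 10.0,
    site_jitter: float = 0.08,
    bulk_density: float = 1.0,
    shell: float = 5.0,
    box_padding: float = 6.0,
    scaffold: StructureModel | None = None,
    seed: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a toy trajectory: static scaffold, bound waters at planted
    sites, uniform bulk background.

    Each site owns one water following a two-state memoryless chain: bound
    with mean continuous lifetime ``tau_ps`` (so the survival probability of
    a bound water is exactly exponential), unbound (teleported into bulk)
    with mean off-time tau·(1−occupancy)/occupancy. Bulk waters are resampled
    uniformly in the box each frame at number density matching
    ``bulk_density`` kg/L (≈0.0334 Å⁻³ at 1 kg/L). Bulk teleportation makes
    bulk waters useless for residence-time checks — plant sites with
    ``bulk_density=0`` for those.
    """
    from .hydration import WATER_MASS_KG, A3_TO_L

    rng = np.random.default_rng(seed)
    if scaffold is None:
        scaffold = toy_protein(n_copies_per_type=1)
    if sites is None:
        positions = auto_site_positions(scaffold, n_sites)
        sites = [PlantedSite(position=p, occupancy=site_occupancy,
                             tau_ps=site_tau_ps) for p in positions]
    prot = scaffold.protein_coords()
    lo = prot.min(axis=0) - box_padding
    hi = prot.max(axis=0) + box_padding
    box_volume_l = float(np.prod(hi - lo)) * A3_TO_L
    n_bulk = int(round(bulk_density * box_volume_l / WATER_MASS_KG))

    dt = frame_interval_ps
    n_sites_actual = len(sites)
    n_waters = n_sites_actual + n_bulk

    coords = np.empty((n_frames, len(scaffold) + n_waters, 3))
    coords[:, :len(scaffold), :] = scaffold.coords[None, :, :]

    # bound-water dynamics per site
    for s_i, site in enumerate(sites):
        occ, tau = site.occupancy, site.tau_ps
        p_leave = 1.0 - np.exp(-dt / tau) if occ < 1.0 else 0.0
        if 0.0 < occ < 1.0:
            tau_off = tau * (1.0 - occ) / occ
            p_enter = 1.0 - np.exp(-dt / tau_off)
        else:
            p_enter = 1.0
        bound = rng.random() < occ
        col = len(scaffold) + s_i
        for f in range(n_frames):
            if bound:
                coords[f, col] = site.position + rng.normal(0.0, site_jitter, 3)
            else:
                coords[f, col] = rng.uniform(lo, hi)
            if bound and rng.random() < p_leave:
                bound = False
            elif not bound and rng.random() < p_enter:
                bound = True
    # bulk background, uncorrelated frame to frame
    if n_bulk:
        coords[:, len(scaffold) + n_sites_actual:, :] = rng.uniform(
            lo, hi, size=(n_frames, n_bulk, 3))

    atoms = [AtomRecord(element=a.element, atom_name=a.atom_name,
                        residue_name=a.residue_name, residue_id=a.residue_id,
                        chain_id=a.chain_id, position=a.position.copy(),
                        occupancy=a.occupancy, b_factor=a.b_factor)
             for a in scaffold.atoms]
    for w in range(n_waters):
        atoms.append(_water_atom(coords[0, len(scaffold) + w].copy(),
                                 resid=1000 + w))
    topology = StructureModel(atoms)
    traj = Trajectory(topology=topology, coords=coords,
                      frame_interval_ps=frame_interval_ps)
    truth = GroundTruth(seed=seed, payload={
        "kind": "trajectory",
        "n_frames": n_frames,
        "frame_interval_ps": frame_interval_ps,
        "sites": [{"position": s.position, "occupancy": s.occupancy,
                   "tau_ps": s.tau_ps} for s in sites],
        "bulk_density_kgL": bulk_density,
        "n_bulk_waters": n_bulk,
        "box": {"lo": lo, "hi": hi},
        "site_jitter": site_jitter,
    })
    if out_dir is not None:
        from .trajectory import write_xyz
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_structure(topology, out_dir / "topology.pdb")
        write_xyz(traj, out_dir / "trajectory.xyz")
        truth.to_json(out_dir / "ground_truth.json")
    return traj, truth


# ---------------------------------------------------------------------------
# λ traces
# ---------------------------------------------------------------------------

def generate_lambda_traces(
    out_dir: str | Path | None,
    residues: Mapping[str, tuple[float, float]] | None = None,
    ph_grid: Sequence[float] | None = None,
    n_samples: int = 2000,
    intermediate_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, dict[float, np.ndarray]], GroundTruth]:
    """Generate λ traces whose two-state occupancies follow a
    Henderson–Hasselbalch law at planted (pKa, Hill n) per residue.

    Per (residue, pH): each sample is intermediate (λ ~ U(0.2, 0.8)) with
    probability ``intermediate_fraction``; otherwise the state is
    Bernoulli(S_deprot(pH)) and λ ~ N(0.95, 0.03) deprotonated or
    N(0.05, 0.03) protonated, clipped to [0, 1]. The default grid spans pH
    1–10.5 in steps of 0.5.
    """
    from .titration import hill_curve

    if residues is None:
        residues = {"GLU104": (8.9, 1.0), "GLU131": (7.9, 1.0)}
    if ph_grid is None:
        ph_grid = np.arange(1.0, 10.51, 0.5)
    rng = np.random.default_rng(seed)
    traces: dict[str, dict[float, np.ndarray]] = {}
    for residue in sorted(residues):
        pka, hill_n = residues[residue]
        traces[residue] = {}
        for ph in ph_grid:
            s = hill_curve(ph, pka, hill_n)
            is_int = rng.random(n_samples) < intermediate_fraction
            state = rng.random(n_samples) < s
            lam = np.where(state, rng.normal(0.95, 0.03, n_samples),
                           rng.normal(0.05, 0.03, n_samples))
            lam[is_int] = rng.uniform(0.2, 0.8, int(is_int.sum()))
            traces[residue][float(ph)] = np.clip(lam, 0.0, 1.0)

    truth = GroundTruth(seed=seed, payload={
        "kind": "lambda_traces",
        "residues": {r: {"pka": float(v[0]), "hill_n": float(v[1])}
                     for r, v in residues.items()},
        "ph_grid": [float(p) for p in ph_grid],
        "n_samples": n_samples,
        "intermediate_fraction": intermediate_fraction,
    })
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, dict[str, str]] = {}
        for residue, ph_map in traces.items():
            manifest[residue] = {}
            for ph, lam in ph_map.items():
                fname = f"{residue}_pH{ph:g}.dat"
                t = np.arange(len(lam), dtype=float)
                lines = [f"{ti:.1f} {li:.6f}" for ti, li in zip(t, lam)]
                (out_dir / fname).write_text("\n".join(lines) + "\n")
                manifest[residue][f"{ph:g}"] = fname
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        truth.to_json(out_dir / "ground_truth.json")
    return traces, truth
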