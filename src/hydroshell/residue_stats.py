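"""Per-residue and per-residue-type bound-water statistics.

Bound-water counts within a contact cutoff, total water inventories per
condition, Shrake–Rupley accessible surface area, correlations of hydration
with surface area or hydrophilicity, the desolvation trend of total waters
against pH, and water–protein distance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .core import AMINO_ACIDS, ModelError, StructureModel

#: Bondi-style van der Waals radii (Å) for ASA; metals use working values
VDW_RADII = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "FE": 2.00, "MG": 1.73, "MN": 2.05, "ZN": 1.39, "NA": 2.27, "K": 2.75,
    "CA": 2.31, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}

#: Hopp–Woods hydrophilicity scale (positive = hydrophilic)
HOPP_WOODS = {
    "ARG": 3.0, "ASP": 3.0, "GLU": 3.0, "LYS": 3.0, "SER": 0.3, "ASN": 0.2,
    "GLN": 0.2, "GLY": 0.0, "PRO": 0.0, "THR": -0.4, "ALA": -0.5, "HIS": -0.5,
    "CYS": -1.0, "MET": -1.3, "VAL": -1.5, "ILE": -1.8, "LEU": -1.8,
    "TYR": -2.3, "PHE": -2.5, "TRP": -3.4,
}


@dataclass
class BoundWaterTable:
    """Per-residue water counts and their per-type aggregate for one model."""
    per_residue: pd.DataFrame   # chain, residue_id, residue_name, n_waters
    per_type: pd.Series         # residue_name -> total count
    condition_label: str


class TotalWaters(NamedTuple):
    count: int
    occupancy_weighted: float


@dataclass
class TrendFit:
    slope: float
    intercept: float
    pearson_r: float
    n_points: int

    @property
    def r_squared(self) -> float:
        return self.pearson_r ** 2


@dataclass
class ASATable:
    per_residue: pd.DataFrame   # chain, residue_id, residue_name, asa
    per_type: pd.Series
    probe_radius: float


@dataclass
class DistanceHistogram:
    distances: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def iqr(self) -> float:
        """Interquartile range of the distances — the 'flatness' scalar."""
        if len(self.distances) == 0:
            return float("nan")
        q1, q3 = np.percentile(self.distances, [25, 75])
        return float(q3 - q1)


def count_bound_waters(model: StructureModel, cutoff: float = 3.6,
                       mode: str = "multi") -> BoundWaterTable:
    """Count waters within ``cutoff`` of each residue's heavy atoms.

    ``mode='multi'`` (default): a water counts once for every residue it
    touches, so per-type totals are additive over contacts. ``mode='nearest'``
    assigns each water only to the residue owning its nearest heavy atom.
    """
    if mode not in ("multi", "nearest"):
        raise ValueError("mode must be 'multi' or 'nearest'")
    prot = model.protein_atoms(heavy_only=True)
    residues: dict[tuple[str, int, str], int] = {}
    order: list[tuple[str, int, str]] = []
    for a in prot:
        key = (a.chain_id, a.residue_id, a.residue_name)
        if key not in residues:
            residues[key] = 0
            order.append(key)
    waters = model.water_coords()
    if len(prot) and len(waters):
        coords = np.array([a.position for a in prot])
        if mode == "multi":
            tree = cKDTree(waters)
            hits: set[tuple[tuple, int]] = set()
            for i, a in enumerate(prot):
                for w in tree.query_ball_point(coords[i], cutoff):
                    hits.add(((a.chain_id, a.residue_id, a.residue_name), w))
            for key, _ in hits:
                residues[key] += 1
        else:
            tree = cKDTree(coords)
            d, idx = tree.query(waters, k=1)
            for dist, i in zip(d, idx):
                if dist <= cutoff:
                    a = prot[int(i)]
                    residues[(a.chain_id, a.residue_id, a.residue_name)] += 1
    df = pd.DataFrame(
        [(c, rid, rn, n) for (c, rid, rn), n in
         ((k, residues[k]) for k in order)],
        columns=["chain", "residue_id", "residue_name", "n_waters"])
    per_type = df.groupby("residue_name")["n_waters"].sum()
    per_type = per_type.reindex(sorted(set(per_type.index) | AMINO_ACIDS),
                                fill_value=0)
    return BoundWaterTable(per_residue=df, per_type=per_type,
                           condition_label=model.condition_label)


def total_bound_waters(model: StructureModel) -> TotalWaters:
    """Total modeled waters: record count plus the occupancy-weighted sum
    (symmetry-axis waters carry fractional occupancies)."""
    waters = model.water_oxygens()
    return TotalWaters(count=len(waters),
                       occupancy_weighted=float(sum(w.occupancy for w in waters)))


# ---------------------------------------------------------------------------
# Accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def accessible_surface_area(model: StructureModel, probe: float = 1.4,
                            n_points: int = 960) -> ASATable:
    """Shrake–Rupley numeric accessible surface area over protein atoms.

    Each atom's sphere of radius r_vdw + probe is sampled at ``n_points``;
    the unoccluded fraction times the sphere area is the atom's ASA, summed
    per residue and per residue type.
    """
    atoms = model.protein_atoms(heavy_only=False)
    if not atoms:
        raise ModelError("no protein atoms for ASA")
    unknown = sorted({a.element for a in atoms if a.element not in VDW_RADII})
    if unknown:
        raise ModelError(f"no van der Waals radius for element(s): {unknown}")
    coords = np.array([a.position for a in atoms])
    radii = np.array([VDW_RADII[a.element] for a in atoms]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2 * radii.max()
    atom_asa = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + radii.max())
                     if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_radii = radii[np.array(neighbors)]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            occluded = (d2 < (nb_radii ** 2)[None, :]).any(axis=1)
            free = np.count_nonzero(~occluded)
        else:
            free = n_points
        atom_asa[i] = free / n_points * 4 * np.pi * radii[i] ** 2

    rows: dict[tuple[str, int, str], float] = {}
    order: list[tuple[str, int, str]] = []
    for a, asa in zip(atoms, atom_asa):
        key = (a.chain_id, a.residue_id, a.residue_name)
        if key not in rows:
            rows[key] = 0.0
            order.append(key)
        rows[key] += asa
    df = pd.DataFrame([(c, rid, rn, rows[(c, rid, rn)]) for (c, rid, rn) in order],
                      columns=["chain", "residue_id", "residue_name", "asa"])
    per_type = df.groupby("residue_name")["asa"].sum()
    return ASATable(per_residue=df, per_type=per_type, probe_radius=probe)


# ---------------------------------------------------------------------------
# Trends
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray) -> TrendFit:
    res = stats.linregress(x, y)
    return TrendFit(slope=float(res.slope), intercept=float(res.intercept),
                    pearson_r=float(res.rvalue), n_points=len(x))


def hydration_correlation(per_type_counts: Mapping[str, float],
                          covariate: Mapping[str, float]) -> TrendFit:
    """OLS of per-residue-type water counts on a per-type covariate (ASA or a
    hydrophilicity scale) across the residue types present in both."""
    types = sorted(set(per_type_counts) & set(covariate))
    if len(types) < 3:
        raise ValueError(f"need ≥3 residue types in common, got {len(types)}")
    x = np.array([covariate[t] for t in types], float)
    y = np.array([per_type_counts[t] for t in types], float)
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance across residue types")
    return _ols(x, y)


def desolvation_trend(totals: Sequence[float], ph_values: Sequence[float]) -> TrendFit:
    """Least-squares line of total bound waters against pH.

    A positive slope means waters are gained as pH rises — equivalently,
    waters are released upon acidification at that rate per pH unit.
    """
    totals = np.asarray(totals, float)
    ph = np.asarray(ph_values, float)
    if len(totals) != len(ph):
        raise ValueError("totals and pH values must have equal length")
    if len(ph) < 3:
        raise ValueError("need ≥3 conditions for a trend")
    return _ols(ph, totals)


def water_protein_distance_distribution(model: StructureModel,
                                        bin_width: float = 0.1) -> DistanceHistogram:
    """Each water oxygen's distance to the nearest protein heavy atom."""
    waters = model.water_coords()
    prot = model.protein_coords(heavy_only=True)
    if len(waters) == 0 or len(prot) == 0:
        return DistanceHistogram(distances=np.empty(0),
                                 bin_edges=np.array([0.0, bin_width]),
                                 counts=np.zeros(1, int))
    tree = cKDTree(prot)
    d, _ = tree.query(waters, k=1)
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    nbins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(d, bins=nbins, range=(lo, lo + nbins * bin_width))
    return DistanceHistogram(distances=np.sort(d), bin_edges=edges, counts=counts)
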