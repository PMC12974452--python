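"""Hydration-site detection from trajectory water density.

Aligned sampling windows are voxelized: the time-averaged water-oxygen count
per voxel is converted to a mass density (18.015 u per water) in kg/L on a
0.5 Å grid restricted to a 5 Å shell around the protein. The grid is smoothed
with a 7-point face-neighbor stencil, local maxima at or above 6 kg/L are
detected, peaks closer than 1 Å are merged (single-linkage, the
min-samples-1 DBSCAN limit), and each site is assigned the residue that most
often has the closest heavy atom across frames.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .persistence import single_linkage_labels
from .trajectory import TrajectoryWindow, TrajectoryError

#: mass of one water molecule, kg (18.015 u)
WATER_MASS_KG = 18.015 * 1.66053906660e-27
#: Å³ → L
A3_TO_L = 1e-27


@dataclass
class DensityGrid:
    """Voxelized water mass density (kg/L) on a regular grid."""
    origin: np.ndarray
    spacing: float
    values: np.ndarray
    shell_mask: np.ndarray

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.values.shape
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T
        return self.origin + (idx + 0.5) * self.spacing

    def total_mass_kg(self) -> float:
        voxel_volume_l = self.spacing ** 3 * A3_TO_L
        return float(self.values.sum() * voxel_volume_l)


@dataclass
class HydrationSite:
    """A detected water-density peak."""
    position: np.ndarray
    smoothed_density: float
    closest_residue: tuple[str, int, str] | None = None
    occupancy_fraction: float | None = None


def density_from_count(mean_count: float, spacing: float) -> float:
    """Convert a mean water count per voxel to a mass density in kg/L."""
    return mean_count * WATER_MASS_KG / (spacing ** 3 * A3_TO_L)


def accumulate_density(window: TrajectoryWindow, config: AnalysisConfig,
                       apply_shell_mask: bool = True,
                       padding: float | None = None) -> DensityGrid:
    """Accumulate the window's water oxygens into a density grid.

    Per voxel: density = 18.015 u × (mean water-oxygen count per frame) /
    voxel volume, in kg/L. Voxels whose centers lie farther than
    ``shell_cutoff`` from every protein heavy atom (first frame) are zeroed
    unless ``apply_shell_mask`` is false.
    """
    if not window.aligned:
        raise TrajectoryError("window must be aligned before density accumulation")
    spacing = config.grid_spacing
    pad = config.shell_cutoff + spacing if padding is None else padding
    prot = window.protein_coords(0)
    if len(prot) == 0:
        raise TrajectoryError("window has no protein atoms")
    lo = prot.min(axis=0) - pad
    hi = prot.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    counts = np.zeros(shape, dtype=float)
    waters = window.water_coords()  # (n_frames, n_waters, 3)
    if waters.shape[1]:
        flat = waters.reshape(-1, 3)
        idx = np.floor((flat - lo) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        idx = idx[ok]
        lin = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), shape)
        counts += np.bincount(lin, minlength=counts.size).reshape(shape)
    mean_count = counts / window.n_frames
    values = density_from_count(mean_count, spacing)

    centers = lo + (np.indices(shape).reshape(3, -1).T + 0.5) * spacing
    tree = cKDTree(prot)
    d, _ = tree.query(centers, k=1)
    mask = (d <= config.shell_cutoff).reshape(shape)
    if apply_shell_mask:
        values = np.where(mask, values, 0.0)
    return DensityGrid(origin=lo, spacing=spacing, values=values, shell_mask=mask)


def smooth_density(grid: DensityGrid, neighbors: int = 6) -> DensityGrid:
    """Smooth by the unweighted mean of each voxel and its adjacent voxels.

    ``neighbors=6`` uses the face-adjacent stencil (7-point); ``neighbors=18``
    adds the edge-diagonal voxels. Boundary voxels average over existing
    neighbors only, so a uniform grid is a fixed point of the smoother.
    """
    if neighbors == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
    elif neighbors == 18:
        offsets = [(dx, dy, dz)
                   for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                   if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) <= 2]
    else:
        raise ValueError("neighbors must be 6 or 18")
    v = grid.values
    total = v.copy()
    count = np.ones_like(v)
    for off in offsets:
        shifted = np.zeros_like(v)
        present = np.zeros_like(v)
        src = tuple(slice(max(-o, 0), v.shape[i] - max(o, 0)) for i, o in enumerate(off))
        dst = tuple(slice(max(o, 0), v.shape[i] + min(o, 0)) for i, o in enumerate(off))
        shifted[dst] = v[src]
        present[dst] = 1.0
        total += shifted
        count += present
    return DensityGrid(origin=grid.origin, spacing=grid.spacing,
                       values=total / count, shell_mask=grid.shell_mask)


def _local_maxima(values: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of voxels ≥ all 26 neighbors and ≥ threshold (plateaus kept)."""
    footprint = np.ones((3, 3, 3), bool)
    maxfilt = ndimage.maximum_filter(values, footprint=footprint, mode="constant",
                                     cval=-np.inf)
    is_max = (values >= maxfilt) & (values >= threshold)
    return np.argwhere(is_max)


def detect_sites(grid: DensityGrid, config: AnalysisConfig,
                 window: TrajectoryWindow | None = None) -> list[HydrationSite]:
    """Detect hydration sites in a smoothed density grid.

    Local maxima (≥ all 26 neighbors) at or above ``density_threshold`` are
    grouped when closer than ``merge_distance`` and replaced by their
    density-weighted mean position (unweighted with
    ``site_position_weighting='uniform'``); the site density is the maximum
    member density. If a window is supplied, each site's occupancy fraction
    (fraction of frames with a water oxygen within ``residue_cutoff``) is
    computed.
    """
    peaks_idx = _local_maxima(grid.values, config.density_threshold)
    if len(peaks_idx) == 0:
        return []
    positions = grid.origin + (peaks_idx + 0.5) * grid.spacing
    densities = grid.values[tuple(peaks_idx.T)]
    labels = single_linkage_labels(positions, config.merge_distance)
    sites: list[HydrationSite] = []
    for lab in np.unique(labels):
        sel = labels == lab
        pos, dens = positions[sel], densities[sel]
        if config.site_position_weighting == "density":
            center = (pos * dens[:, None]).sum(axis=0) / dens.sum()
        else:
            center = pos.mean(axis=0)
        sites.append(HydrationSite(position=center,
                                   smoothed_density=float(dens.max())))
    sites.sort(key=lambda s: (-s.smoothed_density, tuple(np.round(s.position, 6))))
    if window is not None:
        waters = window.water_coords()
        for s in sites:
            if waters.shape[1] == 0:
                s.occupancy_fraction = 0.0
                continue
            d = np.linalg.norm(waters - s.position, axis=2)
            s.occupancy_fraction = float(
                np.mean((d <= config.residue_cutoff).any(axis=1)))
    return sites


def assign_site_residue(site: HydrationSite, window: TrajectoryWindow,
                        config: AnalysisConfig) -> tuple[str, int, str]:
    """Assign the residue that most often has the closest heavy atom to the
    site across the window's frames; ties go to the lower residue_id."""
    prot_idx = window.protein_indices
    atoms = [window.topology.atoms[i] for i in prot_idx]
    res_keys = [(a.residue_name, a.residue_id, a.chain_id) for a in atoms]
    votes: Counter = Counter()
    for f in range(window.n_frames):
        coords = window.coords[f][prot_idx]
        d = np.linalg.norm(coords - site.position, axis=1)
        votes[res_keys[int(np.argmin(d))]] += 1
    best = max(votes.items(), key=lambda kv: (kv[1], -kv[0][1]))
    site.closest_residue = best[0]
    return best[0]


def merge_window_sites(per_window_sites: Sequence[Sequence[HydrationSite]],
                       merge_distance: float) -> list[HydrationSite]:
    """Combine site lists detected in separate windows.

    Sites from all windows are grouped at ``merge_distance`` (single-linkage);
    each merged site's density is the mean over contributing windows and its
    position the mean of member positions, so the result is independent of
    window order.
    """
    all_sites = [s for sites in per_window_sites for s in sites]
    if not all_sites:
        return []
    pos = np.array([s.position for s in all_sites])
    labels = single_linkage_labels(pos, merge_distance)
    merged = []
    for lab in np.unique(labels):
        members = [all_sites[i] for i in np.flatnonzero(labels == lab)]
        center = np.mean([m.position for m in members], axis=0)
        dens = float(np.mean([m.smoothed_density for m in members]))
        occs = [m.occupancy_fraction for m in members
                if m.occupancy_fraction is not None]
        merged.append(HydrationSite(
            position=center, smoothed_density=dens,
            occupancy_fraction=float(np.mean(occs)) if occs else None))
    merged.sort(key=lambda s: (-s.smoothed_density, tuple(np.round(s.position, 6))))
    return merged
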